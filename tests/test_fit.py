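import numpy as np
import pytest
from sklearn.base import clone

import ghostintro as gi
from ghostintro.fit import fit_scenario, loglik, select_scenario


@pytest.fixture(scope="module")
def study_arrays(study_models):
    """600-locus trio summaries per generating scenario (shared)."""
    return {
        scen: gi.simulate_trio_arrays(m, 600, np.random.default_rng(100 + i))
        for i, (scen, m) in enumerate(study_models.items())
    }


class TestLoglik:
    def test_accepts_trees_and_ignores_outgroup(self, study_models, ghost_trees_small):
        m = study_models["ghost"]
        ll_trees = loglik(m, ghost_trees_small)
        arrays = gi.trees_to_arrays(ghost_trees_small, outgroup="o")
        assert loglik(m, arrays) == pytest.approx(ll_trees)

    def test_locus_order_invariance(self, study_models, study_arrays):
        m = study_models["inflow"]
        topo, t1, t2 = study_arrays["inflow"]
        perm = np.random.default_rng(0).permutation(len(topo))
        assert loglik(m, (topo[perm], t1[perm], t2[perm])) == pytest.approx(
            loglik(m, (topo, t1, t2)), rel=1e-12)

    def test_generating_model_beats_matched_wrong_scenarios(
            self, study_models, study_arrays):
        """Mean per-locus log-likelihood under the generating scenario exceeds
        that under the other two scenarios at matched grid parameters."""
        for truth, arrays in study_arrays.items():
            lls = {scen: loglik(m, arrays) for scen, m in study_models.items()}
            assert max(lls, key=lls.get) == truth
            others = [v for k, v in lls.items() if k != truth]
            assert lls[truth] - max(others) > 10.0

    def test_out_of_support_loci_give_minus_infinity(self, study_models):
        m = study_models["ghost"]
        assert np.isneginf(loglik(m, (np.array([0]), np.array([m.tau_T / 3]),
                                      np.array([m.tau_R]))))

    def test_misordered_ages_rejected(self, study_models):
        with pytest.raises(ValueError):
            loglik(study_models["ghost"], (np.array([0]), np.array([0.2]),
                                           np.array([0.1])))


class TestFitScenario:
    def test_truth_start_contract(self, study_models, study_arrays):
        """The fitted optimum is never worse than the generating parameters."""
        for scen in ("ghost", "outflow"):
            fit = fit_scenario(study_arrays[scen], scen, seed=2, n_restarts=4)
            assert fit.loglik >= loglik(study_models[scen], study_arrays[scen]) - 1e-6
            assert fit.converged

    def test_parameter_recovery_smoke(self, study_models, study_arrays):
        m = study_models["ghost"]
        fit = fit_scenario(study_arrays["ghost"], "ghost", seed=3, n_restarts=4)
        assert fit.estimates["tau_T"] == pytest.approx(m.tau_T, rel=0.05)
        assert fit.estimates["tau_R"] == pytest.approx(m.tau_R, rel=0.05)
        assert fit.estimates["gamma"] == pytest.approx(m.gamma, abs=0.12)
        assert fit.estimates["theta"] == pytest.approx(m.common_theta, rel=0.25)

    def test_tau_h_profiled_and_flagged(self, study_arrays):
        fit = fit_scenario(study_arrays["inflow"], "inflow", seed=4, n_restarts=2)
        assert fit.tau_h_weakly_identified
        assert len(fit.tau_h_profile) == 4  # default coarse grid
        assert all(ll <= fit.loglik + 1e-9 for _, ll in fit.tau_h_profile)

    def test_ghost_fit_has_no_tau_h_profile(self, study_arrays):
        fit = fit_scenario(study_arrays["ghost"], "ghost", seed=5, n_restarts=2)
        assert not fit.tau_h_weakly_identified
        assert fit.tau_h_profile == ()

    def test_free_theta_mode_exposes_ancestral_thetas(self, study_arrays):
        fit = fit_scenario(study_arrays["inflow"], "inflow", seed=6, n_restarts=2,
                           theta_mode="free")
        assert {"theta_T", "theta_R", "theta_C"} <= set(fit.estimates)

    def test_warns_on_few_loci(self, study_arrays):
        topo, t1, t2 = study_arrays["ghost"]
        with pytest.warns(UserWarning, match="loci"):
            fit_scenario((topo[:30], t1[:30], t2[:30]), "ghost", seed=7, n_restarts=1,
                         maxiter=50)


class TestSelection:
    def test_seeded_determinism(self, study_arrays):
        a = select_scenario(study_arrays["outflow"], seed=8, n_restarts=2)
        b = select_scenario(study_arrays["outflow"], seed=8, n_restarts=2)
        assert a.best_scenario == b.best_scenario
        assert a.fits[a.best_scenario].estimates == b.fits[b.best_scenario].estimates

    def test_ranking_consistent_with_logliks(self, study_arrays):
        sel = select_scenario(study_arrays["ghost"], seed=9, n_restarts=2)
        lls = [sel.fits[s].loglik for s in sel.ranking]
        assert lls == sorted(lls, reverse=True)
        assert all(d >= 0 for d in sel.loglik_diffs.values())
        assert sel.loglik_diffs[sel.best_scenario] == 0.0

    def test_msc_data_leaves_scenarios_indistinguishable(self):
        """gamma = 0: the three scenarios coincide, so their maximized
        log-likelihoods agree to within optimization noise."""
        m = gi.from_coalescent_grid("ghost", 0.3, 0.8, 0.0)
        arrays = gi.simulate_trio_arrays(m, 500, np.random.default_rng(55))
        sel = select_scenario(arrays, seed=10, n_restarts=3)
        assert max(sel.loglik_diffs.values()) < 3.0


class TestStatisticalBehavior:
    def test_root_theta_estimated_more_precisely_than_internal_thetas(self):
        """More coalescences happen in R than in T, so theta_R carries more
        information than theta_T in the free-theta fit."""
        m = gi.from_coalescent_grid("ghost", 0.3, 0.5, 0.3)
        err_T, err_R = [], []
        for rep in range(6):
            arrays = gi.simulate_trio_arrays(m, 800, np.random.default_rng(700 + rep))
            fit = fit_scenario(arrays, "ghost", seed=rep, n_restarts=3,
                               theta_mode="free")
            err_T.append(abs(fit.estimates["theta_T"] - m.common_theta))
            err_R.append(abs(fit.estimates["theta_R"] - m.common_theta))
        assert np.mean(err_R) < np.mean(err_T)

    def test_gamma_rmse_shrinks_with_more_loci(self):
        m = gi.from_coalescent_grid("ghost", 0.3, 0.5, 0.3)
        rmse = {}
        for n in (250, 2000):
            errs = []
            for rep in range(5):
                arrays = gi.simulate_trio_arrays(m, n, np.random.default_rng(800 + rep))
                fit = fit_scenario(arrays, "ghost", seed=rep, n_restarts=3)
                errs.append(fit.estimates["gamma"] - m.gamma)
            rmse[n] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[2000] < rmse[250]


class TestEstimators:
    def test_scenario_mle_estimator(self, study_arrays):
        est = gi.ScenarioMLE(scenario="ghost", n_restarts=2, random_state=1)
        assert clone(est).get_params()["scenario"] == "ghost"
        est.fit(study_arrays["ghost"])
        assert est.loglik_ == est.fit_.loglik
        assert est.score(study_arrays["ghost"]) <= est.loglik_ + 1e-9

    def test_selector_estimator(self, study_arrays):
        est = gi.ScenarioSelector(n_restarts=2, random_state=1).fit(study_arrays["inflow"])
        assert est.best_scenario_ == "inflow"
        assert set(est.fits_) == {"ghost", "inflow", "outflow"}
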