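"""Analytic coalescent-time densities: normalization, supports, consistency."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

import ghostintro as gi
from ghostintro.density import PiecewiseExpComponent, PiecewiseExpMixture


def _integral(mix, upper):
    val, _ = quad(lambda s: float(mix.pdf(s)), 0.0, upper, limit=400,
                  points=sorted({c.start for c in mix.components}))
    return val


class TestPiecewiseExponential:
    def test_single_population_is_plain_exponential(self):
        theta = 0.036
        comp = PiecewiseExpComponent(1.0, 0.0, np.array([np.inf]), np.array([2 / theta]))
        mix = PiecewiseExpMixture((comp,))
        t = np.linspace(0, 0.2, 50)
        np.testing.assert_allclose(mix.pdf(t), (2 / theta) * np.exp(-2 * t / theta))
        assert mix.mean() == pytest.approx(theta / 2, rel=1e-6)

    def test_cdf_zero_at_support_start_and_one_at_infinity(self, study_models):
        for m in study_models.values():
            for pair in ("ab", "bc", "ac"):
                mix = gi.pairwise_density(m, pair)
                assert gi.mixture_cdf(mix, mix.support_start) == 0.0
                assert float(gi.mixture_cdf(mix, 50 * m.common_theta)) == pytest.approx(
                    1.0, abs=1e-6)

    def test_density_normalizes(self, study_models):
        for m in study_models.values():
            for pair in ("ab", "bc", "ac"):
                mix = gi.pairwise_density(m, pair)
                assert _integral(mix, 50 * m.common_theta) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_mixture_rejected(self):
        comp = PiecewiseExpComponent(0.5, 0.0, np.array([np.inf]), np.array([1.0]))
        with pytest.raises(ValueError, match="sum to 1"):
            PiecewiseExpMixture((comp,))
        with pytest.raises(ValueError, match="infinity"):
            PiecewiseExpComponent(1.0, 0.0, np.array([1.0]), np.array([1.0]))


class TestSupportOrderings:
    """Minimum coalescence times order differently in each scenario."""

    def test_ghost(self, study_models):
        m = study_models["ghost"]
        s = {p: gi.pairwise_density(m, p).support_start for p in ("ab", "bc", "ac")}
        assert s["ab"] == m.tau_T < s["ac"] == s["bc"] == m.tau_R

    def test_inflow(self, study_models):
        m = study_models["inflow"]
        s = {p: gi.pairwise_density(m, p).support_start for p in ("ab", "bc", "ac")}
        assert s["bc"] == m.tau_H < s["ab"] == m.tau_T < s["ac"] == m.tau_R

    def test_outflow(self, study_models):
        m = study_models["outflow"]
        s = {p: gi.pairwise_density(m, p).support_start for p in ("ab", "bc", "ac")}
        assert s["bc"] == m.tau_H < s["ab"] == s["ac"] == m.tau_T

    def test_ghost_gamma_component_starts_at_the_join(self, study_models):
        m = study_models["ghost"]
        mix = gi.pairwise_density(m, "ab")
        weights = {c.start: c.weight for c in mix.components}
        assert weights[m.tau_G] == pytest.approx(m.gamma)
        assert weights[m.tau_T] == pytest.approx(1 - m.gamma)

    def test_non_recipient_pair_is_a_single_smooth_component(self, study_models):
        smooth_pair = {"ghost": "bc", "inflow": "ac", "outflow": "ab"}
        for scen, m in study_models.items():
            mix = gi.pairwise_density(m, smooth_pair[scen])
            assert len(mix.components) == 1


class TestJointDensity:
    def test_marginal_topologies_match_closed_form(self, study_models):
        for m in study_models.values():
            probs = gi.joint_density(m).topology_probabilities()
            expected = gi.topology_probs(m.gamma, *gi.coalescent_units(m)).as_array()
            np.testing.assert_allclose(probs, expected, atol=1e-12)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_gamma_zero_reduces_to_three_taxon_msc(self):
        """Against the standard MSC closed form, written out independently."""
        m = gi.from_coalescent_grid("inflow", 0.3, 0.8, 0.0)
        theta, tT, tR = m.common_theta, m.tau_T, m.tau_R
        r = 2 / theta
        d = gi.joint_density(m)

        def msc_logpdf(topo, t1, t2):
            if topo == 0 and tT <= t1 < tR:  # a,b coalesce inside T
                return np.log(r) - r * (t1 - tT) + np.log(r) - r * (t2 - tR)
            # otherwise all three enter R: any first pair at rate r, 3 pairs racing
            if t1 < tR:
                return -np.inf
            surv_T = -r * (tR - tT)
            return (surv_T - 3 * r * (t1 - tR) + np.log(r)
                    + np.log(r) - r * (t2 - t1))

        for topo, t1, t2 in [(0, 0.03, 0.06), (0, 0.05, 0.051), (1, 0.045, 0.05),
                             (2, 0.05, 0.12), (1, 0.0405, 0.8)]:
            assert d.logpdf(topo, t1, t2).item() == pytest.approx(
                msc_logpdf(topo, t1, t2), rel=1e-10)

    def test_support_violations_give_zero_density_not_errors(self, study_models):
        m = study_models["ghost"]
        assert np.isneginf(gi.joint_density(m).logpdf(0, m.tau_T / 2, m.tau_R))

    def test_t1_after_t2_rejected(self, study_models):
        with pytest.raises(ValueError, match="t1"):
            gi.joint_density(study_models["ghost"]).logpdf(0, 0.06, 0.03)

    def test_pair_marginal_consistent_with_pairwise_density(self, study_models):
        m = study_models["inflow"]
        d = gi.joint_density(m)
        for pair in ("ab", "bc", "ac"):
            mix = gi.pairwise_density(m, pair)
            for t in (0.02, 0.04, 0.07, 0.12):
                assert d.pair_age_pdf(pair, t) == pytest.approx(
                    float(mix.pdf(t)), abs=1e-6 * max(1.0, float(mix.pdf(t))))

    def test_simulated_ages_match_density(self, study_models):
        rng = np.random.default_rng(99)
        for scen, m in study_models.items():
            topo, t1, t2 = gi.simulate_trio_arrays(m, 10_000, rng)
            for pair in ("ab", "bc"):
                mix = gi.pairwise_density(m, pair)
                ages = gi.pair_ages_from_arrays(pair, topo, t1, t2)
                ks = stats.kstest(ages, lambda x: np.asarray(mix.cdf(x), dtype=float))
                assert ks.pvalue > 0.01, (scen, pair)


class TestDistinguishability:
    def test_matched_scenarios_same_topologies_different_densities(self, matched_models):
        """The central contrast: identical topology probabilities, yet the
        coalescent-time densities separate the three scenarios."""
        probs = [gi.joint_density(m).topology_probabilities()
                 for m in matched_models.values()]
        for p in probs[1:]:
            np.testing.assert_allclose(p, probs[0], atol=1e-12)
        grid = np.linspace(0.0, 0.15, 400)
        pdfs = {scen: np.column_stack([gi.pairwise_density(m, p).pdf(grid)
                                       for p in ("ab", "bc", "ac")])
                for scen, m in matched_models.items()}
        names = list(pdfs)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                sup = np.max(np.abs(pdfs[names[i]] - pdfs[names[j]]))
                assert sup > 1.0, (names[i], names[j])
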