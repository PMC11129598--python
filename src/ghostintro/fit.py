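"""Gene-tree-level maximum likelihood: fit and compare the three scenarios.

Whereas topology counts cannot separate ghost, inflow and outflow, the joint
density of (topology, coalescence ages) can: the support minima and the
mixture structure of the coalescent times differ across scenarios.  This
module maximizes the exact per-locus joint density over the scenario's
parameters (divergence times, theta, gamma) on observed 3-tip clock-rooted
gene trees, and selects the best-fitting scenario by maximized
log-likelihood (all three scenarios have the same number of free
parameters).

The introgression time tau_H enters the likelihood only through the support
boundary of the b-c coalescence (inflow/outflow) and not at all for ghost
(with one sequence per species the ghost population never holds two sampled
lineages), so it is profiled on a coarse grid of fractions of the smallest
observed b-c age rather than freely optimized, and flagged as weakly
identified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .density import GeneTreeDensity
from .model import MSciModel, POPULATIONS, Scenario
from .trees import GeneTree, trees_to_arrays

__all__ = [
    "ScenarioFit",
    "ModelSelection",
    "loglik",
    "fit_scenario",
    "select_scenario",
    "ScenarioMLE",
    "ScenarioSelector",
]

_PENALTY = 1e12
_SCENARIO_ORDER = (Scenario.GHOST, Scenario.INFLOW, Scenario.OUTFLOW)


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(data, tuple) and len(data) == 3:
        topo, t1, t2 = (np.asarray(x) for x in data)
        if np.any(t1 > t2):
            raise ValueError("found a locus with t1 > t2; ages must be ordered")
        return topo.astype(int), t1.astype(float), t2.astype(float)
    trees = list(data)
    if trees and not isinstance(trees[0], GeneTree):
        raise TypeError("expected GeneTree objects or a (topology, t1, t2) tuple")
    labels_present = set(trees[0].tip_labels()) if trees else set()
    outgroup = "o" if "o" in labels_present else None
    return trees_to_arrays(trees, outgroup=outgroup)


def loglik(model: MSciModel, data) -> float:
    """Multilocus log-likelihood of 3-tip gene trees under one model.

    ``data`` is a list of :class:`GeneTree` (outgroup tolerated and ignored)
    or a ``(topology, t1, t2)`` array triple.  Loci outside the model's
    support contribute -inf (reported, not raised).
    """
    topo, t1, t2 = _as_arrays(data)
    return GeneTreeDensity(model).loglik(topo, t1, t2)


@dataclass(frozen=True)
class ScenarioFit:
    """Maximum-likelihood fit of one scenario."""

    scenario: Scenario
    estimates: dict[str, float]
    loglik: float
    converged: bool
    n_restarts: int
    tau_h_profile: tuple[tuple[float, float], ...] = ()
    tau_h_weakly_identified: bool = False

    @property
    def model(self) -> MSciModel:
        return _model_from_estimates(self.scenario, self.estimates)


@dataclass(frozen=True)
class ModelSelection:
    """Fits of all three scenarios on one dataset, ranked by log-likelihood."""

    fits: dict[str, ScenarioFit] = field(repr=False)
    ranking: tuple[str, ...]
    loglik_diffs: dict[str, float]

    @property
    def best_scenario(self) -> str:
        return self.ranking[0]

    @property
    def best_fit(self) -> ScenarioFit:
        return self.fits[self.best_scenario]


# ---------------------------------------------------------------------------
# model construction from free parameters
# ---------------------------------------------------------------------------


def _model_from_estimates(scenario: Scenario, est: dict[str, float]) -> MSciModel:
    theta_common = est["theta"]
    theta = {p: theta_common for p in POPULATIONS}
    for key, val in est.items():
        if key.startswith("theta_"):
            theta[key[6:]] = val
    # the outgroup plays no role in the trio likelihood: tie the ancestral
    # population to R and put tau_O safely above everything
    theta["anc"] = theta["R"]
    top = est.get("tau_G", est["tau_R"])
    tau_O = top + 10.0 * theta_common
    return MSciModel(
        scenario=scenario,
        tau_H=est["tau_H"],
        tau_T=est["tau_T"],
        tau_R=est["tau_R"],
        tau_G=est.get("tau_G"),
        tau_O=tau_O,
        gamma=est["gamma"],
        theta=theta,
    )


class _Parameterization:
    """Transformed (unconstrained) parameter vector for one scenario."""

    def __init__(self, scenario: Scenario, theta_mode: str, tau_H: float | None):
        self.scenario = scenario
        self.theta_mode = theta_mode
        self.tau_H = tau_H  # fixed (profiled) for inflow/outflow, None for ghost
        names = []
        if scenario is Scenario.GHOST:
            names += ["log_tau_T", "log_gap_RT", "log_gap_GR"]
        else:
            names += ["log_gap_HT", "log_gap_RT"]
        names += ["log_theta"]
        if theta_mode == "free":
            names += ["log_theta_T", "log_theta_R"]
            if scenario is Scenario.INFLOW:
                names += ["log_theta_C"]
            elif scenario is Scenario.OUTFLOW:
                names += ["log_theta_B"]
        names += ["logit_gamma"]
        self.names = names

    @property
    def dim(self) -> int:
        return len(self.names)

    def to_estimates(self, v: np.ndarray) -> dict[str, float]:
        # overflow to inf is fine: the resulting model is rejected by the
        # penalty in the objective
        with np.errstate(over="ignore"):
            return self._to_estimates(v)

    def _to_estimates(self, v: np.ndarray) -> dict[str, float]:
        d = dict(zip(self.names, v))
        est: dict[str, float] = {}
        if self.scenario is Scenario.GHOST:
            est["tau_T"] = np.exp(d["log_tau_T"])
            est["tau_H"] = est["tau_T"] / 2.0  # nuisance: no effect on the density
            est["tau_R"] = est["tau_T"] + np.exp(d["log_gap_RT"])
            est["tau_G"] = est["tau_R"] + np.exp(d["log_gap_GR"])
        else:
            assert self.tau_H is not None
            est["tau_H"] = self.tau_H
            est["tau_T"] = self.tau_H + np.exp(d["log_gap_HT"])
            est["tau_R"] = est["tau_T"] + np.exp(d["log_gap_RT"])
        est["theta"] = np.exp(d["log_theta"])
        for name in ("T", "R", "C", "B"):
            key = f"log_theta_{name}"
            if key in d:
                est[f"theta_{name}"] = np.exp(d[key])
        est["gamma"] = 1.0 / (1.0 + np.exp(-d["logit_gamma"]))
        return est

    def from_estimates(self, est: dict[str, float]) -> np.ndarray:
        v = []
        for name in self.names:
            if name == "log_tau_T":
                v.append(np.log(est["tau_T"]))
            elif name == "log_gap_HT":
                v.append(np.log(est["tau_T"] - est["tau_H"]))
            elif name == "log_gap_RT":
                v.append(np.log(est["tau_R"] - est["tau_T"]))
            elif name == "log_gap_GR":
                v.append(np.log(est["tau_G"] - est["tau_R"]))
            elif name == "log_theta":
                v.append(np.log(est["theta"]))
            elif name.startswith("log_theta_"):
                v.append(np.log(est.get("theta_" + name[10:], est["theta"])))
            elif name == "logit_gamma":
                g = np.clip(est["gamma"], 1e-4, 1.0 - 1e-4)
                v.append(np.log(g / (1.0 - g)))
        return np.array(v)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _moment_start(scenario: Scenario, topo, t1, t2, tau_H: float | None) -> dict[str, float]:
    """Support-aware initial values from simple summaries of the gene trees."""
    m_ab = float(np.where(topo == 0, t1, t2).min())
    m_bc = float(np.where(topo == 1, t1, t2).min())
    m_ac = float(np.where(topo == 2, t1, t2).min())
    theta0 = float(np.clip(2.0 * np.mean(t2 - t1), 1e-4, 0.5))
    freqs = np.array([(topo == k).mean() for k in range(3)])
    lo, hi = freqs[1] - freqs[2], 1.0 - (freqs[0] - freqs[2])
    gamma0 = float(np.clip((lo + hi) / 2.0, 0.05, 0.95))
    est: dict[str, float] = {"theta": theta0, "gamma": gamma0}
    if scenario is Scenario.GHOST:
        est["tau_T"] = 0.95 * m_ab
        est["tau_R"] = max(0.97 * min(m_ac, m_bc), 1.001 * est["tau_T"])
        est["tau_G"] = est["tau_R"] + theta0 / 2.0
        est["tau_H"] = est["tau_T"] / 2.0
    else:
        assert tau_H is not None
        est["tau_H"] = tau_H
        if scenario is Scenario.INFLOW:
            est["tau_T"] = max(0.95 * m_ab, 1.02 * tau_H)
            est["tau_R"] = max(0.97 * m_ac, 1.001 * est["tau_T"])
        else:
            est["tau_T"] = max(0.95 * min(m_ab, m_ac), 1.02 * tau_H)
            est["tau_R"] = est["tau_T"] + theta0 / 2.0
    return est


def _tau_h_grid(scenario: Scenario, topo, t1, t2, fractions) -> list[float]:
    m_bc = float(np.where(topo == 1, t1, t2).min())
    m_ab = float(np.where(topo == 0, t1, t2).min())
    m_ac = float(np.where(topo == 2, t1, t2).min())
    if scenario is Scenario.INFLOW:
        cap = min(m_bc, 0.95 * m_ab)
    else:  # OUTFLOW: tau_H < tau_T <= min(m_ab, m_ac)
        cap = min(m_bc, 0.95 * min(m_ab, m_ac))
    return [float(f * cap) for f in fractions]


def _negloglik_factory(param: _Parameterization, topo, t1, t2):
    def neg(v: np.ndarray) -> float:
        try:
            est = param.to_estimates(v)
            model = _model_from_estimates(param.scenario, est)
        except (ValueError, OverflowError, FloatingPointError):
            return _PENALTY
        ll = GeneTreeDensity(model).loglik(topo, t1, t2)
        if not np.isfinite(ll):
            return _PENALTY
        return -ll

    return neg


def fit_scenario(
    data,
    scenario: Scenario | str,
    seed: int | None = 0,
    n_restarts: int = 8,
    theta_mode: str = "common",
    tau_h_fractions=(0.5, 0.75, 0.9, 0.98),
    maxiter: int = 400,
) -> ScenarioFit:
    """Maximize the gene-tree likelihood of one scenario (multi-start).

    Optimization runs Nelder-Mead on log/logit-transformed parameters (the
    likelihood is only piecewise-smooth because divergence times are support
    boundaries), from a moment-based start plus Latin-hypercube restarts;
    tau_H (inflow/outflow) is profiled over ``tau_h_fractions`` of the
    smallest observed b-c coalescence age.  Deterministic given ``seed``.
    """
    scenario = Scenario.coerce(scenario)
    if theta_mode not in ("common", "free"):
        raise ValueError("theta_mode must be 'common' or 'free'")
    topo, t1, t2 = _as_arrays(data)
    if len(topo) < 50:
        warnings.warn(f"only {len(topo)} loci; scenario fits are unreliable below ~50")
    rng = np.random.default_rng(seed)

    if scenario is Scenario.GHOST:
        tau_hs: list[float | None] = [None]
    else:
        tau_hs = list(_tau_h_grid(scenario, topo, t1, t2, tau_h_fractions))

    best: tuple[float, dict[str, float], bool] | None = None
    profile: list[tuple[float, float]] = []
    warm: np.ndarray | None = None
    for j, tau_h in enumerate(tau_hs):
        param = _Parameterization(scenario, theta_mode, tau_h)
        neg = _negloglik_factory(param, topo, t1, t2)
        center = param.from_estimates(_moment_start(scenario, topo, t1, t2, tau_h))
        starts = [center]
        if warm is not None:
            w = warm.copy()
            # re-anchor the first gap so tau_T stays put across the tau_H grid
            if scenario is not Scenario.GHOST:
                prev_tau_T = tau_hs[j - 1] + np.exp(warm[0])
                if prev_tau_T > tau_h:
                    w[0] = np.log(prev_tau_T - tau_h)
            starts.append(w)
        n_extra = max(n_restarts - len(starts), 0) if j == 0 else 0
        if n_extra:
            sampler = qmc.LatinHypercube(d=param.dim, seed=rng.integers(2**31 - 1))
            jitter = (sampler.random(n_extra) - 0.5) * 3.0
            starts += [center + row for row in jitter]
        local_best = None
        for s in starts:
            res = minimize(neg, s, method="Nelder-Mead",
                           options=dict(maxiter=maxiter, xatol=1e-8, fatol=1e-9))
            if local_best is None or res.fun < local_best[0]:
                local_best = (res.fun, res.x, bool(res.success))
        assert local_best is not None
        fun, x, ok = local_best
        # Nelder-Mead stalls on narrow curved valleys; restarting the simplex
        # from the incumbent until no further gain is the standard remedy.
        ok = False
        for _ in range(6):
            res = minimize(neg, x, method="Nelder-Mead",
                           options=dict(maxiter=maxiter, xatol=1e-8, fatol=1e-9))
            improved = fun - res.fun
            if res.fun < fun:
                fun, x = res.fun, res.x
            if improved < 1e-7:
                ok = True  # the incumbent is stable under simplex restarts
                break
        warm = x
        if tau_h is not None:
            profile.append((tau_h, -fun))
        est = param.to_estimates(x)
        if best is None or fun < best[0]:
            best = (fun, est, ok)

    assert best is not None
    fun, est, ok = best
    return ScenarioFit(
        scenario=scenario,
        estimates={k: float(v) for k, v in est.items()},
        loglik=float(-fun),
        converged=ok and fun < _PENALTY / 2,
        n_restarts=n_restarts,
        tau_h_profile=tuple(profile),
        tau_h_weakly_identified=scenario is not Scenario.GHOST,
    )


def select_scenario(
    data, seed: int | None = 0, n_restarts: int = 8, theta_mode: str = "common",
    **kwargs,
) -> ModelSelection:
    """Fit all three scenarios and rank them by maximized log-likelihood.

    The scenarios have equal numbers of free parameters, so the maximized
    log-likelihoods are directly comparable.  Deterministic given ``seed``.
    """
    topo, t1, t2 = _as_arrays(data)
    fits = {}
    for k, scen in enumerate(_SCENARIO_ORDER):
        fit_seed = None if seed is None else seed + 7919 * k
        fits[scen.value] = fit_scenario(
            (topo, t1, t2), scen, seed=fit_seed, n_restarts=n_restarts,
            theta_mode=theta_mode, **kwargs,
        )
    ranking = tuple(sorted(fits, key=lambda s: fits[s].loglik, reverse=True))
    best_ll = fits[ranking[0]].loglik
    diffs = {s: float(best_ll - fits[s].loglik) for s in fits}
    return ModelSelection(fits=fits, ranking=ranking, loglik_diffs=diffs)


# ---------------------------------------------------------------------------
# estimator front-ends
# ---------------------------------------------------------------------------


class ScenarioMLE(BaseEstimator):
    """Maximum-likelihood fit of a single introgression scenario.

    Attributes (after :meth:`fit`): ``fit_`` (:class:`ScenarioFit`),
    ``estimates_``, ``loglik_``, ``converged_``.
    """

    def __init__(self, scenario: str = "ghost", n_restarts: int = 8,
                 theta_mode: str = "common", random_state: int | None = 0,
                 tau_h_fractions=(0.5, 0.75, 0.9, 0.98), maxiter: int = 400) -> None:
        self.scenario = scenario
        self.n_restarts = n_restarts
        self.theta_mode = theta_mode
        self.random_state = random_state
        self.tau_h_fractions = tau_h_fractions
        self.maxiter = maxiter

    def fit(self, X, y=None) -> "ScenarioMLE":
        self.fit_ = fit_scenario(
            X, self.scenario, seed=self.random_state, n_restarts=self.n_restarts,
            theta_mode=self.theta_mode, tau_h_fractions=self.tau_h_fractions,
            maxiter=self.maxiter,
        )
        self.estimates_ = self.fit_.estimates
        self.loglik_ = self.fit_.loglik
        self.converged_ = self.fit_.converged
        return self

    def score(self, X, y=None) -> float:
        """Log-likelihood of held-out gene trees under the fitted model."""
        return loglik(self.fit_.model, X)


class ScenarioSelector(BaseEstimator):
    """Fit ghost/inflow/outflow and select the best by log-likelihood.

    Attributes (after :meth:`fit`): ``selection_`` (:class:`ModelSelection`),
    ``best_scenario_``, ``ranking_``, ``loglik_diffs_``, ``fits_``.
    """

    def __init__(self, n_restarts: int = 8, theta_mode: str = "common",
                 random_state: int | None = 0, maxiter: int = 400) -> None:
        self.n_restarts = n_restarts
        self.theta_mode = theta_mode
        self.random_state = random_state
        self.maxiter = maxiter

    def fit(self, X, y=None) -> "ScenarioSelector":
        self.selection_ = select_scenario(
            X, seed=self.random_state, n_restarts=self.n_restarts,
            theta_mode=self.theta_mode, maxiter=self.maxiter,
        )
        self.best_scenario_ = self.selection_.best_scenario
        self.ranking_ = self.selection_.ranking
        self.loglik_diffs_ = self.selection_.loglik_diffs
        self.fits_ = self.selection_.fits
        return self
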