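"""Topology-count inference: the pseudo-likelihood analog for a trio.

Counting only the rooted-triple topologies of the gene trees gives a
multinomial likelihood whose probabilities depend on (gamma, C_T, C_S)
through just two free contrasts, so the likelihood surface has a ridge: for
every gamma in the open interval

    (p2_hat - p3_hat,  1 - (p1_hat - p3_hat))

there exist (C_T, C_S) reproducing the observed frequencies exactly, and the
maximized log-likelihood is constant on that interval.  The profile over
gamma computed here exhibits the ridge; the flat region is the plug-in
version of the gamma bounds, and the scenario label (ghost / inflow /
outflow) never enters the likelihood at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .trees import GeneTree, trees_to_arrays

__all__ = [
    "TopologyCounts",
    "RidgeProfile",
    "count_topologies",
    "fit_multinomial",
    "multinomial_loglik",
    "scenario_logliks",
    "TopologyRidgeEstimator",
]

_CU_CAP = 50.0  # coalescent-unit cap standing in for infinity
_EMIN = np.exp(-_CU_CAP)


@dataclass(frozen=True)
class TopologyCounts:
    """Counts of the rooted triples n1 = ab|c, n2 = a|bc, n3 = ac|b."""

    n1: int
    n2: int
    n3: int

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.n3) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_total(self) -> int:
        return self.n1 + self.n2 + self.n3

    def as_array(self) -> np.ndarray:
        return np.array([self.n1, self.n2, self.n3], dtype=float)

    @property
    def frequencies(self) -> np.ndarray:
        return self.as_array() / self.n_total


def count_topologies(
    trees: list[GeneTree], outgroup: str = "o", labels=("a", "b", "c")
) -> TopologyCounts:
    """Classify each gene tree's rooted triple after outgroup removal.

    Trees are clock-rooted, so rerooting on the outgroup and pruning it is
    the restriction to the ingroup tips; ages break zero-length ties.
    """
    topo, _, _ = trees_to_arrays(trees, labels=labels, outgroup=outgroup)
    return TopologyCounts(*(int((topo == k).sum()) for k in range(3)))


def _probs(gamma: float, eT, eS) -> np.ndarray:
    p3 = ((1.0 - gamma) * eT + gamma * eS) / 3.0
    p1 = (1.0 - gamma) * (1.0 - eT) + p3
    p2 = gamma * (1.0 - eS) + p3
    return np.array([p1, p2, p3])


def multinomial_loglik(counts: TopologyCounts, gamma: float, C_T: float, C_S: float) -> float:
    """Multinomial log-likelihood of the counts at (gamma, C_T, C_S)."""
    n = counts.as_array()
    p = _probs(gamma, np.exp(-C_T), np.exp(-C_S))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > 0, n * np.log(p), 0.0)
    return float(np.sum(terms)) if np.all(p[n > 0] > 0) else -np.inf


def _profile_at_gamma(counts: TopologyCounts, gamma: float) -> float:
    """Max over (C_T, C_S) in [0, cap]^2 of the multinomial log-likelihood."""
    n = counts.as_array()
    N = counts.n_total
    phat = n / N
    # closed form when the observed frequencies are attainable at this gamma
    if 0.0 < gamma < 1.0:
        xT = 1.0 - (phat[0] - phat[2]) / (1.0 - gamma)  # e^{-C_T}
        xS = 1.0 - (phat[1] - phat[2]) / gamma  # e^{-C_S}
        if _EMIN <= xT <= 1.0 and _EMIN <= xS <= 1.0:
            with np.errstate(divide="ignore"):
                return float(np.sum(np.where(n > 0, n * np.log(phat), 0.0)))

    def neg(v: np.ndarray) -> float:
        eT = 1.0 / (1.0 + np.exp(-v[0]))
        eS = 1.0 / (1.0 + np.exp(-v[1]))
        p = _probs(gamma, eT, eS)
        if np.any(p <= 0):
            return 1e12
        with np.errstate(divide="ignore"):
            return -float(np.sum(np.where(n > 0, n * np.log(p), 0.0)))

    best = np.inf
    for start in ([0.0, 0.0], [3.0, -3.0], [-3.0, 3.0], [-5.0, -5.0]):
        res = minimize(neg, np.array(start), method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-12, maxiter=2000))
        best = min(best, res.fun)
    return -best


@dataclass(frozen=True)
class RidgeProfile:
    """Profile log-likelihood over gamma with its flat (ridge) interval."""

    gamma_grid: np.ndarray
    loglik: np.ndarray
    flat_interval: tuple[float, float]
    max_loglik: float
    counts: TopologyCounts

    def sample_point_estimate(self, rng: np.random.Generator | int | None = None) -> float:
        """A gamma drawn uniformly from the flat region, emulating the
        arbitrary point output of a pseudo-likelihood network search."""
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        lo, hi = self.flat_interval
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def fit_multinomial(counts: TopologyCounts, gamma_grid_size: int = 101) -> RidgeProfile:
    """Profile the multinomial likelihood over gamma.

    The flat region is the plug-in unidentifiability interval
    (p2_hat - p3_hat, 1 - (p1_hat - p3_hat)) clipped to [0, 1]; on its
    interior the profile equals the saturated log-likelihood.  Degenerate
    counts (n3 >= min(n1, n2)) can make the interval empty, in which case
    the numerically profiled maximum (a boundary solution) is reported and
    the interval collapses to the profile's argmax.
    """
    if counts.n_total < 1:
        raise ValueError("need at least one counted gene tree")
    phat = counts.frequencies
    lo = float(np.clip(phat[1] - phat[2], 0.0, 1.0))
    hi = float(np.clip(1.0 - (phat[0] - phat[2]), 0.0, 1.0))
    grid = np.linspace(1e-6, 1.0 - 1e-6, gamma_grid_size)
    prof = np.array([_profile_at_gamma(counts, g) for g in grid])
    max_ll = float(prof.max())
    # the plug-in interval is the ridge only if the observed frequencies are
    # attainable there (requires p3_hat <= min(p1_hat, p2_hat))
    attainable = hi > lo and phat[2] <= min(phat[0], phat[1])
    if attainable:
        interval = (lo, hi)
    else:
        near = grid[prof >= max_ll - 1e-6]
        interval = (float(near.min()), float(near.max())) if len(near) else \
            (float(grid[int(np.argmax(prof))]),) * 2
    return RidgeProfile(
        gamma_grid=grid, loglik=prof, flat_interval=interval,
        max_loglik=max_ll, counts=counts,
    )


def scenario_logliks(counts: TopologyCounts) -> dict[str, float]:
    """Maximized topology-count log-likelihood under each scenario label.

    The three labels share the same likelihood function of (gamma, C_T,
    C_S), so the values coincide -- the non-identifiability exhibited by
    topology-only network inference.  Each maximization is run
    independently.
    """
    out = {}
    for label in ("ghost", "inflow", "outflow"):
        prof = fit_multinomial(counts, gamma_grid_size=21)
        out[label] = prof.max_loglik
    return out


class TopologyRidgeEstimator(BaseEstimator):
    """Multinomial topology-count fit exposing the gamma ridge.

    Attributes (after :meth:`fit`)
    ------------------------------
    counts_ : TopologyCounts
    profile_ : RidgeProfile
    flat_region_ : (low, high) gamma interval of constant maximized likelihood
    gamma_point_ : a uniform draw from the flat region (seeded)
    max_loglik_ : float
    """

    def __init__(self, outgroup: str = "o", labels=("a", "b", "c"),
                 gamma_grid_size: int = 101, random_state: int | None = 0) -> None:
        self.outgroup = outgroup
        self.labels = labels
        self.gamma_grid_size = gamma_grid_size
        self.random_state = random_state

    def fit(self, X, y=None) -> "TopologyRidgeEstimator":
        if isinstance(X, TopologyCounts):
            counts = X
        else:
            counts = count_topologies(list(X), outgroup=self.outgroup, labels=self.labels)
        self.counts_ = counts
        self.profile_ = fit_multinomial(counts, gamma_grid_size=self.gamma_grid_size)
        self.flat_region_ = self.profile_.flat_interval
        self.max_loglik_ = self.profile_.max_loglik
        self.gamma_point_ = self.profile_.sample_point_estimate(
            np.random.default_rng(self.random_state)
        )
        return self
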