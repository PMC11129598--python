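"""Analytic coalescent-time distributions under the three MSci scenarios.

Two objects are provided:

* :func:`pairwise_density` -- the first-coalescence time of one sequence pair
  (t_ab, t_bc or t_ac), a mixture of piecewise-exponential components, one per
  introgression path of the recipient lineage.  These are the curves whose
  support minima and discontinuities distinguish the scenarios.
* :func:`joint_density` -- the joint density of (rooted-triple topology,
  first coalescence age t1, second coalescence age t2) for one sequence per
  species, which is the per-locus likelihood used by the full-likelihood
  fitter.

Both are assembled from the same lineage itineraries as the simulator, so the
constructions are forced by the MSci process rather than transcribed formulas.
Densities are evaluated in log space; piecewise boundaries are half-open
[start, end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .model import MSciModel
from .process import PAIR_INDEX, pair_rate_tables

__all__ = [
    "PiecewiseExpComponent",
    "PiecewiseExpMixture",
    "pairwise_density",
    "mixture_pdf",
    "mixture_cdf",
    "GeneTreeDensity",
    "joint_density",
]


@dataclass(frozen=True)
class PiecewiseExpComponent:
    """One first-passage component: hazard `rates[i]` on [bounds[i-1], bounds[i]).

    ``bounds[-1]`` is +inf; the support starts at ``start`` (bounds[-1-len]
    convention: segment i spans [prev, bounds[i]) with prev = start for i=0).
    """

    weight: float
    start: float
    bounds: np.ndarray  # segment end times, strictly increasing, last = inf
    rates: np.ndarray  # hazard per segment, same length as bounds

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if b.shape != r.shape or b.ndim != 1 or len(b) == 0:
            raise ValueError("bounds and rates must be 1-D arrays of equal length")
        if not np.isinf(b[-1]):
            raise ValueError("last segment must extend to infinity")
        if np.any(r < 0) or self.weight < 0:
            raise ValueError("rates and weight must be nonnegative")
        object.__setattr__(self, "bounds", b)
        object.__setattr__(self, "rates", r)

    def _starts(self) -> np.ndarray:
        return np.concatenate([[self.start], self.bounds[:-1]])

    def cumulative_hazard(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        starts = self._starts()
        cum = np.concatenate([[0.0], np.cumsum(self.rates[:-1] * np.diff(starts))]) \
            if len(self.rates) > 1 else np.array([0.0])
        # cum[i] = hazard accumulated at the start of segment i
        idx = np.clip(np.searchsorted(self.bounds, t, side="right"), 0, len(self.rates) - 1)
        h = cum[idx] + self.rates[idx] * (t - starts[idx])
        return np.where(t <= self.start, 0.0, h)

    def pdf(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        starts = self._starts()
        idx = np.clip(np.searchsorted(self.bounds, t, side="right"), 0, len(self.rates) - 1)
        rate = self.rates[idx]
        out = rate * np.exp(-self.cumulative_hazard(t))
        return np.where(t < self.start, 0.0, out)

    def cdf(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = 1.0 - np.exp(-self.cumulative_hazard(t))
        return np.where(t <= self.start, 0.0, out)

    def total_mass(self) -> float:
        """Probability that coalescence eventually happens (1 if the terminal
        rate is positive)."""
        return 1.0 if self.rates[-1] > 0 else float(self.cdf(self.bounds[-2]))


@dataclass(frozen=True)
class PiecewiseExpMixture:
    """Mixture of piecewise-exponential first-coalescence densities."""

    components: tuple[PiecewiseExpComponent, ...]

    def __post_init__(self) -> None:
        w = sum(c.weight for c in self.components)
        if not np.isclose(w, 1.0, atol=1e-9):
            raise ValueError(f"component weights must sum to 1, got {w}")

    @property
    def support_start(self) -> float:
        return min(c.start for c in self.components if c.weight > 0)

    def pdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum(c.weight * c.pdf(t) for c in self.components)

    def cdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum(c.weight * c.cdf(t) for c in self.components)

    def mean(self) -> float:
        upper = max(c.bounds[-2] if len(c.bounds) > 1 else c.start for c in self.components)
        scale = max(1.0 / min(c.rates[-1] for c in self.components), 1e-3)
        hi = upper + 60.0 * scale
        val, _ = quad(lambda s: s * float(self.pdf(s)), self.support_start, hi, limit=400)
        return val


def mixture_pdf(mix: PiecewiseExpMixture, t) -> np.ndarray:
    """Density of the first-coalescence time at t (t >= 0)."""
    return mix.pdf(t)


def mixture_cdf(mix: PiecewiseExpMixture, t) -> np.ndarray:
    """P(first coalescence <= t)."""
    return mix.cdf(t)


def _component_for_pair(model: MSciModel, pair_idx: int, jumped: bool, weight: float):
    breaks, r3, _ = pair_rate_tables(model, jumped)
    rates = r3[pair_idx]
    pos = np.nonzero(rates > 0)[0]
    if len(pos) == 0:  # pragma: no cover - cannot happen: everything merges
        raise RuntimeError("pair never cohabits")
    k0 = pos[0]
    start = breaks[k0]
    bounds = np.concatenate([breaks[k0 + 1:], [np.inf]])
    return PiecewiseExpComponent(weight=weight, start=start, bounds=bounds, rates=rates[k0:])


def pairwise_density(model: MSciModel, pair: str) -> PiecewiseExpMixture:
    """First-coalescence density of a sequence pair ('ab', 'bc' or 'ac').

    The mixture has one component per introgression path of the recipient
    lineage (weights 1-gamma and gamma); when the pair does not involve the
    recipient the two paths coincide and a single smooth component is
    returned.
    """
    key = frozenset(pair)
    if key not in PAIR_INDEX:
        raise ValueError(f"pair must be one of 'ab', 'bc', 'ac', got {pair!r}")
    p = PAIR_INDEX[key]
    comps = []
    for jumped, w in ((False, 1.0 - model.gamma), (True, model.gamma)):
        if w == 0.0:
            continue
        comps.append(_component_for_pair(model, p, jumped, w))
    # merge identical components (pair not involving the recipient)
    if len(comps) == 2 and comps[0].start == comps[1].start and \
            np.array_equal(comps[0].bounds, comps[1].bounds) and \
            np.array_equal(comps[0].rates, comps[1].rates):
        comps = [PiecewiseExpComponent(1.0, comps[0].start, comps[0].bounds, comps[0].rates)]
    return PiecewiseExpMixture(tuple(comps))


class GeneTreeDensity:
    """Joint density of (rooted-triple topology, t1, t2) for one locus.

    Topologies are indexed 0 = ab|c, 1 = a|bc, 2 = ac|b; t1 < t2 are the two
    coalescence ages of the trio.  The density marginalizes nothing: it is the
    exact per-locus likelihood of a 3-tip clock-rooted gene tree under the
    model, obtained by summing over the recipient lineage's two introgression
    paths.
    """

    def __init__(self, model: MSciModel) -> None:
        self.model = model
        self._paths = []
        for jumped, w in ((False, 1.0 - model.gamma), (True, model.gamma)):
            if w == 0.0:
                continue
            breaks, r3, r2 = pair_rate_tables(model, jumped)
            widths = np.diff(breaks)
            R3 = r3.sum(axis=0)
            cum3 = np.concatenate([[0.0], np.cumsum(R3[:-1] * widths)])
            cum2 = np.concatenate(
                [np.zeros((3, 1)), np.cumsum(r2[:, :-1] * widths, axis=1)], axis=1
            )
            self._paths.append(
                dict(logw=np.log(w), breaks=breaks, r3=r3, R3=R3, cum3=cum3, r2=r2, cum2=cum2)
            )

    # -- evaluation ----------------------------------------------------------

    def logpdf(self, topology, t1, t2) -> np.ndarray:
        """Vectorized log density; -inf outside the support."""
        topo = np.atleast_1d(np.asarray(topology, dtype=int))
        t1 = np.atleast_1d(np.asarray(t1, dtype=float))
        t2 = np.atleast_1d(np.asarray(t2, dtype=float))
        if np.any(t1 < 0) or np.any(t2 < t1):
            raise ValueError("require 0 <= t1 <= t2 for every locus")
        if np.any((topo < 0) | (topo > 2)):
            raise ValueError("topology index must be 0 (ab|c), 1 (a|bc) or 2 (ac|b)")
        total = np.full(t1.shape, -np.inf)
        with np.errstate(divide="ignore"):
            for path in self._paths:
                breaks = path["breaks"]
                k1 = np.searchsorted(breaks, t1, side="right") - 1
                k2 = np.searchsorted(breaks, t2, side="right") - 1
                lam1 = path["cum3"][k1] + path["R3"][k1] * (t1 - breaks[k1])
                rate1 = path["r3"][topo, k1]
                h2_t1 = path["cum2"][topo, k1] + path["r2"][topo, k1] * (t1 - breaks[k1])
                h2_t2 = path["cum2"][topo, k2] + path["r2"][topo, k2] * (t2 - breaks[k2])
                rate2 = path["r2"][topo, k2]
                logf = (
                    path["logw"]
                    + np.log(rate1)
                    - lam1
                    + np.log(rate2)
                    - (h2_t2 - h2_t1)
                )
                total = np.logaddexp(total, logf)
        return total

    def loglik(self, topology, t1, t2) -> float:
        """Sum of per-locus log densities (the multilocus log-likelihood)."""
        return float(np.sum(self.logpdf(topology, t1, t2)))

    # -- marginals -----------------------------------------------------------

    def topology_probabilities(self) -> np.ndarray:
        """Exact (closed-form) marginal probabilities of the three topologies.

        Integrates the first-coalescence density over each interval; since the
        terminal population always absorbs the remaining pair, the second
        coalescence integrates to one.
        """
        probs = np.zeros(3)
        for path in self._paths:
            breaks, r3, R3, cum3 = path["breaks"], path["r3"], path["R3"], path["cum3"]
            widths = np.concatenate([np.diff(breaks), [np.inf]])
            w = np.exp(path["logw"])
            for k in range(len(breaks)):
                if R3[k] <= 0:
                    continue
                seg = np.exp(-cum3[k]) * (-np.expm1(-R3[k] * widths[k])) / R3[k]
                probs += w * r3[:, k] * seg
        return probs

    def pair_age_pdf(self, pair: str, t: float) -> float:
        """Marginal density of one pair's MRCA age (numerical; for validation).

        The pair's age equals t1 when that pair coalesces first and t2
        otherwise, so the marginal mixes a direct first-coalescence term with
        integrals over the other two topologies.
        """
        p = PAIR_INDEX[frozenset(pair)]
        total = 0.0
        for path in self._paths:
            breaks, r3, R3 = path["breaks"], path["r3"], path["R3"]
            cum3, r2, cum2 = path["cum3"], path["r2"], path["cum2"]
            w = np.exp(path["logw"])

            def f3(s, q):  # density of "pair q coalesces first at s"
                k = min(np.searchsorted(breaks, s, side="right") - 1, len(breaks) - 1)
                lam = cum3[k] + R3[k] * (s - breaks[k])
                return r3[q, k] * np.exp(-lam)

            def h2(s, q):
                k = min(np.searchsorted(breaks, s, side="right") - 1, len(breaks) - 1)
                return cum2[q, k] + r2[q, k] * (s - breaks[k]), r2[q, k]

            total += w * f3(t, p)
            for q in range(3):
                if q == p:
                    continue
                h2_t, rate2_t = h2(t, q)
                if rate2_t == 0:
                    continue

                def integrand(s):
                    h2_s, _ = h2(s, q)
                    return f3(s, q) * rate2_t * np.exp(-(h2_t - h2_s))

                val, _ = quad(integrand, 0.0, t, limit=200,
                              points=[b for b in breaks if 0 < b < t])
                total += w * val
        return float(total)


def joint_density(model: MSciModel) -> GeneTreeDensity:
    """The joint gene-tree density (topology, t1, t2) for one sequence per
    species; see :class:`GeneTreeDensity`."""
    return GeneTreeDensity(model)
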