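"""Closed-form identifiability results for the three introgression scenarios.

All quantities depend on the scenario geometry only through the internal
branch lengths of the speciation history (l_T, or C_T = 2 l_T / theta in
coalescent units) and of the introgressed history (l_S, C_S), plus the
introgression probability gamma.  That is the crux of the non-identifiability:
ghost, inflow and outflow models matched on (gamma, C_T, C_S) generate
identical gene-tree topology frequencies and identical site-pattern
frequencies, so methods using only those summaries cannot tell them apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MSciModel, coalescent_units, internal_branch_lengths

__all__ = [
    "TopologyProbs",
    "SitePatternFreqs",
    "topology_probs",
    "gamma_bounds_mpl",
    "site_pattern_freqs",
    "gamma_hyde_expected",
    "hyde_detectability",
    "topology_probs_of_model",
]


@dataclass(frozen=True)
class TopologyProbs:
    """Probabilities of the rooted-triple gene trees G1=ab|c, G2=a|bc, G3=ac|b."""

    p1: float
    p2: float
    p3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3])


@dataclass(frozen=True)
class SitePatternFreqs:
    """Per-site frequencies of the parsimony-informative biallelic patterns
    for taxon order (A, B, C, outgroup), outgroup carrying the ancestral state."""

    f_BBAA: float
    f_ABBA: float
    f_BABA: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_BBAA, self.f_ABBA, self.f_BABA])


def topology_probs(gamma: float, C_T: float, C_S: float) -> TopologyProbs:
    """Rooted-triple probabilities under any of the three scenarios.

    With probability 1-gamma the locus follows the speciation history and the
    a-b pair coalesces within its internal branch with probability
    1 - exp(-C_T); with probability gamma it follows the introgressed history
    and b-c coalesces with probability 1 - exp(-C_S); otherwise deep
    coalescence makes the three topologies equally likely:

        P(G3) = (1-gamma) e^{-C_T}/3 + gamma e^{-C_S}/3
        P(G1) = (1-gamma)(1 - e^{-C_T}) + P(G3)
        P(G2) = gamma (1 - e^{-C_S}) + P(G3)
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    if C_T < 0 or C_S < 0:
        raise ValueError("C_T and C_S must be nonnegative")
    eT = np.exp(-C_T)
    eS = np.exp(-C_S)
    p3 = (1.0 - gamma) * eT / 3.0 + gamma * eS / 3.0
    p1 = (1.0 - gamma) * (1.0 - eT) + p3
    p2 = gamma * (1.0 - eS) + p3
    return TopologyProbs(float(p1), float(p2), float(p3))


def gamma_bounds_mpl(gamma: float, C_T: float, C_S: float) -> tuple[float, float]:
    """The interval of gamma values indistinguishable from topology counts.

    A pseudo-likelihood method seeing the exact topology probabilities can
    return any gamma in (gamma - gamma e^{-C_S}, gamma + (1-gamma) e^{-C_T});
    the bounds collapse to the truth only when both histories are free of
    deep coalescence (C_T, C_S -> infinity).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    if C_T < 0 or C_S < 0:
        raise ValueError("C_T and C_S must be nonnegative")
    low = gamma - gamma * np.exp(-C_S)
    high = gamma + (1.0 - gamma) * np.exp(-C_T)
    return float(low), float(high)


def site_pattern_freqs(model: MSciModel) -> SitePatternFreqs:
    """Expected per-site frequencies of BBAA, ABBA and BABA (infinite sites).

    Requires a common theta across populations (the assumption under which
    the closed forms hold):

        f(BABA) = (theta/6) [(1-gamma) e^{-2 l_T/theta} + gamma e^{-2 l_S/theta}]
        f(BBAA) = (1-gamma) l_T + f(BABA)
        f(ABBA) = gamma l_S + f(BABA)
    """
    if not model.has_common_theta():
        raise ValueError(
            "site-pattern frequencies are derived under a common theta across "
            "populations; this model has population-specific theta values"
        )
    theta = model.common_theta
    gamma = model.gamma
    l_T, l_S = internal_branch_lengths(model)
    f_baba = (theta / 6.0) * (
        (1.0 - gamma) * np.exp(-2.0 * l_T / theta) + gamma * np.exp(-2.0 * l_S / theta)
    )
    f_bbaa = (1.0 - gamma) * l_T + f_baba
    f_abba = gamma * l_S + f_baba
    return SitePatternFreqs(float(f_bbaa), float(f_abba), float(f_baba))


def gamma_hyde_expected(gamma: float, ratio_CT_over_CS: float) -> float:
    """Expected site-pattern estimate of gamma, 1 / (1 + (1/gamma - 1) C_T/C_S).

    The pattern-ratio estimator recovers gamma exactly only when C_T = C_S;
    otherwise it is biased downward (ratio > 1) or upward (ratio < 1).
    gamma = 0 and 1 return their limit values.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    if not ratio_CT_over_CS > 0:
        raise ValueError("C_T/C_S ratio must be positive")
    if gamma == 0.0:
        return 0.0
    if gamma == 1.0:
        return 1.0
    return float(1.0 / (1.0 + (1.0 / gamma - 1.0) * ratio_CT_over_CS))


def hyde_detectability(model: MSciModel) -> float:
    """Size of the smallest pattern-frequency excess over the null,
    min{f(BBAA), f(ABBA)} - f(BABA) = min{(1-gamma) l_T, gamma l_S}.

    Larger values make the site-pattern test easier to reject; zero means
    introgression is undetectable from pooled site patterns.
    """
    if not model.has_common_theta():
        raise ValueError("detectability is defined under a common theta")
    l_T, l_S = internal_branch_lengths(model)
    return float(min((1.0 - model.gamma) * l_T, model.gamma * l_S))


def topology_probs_of_model(model: MSciModel) -> TopologyProbs:
    """Convenience: rooted-triple probabilities evaluated at the model's own
    (gamma, C_T, C_S)."""
    c_T, c_S = coalescent_units(model)
    return topology_probs(model.gamma, c_T, c_S)
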