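"""Parameterization of the three introgression scenarios on the species tree AB|C.

The multispecies-coalescent-with-introgression (MSci) models handled here all
share the rooted species tree ((A,B)T, C)R with a distant outgroup O, plus a
single introgression edge whose geometry defines the scenario:

* ``GHOST``   -- an unsampled ("ghost") lineage that diverged above the sampled
  root R donates into A at time ``tau_H``; the ghost rejoins the ancestral
  lineage at ``tau_G`` (above R, below the outgroup divergence ``tau_O``).
* ``INFLOW``  -- C donates into B at ``tau_H`` (gene flow into the sister pair).
* ``OUTFLOW`` -- B donates into C at ``tau_H`` (gene flow out of the sister pair).

All times are measured backwards from the present in expected substitutions
per site; population sizes are theta = 4*N*mu in the same mutation units, so a
pair of lineages sharing a population coalesces at rate 2/theta per unit time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

__all__ = [
    "Scenario",
    "MSciModel",
    "POPULATIONS",
    "DEFAULT_THETA",
    "internal_branch_lengths",
    "coalescent_units",
    "tau_S",
    "from_coalescent_grid",
]

#: Default population-scaled mutation parameter: the branch-length scale
#: used throughout the simulation study conditions.
DEFAULT_THETA = 0.036

#: Population labels used as keys of :attr:`MSciModel.theta`.
POPULATIONS = ("A", "B", "C", "T", "R", "ghost", "O", "anc")


class Scenario(str, enum.Enum):
    """The three introgression geometries on the species tree AB|C."""

    GHOST = "ghost"
    INFLOW = "inflow"
    OUTFLOW = "outflow"

    @classmethod
    def coerce(cls, value: "Scenario | str") -> "Scenario":
        if isinstance(value, Scenario):
            return value
        return cls(str(value).strip().lower())


@dataclass(frozen=True)
class MSciModel:
    """Complete parameterization of one introgression scenario.

    Parameters
    ----------
    scenario:
        One of :class:`Scenario`.
    tau_H:
        Introgression time (the hybridization arrow).
    tau_T:
        Divergence time of the sister species A and B.
    tau_R:
        Root of the sampled ingroup: divergence of (AB) from C.
    tau_G:
        Ghost-lineage attachment above the sampled root (GHOST only;
        ``None`` otherwise).
    tau_O:
        Divergence of the distant outgroup O.
    theta:
        Mapping population label -> theta = 4*N*mu, for the populations in
        :data:`POPULATIONS`.
    gamma:
        Introgression probability in [0, 1]: the chance that a lineage of the
        recipient species traces the introgressed history.
    """

    scenario: Scenario
    tau_H: float
    tau_T: float
    tau_R: float
    tau_O: float
    gamma: float
    tau_G: float | None = None
    theta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario", Scenario.coerce(self.scenario))
        th = dict(self.theta) if self.theta else {}
        if not th:
            th = {p: DEFAULT_THETA for p in POPULATIONS}
        elif set(th) == {"all"} or len(th) == 1 and "common" in th:
            val = next(iter(th.values()))
            th = {p: float(val) for p in POPULATIONS}
        missing = [p for p in POPULATIONS if p not in th]
        if missing:
            raise ValueError(f"theta map is missing populations: {missing}")
        bad = {k: v for k, v in th.items() if not v > 0}
        if bad:
            raise ValueError(f"all theta values must be positive, got {bad}")
        object.__setattr__(self, "theta", dict(th))

        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if not self.tau_H > 0:
            raise ValueError("tau_H must be positive")
        if not self.tau_H < self.tau_T:
            # The recipient (GHOST: A, INFLOW: B) or donor (OUTFLOW: B) branch
            # only exists below tau_T, so the arrow must predate it.
            raise ValueError("tau_H must be below tau_T (recipient/donor branch must exist)")
        if not self.tau_T <= self.tau_R:
            # equality allowed: the degenerate polytomy limit (l_T = 0)
            raise ValueError("tau_T must not exceed tau_R")
        if self.scenario is Scenario.GHOST:
            if self.tau_G is None:
                raise ValueError("GHOST models require tau_G")
            if not self.tau_R < self.tau_G < self.tau_O:
                raise ValueError("GHOST requires tau_R < tau_G < tau_O")
        else:
            if self.tau_G is not None:
                raise ValueError("tau_G is only meaningful for GHOST models")
            if not self.tau_R < self.tau_O:
                raise ValueError("tau_R must be below tau_O")

    # -- convenience ---------------------------------------------------------

    @property
    def common_theta(self) -> float:
        """The shared theta if all populations have the same value, else raise."""
        vals = set(self.theta.values())
        if len(vals) != 1:
            raise ValueError("model does not have a common theta across populations")
        return vals.pop()

    def has_common_theta(self) -> bool:
        return len(set(self.theta.values())) == 1

    def with_gamma(self, gamma: float) -> "MSciModel":
        return replace(self, gamma=gamma)

    # -- serialization -------------------------------------------------------

    def to_config(self) -> str:
        """Serialize as flat ``key = value`` lines (plain text)."""
        lines = [
            f"scenario = {self.scenario.value}",
            f"tau_H = {self.tau_H!r}",
            f"tau_T = {self.tau_T!r}",
            f"tau_R = {self.tau_R!r}",
            f"tau_O = {self.tau_O!r}",
            f"gamma = {self.gamma!r}",
        ]
        if self.tau_G is not None:
            lines.append(f"tau_G = {self.tau_G!r}")
        for pop in POPULATIONS:
            lines.append(f"theta_{pop} = {self.theta[pop]!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "MSciModel":
        kv: dict[str, str] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            kv[key] = val
        theta = {p: float(kv[f"theta_{p}"]) for p in POPULATIONS if f"theta_{p}" in kv}
        return cls(
            scenario=Scenario.coerce(kv["scenario"]),
            tau_H=float(kv["tau_H"]),
            tau_T=float(kv["tau_T"]),
            tau_R=float(kv["tau_R"]),
            tau_O=float(kv["tau_O"]),
            tau_G=float(kv["tau_G"]) if "tau_G" in kv else None,
            gamma=float(kv["gamma"]),
            theta=theta,
        )

    def write_config(self, path: str | Path) -> None:
        Path(path).write_text(self.to_config())

    @classmethod
    def read_config(cls, path: str | Path) -> "MSciModel":
        return cls.from_config(Path(path).read_text())


def tau_S(model: MSciModel) -> float:
    """The scenario-appropriate age of the introgression-history ancestor node S.

    For GHOST this is the ghost-attachment node above the sampled root
    (``tau_G``); for INFLOW and OUTFLOW it is the introgression node itself
    (``tau_H``).
    """
    if model.scenario is Scenario.GHOST:
        assert model.tau_G is not None
        return model.tau_G
    return model.tau_H


def internal_branch_lengths(model: MSciModel) -> tuple[float, float]:
    """Lengths ``(l_T, l_S)`` of the internal branches of the two histories.

    ``l_T`` is the interval during which a and b may coalesce exclusively
    (the speciation history AB|C); ``l_S`` the interval during which b and c
    may coalesce exclusively of a (the introgressed history A|BC):

    * all scenarios: ``l_T = tau_R - tau_T``;
    * GHOST:   ``l_S = tau_G - tau_R`` (a is away on the ghost lineage);
    * INFLOW:  ``l_S = tau_R - tau_H`` (b sits in C's population);
    * OUTFLOW: ``l_S = tau_T - tau_H`` (c sits in B's population; the window
      closes at tau_T when a joins them in T).
    """
    l_T = model.tau_R - model.tau_T
    if model.scenario is Scenario.GHOST:
        assert model.tau_G is not None
        l_S = model.tau_G - model.tau_R
    elif model.scenario is Scenario.INFLOW:
        l_S = model.tau_R - model.tau_H
    else:
        l_S = model.tau_T - model.tau_H
    return l_T, l_S


def coalescent_units(model: MSciModel) -> tuple[float, float]:
    """Internal branch lengths ``(C_T, C_S)`` in coalescent units, 2*l/theta.

    The theta used for ``C_S`` is that of the population where the exclusive
    b-c coalescence takes place: R's (between the root and the ghost join)
    for GHOST, C's for INFLOW, and B's for OUTFLOW.
    """
    l_T, l_S = internal_branch_lengths(model)
    c_T = 2.0 * l_T / model.theta["T"]
    if model.scenario is Scenario.GHOST:
        c_S = 2.0 * l_S / model.theta["R"]
    elif model.scenario is Scenario.INFLOW:
        c_S = 2.0 * l_S / model.theta["C"]
    else:
        c_S = 2.0 * l_S / model.theta["B"]
    return c_T, c_S


def from_coalescent_grid(
    scenario: Scenario | str,
    C1: float,
    C2: float,
    gamma: float,
    theta: float = DEFAULT_THETA,
    outgroup_cu: float = 5.0,
    anchor_cu: float = 1.5,
    ghost_join_cu: float = 1.5,
) -> MSciModel:
    """Build the constant-theta model of one simulation-grid cell.

    The grid places the sister divergence at ``anchor_cu`` coalescent units
    before the present (one coalescent unit being theta/2 mutation units) and
    then stacks the remaining events on top of it:

    * ``C1`` -- introgression time from the present: ``tau_H = C1 * theta/2``;
    * ``C2`` -- speciation-history internal branch: ``tau_R = tau_T + C2*theta/2``;
    * GHOST only: the ghost rejoins ``ghost_join_cu`` units above the root, so
      the introgressed-history branch C_S is fixed at ``ghost_join_cu``;
    * the outgroup O diverges ``outgroup_cu`` units above the root.

    ``C1 < anchor_cu`` is required so the arrow predates the sister divergence.
    """
    scenario = Scenario.coerce(scenario)
    for name, val in (("C1", C1), ("C2", C2), ("theta", theta), ("outgroup_cu", outgroup_cu)):
        if not val > 0:
            raise ValueError(f"{name} must be positive, got {val}")
    if not C1 < anchor_cu:
        raise ValueError(
            f"C1 (={C1}) must be below the sister-divergence anchor ({anchor_cu} coalescent units)"
        )
    half = theta / 2.0
    tau_T = anchor_cu * half
    tau_H = C1 * half
    tau_R = tau_T + C2 * half
    tau_G = tau_R + ghost_join_cu * half if scenario is Scenario.GHOST else None
    tau_O = tau_R + outgroup_cu * half
    if tau_G is not None and not tau_G < tau_O:
        raise ValueError("outgroup_cu must exceed ghost_join_cu")
    return MSciModel(
        scenario=scenario,
        tau_H=tau_H,
        tau_T=tau_T,
        tau_R=tau_R,
        tau_G=tau_G,
        tau_O=tau_O,
        gamma=gamma,
        theta={p: theta for p in POPULATIONS},
    )
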