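"""Population structure shared by the simulator and the analytic densities.

An MSci scenario is encoded as (i) a merge schedule -- each population is
absorbed into a parent population at a fixed time -- and (ii) a single
introgression jump: at ``tau_H`` every lineage currently in the recipient
population moves to the donor-side population independently with probability
gamma.  Everything downstream (gene-tree simulation, pairwise coalescent-time
densities, the joint gene-tree density) is derived from the resulting
piecewise-constant population membership of each sampled lineage.
"""

from __future__ import annotations

import numpy as np

from .model import MSciModel, Scenario

__all__ = [
    "merge_schedule",
    "jump_event",
    "resolve",
    "breakpoints",
    "lineage_itineraries",
    "PAIRS",
    "PAIR_INDEX",
    "pair_rate_tables",
]

#: Rooted-triple conventions: index 0 = ab|c (G1), 1 = a|bc (G2), 2 = ac|b (G3).
PAIRS = (("a", "b"), ("b", "c"), ("a", "c"))
PAIR_INDEX = {frozenset(p): i for i, p in enumerate(PAIRS)}


def merge_schedule(model: MSciModel) -> dict[str, tuple[float, str]]:
    """Map population -> (absorption time, parent population)."""
    sched = {
        "A": (model.tau_T, "T"),
        "B": (model.tau_T, "T"),
        "T": (model.tau_R, "R"),
        "C": (model.tau_R, "R"),
        "R": (model.tau_O, "anc"),
        "O": (model.tau_O, "anc"),
    }
    if model.scenario is Scenario.GHOST:
        assert model.tau_G is not None
        sched["ghost"] = (model.tau_G, "R")
    return sched


def jump_event(model: MSciModel) -> tuple[str, str, str]:
    """(recipient tip label, recipient population, donor-side target population).

    Backwards in time, the recipient's lineages move INTO the donor-side
    population at ``tau_H`` with probability gamma.
    """
    if model.scenario is Scenario.GHOST:
        return "a", "A", "ghost"
    if model.scenario is Scenario.INFLOW:
        return "b", "B", "C"
    return "c", "C", "B"


def resolve(pop: str, t: float, sched: dict[str, tuple[float, str]]) -> str:
    """Population containing `pop`'s lineage content at time t (half-open: a
    merge happening exactly at t has already occurred)."""
    while pop in sched and t >= sched[pop][0]:
        pop = sched[pop][1]
    return pop


def breakpoints(model: MSciModel) -> np.ndarray:
    """Sorted interval start times [0, tau_H, tau_T, tau_R, (tau_G), tau_O].

    Interval k spans [breaks[k], breaks[k+1]); the last interval is unbounded.
    """
    ts = {0.0, model.tau_H, model.tau_T, model.tau_R, model.tau_O}
    if model.tau_G is not None:
        ts.add(model.tau_G)
    return np.array(sorted(ts))


def lineage_itineraries(
    model: MSciModel, jumped: bool, include_outgroup: bool = False
) -> tuple[np.ndarray, dict[str, list[str]]]:
    """Per-interval population label of each sampled lineage.

    Parameters
    ----------
    jumped:
        Whether the recipient lineage takes the introgressed path at tau_H.

    Returns
    -------
    (breaks, itineraries) where ``itineraries[label][k]`` is the population of
    lineage `label` during interval k.
    """
    breaks = breakpoints(model)
    sched = merge_schedule(model)
    recipient, _, target = jump_event(model)
    base = {"a": "A", "b": "B", "c": "C"}
    if include_outgroup:
        base["o"] = "O"
    itins: dict[str, list[str]] = {}
    for label, pop0 in base.items():
        pops = []
        for t in breaks:
            pop = pop0
            if jumped and label == recipient and t >= model.tau_H:
                pop = target
            pops.append(resolve(pop, t, sched))
        itins[label] = pops
    return breaks, itins


def pair_rate_tables(
    model: MSciModel, jumped: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-constant coalescence machinery for the sampled trio (a, b, c).

    Returns
    -------
    breaks : (K,) interval start times.
    r3 : (3, K) pairwise coalescence rate (2/theta when cohabiting, else 0)
        for pairs ordered as :data:`PAIRS`, during the 3-lineage phase.
    r2 : (3, K) rate between the lineage formed by first coalescence of pair p
        and the remaining lineage (valid for intervals at/after that event).
    """
    breaks, itins = lineage_itineraries(model, jumped)
    K = len(breaks)
    r3 = np.zeros((3, K))
    r2 = np.zeros((3, K))
    third = {0: "c", 1: "a", 2: "b"}
    for p, (x, y) in enumerate(PAIRS):
        z = third[p]
        for k in range(K):
            px, py, pz = itins[x][k], itins[y][k], itins[z][k]
            if px == py:
                r3[p, k] = 2.0 / model.theta[px]
            # After (x, y) merge, the merged lineage follows x's resolved
            # population; merging is monotone so px == py post-event.
            if px == pz:
                r2[p, k] = 2.0 / model.theta[px]
    return breaks, r3, r2
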