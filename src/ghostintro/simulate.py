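"""Synthetic multilocus data under the MSci scenarios.

The generator mirrors the classic two-stage pipeline: coalescent gene trees
per locus (with the recipient lineage flipping an independent gamma-coin at
the introgression time, as in ms's ``-es``), then i.i.d. nucleotide sites
evolved along each tree under HKY.  The study conditions it emulates are
1000 loci of 1000 bp with one sequence per species, branch lengths scaled so
that theta = 0.036, and an outgroup 5 coalescent units above the ingroup
root.

Two simulation paths are provided and tested against each other: an
event-driven per-locus simulator returning full :class:`~ghostintro.trees.GeneTree`
objects (any number of sequences per species, outgroup included), and a
vectorized trio path used for large-replicate frequency checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import MSciModel
from .process import jump_event, merge_schedule, pair_rate_tables, resolve
from .trees import GeneTree, Node

__all__ = [
    "SimConfig",
    "LocusAlignment",
    "simulate_gene_trees",
    "simulate_trio_arrays",
    "pair_ages_from_arrays",
    "simulate_alignments",
    "write_dataset",
    "read_dataset",
]

_NUC = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(_NUC)}


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; the defaults are the study conditions."""

    n_loci: int = 1000
    sites_per_locus: int = 1000
    seqs_per_species: int = 1
    subst_model: str = "HKY"  # "HKY" or "JC69"
    kappa: float = 1.0  # HKY transition/transversion rate ratio
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.sites_per_locus < 1 or self.seqs_per_species < 1:
            raise ValueError("n_loci, sites_per_locus and seqs_per_species must be >= 1")
        model = self.subst_model.upper()
        if model not in ("HKY", "JC69"):
            raise ValueError(f"substitution model must be HKY or JC69, got {self.subst_model}")
        object.__setattr__(self, "subst_model", model)
        if model == "JC69":
            object.__setattr__(self, "kappa", 1.0)
            object.__setattr__(self, "base_freqs", (0.25, 0.25, 0.25, 0.25))
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs <= 0) or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("base_freqs must be 4 positive values summing to 1")
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")


@dataclass(frozen=True)
class LocusAlignment:
    """Equal-length nucleotide sequences for one locus (rows follow `labels`)."""

    labels: tuple[str, ...]
    data: np.ndarray  # (n_taxa, L) int8 codes into "ACGT"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.int8)
        if data.ndim != 2 or data.shape[0] != len(self.labels):
            raise ValueError("data must be (n_taxa, L) with one row per label")
        if np.any((data < 0) | (data > 3)):
            raise ValueError("sequence codes must be in 0..3 (ACGT)")
        object.__setattr__(self, "data", data)

    @classmethod
    def from_strings(cls, sequences: dict[str, str]) -> "LocusAlignment":
        labels = tuple(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("all sequences in a locus must have equal length")
        rows = []
        for lab in labels:
            seq = sequences[lab].upper()
            bad = set(seq) - set(_NUC)
            if bad:
                raise ValueError(f"unknown characters {sorted(bad)} in sequence {lab!r}")
            rows.append([_NUC_INDEX[c] for c in seq])
        return cls(labels=labels, data=np.array(rows, dtype=np.int8))

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequence(self, label: str) -> str:
        row = self.data[self.labels.index(label)]
        return "".join(_NUC[i] for i in row)

    def to_dict(self) -> dict[str, str]:
        return {lab: self.sequence(lab) for lab in self.labels}


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------


def _tip_labels(species: str, n: int) -> list[str]:
    return [species] if n == 1 else [f"{species}{i + 1}" for i in range(n)]


def _simulate_locus_tree(model: MSciModel, rng: np.random.Generator, seqs: int) -> GeneTree:
    sched = merge_schedule(model)
    recipient, rec_pop, target = jump_event(model)
    lineages: list[list] = []  # [Node, base_population]
    for sp, pop in (("a", "A"), ("b", "B"), ("c", "C"), ("o", "O")):
        for lab in _tip_labels(sp, seqs):
            lineages.append([Node(age=0.0, label=lab), pop])

    event_times = sorted({model.tau_H, model.tau_T, model.tau_R, model.tau_O}
                         | ({model.tau_G} if model.tau_G is not None else set()))
    t = 0.0
    for next_t in event_times + [np.inf]:
        while len(lineages) > 1:
            groups: dict[str, list[int]] = {}
            for i, (_, pop) in enumerate(lineages):
                groups.setdefault(resolve(pop, t, sched), []).append(i)
            rates = {
                pop: len(idx) * (len(idx) - 1) / model.theta[pop]
                for pop, idx in groups.items()
                if len(idx) > 1
            }
            total = sum(rates.values())
            if total == 0.0:
                break
            dt = rng.exponential(1.0 / total)
            if t + dt >= next_t:
                break
            t += dt
            u = rng.random() * total
            for pop, rate in rates.items():
                u -= rate
                if u <= 0.0:
                    break
            idx = groups[pop]
            i, j = rng.choice(len(idx), size=2, replace=False)
            ni, nj = lineages[idx[i]], lineages[idx[j]]
            merged = [Node(age=t, children=(ni[0], nj[0])), pop]
            for k in sorted((idx[i], idx[j]), reverse=True):
                lineages.pop(k)
            lineages.append(merged)
        if len(lineages) == 1:
            break
        t = next_t
        if t == model.tau_H:
            for lin in lineages:
                if resolve(lin[1], t, sched) == rec_pop and rng.random() < model.gamma:
                    lin[1] = target
    return GeneTree(root=lineages[0][0])


def simulate_gene_trees(
    model: MSciModel, config: SimConfig | int, seed: int | None = None
) -> list[GeneTree]:
    """Simulate independent gene trees (tips a, b, c, o; node ages exact).

    Each lineage present in the recipient population at the introgression
    time independently takes the introgressed path with probability gamma.
    Per-locus random substreams are derived deterministically from the seed,
    so locus i is reproducible in isolation.
    """
    if isinstance(config, int):
        config = SimConfig(n_loci=config, seed=seed)
    root_seed = config.seed if config.seed is not None else seed
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(config.n_loci)
    return [
        _simulate_locus_tree(model, np.random.default_rng(child), config.seqs_per_species)
        for child in children
    ]


def simulate_trio_arrays(
    model: MSciModel, n_loci: int, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized trio simulation (one sequence per species, no outgroup).

    Returns per-locus ``(topology, t1, t2)`` with topology 0 = ab|c,
    1 = a|bc, 2 = ac|b.  By the sampling-consistency of the coalescent this
    has exactly the law of the outgroup-pruned gene trees.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    topo = np.empty(n_loci, dtype=int)
    t1 = np.empty(n_loci)
    t2 = np.empty(n_loci)
    jumped_mask = rng.random(n_loci) < model.gamma
    for flag in (False, True):
        idx = np.nonzero(jumped_mask == flag)[0]
        if len(idx) == 0:
            continue
        breaks, r3, r2 = pair_rate_tables(model, flag)
        K = len(breaks)
        widths = np.append(np.diff(breaks), np.inf)
        R3 = r3.sum(axis=0)
        m = len(idx)

        # phase 1: first coalescence (memoryless restart at each breakpoint)
        loc_t1 = np.empty(m)
        loc_pair = np.empty(m, dtype=int)
        waiting = np.arange(m)
        for k in range(K):
            if len(waiting) == 0:
                break
            if R3[k] <= 0.0:
                continue
            e = rng.exponential(1.0, size=len(waiting)) / R3[k]
            hit = e < widths[k]
            sel = waiting[hit]
            loc_t1[sel] = breaks[k] + e[hit]
            cp = np.cumsum(r3[:, k] / R3[k])
            loc_pair[sel] = np.clip(np.searchsorted(cp, rng.random(len(sel))), 0, 2)
            waiting = waiting[~hit]
        assert len(waiting) == 0, "terminal population must absorb all lineages"

        # phase 2: second coalescence from t1 onward
        loc_t2 = np.empty(m)
        cur = loc_t1.copy()
        done = np.zeros(m, dtype=bool)
        with np.errstate(divide="ignore"):
            for k in range(K):
                if done.all():
                    break
                seg_end = breaks[k] + widths[k]
                inseg = (~done) & (cur >= breaks[k]) & (cur < seg_end)
                if not inseg.any():
                    continue
                sel = np.nonzero(inseg)[0]
                rate = r2[loc_pair[sel], k]
                e = np.where(rate > 0, rng.exponential(1.0, size=len(sel)) / np.where(rate > 0, rate, 1.0), np.inf)
                hit = cur[sel] + e < seg_end
                loc_t2[sel[hit]] = cur[sel[hit]] + e[hit]
                done[sel[hit]] = True
                cur[sel[~hit]] = seg_end
        assert done.all()
        topo[idx] = loc_pair
        t1[idx] = loc_t1
        t2[idx] = loc_t2
    return topo, t1, t2


def pair_ages_from_arrays(
    pair: str, topo: np.ndarray, t1: np.ndarray, t2: np.ndarray
) -> np.ndarray:
    """MRCA age of one sequence pair per locus from trio summaries."""
    from .process import PAIR_INDEX

    p = PAIR_INDEX[frozenset(pair)]
    return np.where(topo == p, t1, t2)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def _hky_rate_matrix(kappa: float, freqs: np.ndarray) -> np.ndarray:
    Q = np.tile(freqs, (4, 1))
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # A<->G, C<->T transitions
        Q[i, j] *= kappa
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.dot(freqs, np.diag(Q))
    return Q / mean_rate  # branch lengths = expected substitutions/site


class _SubstitutionKernel:
    """P(t) = expm(Q t) via eigendecomposition, cached per configuration."""

    def __init__(self, kappa: float, freqs) -> None:
        self.freqs = np.asarray(freqs, dtype=float)
        Q = _hky_rate_matrix(kappa, self.freqs)
        w, V = np.linalg.eig(Q)
        self._w, self._V, self._Vinv = w, V, np.linalg.inv(V)

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self._V * np.exp(self._w * t)) @ self._Vinv
        P = np.clip(P.real, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)


def _evolve_tree(tree: GeneTree, L: int, kernel: _SubstitutionKernel,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}

    def rec(node: Node, parent_states: np.ndarray | None, parent_age: float | None) -> None:
        if parent_states is None:
            states = rng.choice(4, size=L, p=kernel.freqs)
        else:
            bl = parent_age - node.age
            if bl < 0:
                raise ValueError("negative branch length in gene tree")
            cum = np.cumsum(kernel.transition_matrix(bl), axis=1)
            u = rng.random(L)
            states = (u[:, None] > cum[parent_states]).sum(axis=1).astype(np.int8)
        if node.is_leaf:
            out[node.label or ""] = states.astype(np.int8)
        for child in node.children:
            rec(child, states, node.age)

    rec(tree.root, None, None)
    return out


def simulate_alignments(
    trees: list[GeneTree], config: SimConfig, seed: int | None = None
) -> list[LocusAlignment]:
    """Evolve i.i.d. sites along each gene tree (HKY; root drawn from the
    stationary frequencies).  Branch lengths are in substitutions/site."""
    root_seed = config.seed if config.seed is not None else seed
    ss = np.random.SeedSequence(root_seed if root_seed is None else root_seed + 1_000_003)
    kernel = _SubstitutionKernel(config.kappa, config.base_freqs)
    alignments = []
    for tree, child in zip(trees, ss.spawn(len(trees))):
        rng = np.random.default_rng(child)
        states = _evolve_tree(tree, config.sites_per_locus, kernel, rng)
        labels = tuple(tree.tip_labels())
        data = np.stack([states[lab] for lab in labels])
        alignments.append(LocusAlignment(labels=labels, data=data))
    return alignments


# ---------------------------------------------------------------------------
# on-disk datasets
# ---------------------------------------------------------------------------


def _records(aln: LocusAlignment):
    return [SeqRecord(Seq(aln.sequence(lab)), id=lab, description="") for lab in aln.labels]


def _write_locus(path: Path, aln: LocusAlignment, fmt: str) -> None:
    schema = "fasta" if fmt == "fasta" else "phylip-relaxed"
    SeqIO.write(_records(aln), str(path), schema)


def _read_locus(path: Path, fmt: str) -> LocusAlignment:
    schema = "fasta" if fmt == "fasta" else "phylip-relaxed"
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), schema)}
    return LocusAlignment.from_strings(seqs)


def write_dataset(
    trees: list[GeneTree],
    alignments: list[LocusAlignment] | None,
    outdir: str | Path,
    model: MSciModel | None = None,
    config: SimConfig | None = None,
    fmt: str = "fasta",
) -> Path:
    """Write a dataset: one Newick per line, one alignment file per locus,
    and a plain-text manifest recording seed and model.  Round-trips
    losslessly (topologies and ages to full float precision)."""
    if fmt not in ("fasta", "phylip"):
        raise ValueError(f"format must be 'fasta' or 'phylip', got {fmt!r}")
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        lines = ["format = %s" % fmt, f"n_loci = {len(trees)}"]
        if config is not None:
            lines += [
                f"seed = {config.seed}",
                f"sites_per_locus = {config.sites_per_locus}",
                f"seqs_per_species = {config.seqs_per_species}",
                f"subst_model = {config.subst_model}",
                f"kappa = {config.kappa!r}",
                f"base_freqs = {','.join(repr(f) for f in config.base_freqs)}",
            ]
        (outdir / "manifest.txt").write_text("\n".join(lines) + "\n")
        if model is not None:
            model.write_config(outdir / "model.cfg")
        if trees:
            with open(outdir / "trees.nwk", "w") as fh:
                for tree in trees:
                    fh.write(tree.to_newick() + "\n")
        if alignments:
            ext = "fasta" if fmt == "fasta" else "phy"
            for i, aln in enumerate(alignments):
                _write_locus(outdir / f"locus_{i:05d}.{ext}", aln, fmt)
    except OSError as err:
        raise OSError(f"failed writing dataset under {outdir}: {err}") from err
    return outdir


def read_dataset(outdir: str | Path):
    """Read back a dataset written by :func:`write_dataset`.

    Returns ``(trees, alignments, manifest, model)``; absent pieces are
    empty/None.
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.txt"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.txt under {outdir}")
    manifest: dict[str, str] = {}
    for ln in manifest_path.read_text().splitlines():
        if "=" in ln:
            k, v = (s.strip() for s in ln.split("=", 1))
            manifest[k] = v
    trees: list[GeneTree] = []
    tree_path = outdir / "trees.nwk"
    if tree_path.exists():
        for ln in tree_path.read_text().splitlines():
            if ln.strip():
                trees.append(GeneTree.from_newick(ln))
    fmt = manifest.get("format", "fasta")
    ext = "fasta" if fmt == "fasta" else "phy"
    alignments = [_read_locus(p, fmt) for p in sorted(outdir.glob(f"locus_*.{ext}"))]
    model = None
    if (outdir / "model.cfg").exists():
        model = MSciModel.read_config(outdir / "model.cfg")
    return trees, alignments, manifest, model
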