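"""Config-driven simulation grids and density figures.

`run_grid` reproduces the simulation-study design at desk scale: a cartesian
grid over scenario x C1 (introgression time, coalescent units from the
present) x C2 (speciation-history internal branch) x gamma, with a number of
replicate datasets per cell, each analyzed by any subset of

* ``hyde``    -- site-pattern block-jackknife test on simulated alignments,
* ``topofit`` -- topology-count multinomial ridge fit,
* ``gtfit``   -- gene-tree likelihood scenario selection.

Everything is deterministic given the spec's seed, cells are resumable from
their per-cell tables, and all downstream reporting reads tables, never
figures.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fit import select_scenario
from .hyde import HydeDetector, bh_adjust
from .model import DEFAULT_THETA, MSciModel, POPULATIONS, Scenario, from_coalescent_grid
from .simulate import SimConfig, pair_ages_from_arrays, simulate_alignments, \
    simulate_gene_trees, simulate_trio_arrays, write_dataset
from .density import pairwise_density
from .topology import count_topologies, fit_multinomial
from .trees import trees_to_arrays

__all__ = [
    "GridSpec",
    "GridReport",
    "parse_grid_config",
    "run_grid",
    "report_tables",
    "fig1_presets",
    "plot_fig1_densities",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class GridSpec:
    """One simulation-grid design (defaults are the desk-scale reproduction)."""

    scenarios: tuple[str, ...] = ("ghost", "inflow", "outflow")
    c1_values: tuple[float, ...] = (0.3,)
    c2_values: tuple[float, ...] = (0.5, 1.5)
    gamma_values: tuple[float, ...] = (0.3,)
    replicates: int = 20
    n_loci: int = 1000
    sites_per_locus: int = 1000
    seed: int = 0
    methods: tuple[str, ...] = ("hyde", "topofit", "gtfit")
    theta: float = DEFAULT_THETA
    outgroup_cu: float = 5.0
    alpha: float = 0.05
    n_restarts: int = 8

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.n_loci < 1 or self.sites_per_locus < 1:
            raise ValueError("replicates, n_loci and sites_per_locus must be positive")
        bad = set(self.methods) - {"hyde", "topofit", "gtfit"}
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")

    def cells(self) -> list[tuple[str, float, float, float]]:
        return list(itertools.product(
            self.scenarios, self.c1_values, self.c2_values, self.gamma_values
        ))


@dataclass(frozen=True)
class GridReport:
    """Per-replicate rows, per-cell summary, and any cells that failed."""

    replicates: pd.DataFrame
    summary: pd.DataFrame
    missing: tuple[int, ...] = ()


def parse_grid_config(text: str) -> GridSpec:
    """Parse a plain `key = value` config into a :class:`GridSpec`.

    List-valued keys take comma-separated entries, e.g.
    ``c2 = 0.5, 1.5`` or ``methods = hyde, gtfit``.
    """
    kv: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        k, v = (s.strip() for s in line.split("=", 1))
        kv[k.lower()] = v

    def floats(key: str, default):
        if key not in kv:
            return default
        return tuple(float(x) for x in kv[key].split(","))

    def strings(key: str, default):
        if key not in kv:
            return default
        return tuple(s.strip().lower() for s in kv[key].split(","))

    spec = GridSpec()
    return replace(
        spec,
        scenarios=strings("scenarios", spec.scenarios),
        c1_values=floats("c1", spec.c1_values),
        c2_values=floats("c2", spec.c2_values),
        gamma_values=floats("gamma", spec.gamma_values),
        replicates=int(kv.get("replicates", spec.replicates)),
        n_loci=int(kv.get("loci", spec.n_loci)),
        sites_per_locus=int(kv.get("sites", spec.sites_per_locus)),
        seed=int(kv.get("seed", spec.seed)),
        methods=strings("methods", spec.methods),
        theta=float(kv.get("theta", spec.theta)),
        outgroup_cu=float(kv.get("outgroup_cu", spec.outgroup_cu)),
        alpha=float(kv.get("alpha", spec.alpha)),
        n_restarts=int(kv.get("n_restarts", spec.n_restarts)),
    )


def _run_cell(spec: GridSpec, cell_id: int, cell, rng: np.random.Generator,
              dataset_dir: Path | None = None) -> pd.DataFrame:
    scenario, c1, c2, gamma = cell
    model = from_coalescent_grid(scenario, c1, c2, gamma,
                                 theta=spec.theta, outgroup_cu=spec.outgroup_cu)
    rows = []
    for rep in range(spec.replicates):
        seed = int(rng.integers(2**31 - 1))
        config = SimConfig(n_loci=spec.n_loci, sites_per_locus=spec.sites_per_locus,
                           seed=seed)
        trees = simulate_gene_trees(model, config)
        if dataset_dir is not None:
            write_dataset(trees, None, dataset_dir / f"rep_{rep:03d}",
                          model=model, config=config)
        row: dict[str, object] = dict(
            cell=cell_id, scenario=scenario, C1=c1, C2=c2, gamma=gamma, replicate=rep,
        )
        if "hyde" in spec.methods:
            alignments = simulate_alignments(trees, config)
            det = HydeDetector(alpha=spec.alpha).fit(alignments)
            row.update(
                hyde_z=det.z_, hyde_p=det.pvalue_,
                hyde_hybrid=det.hybrid_ or "", hyde_gamma=det.gamma_hat_,
            )
        arrays = trees_to_arrays(trees, outgroup="o")
        if "topofit" in spec.methods:
            counts = count_topologies(trees)
            prof = fit_multinomial(counts, gamma_grid_size=41)
            lo, hi = prof.flat_interval
            row.update(
                topo_n1=counts.n1, topo_n2=counts.n2, topo_n3=counts.n3,
                topo_gamma_low=lo, topo_gamma_high=hi,
                topo_gamma_point=prof.sample_point_estimate(
                    np.random.default_rng(seed + 13)),
            )
        if "gtfit" in spec.methods:
            sel = select_scenario(arrays, seed=seed, n_restarts=spec.n_restarts)
            best = sel.best_fit
            row.update(
                gtfit_best=sel.best_scenario,
                gtfit_gamma=best.estimates["gamma"],
                gtfit_tau_T=best.estimates["tau_T"],
                gtfit_tau_R=best.estimates["tau_R"],
                gtfit_theta=best.estimates["theta"],
                gtfit_dll_ghost=sel.loglik_diffs["ghost"],
                gtfit_dll_inflow=sel.loglik_diffs["inflow"],
                gtfit_dll_outflow=sel.loglik_diffs["outflow"],
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if "hyde" in spec.methods:
        df["hyde_p_adj"] = bh_adjust(df["hyde_p"].to_numpy())
        df["hyde_significant"] = df["hyde_p_adj"] < spec.alpha
    return df


def _summarize(spec: GridSpec, reps: pd.DataFrame, missing: list[int]) -> pd.DataFrame:
    rows = []
    for cell_id, cell in enumerate(spec.cells()):
        scenario, c1, c2, gamma = cell
        row: dict[str, object] = dict(
            cell=cell_id, scenario=scenario, C1=c1, C2=c2, gamma=gamma,
            status="missing" if cell_id in missing else "ok",
        )
        sub = reps[reps["cell"] == cell_id] if len(reps) else reps
        if len(sub):
            row["replicates"] = len(sub)
            if "hyde_significant" in sub:
                sig = sub[sub["hyde_significant"].astype(bool)]
                row["hyde_n_significant"] = int(len(sig))
                row["hyde_n_hybrid_b"] = int((sig["hyde_hybrid"] == "b").sum())
                row["hyde_mean_gamma"] = float(sub["hyde_gamma"].mean())
            if "topo_gamma_low" in sub:
                row["topo_mean_gamma_low"] = float(sub["topo_gamma_low"].mean())
                row["topo_mean_gamma_high"] = float(sub["topo_gamma_high"].mean())
            if "gtfit_best" in sub:
                for scen in ("ghost", "inflow", "outflow"):
                    row[f"gtfit_n_{scen}"] = int((sub["gtfit_best"] == scen).sum())
                row["gtfit_mean_gamma"] = float(sub["gtfit_gamma"].mean())
        else:
            row["replicates"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


def run_grid(spec: GridSpec, outdir: str | Path | None = None, resume: bool = False) -> GridReport:
    """Run a simulation grid; deterministic given ``spec.seed``.

    With ``outdir`` set, each completed cell's rows are written to
    ``cells/cell_<id>.tsv``; with ``resume=True`` existing cell tables are
    loaded instead of recomputed.  A failing cell is logged, marked missing
    in the summary, and never aborts the grid.
    """
    cells = spec.cells()
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(cells))
    cell_dir = None
    if outdir is not None:
        cell_dir = Path(outdir) / "cells"
        cell_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    missing: list[int] = []
    for cell_id, (cell, child) in enumerate(zip(cells, children)):
        path = cell_dir / f"cell_{cell_id:03d}.tsv" if cell_dir is not None else None
        if resume and path is not None and path.exists():
            frames.append(pd.read_csv(path, sep="\t"))
            continue
        # with no analysis methods requested the grid is a pure data generator
        dataset_dir = None
        if not spec.methods and cell_dir is not None:
            dataset_dir = cell_dir / f"cell_{cell_id:03d}_data"
        try:
            df = _run_cell(spec, cell_id, cell, np.random.default_rng(child),
                           dataset_dir=dataset_dir)
        except Exception:  # noqa: BLE001 - per-cell failures must not abort the grid
            logger.exception("cell %d %r failed; skipping", cell_id, cell)
            missing.append(cell_id)
            continue
        frames.append(df)
        if path is not None:
            df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    reps = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    summary = _summarize(spec, reps, missing)
    report = GridReport(replicates=reps, summary=summary, missing=tuple(missing))
    if outdir is not None:
        report_tables(report, outdir)
    return report


def report_tables(report: GridReport, outdir: str | Path) -> list[Path]:
    """Write replicate-level and summary tables as TSV (idempotent)."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        paths = [outdir / "replicates.tsv", outdir / "summary.tsv"]
        report.replicates.to_csv(paths[0], sep="\t", index=False, float_format=_FLOAT_FMT)
        report.summary.to_csv(paths[1], sep="\t", index=False, float_format=_FLOAT_FMT)
    except OSError as err:
        raise OSError(f"failed writing report tables under {outdir}: {err}") from err
    return paths


# ---------------------------------------------------------------------------
# coalescent-time density figures
# ---------------------------------------------------------------------------


def fig1_presets(theta: float = DEFAULT_THETA) -> dict[str, MSciModel]:
    """The three scenario presets used for the coalescent-time density plots.

    Ghost: sister divergence at 0.75*theta, sampled root at theta, ghost
    join at 1.75*theta; inflow/outflow: introgression at 0.15*theta, sister
    divergence at 0.75*theta, root at theta.  gamma = 0.3 and a common theta
    everywhere; the ghost introgression time (0.15*theta) is irrelevant to
    the densities and fixed for concreteness.
    """
    th = {p: theta for p in POPULATIONS}
    ghost = MSciModel(
        scenario=Scenario.GHOST, tau_H=0.15 * theta, tau_T=0.75 * theta,
        tau_R=1.0 * theta, tau_G=1.75 * theta, tau_O=3.5 * theta,
        gamma=0.3, theta=th,
    )
    flow = dict(tau_H=0.15 * theta, tau_T=0.75 * theta, tau_R=1.0 * theta,
                tau_O=3.5 * theta, gamma=0.3, theta=th)
    return {
        "ghost": ghost,
        "inflow": MSciModel(scenario=Scenario.INFLOW, **flow),
        "outflow": MSciModel(scenario=Scenario.OUTFLOW, **flow),
    }


def plot_fig1_densities(
    outdir: str | Path,
    models: dict[str, MSciModel] | None = None,
    n_sim: int = 20000,
    seed: int = 0,
) -> list[Path]:
    """Overlay analytic pairwise coalescent-time densities with simulated
    MRCA-age histograms, one figure per scenario; returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    models = models or fig1_presets()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    rng = np.random.default_rng(seed)
    for name, model in models.items():
        topo, t1, t2 = simulate_trio_arrays(model, n_sim, rng)
        fig, axes = plt.subplots(1, 3, figsize=(11, 3), sharey=True)
        tmax = float(np.quantile(t2, 0.99))
        grid = np.linspace(0.0, tmax, 600)
        for ax, pair in zip(axes, ("ab", "bc", "ac")):
            mix = pairwise_density(model, pair)
            ages = pair_ages_from_arrays(pair, topo, t1, t2)
            ax.hist(ages, bins=60, range=(0, tmax), density=True,
                    alpha=0.4, color="grey", label="simulated")
            ax.plot(grid, mix.pdf(grid), lw=1.5, label="analytic")
            ax.set_title(f"t_{pair} ({name})")
            ax.set_xlabel("coalescent time (subst/site)")
        axes[0].set_ylabel("density")
        axes[0].legend(frameon=False)
        fig.tight_layout()
        path = outdir / f"fig1_{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
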