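"""Monte-Carlo replication and operating-characteristics aggregation.

Replicate seeds are spawned deterministically from a master seed, so a
given (seed, replicate) pair yields the same random stream for every
design — designs are compared on common streams by default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engines import DESIGNS, run_trial
from .estimation import TrialConfig
from .patients import Scenario

__all__ = [
    "OperatingCharacteristics",
    "ComparisonResult",
    "CalibrationResult",
    "simulate_ocs",
    "compare_designs",
    "calibrate_fstar",
    "flag_against_reference",
    "plot_selection_profiles",
]


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Replicate-averaged performance of one design in one scenario.

    Percentages are on the 0-100 scale; durations in years.
    """

    design: str
    scenario: str
    n_reps: int
    pcd: float
    mean_ntox: float
    mean_n: float
    mean_duration_years: float
    alloc_below: float
    alloc_at: float
    alloc_above: float
    mc_se: float  # binomial Monte-Carlo standard error of pcd, percentage points
    selection_pct: tuple[float, ...] = ()

    def as_row(self) -> dict:
        row = dataclasses.asdict(self)
        row.pop("selection_pct")
        return row


def _replicate_seeds(seed: int | None, n_reps: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n_reps)


def simulate_ocs(
    design: str,
    scenario: Scenario,
    config: TrialConfig,
    n_reps: int,
    seed: int | None = None,
    **engine_kwargs,
) -> OperatingCharacteristics:
    """Simulate ``n_reps`` independent trials of one design and aggregate
    the operating characteristics."""
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    true_mtd = scenario.true_mtd(config.target)
    n_doses = scenario.n_doses
    picks = np.zeros(n_doses + 1, dtype=np.int64)  # index 0 unused
    ntox = np.zeros(n_reps)
    nsize = np.zeros(n_reps)
    dur = np.zeros(n_reps)
    alloc = np.zeros((n_reps, 3))
    for r, ss in enumerate(_replicate_seeds(seed, n_reps)):
        res = run_trial(design, scenario, config, np.random.default_rng(ss), **engine_kwargs)
        picks[res.mtd_index] += 1
        ntox[r] = res.n_toxicities
        nsize[r] = res.n_enrolled
        dur[r] = res.duration_years
        alloc[r] = np.asarray(res.allocation) / res.n_enrolled
    pcd = 100.0 * picks[true_mtd] / n_reps
    return OperatingCharacteristics(
        design=design,
        scenario=scenario.name,
        n_reps=n_reps,
        pcd=float(pcd),
        mean_ntox=float(ntox.mean()),
        mean_n=float(nsize.mean()),
        mean_duration_years=float(dur.mean()),
        alloc_below=float(100.0 * alloc[:, 0].mean()),
        alloc_at=float(100.0 * alloc[:, 1].mean()),
        alloc_above=float(100.0 * alloc[:, 2].mean()),
        mc_se=float(100.0 * np.sqrt((pcd / 100.0) * (1.0 - pcd / 100.0) / n_reps)),
        selection_pct=tuple(100.0 * picks[1:] / n_reps),
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Cross-design comparison: one OC row per (scenario, design), the
    per-dose selection-percentage profile, and cross-scenario aggregate
    contrasts of the time-to-event design against each comparator."""

    oc_table: pd.DataFrame
    selection: pd.DataFrame
    pcd_advantage: dict[str, float]  # mean pcd(TITE-IR) - pcd(design)
    duration_saving: dict[str, float]  # mean duration(design) - duration(TITE-IR)


def compare_designs(
    scenarios: Sequence[Scenario],
    designs: Sequence[str],
    config: TrialConfig,
    n_reps: int,
    seed: int | None = None,
    **engine_kwargs,
) -> ComparisonResult:
    if len(scenarios) == 0 or len(designs) == 0:
        raise ValueError("scenarios and designs must be non-empty")
    rows = []
    sel_rows = []
    for sc in scenarios:
        for d in designs:
            oc = simulate_ocs(d, sc, config, n_reps, seed, **engine_kwargs)
            rows.append(oc.as_row())
            sel = {"scenario": sc.name, "design": d}
            sel.update({f"dose{k + 1}": v for k, v in enumerate(oc.selection_pct)})
            sel_rows.append(sel)
    oc_table = pd.DataFrame(rows)
    selection = pd.DataFrame(sel_rows)
    pcd_adv: dict[str, float] = {}
    dur_save: dict[str, float] = {}
    if "TITE-IR" in designs:
        tite = oc_table[oc_table.design == "TITE-IR"].set_index("scenario")
        for d in designs:
            if d == "TITE-IR":
                continue
            other = oc_table[oc_table.design == d].set_index("scenario")
            pcd_adv[d] = float((tite.pcd - other.pcd).mean())
            dur_save[d] = float(
                (other.mean_duration_years - tite.mean_duration_years).mean()
            )
    return ComparisonResult(oc_table, selection, pcd_adv, dur_save)


#: tolerances (per OC column) used when flagging simulated cells against
#: an external reference table
DEFAULT_TOLERANCES = {
    "pcd": 3.0,
    "mean_ntox": 0.4,
    "mean_n": 0.5,
    "mean_duration_years": 0.15,
    "alloc_below": 3.0,
    "alloc_at": 3.0,
    "alloc_above": 3.0,
}


def flag_against_reference(
    oc_table: pd.DataFrame,
    reference: pd.DataFrame,
    tolerances: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Compare a simulated OC table against a reference table cell by
    cell; returns the rows/columns whose absolute deviation exceeds the
    tolerance, for the comparison report."""
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    merged = oc_table.merge(
        reference, on=["scenario", "design"], suffixes=("", "_ref")
    )
    records = []
    for col, t in tol.items():
        if col not in merged or f"{col}_ref" not in merged:
            continue
        dev = (merged[col] - merged[f"{col}_ref"]).abs()
        bad = merged[dev > t]
        for _, row in bad.iterrows():
            records.append(
                {
                    "scenario": row["scenario"],
                    "design": row["design"],
                    "column": col,
                    "simulated": row[col],
                    "reference": row[f"{col}_ref"],
                    "tolerance": t,
                }
            )
    return pd.DataFrame(
        records, columns=["scenario", "design", "column", "simulated", "reference", "tolerance"]
    )


def plot_selection_profiles(selection: pd.DataFrame, path=None):
    """Bar chart of per-dose selection percentages, one panel per
    scenario with designs side by side.  Requires matplotlib (the
    ``plots`` extra); returns the figure, optionally saving it."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dose_cols = [c for c in selection.columns if c.startswith("dose")]
    scen_names = list(dict.fromkeys(selection.scenario))
    ncols = min(5, len(scen_names))
    nrows = -(-len(scen_names) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.5 * nrows),
                             squeeze=False, sharey=True)
    x = np.arange(len(dose_cols))
    for k, scen in enumerate(scen_names):
        ax = axes[k // ncols][k % ncols]
        rows = selection[selection.scenario == scen]
        width = 0.8 / len(rows)
        for i, (_, row) in enumerate(rows.iterrows()):
            ax.bar(x + i * width, row[dose_cols].to_numpy(dtype=float),
                   width, label=row.design)
        ax.set_title(f"scenario {scen}", fontsize=9)
        ax.set_xticks(x + 0.4, [str(d + 1) for d in range(len(dose_cols))])
    axes[0][0].set_ylabel("selection %")
    handles, labels = axes[0][0].get_legend_handles_labels()
    fig.legend(handles, labels, loc="lower center", ncol=len(labels), fontsize=8)
    fig.tight_layout(rect=(0, 0.06, 1, 1))
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the conservatism-offset grid search."""

    selected: float
    table: pd.DataFrame  # one row per grid value with the diagnostics
    reference_over_pct: float  # mean over-MTD % of the 3+3 and UD references


def calibrate_fstar(
    grid: Sequence[float],
    toxic_scenario: Scenario,
    high_mtd_scenario: Scenario,
    config: TrialConfig,
    n_reps: int,
    seed: int | None = None,
    over_margin: float = 3.0,
    pcd_margin: float = 5.0,
) -> CalibrationResult:
    """Grid search for the conservatism offset.

    For each candidate offset the time-to-event design is simulated under
    a toxic scenario (only the lowest dose acceptable) and a high-MTD
    scenario, on common replicate streams.  Candidates are first
    restricted to those whose percentage of patients treated above the
    true MTD in the toxic scenario is within ``over_margin`` points of
    the mean of the 3+3 and up-and-down reference rates; among those,
    the selected value is the smallest offset whose high-MTD selection
    probability is within ``pcd_margin`` points of the best achieved by
    a safety-feasible candidate.  When no candidate meets the safety
    margin, the grid value with the smallest over-MTD rate is returned.
    """
    grid = sorted(float(g) for g in grid)
    if len(grid) == 0:
        raise ValueError("calibration grid is empty")
    if any(g < 0 for g in grid):
        raise ValueError("grid values must be non-negative")
    ref_rates = [
        simulate_ocs(d, toxic_scenario, config, n_reps, seed).alloc_above
        for d in ("3+3", "UD")
    ]
    reference = float(np.mean(ref_rates))
    rows = []
    for g in grid:
        cfg = dataclasses.replace(config, f_star=g)
        toxic = simulate_ocs("TITE-IR", toxic_scenario, cfg, n_reps, seed)
        high = simulate_ocs("TITE-IR", high_mtd_scenario, cfg, n_reps, seed)
        rows.append(
            {
                "f_star": g,
                "over_mtd_pct": toxic.alloc_above,
                "high_mtd_pcd": high.pcd,
            }
        )
    table = pd.DataFrame(rows)
    feasible = table[table.over_mtd_pct <= reference + over_margin]
    if len(feasible):
        pcd_max = feasible.high_mtd_pcd.max()
        ok = feasible[feasible.high_mtd_pcd >= pcd_max - pcd_margin]
        selected = float(ok.f_star.iloc[0])
    else:
        selected = float(table.sort_values("over_mtd_pct").f_star.iloc[0])
    return CalibrationResult(selected=selected, table=table, reference_over_pct=reference)
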