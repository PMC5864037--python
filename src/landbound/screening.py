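"""Ensemble screening, scenario narratives and report rendering.

Runs are filtered into three nested tiers: (1) the food-supply target
met, (2) food plus the cropland planetary boundary, (3) all three
targets including bioenergy. Near-miss parameterisations (at least two
targets met) are ranked by the ``closeness`` score, and flagged runs are
described by a narrative table that places every parameter within its
uncertainty range and bins it qualitatively.

The qualitative bin uses the trend-anchored position: the parameter's
value is mapped so that the range minimum sits at 0, the current-trend
setting at 0.5 and the maximum at 1, then binned at thirds
(low <= 1/3 < moderate <= 2/3 < high). A run at all-trend settings is
therefore "moderate" in every parameter, regardless of where the trend
sits inside the raw range.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .experiment import RunRecord, records_to_frame
from .parameters import PARAM_BOUNDS, PARAM_NAMES, PARAM_TREND

logger = logging.getLogger(__name__)


@dataclass
class ScreeningResult:
    """Nested target-tier counts and satisfier identifiers."""

    n_runs: int
    n_failed: int
    count_food: int
    count_food_cropland: int
    count_all: int
    tier1_ids: list
    tier2_ids: list
    tier3_ids: list
    closest_run_id: str | None  # argmin closeness among runs meeting >= 2 targets
    # trajectory-wide variant of the boundary check (2050 is authoritative)
    count_food_cropland_trajectory: int = 0

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.count_food, self.count_food_cropland, self.count_all)


def screen(records: Sequence[RunRecord]) -> ScreeningResult:
    """Filter an ensemble by the three nested target combinations."""
    records = list(records)
    if not records:
        raise ValueError("cannot screen an empty record stream")
    ok = [r for r in records if not r.failed and r.outcome is not None]
    tier1 = [r for r in ok if r.outcome.food_met]
    tier2 = [r for r in tier1 if r.outcome.cropland_met]
    tier3 = [r for r in tier2 if r.outcome.bioenergy_met]
    # boundary value recovered per run: margin = boundary - cropland_2050
    traj2 = [r for r in tier1
             if max(r.cropland_path) <= r.cropland_path[-1] + r.outcome.cropland_margin + 1e-9]
    near = [r for r in ok if r.outcome.n_met >= 2]
    closest = min(near, key=lambda r: (r.outcome.closeness, r.run_id)).run_id if near else None
    return ScreeningResult(
        n_runs=len(records), n_failed=len(records) - len(ok),
        count_food=len(tier1), count_food_cropland=len(tier2), count_all=len(tier3),
        tier1_ids=[r.run_id for r in tier1], tier2_ids=[r.run_id for r in tier2],
        tier3_ids=[r.run_id for r in tier3], closest_run_id=closest,
        count_food_cropland_trajectory=len(traj2),
    )


def trend_position(name: str, value: float) -> float:
    """Map a parameter value to [0, 1] with the trend setting at 0.5."""
    lo, hi = PARAM_BOUNDS[name]
    trend = PARAM_TREND[name]
    if not lo <= value <= hi:
        raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
    if value <= trend:
        return 0.5 * (value - lo) / (trend - lo) if trend > lo else 0.5
    return 0.5 + 0.5 * (value - trend) / (hi - trend) if hi > trend else 0.5


def qualitative_bin(name: str, value: float) -> str:
    """Tercile bin of the trend-anchored position: low / moderate / high."""
    p = trend_position(name, value)
    if p <= 1.0 / 3.0:
        return "low"
    if p <= 2.0 / 3.0:
        return "moderate"
    return "high"


def extract_narratives(result: ScreeningResult,
                       records: Sequence[RunRecord]) -> pd.DataFrame:
    """Narrative table for flagged (near-miss) runs.

    One row per (run, parameter): the sampled value, its raw position in
    the [min, max] range, the trend-anchored position and the qualitative
    bin. Flagged runs are the tier-2 members plus the closest run.
    """
    by_id = {r.run_id: r for r in records}
    flagged = list(dict.fromkeys(result.tier2_ids
                                 + ([result.closest_run_id] if result.closest_run_id else [])))
    rows = []
    for run_id in flagged:
        rec = by_id[run_id]
        p = rec.params.as_dict()
        for name in PARAM_NAMES:
            lo, hi = PARAM_BOUNDS[name]
            v = p[name]
            rows.append({
                "run_id": run_id, "parameter": name, "value": v,
                "range_position": (v - lo) / (hi - lo) if hi > lo else 0.5,
                "trend_position": trend_position(name, v),
                "bin": qualitative_bin(name, v),
            })
    return pd.DataFrame(rows, columns=["run_id", "parameter", "value",
                                       "range_position", "trend_position", "bin"])


def report(result: ScreeningResult, records: Sequence[RunRecord],
           outdir: str | Path, boundary_mha: float = 2010.0) -> list[Path]:
    """Render the screening report: three figures and two CSV tables.

    Figures: global cropland trajectories with the planetary boundary
    line, global mean-yield trajectories, and the parameter-setting chart
    of flagged runs. CSVs: the per-run summary and the narrative table.
    Plotting failures degrade to CSV-only output with a logged warning.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary = records_to_frame(records)
    p = out / "summary.csv"
    summary.to_csv(p, index=False)
    written.append(p)
    narratives = extract_narratives(result, records)
    p = out / "narratives.csv"
    narratives.to_csv(p, index=False)
    written.append(p)
    p = out / "screening.csv"
    pd.DataFrame([{
        "n_runs": result.n_runs, "n_failed": result.n_failed,
        "count_food": result.count_food,
        "count_food_cropland": result.count_food_cropland,
        "count_all": result.count_all,
        "count_food_cropland_trajectory": result.count_food_cropland_trajectory,
        "closest_run_id": result.closest_run_id,
    }]).to_csv(p, index=False)
    written.append(p)

    try:
        written.extend(_render_figures(result, records, out, boundary_mha))
    except Exception as exc:  # noqa: BLE001 - degrade to CSV-only output
        logger.warning("figure rendering failed (%s); CSV outputs only", exc)
    return written


def _render_figures(result: ScreeningResult, records: Sequence[RunRecord],
                    out: Path, boundary_mha: float) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = [r for r in records if not r.failed and r.outcome is not None]
    years = np.arange(2000, 2000 + len(ok[0].cropland_path)) if ok else np.arange(2000, 2051)
    tier1, tier2 = set(result.tier1_ids), set(result.tier2_ids)
    written = []

    def trajectories(attr: str, ylabel: str, fname: str, hline: float | None) -> Path:
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for r in ok:
            ax.plot(years, getattr(r, attr), color="0.8", lw=0.4, zorder=1)
        for r in ok:
            if r.run_id in tier1 and r.run_id not in tier2:
                ax.plot(years, getattr(r, attr), color="tab:blue", lw=0.7, zorder=2)
        for r in ok:
            if r.run_id in tier2:
                ax.plot(years, getattr(r, attr), color="gold", lw=1.2, zorder=3)
        if result.closest_run_id:
            rec = next(r for r in ok if r.run_id == result.closest_run_id)
            ax.plot(years, getattr(rec, attr), color="tab:red", lw=1.6, zorder=4,
                    label="closest to all targets")
            ax.legend(loc="upper left", frameon=False)
        if hline is not None:
            ax.axhline(hline, color="black", ls="--", lw=1.0, zorder=5)
        ax.set_xlabel("year")
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        path = out / fname
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path

    written.append(trajectories("cropland_path", "global cropland (Mha)",
                                "cropland_trajectories.png", boundary_mha))
    written.append(trajectories("yield_path", "global mean yield (t ha$^{-1}$)",
                                "yield_trajectories.png", None))

    fig, ax = plt.subplots(figsize=(7, 5))
    narr = extract_narratives(result, records)
    for i, name in enumerate(PARAM_NAMES):
        ax.plot([0, 1], [i, i], color="0.85", lw=4, solid_capstyle="butt", zorder=1)
        ax.plot([0.5], [i], marker="|", color="tab:orange", ms=14, zorder=2)
        if not narr.empty:
            sub = narr[narr["parameter"] == name]
            ax.plot(sub["trend_position"], [i] * len(sub), "o", color="tab:red",
                    ms=5, zorder=3)
    ax.set_yticks(range(len(PARAM_NAMES)), PARAM_NAMES)
    ax.set_xlabel("trend-anchored position in uncertainty range")
    ax.set_xlim(-0.05, 1.05)
    fig.tight_layout()
    path = out / "parameter_settings.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)
    return written
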