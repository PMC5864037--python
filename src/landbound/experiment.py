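"""Sobol-sampled Monte Carlo experiment over the 14-parameter space.

Two experiment sets share the same quasi-random points: set A pairs a
current-policy bioenergy pathway (74 EJ by 2050, 3.5% first generation)
with the higher-warming potential-yield variant; set B pairs the
stringent-mitigation pathway (125 EJ, 7%) with the low-warming variant.
Each sampled point is simulated deterministically, screened against the
normative targets, and recorded as a :class:`RunRecord`.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .config import DemandConfig, DesignConfig, SupplyConfig
from .parameters import PARAM_BOUNDS, PARAM_NAMES, ScenarioParameters
from .simulate import PreparedWorld, RunResult, calibrate_kappa, prepare_world, simulate_run
from .synthetic_world import WorldBaseline
from .targets import TargetOutcome, TargetSpec, evaluate_targets


@dataclass(frozen=True)
class SamplingDesign:
    """Sobol design: run count per set, bounds, seed and skip offset."""

    n_runs_per_set: int = 1000
    bounds: dict = field(default_factory=lambda: dict(PARAM_BOUNDS))
    sobol_seed: int = 1234
    sobol_skip: int = 0
    share_points_across_sets: bool = True

    def __post_init__(self) -> None:
        if self.n_runs_per_set <= 0:
            raise ValueError("n_runs_per_set must be positive")
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bounds for {name!r} have min > max")

    @classmethod
    def from_config(cls, cfg: DesignConfig) -> "SamplingDesign":
        return cls(n_runs_per_set=cfg.n_runs_per_set, sobol_seed=cfg.sobol_seed,
                   sobol_skip=cfg.sobol_skip)


def sobol_sample(design: SamplingDesign) -> np.ndarray:
    """Sample the parameter hypercube with a scrambled Sobol sequence.

    Returns an ``(n_runs_per_set, 14)`` array in parameter units, columns
    in :data:`~landbound.parameters.PARAM_NAMES` order. Deterministic
    given ``(sobol_seed, sobol_skip)``.
    """
    names = [n for n in PARAM_NAMES if n in design.bounds]
    if set(names) != set(design.bounds):
        raise ValueError("bounds must cover exactly the 14 sampled parameters")
    lo = np.array([design.bounds[n][0] for n in names])
    hi = np.array([design.bounds[n][1] for n in names])
    engine = qmc.Sobol(d=len(names), scramble=True, seed=design.sobol_seed)
    if design.sobol_skip:
        engine.fast_forward(design.sobol_skip)
    with warnings.catch_warnings():
        # run counts need not be powers of two for a screening ensemble
        warnings.simplefilter("ignore", UserWarning)
        unit = engine.random(design.n_runs_per_set)
    return qmc.scale(unit, lo, hi)


def scenario_from_row(row: Sequence[float], set_id: str) -> ScenarioParameters:
    return ScenarioParameters(set_id=set_id, **dict(zip(PARAM_NAMES, map(float, row))))


@dataclass
class RunRecord:
    """Parameters, trajectory summaries and outcome of one model run."""

    run_id: str
    set_id: str
    params: ScenarioParameters
    cropland_path: list  # Mha, 2000-2050
    yield_path: list  # t ha-1, net global mean
    kcal_2050: list  # per-country daily supply
    outcome: TargetOutcome | None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None

    def to_json(self) -> str:
        payload = {
            "run_id": self.run_id,
            "set_id": self.set_id,
            "params": self.params.as_dict(),
            "cropland_path": self.cropland_path,
            "yield_path": self.yield_path,
            "kcal_2050": self.kcal_2050,
            "outcome": self.outcome.as_dict() if self.outcome else None,
            "error": self.error,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "RunRecord":
        d = json.loads(line)
        outcome = None
        if d.get("outcome"):
            outcome = TargetOutcome(**d["outcome"])
        return cls(run_id=d["run_id"], set_id=d["set_id"],
                   params=ScenarioParameters(**d["params"]),
                   cropland_path=d["cropland_path"], yield_path=d["yield_path"],
                   kcal_2050=d["kcal_2050"], outcome=outcome, error=d.get("error"))


def _record_from_result(run_id: str, res: RunResult, spec: TargetSpec) -> RunRecord:
    outcome = evaluate_targets(res.final_state, spec)
    return RunRecord(run_id=run_id, set_id=res.params.set_id, params=res.params,
                     cropland_path=[float(x) for x in res.cropland_path],
                     yield_path=[float(x) for x in res.yield_path],
                     kcal_2050=[float(x) for x in res.final_state.kcal],
                     outcome=outcome)


def run_experiment(world: WorldBaseline | PreparedWorld,
                   design: SamplingDesign,
                   sets: Iterable[str] = ("A", "B"),
                   demand_cfg: DemandConfig | None = None,
                   supply_cfg: SupplyConfig | None = None,
                   target_spec: TargetSpec | None = None,
                   out_dir: str | Path | None = None,
                   resume: bool = False,
                   progress: bool = False) -> list[RunRecord]:
    """Execute the two-set Monte Carlo design and return all run records.

    The same Sobol points are reused across sets (each set re-simulates
    them under its own bioenergy pathway and climate variant). A run that
    raises is recorded with its error message and excluded from screening
    by the caller, never silently dropped. With ``out_dir`` the records
    are streamed to ``runs.jsonl`` plus a flat ``summary.csv``; with
    ``resume`` run ids already present in the JSONL are skipped.
    """
    dem = demand_cfg or DemandConfig()
    sup = supply_cfg or SupplyConfig()
    spec = target_spec or TargetSpec()
    prep = world if isinstance(world, PreparedWorld) else prepare_world(world, dem, sup)
    if sup.kappa is None:
        kappa = calibrate_kappa(prep, dem, sup)
        sup = SupplyConfig(ref_income_growth=sup.ref_income_growth, kappa=kappa,
                           yield_anchor_2050=sup.yield_anchor_2050,
                           crop_energy_content=sup.crop_energy_content)

    matrix = sobol_sample(design)
    done: set[str] = set()
    jsonl_path = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        jsonl_path = out / "runs.jsonl"
        if resume and jsonl_path.exists():
            for line in jsonl_path.read_text().splitlines():
                done.add(json.loads(line)["run_id"])
        elif jsonl_path.exists():
            jsonl_path.unlink()

    records: list[RunRecord] = []
    handle = jsonl_path.open("a") if jsonl_path else None
    try:
        for set_id in sets:
            if design.share_points_across_sets:
                set_matrix = matrix
            else:
                offset_design = SamplingDesign(
                    n_runs_per_set=design.n_runs_per_set, bounds=design.bounds,
                    sobol_seed=design.sobol_seed,
                    sobol_skip=design.sobol_skip + design.n_runs_per_set
                    * (0 if set_id == "A" else 1))
                set_matrix = sobol_sample(offset_design)
            for i, row in enumerate(set_matrix):
                run_id = f"{set_id}-{i:05d}"
                if run_id in done:
                    continue
                try:
                    params = scenario_from_row(row, set_id)
                    rec = _record_from_result(run_id, simulate_run(prep, params, dem, sup), spec)
                except Exception as exc:  # noqa: BLE001 - flagged, not dropped
                    rec = RunRecord(run_id=run_id, set_id=set_id,
                                    params=scenario_from_row(row, set_id),
                                    cropland_path=[], yield_path=[], kcal_2050=[],
                                    outcome=None, error=f"{type(exc).__name__}: {exc}")
                records.append(rec)
                if handle:
                    handle.write(rec.to_json() + "\n")
                if progress and (i + 1) % 200 == 0:
                    print(f"set {set_id}: {i + 1}/{design.n_runs_per_set} runs")
    finally:
        if handle:
            handle.close()
    if out_dir is not None:
        records_to_frame(records).to_csv(Path(out_dir) / "summary.csv", index=False)
    return records


def load_records(path: str | Path) -> list[RunRecord]:
    """Read a run-record JSONL stream written by :func:`run_experiment`."""
    lines = Path(path).read_text().splitlines()
    return [RunRecord.from_json(line) for line in lines if line.strip()]


def records_to_frame(records: Sequence[RunRecord]) -> pd.DataFrame:
    """Flat one-row-per-run summary of an ensemble."""
    rows = []
    for r in records:
        row = {"run_id": r.run_id, "set_id": r.set_id, **r.params.as_dict(),
               "failed": r.failed}
        if r.outcome is not None:
            row.update({
                "cropland_2050": r.cropland_path[-1],
                "yield_2050": r.yield_path[-1],
                "min_kcal_2050": min(r.kcal_2050),
                **r.outcome.as_dict(),
            })
        rows.append(row)
    return pd.DataFrame(rows)
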