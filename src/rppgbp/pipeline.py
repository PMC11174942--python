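"""End-to-end orchestration: simulate, calibrate, estimate, evaluate.

Each function here is the library form of one CLI command. The camera /
face-detection front end is an input boundary, not code: the pipeline
consumes per-frame ROI channel-mean traces (CSV) and subject records,
and produces parameter tables, per-measurement reports, and agreement
metrics. Every run is reproducible from its config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import bp, features, ica, optimize, synthetic
from .bp import ParamTable, compute_bmi, default_intervals, estimate_bp, evaluate_metrics
from .errors import InsufficientDataError, InvalidArgumentError, SchemaError
from .trace import PulseTrace, read_trace_csv, write_trace_csv

__all__ = ["RunConfig", "simulate", "calibrate", "estimate", "evaluate"]

log = logging.getLogger("rppgbp")


@dataclass
class RunConfig:
    """Configuration shared by the pipeline commands.

    Mirrors the YAML config file: file paths, the frame rate, the
    measurement duration (10 s by default — one session of ten
    one-second windows), optimizer/ICA settings and the BMI strata.
    """

    trace_csv: str | None = None
    cohort_csv: str | None = None
    param_table_csv: str | None = None
    fps: float = 30.0
    duration_s: int = 10
    hr_band: tuple[float, float] = ica.DEFAULT_HR_BAND
    bmi_domain: tuple[float, float] = bp.DEFAULT_BMI_DOMAIN
    bmi_interval_width: float = bp.DEFAULT_INTERVAL_WIDTH
    expansion_target: int = 20
    n_subjects_per_interval: int = 10
    bp_noise_sd: float = 0.0
    noise_sd: float = 0.05
    seed: int = 0
    ica: ica.ICAConfig = field(default_factory=ica.ICAConfig)
    nmpso: optimize.NMPSOConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        if "ica" in raw:
            raw["ica"] = ica.ICAConfig(**raw["ica"])
        if "nmpso" in raw:
            raw["nmpso"] = optimize.NMPSOConfig(**raw["nmpso"])
        for key in ("hr_band", "bmi_domain"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def intervals(self) -> list[tuple[float, float]]:
        return default_intervals(self.bmi_domain, self.bmi_interval_width)


def simulate(config: RunConfig, out_dir: str | Path) -> dict[str, str]:
    """Write a mixed noisy RGB trace and a synthetic cohort CSV.

    The trace is a pulse wave plus two artifact sources mixed into three
    channels; the cohort draws subjects per BMI stratum from the default
    generating parameters. Deterministic under ``config.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    sources = synthetic.make_artifact_sources(
        duration=config.duration_s, fps=config.fps, seed=seed)
    A = np.array([[1.0, 0.5, 0.3],
                  [0.6, 1.0, 0.4],
                  [0.4, 0.7, 1.0]])
    mixed = synthetic.mix_sources(
        sources, synthetic.MixingSpec(A=A, noise_sd=config.noise_sd, seed=seed + 1))
    trace_path = out_dir / "trace.csv"
    write_trace_csv(mixed, trace_path)

    records = []
    for k, (lo, hi) in enumerate(config.intervals()):
        spec = synthetic.CohortSpec(
            n_subjects=config.n_subjects_per_interval,
            bmi_range=(lo, hi),
            bp_noise_sd=config.bp_noise_sd,
            seed=seed + 100 + k,
        )
        records.extend(synthetic.generate_cohort(spec))
    cohort_path = out_dir / "cohort.csv"
    bp.write_cohort_csv(records, cohort_path)
    log.info("simulate: wrote %s (%d samples) and %s (%d subjects), seed=%d",
             trace_path, mixed.n_samples, cohort_path, len(records), seed)
    return {"trace_csv": str(trace_path), "cohort_csv": str(cohort_path)}


def calibrate(config: RunConfig, out_dir: str | Path) -> ParamTable:
    """Fit the per-stratum empirical parameters from a cohort CSV and
    write the table as CSV + JSON."""
    if not config.cohort_csv:
        raise InvalidArgumentError("calibrate requires cohort_csv")
    cohort = bp.read_cohort_csv(config.cohort_csv)
    table = optimize.build_param_table(
        cohort, config.intervals(),
        expansion_target=config.expansion_target,
        config=config.nmpso, seed=config.seed,
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / "param_table.csv")
    table.to_json(out_dir / "param_table.json")
    for iv in table.intervals:
        recs = [r for r in cohort if iv.contains(r.bmi)]
        for kind in ("sbp", "dbp"):
            params = iv.sbp if kind == "sbp" else iv.dbp
            pred = [estimate_bp(params, r.feature(kind), r.bmi) for r in recs]
            ref = [r.reference(kind) for r in recs]
            rmse = float(np.sqrt(np.mean((np.array(pred) - np.array(ref)) ** 2)))
            log.info("calibrate: interval [%.1f, %.1f) %s fitness RMSE %.3f mmHg",
                     iv.low, iv.high, kind.upper(), rmse)
    return table


def estimate(config: RunConfig, height_m: float, weight_kg: float) -> dict[str, Any]:
    """One non-contact measurement: trace -> ICA -> features -> formulas.

    Returns a report with the per-second amplitude table, the session
    E_peak / E_valley, and the SBP/DBP estimates (truncated at the
    reporting boundary only).
    """
    if not (config.trace_csv and config.param_table_csv):
        raise InvalidArgumentError("estimate requires trace_csv and param_table_csv")
    trace = read_trace_csv(config.trace_csv, fps=config.fps)
    if trace.duration < config.duration_s:
        raise InsufficientDataError(
            f"trace covers {trace.duration:.2f} s but {config.duration_s} s are required")
    table = ParamTable.from_csv(config.param_table_csv)
    bmi = compute_bmi(height_m, weight_kg)

    pulse, _ = ica.separate_pulse(trace, config.ica, config.hr_band)
    summary = features.summarize_trace(pulse, config.duration_s)

    sbp_params = table.lookup(bmi, "sbp")
    dbp_params = table.lookup(bmi, "dbp")
    sbp = estimate_bp(sbp_params, summary.e_peak, bmi)
    dbp = estimate_bp(dbp_params, summary.e_valley, bmi)
    report = {
        "bmi": bmi,
        "e_peak": summary.e_peak,
        "e_valley": summary.e_valley,
        "sbp_mmhg": bp.truncate2(sbp),
        "dbp_mmhg": bp.truncate2(dbp),
        "per_second": summary.to_frame().to_dict(orient="records"),
    }
    log.info("estimate: BMI %.2f, E_peak %.4f, E_valley %.4f -> SBP %.2f / DBP %.2f",
             bmi, summary.e_peak, summary.e_valley, report["sbp_mmhg"], report["dbp_mmhg"])
    return report


def evaluate(reference_csv: str | Path, out_path: str | Path | None = None) -> dict[str, Any]:
    """Agreement metrics from a paired reference/estimate CSV.

    Expects columns ``sbp_ref,sbp_est,dbp_ref,dbp_est`` (any subset of
    the two pairs). Writes a JSON report when ``out_path`` is given.
    """
    import pandas as pd

    df = pd.read_csv(reference_csv)
    out: dict[str, Any] = {}
    pairs = [("sbp", "sbp_ref", "sbp_est"), ("dbp", "dbp_ref", "dbp_est")]
    found = False
    for name, ref_col, est_col in pairs:
        if ref_col in df.columns and est_col in df.columns:
            found = True
            m = evaluate_metrics(df[ref_col], df[est_col])
            out[name] = m.to_dict()
    if not found:
        raise SchemaError(
            f"{reference_csv}: need columns sbp_ref,sbp_est and/or dbp_ref,dbp_est")
    if out_path is not None:
        Path(out_path).write_text(json.dumps(out, indent=1))
    return out
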