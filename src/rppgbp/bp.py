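"""Blood-pressure model: BMI, the empirical pressure formulas, the
BMI-interval parameter table, and the evaluation metrics.

The model at the core of the package predicts systolic and diastolic
pressure from a single pulse-amplitude feature and the subject's body
mass index::

    SBP = a0 + a1 * E_peak   + BMI * (1 + a2 * E_peak)
    DBP = a0 + a1 * E_valley + BMI * (1 + a2 * E_valley)

where ``E_peak`` / ``E_valley`` are the session-averaged pulse peak and
valley amplitudes and ``(a0, a1, a2)`` are empirical parameters fitted
per BMI stratum. The parenthesised reading ``BMI * (1 + a2 * x)`` is the
only non-degenerate three-parameter form: the flat alternative collapses
into an affine model with a redundant coefficient.

Reported percentages and averages are truncated (not rounded) to two
decimals, matching the convention of the reference worked examples;
internal computation keeps full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, OutOfRangeError, SchemaError

__all__ = [
    "Kind",
    "BPParams",
    "SubjectRecord",
    "BMIInterval",
    "ParamTable",
    "Metrics",
    "truncate2",
    "compute_bmi",
    "estimate_bp",
    "absolute_error_pct",
    "evaluate_metrics",
    "read_cohort_csv",
    "write_cohort_csv",
]

Kind = Literal["sbp", "dbp"]

#: BMI domain the calibration is recommended for, kg/m^2.
DEFAULT_BMI_DOMAIN = (17.0, 29.0)
#: Default stratum width, kg/m^2.
DEFAULT_INTERVAL_WIDTH = 2.0


def truncate2(x: float) -> float:
    """Truncate toward zero to two decimals.

    Used at reporting boundaries only. A tiny guard absorbs binary
    representation error so that e.g. a value that is exactly 0.55 in
    decimal does not truncate to 0.54.
    """
    if not math.isfinite(x):
        raise InvalidArgumentError(f"cannot truncate non-finite value {x}")
    sign = -1.0 if x < 0 else 1.0
    return sign * math.floor(abs(x) * 100.0 + 1e-9) / 100.0


def compute_bmi(height_m: float, weight_kg: float) -> float:
    """Body mass index, weight / height^2 (kg/m^2)."""
    if not (height_m > 0) or not (weight_kg > 0):
        raise InvalidArgumentError(
            f"height and weight must be positive, got height={height_m}, weight={weight_kg}"
        )
    return weight_kg / height_m**2


@dataclass(frozen=True)
class BPParams:
    """The empirical triple (a0, a1, a2) for one pressure kind.

    ``a0`` carries mmHg; ``a1`` maps feature amplitude to mmHg; ``a2``
    scales the feature-BMI interaction (per-amplitude, dimensionless
    against BMI's own mmHg-per-unit contribution).
    """

    a0: float
    a1: float
    a2: float
    kind: Kind = "sbp"

    def __post_init__(self):
        for name in ("a0", "a1", "a2"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidArgumentError(f"{name} must be finite")
        if self.kind not in ("sbp", "dbp"):
            raise InvalidArgumentError(f"kind must be 'sbp' or 'dbp', got {self.kind!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2], dtype=float)


def estimate_bp(params: BPParams, x: float, bmi: float) -> float:
    """Evaluate the pressure formula a0 + a1*x + BMI*(1 + a2*x), mmHg.

    ``x`` is E_peak for systolic parameters, E_valley for diastolic.
    Accepts scalars or arrays (broadcast).
    """
    x = np.asarray(x, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(bmi))):
        raise InvalidArgumentError("x and bmi must be finite")
    out = params.a0 + params.a1 * x + bmi * (1.0 + params.a2 * x)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SubjectRecord:
    """One calibration row: anthropometrics, reference pressures, and the
    measured pulse features."""

    height_m: float
    weight_kg: float
    sbp_ref: float
    dbp_ref: float
    e_peak: float
    e_valley: float
    subject_id: str = ""

    def __post_init__(self):
        if not (self.height_m > 0 and self.weight_kg > 0):
            raise InvalidArgumentError("height and weight must be positive")
        if not (self.sbp_ref > 0 and self.dbp_ref > 0):
            raise InvalidArgumentError("reference pressures must be positive")
        if self.sbp_ref <= self.dbp_ref:
            raise InvalidArgumentError(
                f"systolic ({self.sbp_ref}) must exceed diastolic ({self.dbp_ref})"
            )

    @property
    def bmi(self) -> float:
        return compute_bmi(self.height_m, self.weight_kg)

    def feature(self, kind: Kind) -> float:
        return self.e_peak if kind == "sbp" else self.e_valley

    def reference(self, kind: Kind) -> float:
        return self.sbp_ref if kind == "sbp" else self.dbp_ref


@dataclass(frozen=True)
class BMIInterval:
    """A half-open BMI stratum [low, high) holding one parameter triple
    per pressure kind."""

    low: float
    high: float
    sbp: BPParams
    dbp: BPParams

    def __post_init__(self):
        if not (self.low < self.high):
            raise InvalidArgumentError(f"empty interval [{self.low}, {self.high})")

    def contains(self, bmi: float) -> bool:
        return self.low <= bmi < self.high


class ParamTable:
    """Ordered, gap-free BMI intervals, each with SBP and DBP parameters.

    The lookup convention is half-open: a BMI on an interval's left edge
    belongs to that interval.
    """

    def __init__(self, intervals: Sequence[BMIInterval]):
        if not intervals:
            raise InvalidArgumentError("parameter table needs at least one interval")
        ivs = sorted(intervals, key=lambda iv: iv.low)
        for a, b in zip(ivs, ivs[1:]):
            if not math.isclose(a.high, b.low, abs_tol=1e-9):
                raise InvalidArgumentError(
                    f"intervals must tile the domain without gaps/overlaps: "
                    f"[{a.low}, {a.high}) then [{b.low}, {b.high})"
                )
        self.intervals: list[BMIInterval] = list(ivs)

    @property
    def domain(self) -> tuple[float, float]:
        return (self.intervals[0].low, self.intervals[-1].high)

    def lookup(self, bmi: float, kind: Kind) -> BPParams:
        """Parameters of the unique interval containing ``bmi``."""
        for iv in self.intervals:
            if iv.contains(bmi):
                return iv.sbp if kind == "sbp" else iv.dbp
        lo, hi = self.domain
        raise OutOfRangeError(f"BMI {bmi} outside covered domain [{lo}, {hi})")

    # ---- serialization ----

    _COLUMNS = ["bmi_low", "bmi_high", "kind", "a0", "a1", "a2"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iv in self.intervals:
            for kind in ("sbp", "dbp"):
                p = iv.sbp if kind == "sbp" else iv.dbp
                rows.append((iv.low, iv.high, kind, p.a0, p.a1, p.a2))
        return pd.DataFrame(rows, columns=self._COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_frame().to_dict(orient="records"), indent=1))

    @classmethod
    def _from_frame(cls, df: pd.DataFrame, source: str) -> "ParamTable":
        missing = set(cls._COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"{source}: missing columns {sorted(missing)}")
        intervals = []
        for (lo, hi), grp in df.groupby(["bmi_low", "bmi_high"], sort=True):
            by_kind = {}
            for _, row in grp.iterrows():
                by_kind[row["kind"]] = BPParams(
                    float(row["a0"]), float(row["a1"]), float(row["a2"]), row["kind"]
                )
            if set(by_kind) != {"sbp", "dbp"}:
                raise SchemaError(f"{source}: interval [{lo}, {hi}) must have sbp and dbp rows")
            intervals.append(BMIInterval(float(lo), float(hi), by_kind["sbp"], by_kind["dbp"]))
        return cls(intervals)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParamTable":
        return cls._from_frame(pd.read_csv(path, float_precision="round_trip"), str(path))

    @classmethod
    def from_json(cls, path: str | Path) -> "ParamTable":
        return cls._from_frame(pd.DataFrame(json.loads(Path(path).read_text())), str(path))

    @classmethod
    def from_xlsx(cls, path: str | Path, sheet: int | str = 0) -> "ParamTable":
        """Import from a spreadsheet with the same columns (first sheet by
        default); provided for parity with spreadsheet-maintained tables."""
        import openpyxl  # noqa: F401 — engine for pandas

        return cls._from_frame(pd.read_excel(path, sheet_name=sheet, engine="openpyxl"), str(path))


def default_intervals(
    domain: tuple[float, float] = DEFAULT_BMI_DOMAIN,
    width: float = DEFAULT_INTERVAL_WIDTH,
) -> list[tuple[float, float]]:
    """Tile the BMI domain with half-open strata of the given width."""
    lo, hi = domain
    if not (lo < hi) or not (width > 0):
        raise InvalidArgumentError("domain must be non-empty and width positive")
    edges = [lo]
    while edges[-1] + width < hi - 1e-9:
        edges.append(edges[-1] + width)
    edges.append(hi)
    return list(zip(edges[:-1], edges[1:]))


def absolute_error_pct(experimental: float, machine: float) -> float:
    """Percent absolute error of a machine (cuff) reading against the
    experimental (system) value, truncated to two decimals:
    |experimental - machine| / experimental * 100.
    """
    if not (experimental > 0):
        raise InvalidArgumentError(f"experimental reading must be positive, got {experimental}")
    return truncate2(abs(experimental - machine) / experimental * 100.0)


@dataclass(frozen=True)
class Metrics:
    """Agreement metrics between reference and estimated pressures."""

    mape: float  # mean absolute percentage error, %
    rmse: float  # root-mean-square error, mmHg
    mae: float  # mean absolute error, mmHg
    std: float  # std of signed errors (estimated - actual), mmHg
    r2: float  # coefficient of determination

    def to_dict(self) -> dict[str, float]:
        return {"mape_pct": self.mape, "rmse": self.rmse, "mae": self.mae,
                "std": self.std, "r2": self.r2}

    def to_table(self) -> str:
        """Human-readable report (values truncated to 2 decimals)."""
        lines = [
            f"R^2          {truncate2(self.r2):>8.2f}",
            f"MAPE (%)     {truncate2(self.mape):>8.2f}",
            f"RMSE (mmHg)  {truncate2(self.rmse):>8.2f}",
            f"MAE (mmHg)   {truncate2(self.mae):>8.2f}",
            f"STD (mmHg)   {truncate2(self.std):>8.2f}",
        ]
        return "\n".join(lines)


def evaluate_metrics(
    actual: Iterable[float],
    predicted: Iterable[float],
    *,
    std_of_absolute: bool = False,
) -> Metrics:
    """Compute MAPE, RMSE, MAE, STD and R^2.

    MAPE is reported in percent. STD is the sample standard deviation
    (N-1 denominator) of the signed errors ``predicted - actual``;
    ``std_of_absolute=True`` switches to the absolute errors.
    """
    y = np.asarray(list(actual), dtype=float)
    yhat = np.asarray(list(predicted), dtype=float)
    if y.size == 0:
        raise InvalidArgumentError("empty input")
    if y.shape != yhat.shape:
        raise InvalidArgumentError(f"length mismatch: {y.size} actual vs {yhat.size} predicted")
    if np.any(y == 0):
        raise InvalidArgumentError("actual values must be non-zero for MAPE")
    err = yhat - y
    mape = float(np.mean(np.abs(err) / np.abs(y))) * 100.0
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    basis = np.abs(err) if std_of_absolute else err
    std = float(np.std(basis, ddof=1)) if y.size > 1 else 0.0
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(err**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return Metrics(mape=mape, rmse=rmse, mae=mae, std=std, r2=r2)


# ---- cohort CSV ----

_COHORT_COLUMNS = ["subject_id", "height_m", "weight_kg", "bmi", "sbp_ref", "dbp_ref",
                   "e_peak", "e_valley"]


def write_cohort_csv(records: Sequence[SubjectRecord], path: str | Path) -> None:
    rows = [
        (r.subject_id or f"S{i:03d}", r.height_m, r.weight_kg, r.bmi,
         r.sbp_ref, r.dbp_ref, r.e_peak, r.e_valley)
        for i, r in enumerate(records)
    ]
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise SchemaError(f"{path}: empty cohort file")
    missing = set(_COHORT_COLUMNS) - set(df.columns) - {"bmi", "subject_id"}
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                height_m=float(row["height_m"]),
                weight_kg=float(row["weight_kg"]),
                sbp_ref=float(row["sbp_ref"]),
                dbp_ref=float(row["dbp_ref"]),
                e_peak=float(row["e_peak"]),
                e_valley=float(row["e_valley"]),
                subject_id=str(row.get("subject_id", "")),
            )
        )
    return records
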