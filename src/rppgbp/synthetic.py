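"""Synthetic signal and cohort generation.

Three generators make every downstream stage testable without a camera:

* :func:`generate_pressure_wave` — the radial-resonance pressure wave,
  truncated to its zeroth and first harmonics:
  ``p(t) = a0 + exp(-z/c) * (Q cos(w t) + R sin(w t))``, where ``z`` is
  the subject-to-lens distance and ``c`` the wave velocity, so the
  first-harmonic amplitude decays with distance.
* :func:`mix_sources` — the linear instantaneous mixing model of blind
  source separation, ``X = A S + noise``.
* :func:`generate_cohort` — calibration cohorts whose reference
  pressures follow the BMI-parameterised formulas with known parameters
  plus Gaussian noise, for parameter-recovery studies.

All randomness flows from an explicit per-call seed; no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import sawtooth

from .bp import BPParams, SubjectRecord, estimate_bp
from .errors import InvalidArgumentError
from .trace import PulseTrace

__all__ = [
    "RRTParams",
    "MixingSpec",
    "CohortSpec",
    "generate_pressure_wave",
    "mix_sources",
    "make_artifact_sources",
    "generate_cohort",
]

#: Default fundamental angular frequency: 72 beats/min.
DEFAULT_OMEGA = 2.0 * np.pi * 1.2


@dataclass(frozen=True)
class RRTParams:
    """Parameters of the two-harmonic radial pressure wave.

    ``a0`` is the zeroth-order (DC) amplitude; ``Q`` and ``R`` the
    first-order cosine/sine amplitudes; ``omega`` the fundamental angular
    frequency in rad/s; ``z`` the subject-to-lens distance (cm) and ``c``
    the wave velocity (cm/s), which together attenuate the first
    harmonic by ``exp(-z/c)``.
    """

    a0: float = 0.0
    Q: float = 1.0
    R: float = 0.0
    omega: float = DEFAULT_OMEGA
    z: float = 0.0
    c: float = 100.0

    def __post_init__(self):
        if not (self.omega > 0):
            raise InvalidArgumentError(f"omega must be positive, got {self.omega}")
        if not (self.c > 0):
            raise InvalidArgumentError(f"wave velocity c must be positive, got {self.c}")
        if self.z < 0:
            raise InvalidArgumentError(f"distance z must be non-negative, got {self.z}")


def generate_pressure_wave(params: RRTParams, duration: float, fps: float) -> PulseTrace:
    """Sample the two-harmonic pressure wave at ``fps`` for ``duration`` s.

    Sample ``i`` equals ``a0 + exp(-z/c) * (Q cos(w t_i) + R sin(w t_i))``
    with ``t_i = i / fps``; the trace has ``round(duration * fps)``
    samples.
    """
    if not (duration > 0) or not (fps > 0):
        raise InvalidArgumentError(f"duration and fps must be positive, got {duration}, {fps}")
    n = int(round(duration * fps))
    if n < 2:
        raise InvalidArgumentError(f"duration*fps = {duration * fps:g} yields fewer than 2 samples")
    t = np.arange(n) / fps
    atten = np.exp(-params.z / params.c)
    samples = params.a0 + atten * (
        params.Q * np.cos(params.omega * t) + params.R * np.sin(params.omega * t)
    )
    return PulseTrace(samples, fps)


@dataclass(frozen=True)
class MixingSpec:
    """Linear mixing of sources into observed channels: X = A S + noise."""

    A: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise InvalidArgumentError("mixing matrix must have full column rank")
        if self.noise_sd < 0:
            raise InvalidArgumentError(f"noise_sd must be non-negative, got {self.noise_sd}")
        object.__setattr__(self, "A", A)


def mix_sources(sources: PulseTrace, spec: MixingSpec) -> PulseTrace:
    """Mix source channels through ``spec.A`` and add Gaussian sensor noise.

    Reproducible under ``spec.seed``.
    """
    if sources.n_channels != spec.A.shape[1]:
        raise InvalidArgumentError(
            f"source channel count {sources.n_channels} does not match "
            f"mixing matrix columns {spec.A.shape[1]}"
        )
    X = spec.A @ sources.samples
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        X = X + rng.normal(0.0, spec.noise_sd, size=X.shape)
    return PulseTrace(X, sources.fps)


def make_artifact_sources(
    duration: float,
    fps: float,
    *,
    pulse: RRTParams | None = None,
    flicker_hz: float = 0.35,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> PulseTrace:
    """A 3-source fixture: pulse wave, sawtooth drift, and white noise.

    The waveforms present in real recordings alongside the pulse (light
    flicker, slow motion drift) are not pinned down by any physical
    model here; a sawtooth plus broadband noise is a generic stand-in
    with the non-Gaussianity blind separation needs. Each source is
    standardised to zero mean, unit variance.
    """
    pulse = pulse or RRTParams(a0=0.0, Q=1.0, R=0.4)
    wave = generate_pressure_wave(pulse, duration, fps)
    t = wave.times
    rng = np.random.default_rng(seed)
    saw = sawtooth(2.0 * np.pi * flicker_hz * t)
    noise = rng.normal(0.0, noise_sd, size=t.size)
    S = np.vstack([wave.samples[0], saw, noise])
    S = S - S.mean(axis=1, keepdims=True)
    sd = S.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return PulseTrace(S / sd, fps)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic calibration cohort.

    Reference pressures are generated from the BMI-parameterised
    formulas at the given true parameters plus Gaussian noise of scale
    ``bp_noise_sd`` (mmHg). BMI and the pulse features are uniform over
    their ranges; heights are uniform over ``height_range`` and weights
    derived so that weight/height^2 reproduces the drawn BMI exactly.
    """

    n_subjects: int
    true_params_sbp: BPParams = field(
        default_factory=lambda: BPParams(90.0, 10.0, 0.5, "sbp"))
    true_params_dbp: BPParams = field(
        default_factory=lambda: BPParams(45.0, 8.0, 0.3, "dbp"))
    bmi_range: tuple[float, float] = (17.0, 29.0)
    feature_range: tuple[float, float] = (0.1, 0.9)
    height_range: tuple[float, float] = (1.5, 1.9)
    bp_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidArgumentError(f"n_subjects must be >= 1, got {self.n_subjects}")
        lo, hi = self.bmi_range
        if not (10.0 <= lo < hi <= 60.0):
            raise InvalidArgumentError(f"implausible BMI range {self.bmi_range}")
        flo, fhi = self.feature_range
        if not (flo < fhi):
            raise InvalidArgumentError(f"empty feature range {self.feature_range}")
        if self.bp_noise_sd < 0:
            raise InvalidArgumentError("bp_noise_sd must be non-negative")


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a cohort of subjects with known-model reference pressures.

    Each subject's reference SBP is the systolic formula evaluated at
    (true_params_sbp, E_peak, BMI) plus N(0, bp_noise_sd); DBP
    analogously with E_valley. Reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    bmi = rng.uniform(*spec.bmi_range, size=n)
    e_peak = rng.uniform(*spec.feature_range, size=n)
    e_valley = rng.uniform(*spec.feature_range, size=n)
    height = rng.uniform(*spec.height_range, size=n)
    weight = bmi * height**2
    sbp = estimate_bp(spec.true_params_sbp, e_peak, bmi)
    dbp = estimate_bp(spec.true_params_dbp, e_valley, bmi)
    if spec.bp_noise_sd > 0:
        sbp = sbp + rng.normal(0.0, spec.bp_noise_sd, size=n)
        dbp = dbp + rng.normal(0.0, spec.bp_noise_sd, size=n)
    sbp = np.atleast_1d(sbp)
    dbp = np.atleast_1d(dbp)
    return [
        SubjectRecord(
            height_m=float(height[i]),
            weight_kg=float(weight[i]),
            sbp_ref=float(sbp[i]),
            dbp_ref=float(dbp[i]),
            e_peak=float(e_peak[i]),
            e_valley=float(e_valley[i]),
            subject_id=f"S{i:03d}",
        )
        for i in range(n)
    ]
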