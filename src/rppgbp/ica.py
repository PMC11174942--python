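"""Blind source separation of the pulse component from channel-mean traces.

The chain is the classical fixed-point independent component analysis:
center each channel, whiten to identity covariance, then estimate an
orthonormal separating matrix W row by row with the Newton-type
fixed-point update

    w  <-  E[z g(w'z)] - E[g'(w'z)] w,

renormalising and decorrelating against previously extracted rows
(deflation) each iteration. The separated components are defined only up
to sign, scale and permutation, so :func:`select_pulse_component` picks
the component whose periodogram concentrates power in the heart-rate
band and standardises its sign and scale.

A semi-blind variant — when the mixing matrix is approximately known —
is supported by initialising W from the supplied matrix instead of at
random (``ICAConfig.init_mixing``); the estimation procedure is
otherwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import linalg
from scipy.signal import periodogram

from .errors import DegenerateInputError, InvalidArgumentError
from .trace import PulseTrace

__all__ = ["ICAConfig", "ICAResult", "center", "whiten", "fastica",
           "select_pulse_component", "separate_pulse"]

#: Physiologically plausible heart-rate band, Hz (42-180 bpm).
DEFAULT_HR_BAND = (0.7, 3.0)

#: Allowed deviation of a "whitened" input's covariance from identity.
_WHITE_TOL = 1e-6


def _logcosh(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = np.tanh(u)
    return g, 1.0 - g**2


def _cube(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return u**3, 3.0 * u**2


_CONTRASTS: dict[str, Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]] = {
    "logcosh": _logcosh,
    "cube": _cube,
}


@dataclass(frozen=True)
class ICAConfig:
    """Settings for the fixed-point estimation.

    ``contrast`` selects the nonlinearity: ``"logcosh"`` (robust default)
    or ``"cube"`` (kurtosis-based). ``decorrelation`` chooses deflation
    (one row at a time, Gram-Schmidt against earlier rows) or symmetric
    (all rows jointly). ``init_mixing`` switches to the semi-blind mode:
    W is initialised from the pseudo-inverse of the whitened mixing
    matrix rather than randomly.
    """

    n_components: int | None = None
    max_iter: int = 200
    tol: float = 1e-6
    contrast: Literal["logcosh", "cube"] = "logcosh"
    decorrelation: Literal["deflation", "symmetric"] = "deflation"
    seed: int = 0
    init_mixing: np.ndarray | None = None

    def __post_init__(self):
        if self.n_components is not None and self.n_components < 1:
            raise InvalidArgumentError("n_components must be >= 1")
        if self.max_iter < 1:
            raise InvalidArgumentError("max_iter must be >= 1")
        if not (self.tol > 0):
            raise InvalidArgumentError("tol must be positive")
        if self.contrast not in _CONTRASTS:
            raise InvalidArgumentError(f"unknown contrast {self.contrast!r}")


@dataclass
class ICAResult:
    """Output of :func:`fastica` plus the preprocessing that produced it.

    ``W`` has the estimated unmixing rows (orthonormal in the whitened
    space); ``Y = W @ Z`` are the independent components. ``V`` and
    ``mean`` record the whitening matrix and removed channel means, so
    the full separation from raw X is ``Y = W @ V @ (X - mean)``.
    """

    W: np.ndarray
    V: np.ndarray
    mean: np.ndarray
    Y: PulseTrace
    converged: bool
    n_iter: int
    #: per extracted row, the contrast objective E[G(w'z)] per iteration
    objective_history: list[list[float]] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "W": self.W.tolist(),
            "V": self.V.tolist(),
            "mean": self.mean.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def center(X: PulseTrace) -> tuple[PulseTrace, np.ndarray]:
    """Remove each channel's mean; returns the centered trace and the means."""
    if X.n_samples < 2:
        raise InvalidArgumentError("need at least 2 samples to center")
    mean = X.samples.mean(axis=1)
    return PulseTrace(X.samples - mean[:, None], X.fps), mean


def whiten(X_centered: PulseTrace) -> tuple[PulseTrace, np.ndarray]:
    """Decorrelate channels to identity covariance.

    V = D^(-1/2) E' from the eigendecomposition of the channel
    covariance C = E D E'; returns (Z, V) with Z = V X and sample
    covariance of Z equal to I.
    """
    Xc = X_centered.samples
    n = Xc.shape[1]
    C = (Xc @ Xc.T) / (n - 1)
    evals, evecs = linalg.eigh(C)
    rel = evals / max(evals.max(), np.finfo(float).tiny)
    if evals.min() <= 0 or rel.min() < 1e-12:
        n_ok = int(np.sum(rel >= 1e-12))
        raise DegenerateInputError(
            f"channel covariance is rank-deficient: only {n_ok} of "
            f"{Xc.shape[0]} channels are linearly independent"
        )
    V = (evecs / np.sqrt(evals)).T  # rows scaled: D^(-1/2) E'
    return PulseTrace(V @ Xc, X_centered.fps), V


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W <- (W W')^(-1/2) W."""
    evals, evecs = linalg.eigh(W @ W.T)
    return (evecs / np.sqrt(evals)) @ evecs.T @ W


def _check_white(Z: np.ndarray) -> None:
    n = Z.shape[1]
    C = (Z @ Z.T) / (n - 1)
    dev = np.max(np.abs(C - np.eye(Z.shape[0])))
    if dev > 1e-2:
        raise InvalidArgumentError(
            f"fastica requires whitened input; covariance deviates from "
            f"identity by {dev:.3g}"
        )


def fastica(Z: PulseTrace, config: ICAConfig = ICAConfig()) -> ICAResult:
    """Estimate the separating matrix from whitened data.

    Deflation mode extracts one row at a time, decorrelating each
    candidate against already-accepted rows; symmetric mode updates all
    rows jointly. Iteration stops when |1 - |<w_new, w_old>|| < tol on
    every row, or at ``max_iter`` (``converged`` reports which).
    """
    Zs = Z.samples
    _check_white(Zs)
    n_ch, n_samp = Zs.shape
    n_comp = config.n_components or n_ch
    if n_comp > n_ch:
        raise InvalidArgumentError(f"cannot extract {n_comp} components from {n_ch} channels")
    g_fn = _CONTRASTS[config.contrast]
    rng = np.random.default_rng(config.seed)

    if config.init_mixing is not None:
        A = np.atleast_2d(np.asarray(config.init_mixing, dtype=float))
        if A.shape[0] != n_ch:
            raise InvalidArgumentError(
                f"init_mixing has {A.shape[0]} rows, expected {n_ch}")
        # Semi-blind: in whitened space the unmixing is ~ pinv(A_white).
        W0 = np.linalg.pinv(A)[:n_comp]
        # Orthonormalise to a valid starting point.
        W0 = _sym_decorrelate(W0 + 1e-12 * np.eye(*W0.shape))
    else:
        W0 = rng.standard_normal((n_comp, n_ch))
        W0 = _sym_decorrelate(W0)

    def _update_row(w: np.ndarray) -> np.ndarray:
        wz = w @ Zs
        g, g_prime = g_fn(wz)
        return (Zs @ g) / n_samp - g_prime.mean() * w

    def _objective(w: np.ndarray) -> float:
        wz = w @ Zs
        if config.contrast == "logcosh":
            return float(np.mean(np.logaddexp(wz, -wz) - np.log(2.0)))  # log cosh
        return float(np.mean(wz**4) / 4.0)

    objective_history: list[list[float]] = []
    if config.decorrelation == "deflation":
        W = np.zeros((n_comp, n_ch))
        total_iter = 0
        converged = True
        for i in range(n_comp):
            w = W0[i].copy()
            w -= W[:i].T @ (W[:i] @ w)
            w /= np.linalg.norm(w)
            row_converged = False
            row_hist: list[float] = []
            for _ in range(config.max_iter):
                total_iter += 1
                w_new = _update_row(w)
                w_new -= W[:i].T @ (W[:i] @ w_new)
                w_new /= np.linalg.norm(w_new)
                row_hist.append(_objective(w_new))
                if abs(1.0 - abs(w_new @ w)) < config.tol:
                    w = w_new
                    row_converged = True
                    break
                w = w_new
            W[i] = w
            converged = converged and row_converged
            objective_history.append(row_hist)
        n_iter = total_iter
    else:
        W = W0.copy()
        converged = False
        n_iter = config.max_iter
        joint_hist: list[float] = []
        for it in range(config.max_iter):
            W_new = np.vstack([_update_row(w) for w in W])
            W_new = _sym_decorrelate(W_new)
            delta = np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0))
            W = W_new
            joint_hist.append(float(sum(_objective(w) for w in W)))
            if delta < config.tol:
                converged = True
                n_iter = it + 1
                break
        objective_history.append(joint_hist)

    Y = PulseTrace(W @ Zs, Z.fps)
    return ICAResult(W=W, V=np.eye(n_ch), mean=np.zeros(n_ch), Y=Y,
                     converged=converged, n_iter=n_iter,
                     objective_history=objective_history)


def band_power_fraction(x: np.ndarray, fps: float, band: tuple[float, float]) -> float:
    """Fraction of (non-DC) periodogram power inside ``band`` Hz."""
    freqs, power = periodogram(x, fs=fps, detrend=False)
    keep = freqs > 0
    freqs, power = freqs[keep], power[keep]
    total = power.sum()
    if total == 0:
        return 0.0
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    return float(power[in_band].sum() / total)


def select_pulse_component(
    Y: PulseTrace,
    hr_band: tuple[float, float] = DEFAULT_HR_BAND,
) -> PulseTrace:
    """Pick the separated component that looks most like a pulse.

    The winner maximises the fraction of periodogram power inside the
    heart-rate band. Because ICA leaves sign and scale undefined, the
    output is flipped so the dominant extremum polarity is peaks-up
    (the excursion above the mean exceeds the one below) and rescaled to
    unit variance.
    """
    lo, hi = hr_band
    nyquist = Y.fps / 2.0
    lo, hi = max(lo, 0.0), min(hi, nyquist)
    if not (0.0 < lo < hi):
        raise InvalidArgumentError(
            f"heart-rate band {hr_band} empty after clipping to (0, {nyquist}) Hz")
    fractions = [band_power_fraction(Y.samples[i], Y.fps, (lo, hi))
                 for i in range(Y.n_channels)]
    best = int(np.argmax(fractions))
    x = Y.samples[best].astype(float)
    x = x - x.mean()
    if (x.max() + x.min()) < 0:  # deeper valleys than peaks: flip
        x = -x
    sd = x.std()
    if sd > 0:
        x = x / sd
    return PulseTrace(x, Y.fps)


def separate_pulse(
    X: PulseTrace,
    config: ICAConfig = ICAConfig(),
    hr_band: tuple[float, float] = DEFAULT_HR_BAND,
) -> tuple[PulseTrace, ICAResult]:
    """Full separation: center -> whiten -> fastica -> component selection.

    Returns the standardized pulse component and the fitted ICAResult
    (with V and mean filled in so the separation can be re-applied).
    """
    Xc, mean = center(X)
    Z, V = whiten(Xc)
    result = fastica(Z, config)
    result.V = V
    result.mean = mean
    pulse = select_pulse_component(result.Y, hr_band)
    return pulse, result
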