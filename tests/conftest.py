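import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rppgbp import MixingSpec, PulseTrace, RRTParams, generate_pressure_wave, mix_sources
from rppgbp.synthetic import make_artifact_sources


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_source_mix():
    """Sinusoid + sawtooth, linearly mixed, zero noise: the canonical
    separable fixture."""
    fps, dur = 100.0, 20.0
    t = np.arange(int(dur * fps)) / fps
    from scipy.signal import sawtooth

    s1 = np.sin(2 * np.pi * 1.2 * t)
    s2 = sawtooth(2 * np.pi * 0.37 * t)
    S = np.vstack([s1, s2])
    S = (S - S.mean(axis=1, keepdims=True)) / S.std(axis=1, keepdims=True)
    sources = PulseTrace(S, fps)
    A = np.array([[1.0, 0.6], [0.4, 1.0]])
    mixed = mix_sources(sources, MixingSpec(A=A, noise_sd=0.0))
    return sources, A, mixed


@pytest.fixture
def clean_pulse():
    """A 12-second clean pulse wave at 30 fps (72 bpm)."""
    return generate_pressure_wave(RRTParams(a0=0.0, Q=1.0, R=0.3), 12.0, 30.0)


def best_match_correlations(recovered: np.ndarray, truth: np.ndarray) -> list[float]:
    """Sign/permutation-invariant match quality: for each true source the
    max |Pearson r| against any recovered component."""
    out = []
    for s in truth:
        rs = [abs(np.corrcoef(s, y)[0, 1]) for y in recovered]
        out.append(max(rs))
    return out
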