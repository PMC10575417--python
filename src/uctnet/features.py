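"""Frequency-domain feature matrices: the network's input representation.

Every recorded trace is Fourier-transformed and its magnitude at the
characteristic frequency (by default the source center frequency) is
extracted; arranging these by (source, receiver) gives an N x N amplitude
matrix for an N-sensor survey. Dividing by the matrix maximum removes the
overall amplitude scale, so the normalized matrix carries only the *relative*
frequency-domain amplitude pattern — the quantity the reconstruction network
learns from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .forward import SurveyData

__all__ = [
    "FeatureMatrix",
    "trace_spectrum",
    "extract_characteristic_amplitude",
    "feature_matrix",
    "normalize_matrix",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """N x N matrix of spectral magnitudes; row = source, column = receiver.

    With a list of characteristic frequencies the values are stacked as
    channels, shape (C, N, N); the normalization divisor is then shared so
    relative amplitudes *between* frequencies survive.
    """

    values: np.ndarray
    characteristic_frequency: object  # Hz; float or tuple of floats
    normalization_divisor: Optional[float] = None  # None until normalized

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim == 2:
            ok = v.shape[0] == v.shape[1]
        elif v.ndim == 3:
            ok = v.shape[1] == v.shape[2]
        else:
            ok = False
        if not ok:
            raise ValueError("feature matrix must be (N, N) or (channels, N, N)")

    @property
    def n(self) -> int:
        return int(self.values.shape[-1])

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 2 else int(self.values.shape[0])

    @property
    def is_normalized(self) -> bool:
        return self.normalization_divisor is not None


def trace_spectrum(trace: np.ndarray, dt: float) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided DFT magnitude spectrum of a trace.

    Returns (frequencies in Hz, magnitudes); frequency of bin k is k/(n*dt).
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or trace.size < 2:
        raise ValueError("trace must be 1D with at least 2 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    freqs = np.fft.rfftfreq(trace.size, d=dt)
    mags = np.abs(np.fft.rfft(trace))
    return freqs, mags


def extract_characteristic_amplitude(trace: np.ndarray, dt: float, f_char: float) -> float:
    """Spectral magnitude at the DFT bin nearest ``f_char``."""
    trace = np.asarray(trace, dtype=np.float64)
    nyquist = 0.5 / dt
    if not (0 < f_char < nyquist):
        raise ValueError(f"f_char must lie in (0, Nyquist={nyquist:g} Hz)")
    freqs, mags = trace_spectrum(trace, dt)
    return float(mags[int(np.argmin(np.abs(freqs - f_char)))])


def feature_matrix(survey: SurveyData, f_char) -> FeatureMatrix:
    """Characteristic-frequency amplitude matrix of a complete survey.

    values[i, j] is the magnitude of the trace from source i to receiver j at
    the DFT bin nearest ``f_char``. A sequence of frequencies yields a
    (C, N, N) channel stack. Not yet normalized.
    """
    n = survey.n_sensors
    if len(survey.shots) != n or any(s is None for s in survey.shots):
        raise ValueError("survey is incomplete: need one shot per sensor")
    freqs_wanted = np.atleast_1d(np.asarray(f_char, dtype=np.float64))
    nyquist = 0.5 / survey.dt
    if np.any(freqs_wanted <= 0) or np.any(freqs_wanted >= nyquist):
        raise ValueError(f"f_char must lie in (0, Nyquist={nyquist:g} Hz)")
    freqs = np.fft.rfftfreq(survey.n_steps, d=survey.dt)
    bins = [int(np.argmin(np.abs(freqs - f))) for f in freqs_wanted]
    values = np.empty((len(bins), n, n), dtype=np.float64)
    for i, shot in enumerate(survey.shots):
        spec = np.abs(np.fft.rfft(shot.traces, axis=1))
        values[:, i, :] = spec[:, bins].T
    if np.isscalar(f_char) or np.ndim(f_char) == 0:
        return FeatureMatrix(values=values[0], characteristic_frequency=float(f_char))
    return FeatureMatrix(values=values,
                         characteristic_frequency=tuple(float(f) for f in freqs_wanted))


def normalize_matrix(m: FeatureMatrix) -> FeatureMatrix:
    """Divide by the matrix maximum so all entries lie in [0, 1] with max 1.

    The divisor is recorded, making the absolute scale recoverable.
    Idempotent; raises on an all-zero matrix.
    """
    peak = float(m.values.max())
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero feature matrix")
    prior = m.normalization_divisor or 1.0
    return FeatureMatrix(
        values=m.values / peak,
        characteristic_frequency=m.characteristic_frequency,
        normalization_divisor=prior * peak,
    )
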