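"""Synthetic THz time-domain spectrometer: source pulse, traces, noise.

The emulated instrument acquires one optical-delay sweep ("waveform") per
0.5 s of wall time and averages 120 consecutive waveforms into a one-minute
trace.  The delay axis itself spans trace_length * time_step ps (default
1024 x 0.05 ps = 51.2 ps), which resolves the 0.13-1.02 THz analysis band,
separates the first chamber echo from the main pulse, and leaves room for
the slow (~8 ps) water-relaxation tail of the transmitted pulse to decay
inside the window so that zero-padded spectra are faithful.

Spectral conventions: the field spectrum is E(omega) = conj(rfft(e(t))),
chosen so that a pure delay by dt multiplies E by e^{+i omega dt} — the
same convention as the e^{i omega d n / c} propagation factor of the
chamber model.  Time traces are recovered with irfft(conj(E)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from pydantic import BaseModel, model_validator


class Arm(str, Enum):
    reference = "reference"
    sample = "sample"


class InstrumentModel(BaseModel):
    """Acquisition parameters of the emulated spectrometer.

    ``peak_dynamic_range_db`` is the ratio of the time-domain peak field of
    the (clean) reference trace to the RMS additive noise per single 0.5 s
    waveform; ``None`` disables noise entirely.
    """

    time_step_ps: float = 0.05
    trace_length: int = 1024
    peak_dynamic_range_db: Optional[float] = 48.0
    traces_per_minute: int = 120
    source_band_thz: tuple[float, float] = (0.1, 3.0)
    source_peak_thz: float = 0.35
    source_log_width: float = 1.1
    source_low_cut_thz: float = 0.04
    source_delay_ps: float = 20.0

    @model_validator(mode="after")
    def _check(self) -> "InstrumentModel":
        if self.time_step_ps <= 0 or self.trace_length < 8:
            raise ValueError("invalid time grid")
        lo, hi = self.source_band_thz
        if not (0 < lo < hi):
            raise ValueError("source band must be a positive interval")
        nyquist = 0.5 / self.time_step_ps
        if nyquist < hi:
            raise ValueError(
                f"time grid Nyquist {nyquist:.2f} THz is below the source band top {hi:.2f} THz"
            )
        if self.traces_per_minute < 1:
            raise ValueError("traces_per_minute must be >= 1")
        return self


@dataclass
class TimeTrace:
    """One sampled THz field waveform (or an average of several)."""

    times_ps: np.ndarray
    field: np.ndarray
    arm: str
    acquisition_index: int = 0
    n_averaged: int = 1

    def __post_init__(self):
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.field = np.asarray(self.field, dtype=float)
        if self.times_ps.shape != self.field.shape:
            raise ValueError("times and field must have the same shape")
        steps = np.diff(self.times_ps)
        if steps.size and (np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9)):
            raise ValueError("time grid must be uniform and strictly increasing")
        if not np.all(np.isfinite(self.field)):
            raise ValueError("field values must be finite")

    @property
    def time_step_ps(self) -> float:
        return float(self.times_ps[1] - self.times_ps[0])


def rfft_freqs_thz(instrument: InstrumentModel) -> np.ndarray:
    """Native (unpadded) rfft frequency grid of the instrument, in THz."""
    return np.fft.rfftfreq(instrument.trace_length, instrument.time_step_ps)


def source_spectrum(freq_thz, instrument: InstrumentModel) -> np.ndarray:
    """Complex source field spectrum E_s(omega) on a frequency grid.

    Amplitude is log-normal in frequency,
    exp(-(ln(f/fp))^2 / (2 w^2)), peaking at ``source_peak_thz`` with
    logarithmic width ``source_log_width``: a broadband single-cycle pulse
    whose spectrum is flat-topped across the analysis band (within ~6 dB
    over 0.1-1.2 THz at the defaults) yet vanishes with all derivatives at
    f = 0, so the time-domain pulse decays essentially to zero inside the
    delay span and zero-padded spectra interpolate it faithfully.  The
    linear phase centres the pulse at ``source_delay_ps`` on the delay
    axis.
    """
    f = np.asarray(freq_thz, dtype=float)
    amp = np.zeros_like(f)
    pos = f > 0
    logf = np.log(f[pos] / instrument.source_peak_thz)
    cutoff = 2.0 / 3.0 * instrument.source_band_thz[1]
    amp[pos] = np.exp(-logf**2 / (2.0 * instrument.source_log_width**2)
                      - (f[pos] / cutoff) ** 4
                      - (instrument.source_low_cut_thz / f[pos]) ** 4)
    return amp * np.exp(1j * 2.0 * np.pi * f * instrument.source_delay_ps)


def trace_from_spectrum(spectrum: np.ndarray, instrument: InstrumentModel,
                        arm: str, acquisition_index: int = 0) -> TimeTrace:
    """Inverse-transform a native-grid field spectrum into a clean trace."""
    n = instrument.trace_length
    field = np.fft.irfft(np.conj(np.asarray(spectrum, dtype=complex)), n=n)
    times = np.arange(n) * instrument.time_step_ps
    return TimeTrace(times, field, arm=arm, acquisition_index=acquisition_index)


def noise_sigma(reference_spectrum: np.ndarray, instrument: InstrumentModel) -> float:
    """Per-sample RMS of the additive time-domain noise.

    The noise is white Gaussian in time; its level is set so that the
    single-waveform spectral peak dynamic range — the ratio of the peak
    reference spectral amplitude to the per-bin spectral noise floor, the
    conventional TDS figure — equals ``peak_dynamic_range_db``.  White
    noise of per-sample variance sigma^2 has a per-bin rfft magnitude of
    sigma * sqrt(N/2) for an N-point trace.
    """
    if instrument.peak_dynamic_range_db is None:
        return 0.0
    peak = float(np.max(np.abs(reference_spectrum)))
    floor = peak * 10.0 ** (-instrument.peak_dynamic_range_db / 20.0)
    return floor / np.sqrt(instrument.trace_length / 2.0)


def noisy_copies(clean: TimeTrace, sigma: float, count: int,
                 rng: np.random.Generator) -> list[TimeTrace]:
    """``count`` independent acquisitions of ``clean`` with white noise."""
    out = []
    for k in range(count):
        field = clean.field if sigma == 0.0 else clean.field + rng.normal(0.0, sigma, clean.field.size)
        out.append(TimeTrace(clean.times_ps, field, arm=clean.arm,
                             acquisition_index=k, n_averaged=1))
    return out
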