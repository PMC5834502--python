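"""Spectral inversion: from paired time traces to n(w), kappa(w), alpha(w).

The measured quantity is the complex spectral ratio of the blood-filled to
the empty chamber,

    R(w) = E_sample(w) / E_ref(w)
         = C(n_bar) * e^{i w d (n - 1) / c} * e^{-w d kappa / c},

where C is the ratio of the Fresnel interface terms (filled over empty).
A first estimate ignores the interfaces (C = 1):

    kappa_0 = -(c / (w d)) * ln |R|,      n_0 = 1 + (c / (w d)) * dphi,

with dphi the unwrapped sample-minus-reference phase.  The interface terms
are then eliminated by fixed-point iteration: given (n_k, kappa_k), form
C_k from n_bar_k = n_k + i kappa_k and update

    kappa_{k+1} = -(c / (w d)) * ln(|R| / |C_k|),
    n_{k+1}     = 1 + (c / (w d)) * (dphi - arg C_k),

stopping per frequency when both |n_{k+1} - n_k| and |kappa_{k+1} - kappa_k|
fall below the tolerance (default 0.001).  The absorption constant is
alpha = 2 w kappa / c, reported in cm^-1.

Note the sign convention: with attenuation written e^{-w d kappa / c},
an attenuating sample (|R| < |C|) gives kappa > 0, so the log-magnitude
estimate carries a leading minus sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, model_validator

from .chamber import ChamberGeometry, interface_correction
from .instrument import TimeTrace
from .units import C_UM_PER_PS, angular_frequency, kappa_to_alpha_cm1

log = logging.getLogger(__name__)


class ExtractionSettings(BaseModel):
    """Tolerance, band, FFT and phase-anchor settings of the inversion."""

    tolerance: float = 1.0e-3
    max_iterations: int = 100
    band_thz: tuple[float, float] = (0.13, 1.02)
    window: str = "rectangular"          # or "hann"
    zero_pad: int = 4
    phase_anchor_thz: Optional[float] = None  # default: low edge of the band

    @model_validator(mode="after")
    def _check(self) -> "ExtractionSettings":
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1 or self.zero_pad < 1:
            raise ValueError("max_iterations and zero_pad must be >= 1")
        lo, hi = self.band_thz
        if not (0 < lo < hi):
            raise ValueError("analysis band must be a positive interval")
        if self.window not in ("rectangular", "hann"):
            raise ValueError("window must be 'rectangular' or 'hann'")
        return self


@dataclass
class FieldSpectrum:
    """Complex field amplitude on a positive, increasing frequency grid."""

    freqs_thz: np.ndarray
    amplitude: np.ndarray
    arm: str

    def __post_init__(self):
        self.freqs_thz = np.asarray(self.freqs_thz, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=complex)
        if np.any(self.freqs_thz <= 0) or np.any(np.diff(self.freqs_thz) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitudes must be finite")


@dataclass
class OpticalConstants:
    """Per-frequency optical constants with convergence bookkeeping."""

    freqs_thz: np.ndarray
    n: np.ndarray
    kappa: np.ndarray
    alpha_cm1: np.ndarray
    converged: np.ndarray
    iterations: np.ndarray
    change_history: list = field(default_factory=list, repr=False)


def average_traces(traces: Sequence[TimeTrace]) -> TimeTrace:
    """Pointwise arithmetic mean of waveforms sharing a grid and arm."""
    if not traces:
        raise ValueError("no traces to average")
    first = traces[0]
    for t in traces[1:]:
        if t.arm != first.arm:
            raise ValueError("cannot average traces from different arms")
        if t.times_ps.shape != first.times_ps.shape or not np.allclose(t.times_ps, first.times_ps):
            raise ValueError("cannot average traces on different time grids")
    mean = np.mean([t.field for t in traces], axis=0)
    return TimeTrace(first.times_ps, mean, arm=first.arm,
                     acquisition_index=-1, n_averaged=len(traces))


def to_spectrum(trace: TimeTrace, settings: ExtractionSettings | None = None) -> FieldSpectrum:
    """Field spectrum of a trace (optional apodization, zero-padding).

    Uses the conjugate-rfft convention in which a pure delay by dt appears
    as a phase of +omega dt, matching the chamber propagation factor.
    The zero-frequency bin is dropped.
    """
    settings = settings or ExtractionSettings()
    field_vals = trace.field
    if settings.window == "hann":
        field_vals = field_vals * np.hanning(field_vals.size)
    n_fft = field_vals.size * settings.zero_pad
    spectrum = np.conj(np.fft.rfft(field_vals, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, trace.time_step_ps)
    return FieldSpectrum(freqs[1:], spectrum[1:], arm=trace.arm)


def absorption_constant(kappa, freq_thz):
    """alpha = 2 omega kappa / c in cm^-1."""
    if np.any(np.asarray(freq_thz) <= 0):
        raise ValueError("frequency must be positive")
    return kappa_to_alpha_cm1(freq_thz, kappa)


def _band_ratio(sample: FieldSpectrum, reference: FieldSpectrum,
                settings: ExtractionSettings, thickness_um: float):
    """Restrict to the analysis band; return (freqs, lnmag, unwrapped phase, ok)."""
    if sample.freqs_thz.shape != reference.freqs_thz.shape or \
            not np.allclose(sample.freqs_thz, reference.freqs_thz):
        raise ValueError("sample and reference must share a frequency grid")
    lo, hi = settings.band_thz
    mask = (sample.freqs_thz >= lo) & (sample.freqs_thz <= hi)
    if not np.any(mask):
        raise ValueError("analysis band outside the spectrum support")
    freqs = sample.freqs_thz[mask]
    e_ref = reference.amplitude[mask]
    e_samp = sample.amplitude[mask]
    floor = np.max(np.abs(reference.amplitude)) * 1.0e-12
    ok = np.abs(e_ref) > floor
    ratio = np.where(ok, e_samp / np.where(ok, e_ref, 1.0), np.nan)
    lnmag = np.log(np.abs(np.where(ok, ratio, 1.0)))
    phase = np.unwrap(np.angle(np.where(ok, ratio, 1.0)))
    # branch anchor: choose the 2*pi offset putting n at the anchor
    # frequency into a physically plausible window (water-like: n in 1..4)
    anchor = settings.phase_anchor_thz if settings.phase_anchor_thz is not None else freqs[0]
    ia = int(np.argmin(np.abs(freqs - anchor)))
    x_a = C_UM_PER_PS / (angular_frequency(freqs[ia]) * thickness_um)
    best = 0
    best_cost = np.inf
    for k in range(-3, 4):
        n_a = 1.0 + (phase[ia] + 2.0 * np.pi * k) * x_a
        cost = max(0.0, 1.0 - n_a, n_a - 4.0) + 1e-6 * abs(k)
        if cost < best_cost:
            best_cost, best = cost, k
    phase = phase + 2.0 * np.pi * best
    return freqs, lnmag, phase, ok


def initial_estimate(sample: FieldSpectrum, reference: FieldSpectrum,
                     geometry: ChamberGeometry,
                     settings: ExtractionSettings | None = None) -> OpticalConstants:
    """Interface-free first estimate (C = 1) of the optical constants."""
    settings = settings or ExtractionSettings()
    freqs, lnmag, phase, ok = _band_ratio(sample, reference, settings, geometry.thickness_um)
    x = C_UM_PER_PS / (angular_frequency(freqs) * geometry.thickness_um)
    kappa = np.where(ok, -x * lnmag, np.nan)
    n = np.where(ok, 1.0 + x * phase, np.nan)
    alpha = np.where(ok, kappa_to_alpha_cm1(freqs, kappa), np.nan)
    return OpticalConstants(freqs, n, kappa, alpha, converged=ok.copy(),
                            iterations=np.zeros(freqs.size, dtype=int))


def refine_index(sample: FieldSpectrum, reference: FieldSpectrum,
                 geometry: ChamberGeometry,
                 settings: ExtractionSettings | None = None) -> OpticalConstants:
    """Iteratively eliminate the Fresnel interface terms from the ratio.

    Runs the per-frequency fixed-point update until the change in both n
    and kappa drops below the tolerance, or max_iterations is reached
    (those frequencies keep their last value with ``converged = False``).
    """
    settings = settings or ExtractionSettings()
    freqs, lnmag, phase, ok = _band_ratio(sample, reference, settings, geometry.thickness_um)
    x = C_UM_PER_PS / (angular_frequency(freqs) * geometry.thickness_um)
    n = np.where(ok, 1.0 + x * phase, np.nan)
    kappa = np.where(ok, -x * lnmag, np.nan)

    converged = np.zeros(freqs.size, dtype=bool)
    iterations = np.zeros(freqs.size, dtype=int)
    history: list[float] = []
    active = ok.copy()
    for it in range(1, settings.max_iterations + 1):
        if not np.any(active):
            break
        corr = interface_correction(n[active] + 1j * kappa[active], geometry)
        kappa_new = -x[active] * (lnmag[active] - np.log(np.abs(corr)))
        n_new = 1.0 + x[active] * (phase[active] - np.angle(corr))
        dn = np.abs(n_new - n[active])
        dk = np.abs(kappa_new - kappa[active])
        n[active] = n_new
        kappa[active] = kappa_new
        iterations[active] = it
        history.append(float(np.max(dn + dk)))
        done = (dn < settings.tolerance) & (dk < settings.tolerance)
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        active[idx[done]] = False
    if np.any(active):
        tail = history[-3:]
        mode = "oscillating" if len(tail) >= 2 and tail[-1] > tail[-2] else "slowly converging"
        log.warning("%d frequencies unconverged after %d iterations (%s)",
                    int(np.sum(active)), settings.max_iterations, mode)
    alpha = kappa_to_alpha_cm1(freqs, kappa)
    return OpticalConstants(freqs, n, kappa, alpha, converged=converged & ok,
                            iterations=iterations, change_history=history)


def resynthesized_ratio(constants: OpticalConstants, geometry: ChamberGeometry):
    """Forward-model the sample/reference ratio from extracted constants.

    Used as a per-frequency residual check: the result should match the
    measured ratio within the convergence tolerance.
    """
    nbar = constants.n + 1j * constants.kappa
    omega = angular_frequency(constants.freqs_thz)
    phase = omega * geometry.thickness_um / C_UM_PER_PS
    return interface_correction(nbar, geometry) * np.exp(1j * phase * (nbar - 1.0))


def extract_subject(reference_traces: Sequence[TimeTrace],
                    sample_traces: Sequence[TimeTrace],
                    geometry: ChamberGeometry,
                    settings: ExtractionSettings | None = None) -> OpticalConstants:
    """Minute-average both arms, transform, and run the full inversion."""
    settings = settings or ExtractionSettings()
    ref = to_spectrum(average_traces(reference_traces), settings)
    samp = to_spectrum(average_traces(sample_traces), settings)
    return refine_index(samp, ref, geometry, settings)
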