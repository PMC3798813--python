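"""Electrode-skin interface characterization: noise RMS and impedance sweeps.

Noise: the recorded trace is band-passed 10-1000 Hz (2nd-order Butterworth,
zero phase), its RMS computed over the whole acquisition, and the
electrode-skin contribution isolated by quadratic subtraction of the
amplifier's referred-to-input noise (0.8 uV default), assuming the two
sources are independent.

Impedance: at each sweep frequency the voltage and injected-current
sinusoids are demodulated by a least-squares fit of
``a sin(2 pi f t) + b cos(2 pi f t) + c`` — tolerant of non-integer cycle
counts, unlike an FFT bin — and the impedance magnitude and phase are the
amplitude ratio and phase difference of the two fits. A two-electrode
measurement lumps two interfaces plus the intervening tissue in series;
reported magnitudes represent that series total.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal as sig

from .errors import AnalysisError, ValidationError

__all__ = [
    "ImpedanceSpectrum",
    "NoiseResult",
    "rms",
    "electrode_noise_rms",
    "noise_pipeline",
    "estimate_impedance",
    "impedance_sweep",
    "white_noise_sigma_for_band_rms",
]


def white_noise_sigma_for_band_rms(
    target_rms: float,
    fs_hz: float,
    low_hz: float = 10.0,
    high_hz: float = 1000.0,
    order: int = 2,
) -> float:
    """Standard deviation of white noise whose RMS after the zero-phase
    band-pass of :func:`noise_pipeline` equals ``target_rms``.

    Uses the filter's noise power gain ``int |H|^4 df / (fs/2)`` (the squared
    magnitude applies twice in a forward-backward pass).
    """
    sos = sig.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos")
    freqs, h = sig.sosfreqz(sos, worN=8192, fs=fs_hz)
    power_gain = np.trapezoid(np.abs(h) ** 4, freqs) / (fs_hz / 2)
    return float(target_rms / math.sqrt(power_gain))


@dataclass
class ImpedanceSpectrum:
    """Magnitude/phase triplets over a frequency sweep (10-1000 Hz default)."""

    frequencies_hz: np.ndarray
    magnitude_ohm: np.ndarray
    phase_deg: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.magnitude_ohm = np.asarray(self.magnitude_ohm, dtype=float)
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)
        if not (
            self.frequencies_hz.shape
            == self.magnitude_ohm.shape
            == self.phase_deg.shape
        ):
            raise ValidationError("spectrum vectors must have equal length")
        if np.any(self.magnitude_ohm <= 0):
            raise ValidationError("impedance magnitudes must be positive")


@dataclass(frozen=True)
class NoiseResult:
    measured_rms_uV: float
    amplifier_rms_uV: float
    electrode_skin_rms_uV: float


def rms(signal: np.ndarray) -> float:
    """Root mean square amplitude, sqrt(mean of squares)."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot compute RMS of an empty signal")
    return float(np.sqrt(np.mean(x**2)))


def electrode_noise_rms(measured_rms_uV: float, amplifier_rms_uV: float = 0.8) -> float:
    """Quadratic subtraction of the amplifier noise from the measured RMS.

    ``sqrt(measured^2 - amplifier^2)``; a measurement below the amplifier
    floor is physically inconsistent and raises rather than clipping to 0.
    """
    if measured_rms_uV < amplifier_rms_uV:
        raise ValidationError(
            f"measured RMS {measured_rms_uV} uV below the amplifier noise "
            f"floor {amplifier_rms_uV} uV: inconsistent measurement"
        )
    return math.sqrt(measured_rms_uV**2 - amplifier_rms_uV**2)


def noise_pipeline(
    trace_uV: np.ndarray,
    fs_hz: float,
    amplifier_rms_uV: float = 0.8,
    low_hz: float = 10.0,
    high_hz: float = 1000.0,
    order: int = 2,
) -> NoiseResult:
    """Band-pass (10-1000 Hz, order 2, zero phase), RMS, quadratic subtraction."""
    if fs_hz <= 2 * high_hz:
        raise ValidationError(
            f"fs {fs_hz} Hz puts the {high_hz} Hz band edge at/above Nyquist"
        )
    x = np.asarray(trace_uV, dtype=float)
    if x.size / fs_hz < 10.0:
        warnings.warn("trace shorter than the recommended 10 s", stacklevel=2)
    sos = sig.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos")
    filtered = sig.sosfiltfilt(sos, x)
    measured = rms(filtered)
    return NoiseResult(
        measured_rms_uV=measured,
        amplifier_rms_uV=amplifier_rms_uV,
        electrode_skin_rms_uV=electrode_noise_rms(measured, amplifier_rms_uV),
    )


def _demodulate(trace: np.ndarray, freq_hz: float, fs_hz: float) -> complex:
    """Least-squares fit of a sin + b cos + c; returns the complex amplitude
    ``b + j a`` whose modulus is the sinusoid amplitude and whose angle is
    the phase of ``A sin(wt + phi)``."""
    t = np.arange(trace.size) / fs_hz
    w = 2 * math.pi * freq_hz
    design = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, trace, rcond=None)
    a, b, _c = coef
    # A sin(wt + phi) = A cos(phi) sin + A sin(phi) cos -> phi = atan2(b, a)
    return complex(a, b)


def estimate_impedance(
    voltage_trace: np.ndarray,
    current_trace: np.ndarray,
    freq_hz: float,
    fs_hz: float,
) -> tuple[float, float]:
    """(magnitude_ohm, phase_deg) of V/I at one sweep frequency.

    Requires at least five full cycles in the traces. Phase is wrapped to
    (-180, 180]; for a passive RC interface it lies in [-90, 0].
    """
    v = np.asarray(voltage_trace, dtype=float)
    i = np.asarray(current_trace, dtype=float)
    if v.shape != i.shape:
        raise ValidationError("voltage and current traces must align")
    if not (0 < freq_hz < fs_hz / 2):
        raise ValidationError("frequency must lie in (0, fs/2)")
    if v.size / fs_hz < 5.0 / freq_hz:
        raise ValidationError("need at least 5 full cycles for demodulation")
    zv = _demodulate(v, freq_hz, fs_hz)
    zi = _demodulate(i, freq_hz, fs_hz)
    if abs(zi) < 1e-15:
        raise AnalysisError("current amplitude below numerical floor")
    mag = abs(zv) / abs(zi)
    # _demodulate returns a + jb; the phase of A sin(wt+phi) is atan2(b, a)
    phase = math.degrees(math.atan2(zv.imag, zv.real) - math.atan2(zi.imag, zi.real))
    phase = (phase + 180.0) % 360.0 - 180.0
    if phase == -180.0:
        phase = 180.0
    return float(mag), float(phase)


def impedance_sweep(
    signals: dict[float, tuple[np.ndarray, np.ndarray]], fs_hz: float
) -> ImpedanceSpectrum:
    """Estimate the spectrum from per-frequency (voltage, current) pairs."""
    freqs = sorted(signals)
    mags, phases = [], []
    for f in freqs:
        v, i = signals[f]
        m, p = estimate_impedance(v, i, f, fs_hz)
        mags.append(m)
        phases.append(p)
    return ImpedanceSpectrum(
        frequencies_hz=np.array(freqs),
        magnitude_ohm=np.array(mags),
        phase_deg=np.array(phases),
    )
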