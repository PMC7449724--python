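"""Core spectral extraction: baseline subtraction, Fourier transform,
sample-to-reference ratio M, and Fresnel/Snell inversion to optical constants.

The measurement has two echoes off the imaging window: the air-quartz
reflection (the *baseline*) and the quartz-sample reflection.  After
subtracting the baseline from both the sample trace and the air-reference
trace, the complex frequency-domain ratio

    M(f) = FFT(E_sample - E_baseline) / FFT(E_air - E_baseline)
         = r_qs(f) / r_qa

equals the ratio of quartz-sample to quartz-air s-polarized Fresnel
amplitudes: every instrument factor (emitter spectrum, quartz transmission
and propagation, window thickness) cancels.  Inverting M for the sample's
complex refractive index uses Snell's law through the closed form

    r_qs = M * r_qa
    X    = n_q cos(theta_q) * (1 - r_qs) / (1 + r_qs)     (= n_s cos(theta_s))
    n_s  = sqrt(X**2 + (n_a sin(theta_a))**2)

with the principal square root, negated if its real part is negative.

Transform convention
--------------------
Spectra use the e^{+i omega t} field convention (the conjugate of numpy's
FFT kernel), so that a lossy medium has extinction k >= 0 and the quartz
propagation factor exp(+i 2 pi f n d cos(theta) / c) both delays and
attenuates the echo.  ``field_fft`` / ``field_ifft`` encapsulate this; all
forward simulation and inversion go through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import windows

from .geometry import Geometry

__all__ = [
    "TimeTrace",
    "ComplexSpectrum",
    "OpticalConstants",
    "DEFAULT_BAND",
    "SPEED_OF_LIGHT_CM_S",
    "field_fft",
    "field_ifft",
    "subtract_baseline",
    "to_spectrum",
    "compute_ratio",
    "fresnel_ratio",
    "invert_fresnel",
    "absorption_coefficient",
    "gate_window",
]

#: default valid band, THz (reflection data above ~1.5 THz are unreliable)
DEFAULT_BAND = (0.2, 1.5)

SPEED_OF_LIGHT_CM_S = 2.99792458e10

_ROLES = ("sample", "air_reference", "baseline")
_MIN_SAMPLES = 64
_AXIS_TOL_PS = 1e-9


@dataclass(frozen=True)
class TimeTrace:
    """A sampled electric-field pulse vs time.

    Fields: ``t`` (ps, uniform and strictly increasing, >= 64 samples),
    ``e`` (field amplitude, arbitrary units), ``role`` (one of ``sample``,
    ``air_reference``, ``baseline``).
    """

    t: np.ndarray
    e: np.ndarray
    role: str = "sample"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        e = np.asarray(self.e, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "e", e)
        if t.ndim != 1 or e.shape != t.shape:
            raise ValueError("t and e must be 1-D arrays of equal length")
        if t.size < _MIN_SAMPLES:
            raise ValueError(f"need at least {_MIN_SAMPLES} samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.ptp(dt) > _AXIS_TOL_PS:
            raise ValueError("time axis must be uniform to 1e-9 ps")
        if not np.all(np.isfinite(e)):
            raise ValueError("field values must be finite")
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class ComplexSpectrum:
    """Frequency-indexed complex values (field spectra, ratios,
    permittivities).  ``f`` in THz, non-negative and strictly increasing.
    Bins masked during processing (e.g. reference amplitude below the noise
    floor) are NaN and flagged False in ``valid``."""

    f: np.ndarray
    v: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        v = np.asarray(self.v, dtype=complex)
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "v", v)
        if f.ndim != 1 or v.shape != f.shape:
            raise ValueError("f and v must be 1-D arrays of equal length")
        if np.any(f < 0) or np.any(np.diff(f) <= 0):
            raise ValueError("f must be non-negative and strictly increasing")
        if self.valid is None:
            object.__setattr__(self, "valid", np.isfinite(v))
        else:
            valid = np.asarray(self.valid, dtype=bool)
            if valid.shape != f.shape:
                raise ValueError("valid mask must match f")
            object.__setattr__(self, "valid", valid)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.v)

    def unwrapped_phase(self) -> np.ndarray:
        """Phase unwrapped along frequency from the lowest valid bin."""
        return np.unwrap(np.angle(self.v))

    def band(self, fmin: float, fmax: float) -> "ComplexSpectrum":
        """Restrict to fmin <= f <= fmax."""
        sel = (self.f >= fmin) & (self.f <= fmax)
        if not np.any(sel):
            raise ValueError(f"no frequency bins in [{fmin}, {fmax}] THz")
        return ComplexSpectrum(self.f[sel], self.v[sel], self.valid[sel])


@dataclass(frozen=True)
class OpticalConstants:
    """Complex refractive index n + ik and absorption coefficient alpha
    (cm^-1) on a frequency axis (THz).  For physical, lossy media n > 0 and
    k >= 0 on the valid band; alpha = 4 pi f k / c pointwise."""

    f: np.ndarray
    n_complex: np.ndarray
    alpha: np.ndarray = field(default=None)  # type: ignore[assignment]
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        n = np.asarray(self.n_complex, dtype=complex)
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "n_complex", n)
        if n.shape != f.shape:
            raise ValueError("n_complex must match the frequency axis")
        if self.alpha is None:
            object.__setattr__(self, "alpha", _alpha_cm(f, np.imag(n)))
        else:
            alpha = np.asarray(self.alpha, dtype=float)
            if alpha.shape != f.shape:
                raise ValueError("alpha must match the frequency axis")
            object.__setattr__(self, "alpha", alpha)
        if self.valid is None:
            object.__setattr__(self, "valid", np.isfinite(n))
        else:
            object.__setattr__(
                self, "valid", np.asarray(self.valid, dtype=bool)
            )

    @property
    def n(self) -> np.ndarray:
        return np.real(self.n_complex)

    @property
    def k(self) -> np.ndarray:
        return np.imag(self.n_complex)


# ---------------------------------------------------------------------------
# transforms


def field_fft(e: np.ndarray, axis: int = -1) -> np.ndarray:
    """One-sided field spectrum under the e^{+i omega t} convention
    (conjugate of numpy's rfft)."""
    return np.conj(np.fft.rfft(e, axis=axis))


def field_ifft(spectrum: np.ndarray, n: int, axis: int = -1) -> np.ndarray:
    """Inverse of :func:`field_fft` back to ``n`` time samples."""
    return np.fft.irfft(np.conj(spectrum), n=n, axis=axis)


def subtract_baseline(trace: TimeTrace, baseline: TimeTrace) -> TimeTrace:
    """Remove the air-quartz (baseline) echo from a trace, pointwise."""
    if trace.t.shape != baseline.t.shape or np.max(
        np.abs(trace.t - baseline.t)
    ) > _AXIS_TOL_PS:
        raise ValueError("trace and baseline must share the same time axis")
    return TimeTrace(trace.t, trace.e - baseline.e, role=trace.role)


def _make_window(window, n: int) -> np.ndarray | None:
    if window is None:
        return None
    if isinstance(window, np.ndarray):
        if window.shape != (n,):
            raise ValueError("explicit window must match the trace length")
        return window
    if isinstance(window, (tuple, list)) and window and window[0] == "tukey":
        alpha = window[1] if len(window) > 1 else 0.25
        return windows.tukey(n, alpha=alpha)
    raise ValueError(f"unknown window spec {window!r}")


def to_spectrum(trace: TimeTrace, window=None) -> ComplexSpectrum:
    """Discrete Fourier transform of a (optionally tapered) trace.

    Returns the non-negative-frequency half, axis in THz, values scaled by
    the sample spacing so amplitudes approximate the continuous transform.
    ``window`` is None (default; simulated traces decay naturally), a
    ``("tukey", alpha)`` spec for gated composite traces, or an explicit
    array.
    """
    e = trace.e
    w = _make_window(window, e.size)
    if w is not None:
        e = e * w
    v = field_fft(e) * trace.dt
    f = np.fft.rfftfreq(e.size, d=trace.dt)  # ps sampling -> THz axis
    return ComplexSpectrum(f, v)


def gate_window(
    trace: TimeTrace, t_start: float, t_stop: float
) -> TimeTrace:
    """Rectangular time gate: zero the trace outside [t_start, t_stop] ps.

    Used to isolate the quartz-sample echo from a composite trace that still
    contains the air-quartz baseline reflection.
    """
    if t_stop <= t_start:
        raise ValueError("t_stop must exceed t_start")
    keep = (trace.t >= t_start) & (trace.t <= t_stop)
    return TimeTrace(trace.t, np.where(keep, trace.e, 0.0), role=trace.role)


# ---------------------------------------------------------------------------
# ratio and inversion

#: reference bins below this fraction of the peak reference amplitude are
#: masked in the ratio (division would amplify noise without bound)
_REFERENCE_FLOOR_REL = 1e-8


def compute_ratio(
    sample_spec: ComplexSpectrum,
    air_spec: ComplexSpectrum,
    band: tuple[float, float] = DEFAULT_BAND,
) -> ComplexSpectrum:
    """Sample-to-reference ratio M on the valid band.

    Pointwise complex division of the baseline-subtracted sample spectrum by
    the baseline-subtracted air-reference spectrum, restricted to ``band``
    (THz).  Bins where the reference amplitude falls below a floor relative
    to its in-band peak are masked (NaN, ``valid=False``).
    """
    if sample_spec.f.shape != air_spec.f.shape or np.max(
        np.abs(sample_spec.f - air_spec.f)
    ) > 1e-12:
        raise ValueError("sample and reference must share a frequency axis")
    s = sample_spec.band(*band)
    a = air_spec.band(*band)
    floor = _REFERENCE_FLOOR_REL * np.max(np.abs(a.v))
    ok = np.abs(a.v) > floor
    m = np.where(ok, s.v, np.nan) / np.where(ok, a.v, 1.0)
    return ComplexSpectrum(s.f, m, valid=ok & s.valid & a.valid)


def fresnel_ratio(n_sample, geometry: Geometry):
    """Forward model for M: the ratio r_qs / r_qa of quartz-sample to
    quartz-air s-polarized reflection amplitudes, for sample index
    ``n_sample`` (scalar or array, may vary with frequency)."""
    return geometry.r_quartz_sample(n_sample) / geometry.r_quartz_air()


def invert_fresnel(M: ComplexSpectrum, geometry: Geometry) -> OpticalConstants:
    """Closed-form inversion of the ratio M to the sample's complex
    refractive index and absorption coefficient.

    Per frequency: ``r_qs = M r_qa``; ``X = n_q cos(theta_q) (1 - r_qs) /
    (1 + r_qs)``; ``n_s = sqrt(X^2 + (n_a sin theta_a)^2)`` with the branch
    chosen so Re(n_s) > 0.  Bins where ``1 + r_qs`` underflows (total
    reflection, division blow-up) are masked.
    """
    r_qa = geometry.r_quartz_air()
    r_qs = M.v * r_qa
    denom = 1.0 + r_qs
    ok = np.asarray(M.valid) & (np.abs(denom) > 1e-12)
    denom = np.where(ok, denom, 1.0)
    x = geometry.q_quartz * (1.0 - r_qs) / denom
    n_s = np.sqrt(x * x + geometry.transverse_index**2)
    n_s = np.where(np.real(n_s) < 0, -n_s, n_s)
    n_s = np.where(ok, n_s, np.nan + 0j)
    return OpticalConstants(M.f, n_s, valid=ok)


def _alpha_cm(f_thz: np.ndarray, k: np.ndarray) -> np.ndarray:
    """alpha = 4 pi f k / c, reported in cm^-1 (f converted THz -> Hz)."""
    return 4.0 * np.pi * (np.asarray(f_thz) * 1e12) * np.asarray(k) / (
        SPEED_OF_LIGHT_CM_S
    )


def absorption_coefficient(constants: OpticalConstants) -> np.ndarray:
    """Absorption coefficient alpha = 4 pi f k / c in cm^-1."""
    k = constants.k
    if np.any(k[np.isfinite(k)] < 0):
        raise ValueError("extinction coefficient must be non-negative")
    return _alpha_cm(constants.f, k)
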