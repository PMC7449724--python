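"""Forward simulation of the THz reflection measurement.

Builds what the instrument would record: a broadband single-cycle pulse, its
reflections off the air/quartz/sample stack (the air-quartz *baseline* echo
and the quartz-sample echo), additive detector noise, and full before/after
image rasters for a five-group (Control/NT/PT/NN/MN), ten-replicate
drug-delivery experiment with a localized uptake spot per treated sample.

The frequency-domain construction is

    baseline      = E0 * r_aq
    sample        = E0 * t_aq * P_q**2 * r_qs * t_qa   (+ baseline when
    air_reference = E0 * t_aq * P_q**2 * r_qa * t_qa    composite mode is on)

with P_q the one-way quartz propagation factor (delay + loss).  Every factor
except r_qs / r_qa cancels in the downstream ratio M, which is what makes the
measurement self-referencing.

All randomness flows from a single seed; identical seeds reproduce every
trace bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterator, Mapping

import numpy as np

from .dielectrics import MediumLibrary, default_library, skin_permittivity
from .geometry import Geometry
from .spectroscopy import TimeTrace, field_fft, field_ifft

__all__ = [
    "Geometry",
    "PulseParams",
    "ExperimentDesign",
    "ImageRaster",
    "ExperimentRecord",
    "default_time_axis",
    "reference_pulse",
    "simulate_reflection",
    "drug_fraction_field",
    "simulate_experiment",
    "DEFAULT_PEAK_FRACTIONS",
]

#: Peak drug volume fraction at the spot center, per treatment group.
#: Ordered NN > PT > MN > NT > Control = 0: the nanoneedle patch delivers the
#: most solution, the topical drop the least, no drug in the control.
DEFAULT_PEAK_FRACTIONS: dict[str, float] = {
    "Control": 0.0,
    "NT": 0.15,
    "PT": 0.25,
    "NN": 0.45,
    "MN": 0.20,
}

#: Spot profile per group: the soaked-pad group (PT) wets a uniform disk the
#: size of the pad; drop/needle-patch groups taper as a raised cosine.
DEFAULT_SPOT_SHAPES: dict[str, str] = {
    "Control": "raised_cosine",
    "NT": "raised_cosine",
    "PT": "disk",
    "NN": "raised_cosine",
    "MN": "raised_cosine",
}


@dataclass(frozen=True)
class PulseParams:
    """Emitter pulse shape: derivative-of-Gaussian single cycle.

    ``width_ps`` sets the spectral peak at 1/(2 pi width) THz (~0.53 THz for
    the 0.3 ps default), with useful energy across 0.1-2 THz.
    """

    amplitude: float = 1.0
    center_ps: float = 8.0
    width_ps: float = 0.3

    def __post_init__(self) -> None:
        if self.width_ps <= 0:
            raise ValueError("width_ps must be positive")


def default_time_axis(n: int = 512, dt_ps: float = 0.1) -> np.ndarray:
    """Uniform acquisition axis: 51.2 ps window at 0.1 ps steps by default
    (5 THz Nyquist, ~0.02 THz resolution)."""
    return np.arange(n) * dt_ps


def reference_pulse(
    t_axis: np.ndarray, params: PulseParams | None = None
) -> TimeTrace:
    """Band-limited single-cycle emitter pulse on a uniform time axis.

    Derivative of a Gaussian, normalized so the time-domain peak equals
    ``params.amplitude``; integrates to zero (no DC component).
    """
    params = params or PulseParams()
    t = np.asarray(t_axis, dtype=float)
    dt = np.diff(t)
    if t.ndim != 1 or np.any(dt <= 0) or np.ptp(dt) > 1e-9:
        raise ValueError("t_axis must be 1-D, uniform and increasing")
    u = (t - params.center_ps) / params.width_ps
    # peak of |u exp(-u^2/2)| is exp(-1/2) at u = +-1; rescale to `amplitude`
    e = -params.amplitude * np.exp(0.5) * u * np.exp(-0.5 * u * u)
    return TimeTrace(t, e, role="air_reference")


def _eps_on_grid(eps_sample, f: np.ndarray) -> np.ndarray:
    if callable(eps_sample):
        eps = np.asarray(eps_sample(f), dtype=complex)
    else:
        eps = np.asarray(eps_sample, dtype=complex)
        if eps.ndim == 0:
            eps = np.full(f.shape, complex(eps))
    if eps.shape[-1] != f.size:
        raise ValueError("eps_sample must be defined on the pulse's band")
    if np.any(np.imag(eps) < -1e-12):
        raise ValueError("sample permittivity must have Im(eps) >= 0")
    return eps


def _sample_index(eps: np.ndarray) -> np.ndarray:
    n_s = np.sqrt(eps)
    return np.where(np.real(n_s) < 0, -n_s, n_s)


def _reflection_spectra(
    pulse: TimeTrace,
    geometry: Geometry,
    eps_sample,
    composite: bool = True,
):
    """Frequency-domain sample/air/baseline spectra (last axis = frequency).

    ``eps_sample`` may be scalar, callable(f), an (nf,) array, or an
    (npix, nf) array for whole-raster simulation.
    """
    n_t = pulse.e.size
    f = np.fft.rfftfreq(n_t, d=pulse.dt)
    e0 = field_fft(pulse.e)
    eps = _eps_on_grid(eps_sample, f)
    r_qs = geometry.r_quartz_sample(_sample_index(eps))
    prop = geometry.propagation_factor(f)
    common = e0 * geometry.t_air_quartz() * prop * prop * geometry.t_quartz_air()
    base = e0 * geometry.r_air_quartz()
    samp = common * r_qs
    air = np.broadcast_to(common * geometry.r_quartz_air(), np.shape(samp))
    if composite:
        samp = samp + base
        air = air + base
    return f, samp, np.asarray(air), base


def simulate_reflection(
    pulse: TimeTrace,
    geometry: Geometry,
    eps_sample,
    noise_sd: float = 0.0,
    seed: int = 0,
    composite: bool = True,
) -> tuple[TimeTrace, TimeTrace, TimeTrace]:
    """Simulate one reflection measurement: (sample, air_reference, baseline).

    ``eps_sample`` is the sample's complex permittivity: a scalar, a callable
    of frequency (THz), or an array on the pulse's rfft frequency grid.
    Additive Gaussian noise with sd ``noise_sd`` x (pulse peak) is drawn
    independently for each returned trace; ``seed`` makes it reproducible.
    In ``composite`` mode (the default — this is what the detector records)
    the sample and reference traces contain the air-quartz baseline echo as
    well as the quartz-sample echo; the baseline is additionally returned as
    its own trace for subtraction or gating.  With ``composite=False`` the
    emitted traces are already baseline-free (pre-gated).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n_t = pulse.e.size
    _, samp, air, base = _reflection_spectra(
        pulse, geometry, eps_sample, composite=composite
    )
    e_samp = field_ifft(samp, n_t)
    e_air = field_ifft(air, n_t)
    e_base = field_ifft(base, n_t)
    rng = np.random.default_rng(seed)
    sd = noise_sd * np.max(np.abs(pulse.e))
    if sd > 0:
        e_samp = e_samp + rng.normal(0.0, sd, n_t)
        e_air = e_air + rng.normal(0.0, sd, n_t)
        e_base = e_base + rng.normal(0.0, sd, n_t)
    return (
        TimeTrace(pulse.t, e_samp, role="sample"),
        TimeTrace(pulse.t, e_air, role="air_reference"),
        TimeTrace(pulse.t, e_base, role="baseline"),
    )


# ---------------------------------------------------------------------------
# image rasters


@dataclass(frozen=True)
class ImageRaster:
    """A 2D raster scan: per-pixel sample traces plus the shared
    air-reference and baseline traces of that acquisition.

    Default geometry is a 2x2 cm field of view at 0.5 mm pitch (40x40
    pixels); pixel (i, j) is centered at ((j+0.5) pitch, (i+0.5) pitch),
    row-major with the origin at top-left.
    """

    t: np.ndarray
    traces: np.ndarray  # (ny, nx, nt) sample field
    air_reference: TimeTrace
    baseline: TimeTrace
    pitch_mm: float = 0.5
    group: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        traces = np.asarray(self.traces, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "traces", traces)
        if traces.ndim != 3 or traces.shape[-1] != t.size:
            raise ValueError("traces must be (ny, nx, nt) matching t")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be positive")
        for shared in (self.air_reference, self.baseline):
            if shared.t.shape != t.shape:
                raise ValueError("shared traces must match the raster axis")

    @property
    def shape(self) -> tuple[int, int]:
        return self.traces.shape[:2]

    @property
    def extent_mm(self) -> tuple[float, float]:
        ny, nx = self.shape
        return (ny * self.pitch_mm, nx * self.pitch_mm)

    def pixel_trace(self, i: int, j: int) -> TimeTrace:
        return TimeTrace(self.t, self.traces[i, j], role="sample")


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of the five-group before/after imaging experiment.

    Five treatment groups (topical drop NT, soaked pad PT, nanoneedle patch
    NN, microneedle patch MN, untreated Control), ``replicates`` skin pieces
    per group, each imaged before and after treatment.  The treated spot is a
    radially symmetric drug-fraction field of radius ``spot_radius_mm`` and
    per-group peak fraction; per-replicate biological variability perturbs
    the 30/70 background/water composition; detector noise is additive with
    sd ``noise_sd`` x pulse peak (default 5e-4, i.e. a peak signal-to-noise
    ratio of 2000, mid-range for commercial time-domain systems).
    """

    groups: tuple[str, ...] = ("Control", "NT", "PT", "NN", "MN")
    replicates: int = 10
    peak_fractions: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_PEAK_FRACTIONS)
    )
    spot_shapes: Mapping[str, str] = dc_field(
        default_factory=lambda: dict(DEFAULT_SPOT_SHAPES)
    )
    spot_radius_mm: float = 5.0
    noise_sd: float = 5e-4
    composition_jitter_sd: float = 0.01
    nx: int = 40
    ny: int = 40
    pitch_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per group")
        for g in self.groups:
            if g not in self.peak_fractions:
                raise ValueError(f"unknown group label {g!r}: no peak fraction")
            if g not in self.spot_shapes:
                raise ValueError(f"unknown group label {g!r}: no spot shape")
            peak = self.peak_fractions[g]
            if not 0.0 <= peak <= 0.7:
                raise ValueError("peak fractions must lie in [0, 0.7]")
        if "Control" in self.groups and self.peak_fractions["Control"] != 0.0:
            raise ValueError("Control peak fraction must be 0")
        if min(self.nx, self.ny) < 5:
            raise ValueError("raster must be at least 5x5 for the ROI")
        if self.spot_radius_mm <= 0 or self.pitch_mm <= 0:
            raise ValueError("spot radius and pitch must be positive")


def drug_fraction_field(design: ExperimentDesign, group: str) -> np.ndarray:
    """Per-pixel delivered drug volume fraction for one group's spot.

    Raised-cosine profile peak*(1+cos(pi r/R))/2 inside radius R, or a
    uniform disk for pad application; centered on the image midpoint.
    """
    if group not in design.peak_fractions:
        raise ValueError(f"unknown group label {group!r}")
    peak = design.peak_fractions[group]
    shape = design.spot_shapes[group]
    ys = (np.arange(design.ny) + 0.5) * design.pitch_mm
    xs = (np.arange(design.nx) + 0.5) * design.pitch_mm
    cy = design.ny * design.pitch_mm / 2.0
    cx = design.nx * design.pitch_mm / 2.0
    r = np.hypot(ys[:, None] - cy, xs[None, :] - cx)
    inside = r <= design.spot_radius_mm
    if shape == "disk":
        return np.where(inside, peak, 0.0)
    if shape == "raised_cosine":
        prof = 0.5 * (1.0 + np.cos(np.pi * r / design.spot_radius_mm))
        return np.where(inside, peak * prof, 0.0)
    raise ValueError(f"unknown spot shape {shape!r}")


@dataclass(frozen=True)
class ExperimentRecord:
    group: str
    replicate: int
    before: ImageRaster
    after: ImageRaster


def _simulate_raster(
    pulse: TimeTrace,
    geometry: Geometry,
    eps_pixels: np.ndarray,  # (npix, nf)
    noise_sd: float,
    rng: np.random.Generator,
    ny: int,
    nx: int,
    pitch_mm: float,
    group: str,
    replicate: int,
) -> ImageRaster:
    n_t = pulse.e.size
    _, samp, air, base = _reflection_spectra(pulse, geometry, eps_pixels)
    traces = field_ifft(samp, n_t, axis=-1)
    e_air = field_ifft(air[0], n_t)
    e_base = field_ifft(base, n_t)
    sd = noise_sd * np.max(np.abs(pulse.e))
    if sd > 0:
        traces = traces + rng.normal(0.0, sd, traces.shape)
        e_air = e_air + rng.normal(0.0, sd, n_t)
        e_base = e_base + rng.normal(0.0, sd, n_t)
    return ImageRaster(
        t=pulse.t,
        traces=traces.reshape(ny, nx, n_t),
        air_reference=TimeTrace(pulse.t, e_air, role="air_reference"),
        baseline=TimeTrace(pulse.t, e_base, role="baseline"),
        pitch_mm=pitch_mm,
        group=group,
        replicate=replicate,
    )


def simulate_experiment(
    design: ExperimentDesign,
    geometry: Geometry | None = None,
    library: MediumLibrary | None = None,
    pulse: TimeTrace | None = None,
) -> Iterator[ExperimentRecord]:
    """Yield before/after raster pairs for every (group, replicate).

    The "before" raster has no drug anywhere; the "after" raster applies the
    group's spot field.  Both share the replicate's perturbed baseline skin
    composition, so normalization sees the same piece of skin.  Rasters are
    yielded lazily (a full experiment holds 100 rasters; generate, process,
    discard).  All randomness derives from ``design.seed``.
    """
    geometry = geometry or Geometry()
    library = library if library is not None else default_library()
    pulse = pulse if pulse is not None else reference_pulse(default_time_axis())
    f = np.fft.rfftfreq(pulse.e.size, d=pulse.dt)
    for gi, group in enumerate(design.groups):
        after_field = drug_fraction_field(design, group).ravel()
        zero_field = np.zeros_like(after_field)
        for rep in range(design.replicates):
            child = np.random.SeedSequence(
                entropy=design.seed, spawn_key=(gi, rep)
            )
            rng = np.random.default_rng(child)
            bg = float(
                np.clip(
                    0.30 + rng.normal(0.0, design.composition_jitter_sd),
                    0.25,
                    0.35,
                )
            )
            rasters = []
            for label, frac in (("before", zero_field), ("after", after_field)):
                eps = skin_permittivity(
                    frac, f, library=library, background_fraction=bg
                )
                rasters.append(
                    _simulate_raster(
                        pulse,
                        geometry,
                        eps,
                        design.noise_sd,
                        rng,
                        design.ny,
                        design.nx,
                        design.pitch_mm,
                        group,
                        rep,
                    )
                )
            yield ExperimentRecord(group, rep, rasters[0], rasters[1])
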