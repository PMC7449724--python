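"""Measurement geometry: oblique-incidence reflection off an
air/quartz/sample stack, s-polarization.

The imaging window is z-cut crystalline quartz; the THz beam hits the
air-quartz interface at ``theta_air`` and the quartz-sample interface at the
internal angle given by Snell's law,

    n_air sin(theta_air) = n_quartz sin(theta_quartz) = n_sample sin(theta_s).

All interface coefficients are s-polarized Fresnel amplitudes in terms of the
"normal index" ``n cos(theta)`` of each medium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: speed of light in mm/ps (= 1e-3 * c in m/s * 1e-12 s/ps ... = 0.29979 mm/ps)
C_MM_PER_PS = 0.299792458

__all__ = ["Geometry", "C_MM_PER_PS"]


@dataclass(frozen=True)
class Geometry:
    """Air/quartz/sample reflection geometry.

    Parameters
    ----------
    n_quartz : complex
        Complex refractive index of the quartz window (ordinary ray).
    n_air : complex
        Refractive index of the incidence medium (air).
    theta_air_deg : float
        Angle of incidence in air, degrees, in [0, 90).
    thickness_mm : float
        Quartz window thickness.  It delays and attenuates the quartz-sample
        echo but cancels exactly in the sample-to-reference ratio.
    polarization : str
        Only ``"s"`` is supported; the Fresnel form of the measurement model
        is the s-polarized one.
    """

    n_quartz: complex = 2.11 + 0.0005j
    n_air: complex = 1.0 + 0.0j
    theta_air_deg: float = 30.0
    thickness_mm: float = 2.0
    polarization: str = "s"

    def __post_init__(self) -> None:
        if self.polarization != "s":
            raise ValueError("only s-polarization is supported")
        if not 0.0 <= self.theta_air_deg < 90.0:
            raise ValueError("theta_air_deg must be in [0, 90)")
        if np.real(self.n_quartz) <= 1.0:
            raise ValueError("Re(n_quartz) must exceed 1")
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")

    # -- Snell's law -------------------------------------------------------

    @property
    def sin_theta_air(self) -> float:
        return float(np.sin(np.deg2rad(self.theta_air_deg)))

    @property
    def transverse_index(self) -> complex:
        """The Snell invariant n_air * sin(theta_air), conserved across
        every interface of the stack."""
        return self.n_air * self.sin_theta_air

    def cos_theta(self, n_medium) -> complex:
        """cos(theta) inside a medium of index ``n_medium`` (principal
        branch; for lossy media this is the complex effective cosine)."""
        s = self.transverse_index / np.asarray(n_medium, dtype=complex)
        return np.sqrt(1.0 - s * s)

    def normal_index(self, n_medium):
        """n cos(theta) of a medium — the quantity entering the s-polarized
        Fresnel coefficients."""
        n_medium = np.asarray(n_medium, dtype=complex)
        out = n_medium * self.cos_theta(n_medium)
        return out if out.ndim else complex(out)

    # -- cached stack quantities ------------------------------------------

    @property
    def q_air(self) -> complex:
        return complex(self.normal_index(self.n_air))

    @property
    def q_quartz(self) -> complex:
        return complex(self.normal_index(self.n_quartz))

    # -- Fresnel amplitudes (s-pol) ---------------------------------------

    def r_air_quartz(self) -> complex:
        return _r(self.q_air, self.q_quartz)

    def r_quartz_air(self) -> complex:
        return _r(self.q_quartz, self.q_air)

    def t_air_quartz(self) -> complex:
        return _t(self.q_air, self.q_quartz)

    def t_quartz_air(self) -> complex:
        return _t(self.q_quartz, self.q_air)

    def r_quartz_sample(self, n_sample):
        """Quartz->sample reflection amplitude for sample index ``n_sample``
        (scalar or array)."""
        return _r(self.q_quartz, self.normal_index(n_sample))

    def propagation_factor(self, f_thz):
        """One-way propagation factor through the quartz window,
        exp(i 2*pi f n_q cos(theta_q) d / c): a delay plus the (small)
        quartz absorption, under the package's lossy-positive convention."""
        f = np.asarray(f_thz, dtype=float)
        tau = self.n_quartz * self.cos_theta(self.n_quartz) * (
            self.thickness_mm / C_MM_PER_PS
        )
        return np.exp(1j * 2.0 * np.pi * f * tau)


def _r(q1, q2):
    return (q1 - q2) / (q1 + q2)


def _t(q1, q2):
    return 2.0 * q1 / (q1 + q2)
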