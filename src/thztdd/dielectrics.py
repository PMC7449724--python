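"""Frequency-dependent complex permittivity models for the media in a THz
reflection measurement of drug-treated skin.

Conventions
-----------
Permittivities are complex with the lossy-positive sign convention
``eps = eps' + i*eps''`` with ``eps'' >= 0`` for passive media, so the complex
refractive index ``n_tilde = sqrt(eps) = n + ik`` has ``k >= 0``.  Frequencies
are in THz and relaxation times in ps throughout (THz * ps = 1, so ``omega*tau
= 2*pi*f_THz*tau_ps`` is dimensionless).

The (double-)Debye relaxation form used here is

    eps(f) = eps_inf + (eps_static - eps_2) / (1 - i*2*pi*f*tau1)
                     + (eps_2 - eps_inf)   / (1 - i*2*pi*f*tau2)

which reduces to the single-Debye form when the second process is absent.

Mixtures use the Landau-Lifshitz-Looyenga (LLL) cube-root rule

    eps_eff = ( sum_i f_i * eps_i**(1/3) )**3

with principal-branch cube roots; all component permittivities lie in the
closed upper half plane, so the branch is continuous on the instrument band.
A linear (volume-weighted) rule is available for sensitivity checks.

Skin before treatment is modeled as 30% frequency-flat biological background
and 70% water; delivered drug solution displaces water volume-for-volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "DebyeModel",
    "ConstantModel",
    "MixtureComposition",
    "MediumLibrary",
    "permittivity",
    "effective_permittivity",
    "mix_permittivities",
    "skin_permittivity",
    "default_library",
    "SKIN_BACKGROUND_FRACTION",
    "SKIN_WATER_FRACTION",
]

#: Unperturbed skin composition: 30% biological background, 70% water.
SKIN_BACKGROUND_FRACTION = 0.30
SKIN_WATER_FRACTION = 0.70

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class DebyeModel:
    """Single- or double-Debye relaxation model.

    Parameters
    ----------
    eps_static : float
        Zero-frequency (static) relative permittivity.
    eps_inf : float
        High-frequency limit of the relative permittivity.
    tau1 : float
        Slow relaxation time in ps.
    eps_intermediate : float, optional
        Amplitude split between the two processes; required together with
        ``tau2`` for the double-Debye form.
    tau2 : float, optional
        Fast relaxation time in ps; must satisfy ``tau2 < tau1``.
    """

    eps_static: float
    eps_inf: float
    tau1: float
    eps_intermediate: float | None = None
    tau2: float | None = None

    def __post_init__(self) -> None:
        if (self.eps_intermediate is None) != (self.tau2 is None):
            raise ValueError(
                "eps_intermediate and tau2 must be given together"
            )
        eps_mid = (
            self.eps_static if self.eps_intermediate is None
            else self.eps_intermediate
        )
        if not (self.eps_static >= eps_mid >= self.eps_inf > 0):
            raise ValueError(
                "require eps_static >= eps_intermediate >= eps_inf > 0, got "
                f"{self.eps_static}, {eps_mid}, {self.eps_inf}"
            )
        if self.tau1 <= 0:
            raise ValueError("tau1 must be positive")
        if self.tau2 is not None and not (0 < self.tau2 < self.tau1):
            raise ValueError("require 0 < tau2 < tau1")

    def permittivity(self, f):
        """Complex permittivity at frequency ``f`` (THz, scalar or array)."""
        f = _check_frequency(f)
        omega_tau1 = 2.0 * np.pi * f * self.tau1
        if self.eps_intermediate is None:
            return self.eps_inf + (self.eps_static - self.eps_inf) / (
                1.0 - 1j * omega_tau1
            )
        omega_tau2 = 2.0 * np.pi * f * self.tau2
        return (
            self.eps_inf
            + (self.eps_static - self.eps_intermediate) / (1.0 - 1j * omega_tau1)
            + (self.eps_intermediate - self.eps_inf) / (1.0 - 1j * omega_tau2)
        )


@dataclass(frozen=True)
class ConstantModel:
    """Frequency-flat permittivity (used for the biological background)."""

    eps: complex

    def __post_init__(self) -> None:
        if np.real(self.eps) <= 0 or np.imag(self.eps) < 0:
            raise ValueError("require Re(eps) > 0 and Im(eps) >= 0")

    def permittivity(self, f):
        f = _check_frequency(f)
        return np.broadcast_to(
            np.asarray(self.eps, dtype=complex), np.shape(f)
        ).copy() if np.ndim(f) else complex(self.eps)


@dataclass(frozen=True)
class MixtureComposition:
    """Volume fractions of the three-component skin mixture."""

    f_background: float
    f_water: float
    f_drug: float

    def __post_init__(self) -> None:
        for name, frac in self.as_dict().items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name}={frac} outside [0, 1]")
        total = self.f_background + self.f_water + self.f_drug
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(f"fractions sum to {total}, expected 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "f_background": self.f_background,
            "f_water": self.f_water,
            "f_drug": self.f_drug,
        }


def _check_frequency(f):
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    return f if f.ndim else float(f)


def permittivity(model, f):
    """Evaluate a dielectric model at frequency ``f`` (THz)."""
    return model.permittivity(f)


def mix_permittivities(fractions, eps_values, rule: str = "lll"):
    """Effective permittivity of a mixture from volume fractions.

    ``fractions`` and ``eps_values`` are broadcastable sequences; fractions
    must sum to 1 along the component axis (axis 0).  ``rule`` is ``"lll"``
    (Landau-Lifshitz-Looyenga cube-root mixing, the default) or ``"linear"``
    (volume-weighted permittivity average, for sensitivity tests).
    """
    fractions = [np.asarray(fr, dtype=float) for fr in fractions]
    eps_values = [np.asarray(ev, dtype=complex) for ev in eps_values]
    if len(fractions) != len(eps_values):
        raise ValueError("fractions and eps_values must pair up")
    total = sum(fractions)
    if np.any(np.abs(total - 1.0) > _FRACTION_TOL):
        raise ValueError("volume fractions must sum to 1")
    if any(np.any(fr < -_FRACTION_TOL) for fr in fractions):
        raise ValueError("volume fractions must be non-negative")
    if rule == "lll":
        root = sum(
            fr * ev ** (1.0 / 3.0) for fr, ev in zip(fractions, eps_values)
        )
        return root * root * root  # cheaper than complex pow on pixel grids
    if rule == "linear":
        return sum(fr * ev for fr, ev in zip(fractions, eps_values))
    raise ValueError(f"unknown mixing rule {rule!r}")


def effective_permittivity(
    comp: MixtureComposition,
    eps_background,
    eps_water,
    eps_drug,
    rule: str = "lll",
):
    """Effective permittivity of the background/water/drug skin mixture."""
    return mix_permittivities(
        [comp.f_background, comp.f_water, comp.f_drug],
        [eps_background, eps_water, eps_drug],
        rule=rule,
    )


class MediumLibrary:
    """Named dielectric models, loadable from a YAML/JSON-style mapping.

    Entries are keyed by medium name and hold one of

    - ``debye``: DebyeModel parameters (``eps_static``, ``eps_inf``,
      ``tau1_ps`` and optionally ``eps_intermediate``, ``tau2_ps``),
    - ``constant``: a flat permittivity (``eps``, optionally ``eps_imag``),
    - ``mixture``: ``components`` mapping other entries to volume fractions,
      resolved with the library's mixing rule.
    """

    def __init__(self, spec: Mapping[str, Mapping], rule: str = "lll"):
        self._spec = dict(spec)
        self.rule = rule
        for name in self._spec:
            self._resolve(name, set())  # validate eagerly, catch cycles

    @classmethod
    def from_yaml(cls, path) -> "MediumLibrary":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(doc["media"], rule=doc.get("mixing_rule", "lll"))

    def names(self) -> list[str]:
        return sorted(self._spec)

    def _resolve(self, name: str, seen: set):
        if name not in self._spec:
            raise KeyError(f"unknown medium {name!r}")
        if name in seen:
            raise ValueError(f"cyclic mixture definition at {name!r}")
        entry = self._spec[name]
        if "debye" in entry:
            p = entry["debye"]
            return DebyeModel(
                eps_static=p["eps_static"],
                eps_inf=p["eps_inf"],
                tau1=p["tau1_ps"],
                eps_intermediate=p.get("eps_intermediate"),
                tau2=p.get("tau2_ps"),
            )
        if "constant" in entry:
            p = entry["constant"]
            return ConstantModel(eps=p["eps"] + 1j * p.get("eps_imag", 0.0))
        if "mixture" in entry:
            comps = entry["mixture"]["components"]
            return dict(comps)
        raise ValueError(f"medium {name!r} has no debye/constant/mixture key")

    def permittivity(self, name: str, f):
        """Complex permittivity of medium ``name`` at ``f`` (THz)."""
        resolved = self._resolve(name, set())
        if isinstance(resolved, dict):
            names, fracs = zip(*sorted(resolved.items()))
            eps = [self.permittivity(n, f) for n in names]
            return mix_permittivities(list(fracs), eps, rule=self.rule)
        return resolved.permittivity(f)

    def refractive_index(self, name: str, f):
        """Principal-branch complex refractive index sqrt(eps)."""
        return np.sqrt(self.permittivity(name, f))


def default_library() -> MediumLibrary:
    """The packaged default medium library (simulator choices, documented
    in ``data/media.yaml``; not values measured in any experiment)."""
    path = resources.files("thztdd").joinpath("data/media.yaml")
    with resources.as_file(path) as p:
        return MediumLibrary.from_yaml(p)


def skin_permittivity(
    drug_fraction,
    f,
    library: MediumLibrary | None = None,
    background_fraction: float = SKIN_BACKGROUND_FRACTION,
    rule: str | None = None,
):
    """Permittivity of skin in which drug solution has displaced water.

    The composition is ``(background, water_total - drug_fraction,
    drug_fraction)`` where ``water_total = 1 - background_fraction`` (0.70 for
    the default 30/70 split).  ``drug_fraction`` may be an array (e.g. one
    value per image pixel); it broadcasts against the frequency axis with
    fractions in a trailing-new-axis layout, returning shape
    ``drug_fraction.shape + f.shape``.
    """
    library = library if library is not None else default_library()
    rule = rule if rule is not None else library.rule
    water_total = 1.0 - background_fraction
    df = np.asarray(drug_fraction, dtype=float)
    if np.any(df < -_FRACTION_TOL) or np.any(df > water_total + _FRACTION_TOL):
        raise ValueError(
            f"drug_fraction must lie in [0, {water_total}] "
            "(drug displaces water only)"
        )
    f = np.asarray(f, dtype=float)
    eps_bg = np.asarray(library.permittivity("biological_background", f))
    eps_w = np.asarray(library.permittivity("water", f))
    eps_d = np.asarray(library.permittivity("drug_solution", f))
    df_b = df.reshape(df.shape + (1,) * f.ndim)  # broadcast over frequency
    eps = mix_permittivities(
        [background_fraction, water_total - df_b, df_b],
        [eps_bg, eps_w, eps_d],
        rule=rule,
    )
    if df.ndim == 0 and f.ndim == 0:
        return complex(eps)
    return eps
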