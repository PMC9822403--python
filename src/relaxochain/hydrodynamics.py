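"""Stokes–Einstein / Stokes–Einstein–Debye hydrodynamic relations.

These link the rotational correlation time probed by NMR relaxation to
bulk fluid properties: a molecule treated as a hydrodynamic sphere of
radius R in a solvent of viscosity eta tumbles at a rate

    1/tau_c = 3 k T / (4 pi eta R^3)

equivalently tau_c = C_r * eta * V / (k T) with V = (4/3) pi R^3 and a
dimensionless fitting factor C_r absorbing deviations from stick
boundary conditions.  The rotational diffusion coefficient is
D_r = k T / (8 pi eta R^3), so tau_c ~ 1/D_r.  For unentangled chains
self-diffusion scales as M_w^(-alpha) with alpha = 1 below the
entanglement coupling molecular weight, which is what ultimately makes
R2/eta proportional to molecular weight — and hence to carbon chain
length for a homologous series.

Viscosity is accepted in centipoise (1 cp = 1 mPa s) to match how oil
tables are reported, and converted to SI internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "HydroParams",
    "BOLTZMANN_K",
    "cp_to_pa_s",
    "pa_s_to_cp",
    "sphere_volume",
    "tumbling_rate",
    "tau_c_sed",
    "rotational_diffusion",
    "self_diffusion_scaling",
    "r2_over_eta_mw_scaling",
]

#: Boltzmann constant (J/K)
BOLTZMANN_K = 1.380649e-23


def cp_to_pa_s(viscosity_cp: float) -> float:
    """Convert viscosity from centipoise to Pa s (1 cp = 1e-3 Pa s)."""
    return viscosity_cp * 1e-3


def pa_s_to_cp(viscosity_pa_s: float) -> float:
    """Convert viscosity from Pa s to centipoise."""
    return viscosity_pa_s * 1e3


def sphere_volume(radius_m: float) -> float:
    """Effective molecular volume of a hydrodynamic sphere, V = 4/3 pi R^3."""
    _require_positive(radius_m=radius_m)
    return 4.0 / 3.0 * math.pi * radius_m**3


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be strictly positive, got {value}")


@dataclass(frozen=True)
class HydroParams:
    """Hydrodynamic description of one molecular species.

    ``radius_m`` is the Stokes (hydrodynamic) radius; ``volume_m3``
    defaults to the spherical volume derived from it.  ``cr_fit`` is the
    empirical Stokes–Einstein–Debye prefactor C_r; ``mwc_gmol`` is the
    entanglement coupling molecular weight above which the unentangled
    M_w^(-alpha) diffusion scaling stops applying (default: infinite, no
    entanglement), and ``alpha`` its exponent.
    """

    viscosity_cp: float
    temperature_k: float = 293.0
    radius_m: float = 0.5e-9
    volume_m3: float | None = None
    cr_fit: float = 1.0
    mw_gmol: float | None = None
    mwc_gmol: float = math.inf
    alpha: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(
            viscosity_cp=self.viscosity_cp,
            temperature_k=self.temperature_k,
            radius_m=self.radius_m,
            cr_fit=self.cr_fit,
        )
        if self.volume_m3 is None:
            object.__setattr__(self, "volume_m3", sphere_volume(self.radius_m))
        else:
            _require_positive(volume_m3=self.volume_m3)


def tumbling_rate(radius_m: float, viscosity_cp: float, temperature_k: float) -> float:
    """Rotational tumbling rate 1/tau_c = 3 k T / (4 pi eta r^3), in s^-1.

    ``radius_m`` is the radius of gyration / Stokes radius in metres,
    ``viscosity_cp`` the fluid viscosity in centipoise.
    """
    _require_positive(
        radius_m=radius_m, viscosity_cp=viscosity_cp, temperature_k=temperature_k
    )
    eta = cp_to_pa_s(viscosity_cp)
    return 3.0 * BOLTZMANN_K * temperature_k / (4.0 * math.pi * eta * radius_m**3)


def tau_c_sed(
    volume_m3: float,
    viscosity_cp: float,
    temperature_k: float,
    cr_fit: float = 1.0,
) -> float:
    """Stokes–Einstein–Debye correlation time tau_c = C_r eta V / (k T), in s.

    With C_r chosen as 3/(4 pi) * V/r^3 (i.e. C_r = 1 for the spherical
    V = 4/3 pi r^3) this is exactly the reciprocal of
    :func:`tumbling_rate`.
    """
    _require_positive(
        volume_m3=volume_m3,
        viscosity_cp=viscosity_cp,
        temperature_k=temperature_k,
        cr_fit=cr_fit,
    )
    eta = cp_to_pa_s(viscosity_cp)
    return cr_fit * eta * volume_m3 / (BOLTZMANN_K * temperature_k)


def rotational_diffusion(
    radius_m: float, viscosity_cp: float, temperature_k: float
) -> float:
    """Rotational diffusion coefficient D_r = k T / (8 pi eta R^3), in s^-1."""
    _require_positive(
        radius_m=radius_m, viscosity_cp=viscosity_cp, temperature_k=temperature_k
    )
    eta = cp_to_pa_s(viscosity_cp)
    return BOLTZMANN_K * temperature_k / (8.0 * math.pi * eta * radius_m**3)


def self_diffusion_scaling(
    mw_gmol: float,
    coefficient: float = 1.0,
    alpha: float = 1.0,
    mwc_gmol: float = math.inf,
) -> float:
    """Unentangled-chain self-diffusion scaling D_self ~ M_w^(-alpha).

    Valid below the entanglement coupling molecular weight; alpha = 1
    for free (untwisted) chains.
    """
    _require_positive(mw_gmol=mw_gmol, coefficient=coefficient)
    if mw_gmol >= mwc_gmol:
        warnings.warn(
            f"M_w = {mw_gmol} g/mol is at or above the entanglement coupling "
            f"molecular weight {mwc_gmol} g/mol",
            UserWarning,
            stacklevel=2,
        )
    return coefficient * mw_gmol ** (-alpha)


def r2_over_eta_mw_scaling(
    mw_gmol: float,
    coefficient: float,
    mwc_gmol: float = math.inf,
) -> float:
    """Viscosity-normalised relaxation rate predicted from molecular weight.

    Implements the proportionality R2/eta ~ M_w that underlies the
    chain-length calibration; valid below the entanglement coupling
    molecular weight ``mwc_gmol``.  Crossing that bound emits a validity
    warning rather than failing, since the scaling degrades gradually.
    """
    _require_positive(mw_gmol=mw_gmol)
    if mw_gmol >= mwc_gmol:
        warnings.warn(
            f"M_w = {mw_gmol} g/mol is at or above the entanglement coupling "
            f"molecular weight {mwc_gmol} g/mol; the unentangled M_w scaling "
            "may not apply",
            UserWarning,
            stacklevel=2,
        )
    return coefficient * mw_gmol
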