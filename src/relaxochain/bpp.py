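"""Bloembergen–Purcell–Pound (BPP) dipolar relaxation theory.

Relaxation of ¹H spins in a liquid is driven by the fluctuating
intramolecular dipole–dipole coupling between neighbouring protons.  For
isotropic rotational tumbling with correlation time ``tau_c`` the BPP
spectral densities give

    1/T1 = (3/10) * P * [ tau_c/(1 + w0^2 tau_c^2) + 4 tau_c/(1 + 4 w0^2 tau_c^2) ]
    1/T2 = (3/20) * P * [ 3 tau_c + 5 tau_c/(1 + w0^2 tau_c^2)
                          + 2 tau_c/(1 + 4 w0^2 tau_c^2) ]

with ``w0 = 2 pi f`` the Larmor angular frequency and the dipolar
prefactor ``P = (mu0/4pi)^2 * gamma^4 * hbar^2 / l^6`` set by the
interproton distance ``l``.  In the extreme-narrowing (fast motion)
regime ``w0 tau_c << 1`` both rates reduce to ``(3/2) P tau_c`` so
T1 = T2; as motion slows T2 keeps shortening while T1 passes through a
minimum near ``w0 tau_c ~ 0.616`` and grows again, so T1 >= T2 always.

The T1/T2 ratio depends only on the dimensionless product ``x = w0 tau_c``
(the prefactor cancels), which makes it invertible: measuring T1/T2 pins
down the rotational correlation time without knowing ``l``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BPPParams",
    "RelaxationPair",
    "t1_bpp",
    "t2_bpp",
    "t1_over_t2",
    "invert_tau_c_from_ratio",
    "fast_motion_r2",
    "theory_curves",
]

#: vacuum permeability / 4 pi (T m / A)
MU0_OVER_4PI = 1e-7
#: ¹H gyromagnetic ratio (rad s^-1 T^-1)
GAMMA_H = 2.675e8
#: reduced Planck constant (J s)
HBAR = 1.054571817e-34
#: default interproton distance: typical geminal ¹H–¹H separation (m)
DEFAULT_INTERPROTON_DISTANCE_M = 1.79e-10


def dipolar_prefactor_from_distance(l_m: float) -> float:
    """Dipolar coupling constant (mu0/4pi)^2 gamma^4 hbar^2 / l^6 in s^-2."""
    if l_m <= 0:
        raise ValueError(f"interproton distance must be positive, got {l_m}")
    return (MU0_OVER_4PI**2) * (GAMMA_H**4) * (HBAR**2) / l_m**6


@dataclass(frozen=True)
class BPPParams:
    """Parameters of the dipolar relaxation model.

    Parameters
    ----------
    larmor_frequency_mhz
        ¹H Larmor frequency f in MHz; the angular frequency
        ``omega0 = 2 pi f`` is derived here, exactly once.
    interproton_distance_m
        Distance l between adjacent protons on the molecule (m).
    dipolar_prefactor
        Combined constant (mu0/4pi)^2 gamma^4 hbar^2 / l^6 in s^-2.
        Computed from ``interproton_distance_m`` when not supplied.
    second_moment
        Dipolar second moment M2 (s^-2) used by the fast-motion law
        :func:`fast_motion_r2`; optional.
    """

    larmor_frequency_mhz: float = 23.0
    interproton_distance_m: float = DEFAULT_INTERPROTON_DISTANCE_M
    dipolar_prefactor: float | None = None
    second_moment: float | None = None

    def __post_init__(self) -> None:
        if self.larmor_frequency_mhz <= 0:
            raise ValueError("larmor_frequency_mhz must be positive")
        if self.interproton_distance_m <= 0:
            raise ValueError("interproton_distance_m must be positive")
        if self.dipolar_prefactor is None:
            object.__setattr__(
                self,
                "dipolar_prefactor",
                dipolar_prefactor_from_distance(self.interproton_distance_m),
            )
        elif self.dipolar_prefactor <= 0:
            raise ValueError("dipolar_prefactor must be positive")

    @property
    def omega0(self) -> float:
        """Larmor angular frequency omega0 = 2 pi f (rad/s)."""
        return 2.0 * math.pi * self.larmor_frequency_mhz * 1e6


@dataclass(frozen=True)
class RelaxationPair:
    """A (T1, T2) pair together with the correlation time that produced it."""

    t1_s: float
    t2_s: float
    tau_c_s: float

    def __post_init__(self) -> None:
        if min(self.t1_s, self.t2_s, self.tau_c_s) <= 0:
            raise ValueError("all relaxation quantities must be positive")
        if self.t2_s > self.t1_s * (1 + 1e-9):
            raise ValueError("unphysical pair: T2 exceeds T1")

    @property
    def ratio(self) -> float:
        return self.t1_s / self.t2_s


def _check_tau_c(tau_c):
    tau_c = np.asarray(tau_c, dtype=float)
    if np.any(tau_c <= 0):
        raise ValueError("tau_c must be strictly positive")
    return tau_c


def t1_bpp(tau_c_s, params: BPPParams):
    """Longitudinal relaxation time T1 (s) for correlation time ``tau_c_s``.

    Accepts a scalar or array of correlation times.
    """
    tau = _check_tau_c(tau_c_s)
    x2 = (params.omega0 * tau) ** 2
    rate = 0.3 * params.dipolar_prefactor * (tau / (1 + x2) + 4 * tau / (1 + 4 * x2))
    out = 1.0 / rate
    return float(out) if np.isscalar(tau_c_s) else out


def t2_bpp(tau_c_s, params: BPPParams):
    """Transverse relaxation time T2 (s) for correlation time ``tau_c_s``."""
    tau = _check_tau_c(tau_c_s)
    x2 = (params.omega0 * tau) ** 2
    rate = (
        0.15
        * params.dipolar_prefactor
        * (3 * tau + 5 * tau / (1 + x2) + 2 * tau / (1 + 4 * x2))
    )
    out = 1.0 / rate
    return float(out) if np.isscalar(tau_c_s) else out


def relaxation_pair(tau_c_s: float, params: BPPParams) -> RelaxationPair:
    """Convenience: evaluate both relaxation times at one correlation time."""
    return RelaxationPair(
        t1_s=t1_bpp(tau_c_s, params), t2_s=t2_bpp(tau_c_s, params), tau_c_s=tau_c_s
    )


def t1_over_t2(omega0_tau_c):
    """T1/T2 ratio as a function of the dimensionless product x = omega0*tau_c.

    The dipolar prefactor cancels in the quotient, leaving

        T1/T2 = [3 + 5/(1+x^2) + 2/(1+4x^2)] / (2 [1/(1+x^2) + 4/(1+4x^2)])

    which equals 1 at x = 0 and grows monotonically with x.
    """
    x = np.asarray(omega0_tau_c, dtype=float)
    if np.any(x < 0):
        raise ValueError("omega0_tau_c must be nonnegative")
    x2 = x**2
    num = 3 + 5 / (1 + x2) + 2 / (1 + 4 * x2)
    den = 2 * (1 / (1 + x2) + 4 / (1 + 4 * x2))
    out = num / den
    return float(out) if np.isscalar(omega0_tau_c) else out


def invert_tau_c_from_ratio(
    ratio: float,
    params: BPPParams,
    bracket_s: tuple[float, float] = (1e-13, 1e-5),
    rtol: float = 1e-12,
) -> float:
    """Correlation time tau_c (s) whose T1/T2 ratio matches ``ratio``.

    Solved by bisection/Brent on the monotone branch of :func:`t1_over_t2`.
    A ratio of exactly 1 maps to the configured lower bracket (the
    extreme-narrowing regime, where tau_c is no longer identifiable from
    the ratio alone).

    Raises
    ------
    ValueError
        If ``ratio < 1`` (unphysical T1/T2) or the bracket does not
        contain the solution.
    """
    if ratio < 1:
        raise ValueError(f"unphysical T1/T2 ratio {ratio}: must be >= 1")
    lo, hi = bracket_s
    if not (0 < lo < hi):
        raise ValueError("bracket must satisfy 0 < lo < hi")
    w0 = params.omega0
    if ratio <= t1_over_t2(w0 * lo):
        return lo
    if ratio > t1_over_t2(w0 * hi):
        raise ValueError(
            f"ratio {ratio} exceeds t1_over_t2 at the upper bracket {hi} s; "
            "widen bracket_s"
        )
    # xtol must be far below the bracket scale (tau_c ~ ns) so the
    # relative tolerance governs
    return brentq(
        lambda t: t1_over_t2(w0 * t) - ratio, lo, hi, rtol=rtol, xtol=1e-30
    )


def fast_motion_r2(tau_c_s: float, second_moment: float, constant: float = 10.0) -> float:
    """Fast-motion (extreme-narrowing) transverse relaxation rate R2 (s^-1).

    In the regime ``omega0 tau_c << 1`` the rate is linear in the
    correlation time, ``R2 = c * M2 * tau_c`` with M2 the dipolar second
    moment.  The proportionality constant defaults to 10 and is exposed
    because conventions for folding numerical factors into M2 differ.
    """
    if tau_c_s <= 0:
        raise ValueError("tau_c_s must be positive")
    if second_moment <= 0:
        raise ValueError("second_moment must be positive")
    return constant * second_moment * tau_c_s


def theory_curves(
    params: BPPParams,
    tau_c_min_s: float = 1e-12,
    tau_c_max_s: float = 1e-6,
    n: int = 200,
):
    """Tabulate T1, T2 and their ratio over a log grid of correlation times.

    Returns a pandas DataFrame with columns tau_c_s, t1_s, t2_s, ratio —
    the data behind the classic T1/T2-versus-correlation-time plot.
    """
    import pandas as pd

    tau = np.logspace(math.log10(tau_c_min_s), math.log10(tau_c_max_s), n)
    t1 = t1_bpp(tau, params)
    t2 = t2_bpp(tau, params)
    return pd.DataFrame(
        {"tau_c_s": tau, "t1_s": t1, "t2_s": t2, "ratio": t1 / t2}
    )
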