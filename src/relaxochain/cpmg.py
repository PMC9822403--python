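"""CPMG echo-train representation and mono-exponential T2 fitting.

A CPMG (Carr–Purcell–Meiboom–Gill) acquisition records echo amplitudes
A_k at times t_k = k * TE.  For a single-component liquid the train
decays as M0 * exp(-t/T2); fitting that model yields the transverse
relaxation time T2 and the rate R2 = 1/T2.

Two fitting routes are provided: ordinary least squares on the log
amplitudes (fast, exact for noiseless data, used as warm start) and
nonlinear least squares on the raw amplitudes (default; unbiased at low
signal-to-noise where the log transform distorts the noise).

Units: T2 in milliseconds throughout, R2 in s^-1 (so R2 = 1000 / T2[ms]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "AcquisitionMeta",
    "EchoTrain",
    "RelaxationFit",
    "FitError",
    "fit_monoexponential",
    "r2_from_t2",
    "normalize_by_viscosity",
]

MIN_ECHOES = 8
#: fits with T2 outside (0, 1e6] ms are treated as failures (no real decay)
MAX_T2_MS = 1e6


class FitError(RuntimeError):
    """Raised when an echo train cannot be fit by a decaying exponential."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition settings of a low-field CPMG measurement.

    Defaults mirror a 23 MHz benchtop relaxometer protocol for oils:
    16 scans, 250 kHz sampling, 10 s repetition delay.
    """

    frequency_mhz: float = 23.0
    n_scans: int = 16
    sampling_khz: float = 250.0
    tr_s: float = 10.0


@dataclass(frozen=True)
class EchoTrain:
    """One CPMG echo train: amplitudes at times k*TE, k = 1..n_echoes."""

    echo_time_ms: float
    amplitudes: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", amps)
        if self.echo_time_ms <= 0:
            raise ValueError("echo_time_ms must be positive")
        if amps.ndim != 1 or amps.size < MIN_ECHOES:
            raise ValueError(
                f"need at least {MIN_ECHOES} echo amplitudes, got {amps.size}"
            )

    @property
    def n_echoes(self) -> int:
        return int(self.amplitudes.size)

    @property
    def times_ms(self) -> np.ndarray:
        """Echo times k*TE for k = 1..n_echoes (first echo at TE)."""
        return self.echo_time_ms * np.arange(1, self.n_echoes + 1)

    def scaled(self, factor: float) -> "EchoTrain":
        return EchoTrain(self.echo_time_ms, self.amplitudes * factor, self.meta)


@dataclass(frozen=True)
class RelaxationFit:
    """Result of mono-exponential fitting of one echo train."""

    t2_ms: float
    amplitude0: float
    rss: float
    method: Literal["log-linear", "nonlinear"]

    def __post_init__(self) -> None:
        if self.t2_ms <= 0:
            raise ValueError("fitted t2_ms must be positive")

    @property
    def r2_per_s(self) -> float:
        """Transverse relaxation rate R2 = 1/T2 in s^-1."""
        return r2_from_t2(self.t2_ms)


def _loglinear_estimate(times_ms: np.ndarray, amps: np.ndarray) -> tuple[float, float]:
    """OLS of log amplitude on time; returns (M0, T2_ms).

    Echoes below 3x the estimated tail-noise floor are dropped before the
    log transform (the transform blows up relative noise near zero); the
    estimate itself is exact for noiseless data.
    """
    keep = amps > 0
    if keep.sum() >= 2 * MIN_ECHOES:
        # noise floor from the scatter of the last 10% of echoes
        tail = amps[-max(4, amps.size // 10):]
        floor = 3.0 * float(np.std(tail))
        cut = amps > floor
        if cut.sum() >= MIN_ECHOES:
            keep = cut
    if keep.sum() < 2:
        raise FitError("too few positive echo amplitudes for log-linear fit")
    t, y = times_ms[keep], np.log(amps[keep])
    slope, intercept = np.polyfit(t, y, 1)
    if slope >= 0:
        raise FitError("echo train does not decay (nonnegative log-slope)")
    return float(np.exp(intercept)), float(-1.0 / slope)


def fit_monoexponential(
    train: EchoTrain,
    method: Literal["nonlinear", "log-linear"] = "nonlinear",
) -> RelaxationFit:
    """Fit A(t) = M0 exp(-t/T2) to a CPMG echo train.

    ``method="log-linear"`` performs OLS on log amplitudes only;
    ``method="nonlinear"`` (default) refines that estimate by
    Levenberg–Marquardt least squares on the raw amplitudes.

    Raises
    ------
    FitError
        If the train does not decay (fitted T2 nonpositive or beyond
        1e6 ms) or the fit cannot be started.
    """
    times = train.times_ms
    amps = train.amplitudes

    if method == "log-linear":
        m0, t2 = _loglinear_estimate(times, amps)
        resid = amps - m0 * np.exp(-times / t2)
        fit = RelaxationFit(t2, m0, float(resid @ resid), "log-linear")
    elif method == "nonlinear":
        try:
            m0, t2 = _loglinear_estimate(times, amps)
        except FitError:
            # warm start unavailable (e.g. negative amplitudes from noise);
            # fall back to a crude scale guess and let the optimiser decide
            m0, t2 = max(float(amps[0]), 1e-12), float(times[-1]) / 3.0
        def model(t, m0_, t2_):
            # clip the exponent so optimizer excursions through tiny or
            # negative T2 do not overflow
            return m0_ * np.exp(np.clip(-t / t2_, -700.0, 700.0))

        try:
            popt, _ = curve_fit(model, times, amps, p0=(m0, t2), maxfev=10000)
        except RuntimeError as exc:  # pragma: no cover - pathological inputs
            raise FitError(f"nonlinear fit did not converge: {exc}") from exc
        m0n, t2n = float(popt[0]), float(popt[1])
        if t2n <= 0:
            raise FitError(f"nonlinear fit returned nonpositive T2 = {t2n} ms")
        resid = amps - model(times, m0n, t2n)
        fit = RelaxationFit(t2n, m0n, float(resid @ resid), "nonlinear")
    else:
        raise ValueError(f"unknown fit method {method!r}")

    if fit.t2_ms > MAX_T2_MS:
        raise FitError(
            f"fitted T2 = {fit.t2_ms:.3g} ms exceeds {MAX_T2_MS:.0g} ms: "
            "signal shows no measurable decay"
        )
    return fit


def r2_from_t2(t2_ms: float) -> float:
    """Transverse relaxation rate R2 = 1/T2 in s^-1 from T2 in ms."""
    if t2_ms <= 0:
        raise ValueError(f"t2_ms must be positive, got {t2_ms}")
    return 1000.0 / t2_ms


def normalize_by_viscosity(r2_per_s: float, viscosity_cp: float) -> float:
    """Viscosity-normalised relaxation rate R2/eta (s^-1 cp^-1).

    This is the predictor of the chain-length calibration: dividing by
    viscosity removes the solvent-friction contribution to the
    correlation time, leaving the molecular-size dependence.
    """
    if viscosity_cp <= 0:
        raise ValueError(f"viscosity_cp must be positive, got {viscosity_cp}")
    if r2_per_s <= 0:
        raise ValueError(f"r2_per_s must be positive, got {r2_per_s}")
    return r2_per_s / viscosity_cp
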