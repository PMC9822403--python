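"""Carbon chain-length calibration from viscosity-normalised relaxation rates.

For a homologous series of oils the viscosity-normalised transverse
relaxation rate R2/eta grows linearly with molecular weight, and hence
with the carbon chain length CL of the dominant acyl/backbone chain.
This module fits and applies the linear calibration

    CL = a * (R2/eta) + b

by ordinary least squares over a panel of reference oils with known CL,
measured T2 (hence R2 = 1/T2) and viscosity.  On the bundled 17-oil
reference panel the fit gives a = +52.998 CL/(s^-1 cp^-1) and
b = -1.5597, valid for CL between about 3 and 24.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OilRecord",
    "CalibrationModel",
    "ChainLengthPrediction",
    "LOOResult",
    "fit_calibration",
    "predict_chain_length",
    "predict_from_ratio",
    "loo_cross_validate",
]

_CONSISTENCY_RTOL = 1e-4


@dataclass(frozen=True)
class OilRecord:
    """One reference oil: identity, chain length, and relaxation observables.

    ``r2_over_eta`` may be carried independently of ``r2_per_s`` and
    ``viscosity_cp`` (reference tables often print it at higher
    precision); when all three are present they must agree to 1e-4
    relative.
    """

    formula: str
    name: str
    chain_length: int
    state: str = "liquid"
    mw_gmol: float | None = None
    purity: str | None = None
    t2_ms: float | None = None
    r2_per_s: float | None = None
    r2_over_eta: float | None = None
    viscosity_cp: float | None = None

    def __post_init__(self) -> None:
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")
        if (
            self.r2_over_eta is not None
            and self.r2_per_s is not None
            and self.viscosity_cp is not None
        ):
            implied = self.r2_per_s / self.viscosity_cp
            if not math.isclose(
                implied, self.r2_over_eta, rel_tol=_CONSISTENCY_RTOL
            ):
                raise ValueError(
                    f"{self.name}: r2_over_eta = {self.r2_over_eta} inconsistent "
                    f"with r2_per_s/viscosity_cp = {implied:.6g}"
                )

    @property
    def is_liquid(self) -> bool:
        return self.state.lower().startswith("liquid")

    @property
    def predictor(self) -> float | None:
        """R2/eta in s^-1 cp^-1, preferring the directly tabulated value."""
        if self.r2_over_eta is not None:
            return self.r2_over_eta
        if self.r2_per_s is not None and self.viscosity_cp is not None:
            return self.r2_per_s / self.viscosity_cp
        return None


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted linear calibration CL = slope_a * (R2/eta) + intercept_b."""

    slope_a: float
    intercept_b: float
    n_samples: int
    r_squared: float
    rmse_cl: float
    residuals: tuple[tuple[str, float], ...]
    predictor_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("a calibration needs at least 3 samples")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "slope_a": self.slope_a,
            "intercept_b": self.intercept_b,
            "n_samples": self.n_samples,
            "r_squared": self.r_squared,
            "rmse_cl": self.rmse_cl,
            "predictor_range": list(self.predictor_range),
            "residuals": {name: r for name, r in self.residuals},
        }


@dataclass(frozen=True)
class ChainLengthPrediction:
    """A chain-length estimate: real-valued, rounded, and an extrapolation flag."""

    chain_length: float
    chain_length_rounded: int
    extrapolated: bool


def _usable(records) -> list[OilRecord]:
    out = []
    for r in records:
        if r.is_liquid and r.predictor is not None and r.predictor > 0:
            out.append(r)
    return out


def fit_calibration(records) -> CalibrationModel:
    """Ordinary least squares of chain length on R2/eta over liquid records.

    Solid records and records without a usable predictor are skipped.

    Raises
    ------
    ValueError
        With fewer than 3 usable records, or if the predictor has zero
        variance (degenerate design).
    """
    usable = _usable(records)
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 liquid records with R2/eta, got {len(usable)}"
        )
    x = np.array([r.predictor for r in usable])
    y = np.array([float(r.chain_length) for r in usable])
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: predictor R2/eta has zero variance")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    resid = y - fitted
    return CalibrationModel(
        slope_a=float(res.slope),
        intercept_b=float(res.intercept),
        n_samples=len(usable),
        r_squared=float(res.rvalue**2),
        rmse_cl=float(np.sqrt(np.mean(resid**2))),
        residuals=tuple((r.name, float(e)) for r, e in zip(usable, resid)),
        predictor_range=(float(x.min()), float(x.max())),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def predict_from_ratio(model: CalibrationModel, r2_over_eta: float) -> ChainLengthPrediction:
    """Apply the calibration to a viscosity-normalised rate R2/eta."""
    if model is None:
        raise ValueError("calibration model is not fitted")
    if r2_over_eta <= 0:
        raise ValueError("r2_over_eta must be positive")
    cl = model.slope_a * r2_over_eta + model.intercept_b
    lo, hi = model.predictor_range
    return ChainLengthPrediction(
        chain_length=float(cl),
        chain_length_rounded=_round_half_away(cl),
        extrapolated=not (lo <= r2_over_eta <= hi),
    )


def predict_chain_length(
    model: CalibrationModel, r2_per_s: float, viscosity_cp: float
) -> ChainLengthPrediction:
    """Predict chain length from a measured rate R2 (s^-1) and viscosity (cp)."""
    if r2_per_s <= 0 or viscosity_cp <= 0:
        raise ValueError("r2_per_s and viscosity_cp must be positive")
    return predict_from_ratio(model, r2_per_s / viscosity_cp)


@dataclass(frozen=True)
class LOOResult:
    """Leave-one-out cross-validation of the calibration."""

    table: pd.DataFrame  # columns: name, chain_length, cl_pred, error
    loo_rmse: float
    in_sample_rmse: float


def loo_cross_validate(records) -> LOOResult:
    """Leave-one-out refits of the calibration; held-out signed errors.

    Each usable record is held out in turn, the line is refit on the
    remainder, and the held-out chain length is predicted.  The LOO RMSE
    is never smaller than the in-sample RMSE for a correctly specified
    linear fit, so the gap measures how much single oils steer the line.
    """
    usable = _usable(records)
    if len(usable) < 4:
        raise ValueError(f"leave-one-out needs >= 4 usable records, got {len(usable)}")
    full = fit_calibration(usable)
    rows = []
    for i, held in enumerate(usable):
        rest = usable[:i] + usable[i + 1:]
        m = fit_calibration(rest)
        pred = m.slope_a * held.predictor + m.intercept_b
        rows.append(
            {
                "name": held.name,
                "chain_length": held.chain_length,
                "cl_pred": pred,
                "error": pred - held.chain_length,
            }
        )
    table = pd.DataFrame(rows)
    return LOOResult(
        table=table,
        loo_rmse=float(np.sqrt(np.mean(table["error"] ** 2))),
        in_sample_rmse=full.rmse_cl,
    )
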