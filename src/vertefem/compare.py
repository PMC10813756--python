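"""Model-vs-experiment statistics and yield-strain-scale calibration.

Per-specimen percent errors, the coefficient of determination (squared
Pearson correlation — equivalent to the regression R^2 for a simple
linear fit), and a 1-D bounded calibration of the dimensionless
yield-strain scaling factor that minimizes the mean absolute strength
percent error.  Stiffness is reported but deliberately not optimized:
the scale enters the yield strain (hence strength) linearly and the
elastic stiffness not at all, and calibrating on strength is what the
underlying validation procedure does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar


def percent_error(predicted, experimental):
    """100 * |predicted - experimental| / |experimental| (absolute errors)."""
    pred = np.asarray(predicted, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if np.any(exp == 0):
        raise ValueError("experimental value of 0 makes percent error undefined")
    return 100.0 * np.abs(pred - exp) / np.abs(exp)


def coefficient_of_determination(predicted, experimental) -> float:
    """Squared Pearson correlation of predicted-vs-experimental pairs."""
    pred = np.asarray(predicted, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1 or len(pred) < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(exp) == 0:
        raise ValueError("experimental values are all equal: correlation undefined")
    if np.ptp(pred) == 0:
        return 0.0  # a constant prediction explains none of the variance
    r = np.corrcoef(pred, exp)[0, 1]
    return float(r**2)


@dataclass
class ComparisonStats:
    stiffness_percent_error: np.ndarray
    strength_percent_error: np.ndarray
    mean_stiffness_error: float
    mean_strength_error: float
    r2_stiffness: float
    r2_strength: float
    n_specimens: int

    def to_dict(self) -> dict:
        return {
            "stiffness_percent_error": self.stiffness_percent_error.tolist(),
            "strength_percent_error": self.strength_percent_error.tolist(),
            "mean_stiffness_error": self.mean_stiffness_error,
            "mean_strength_error": self.mean_strength_error,
            "r2_stiffness": self.r2_stiffness,
            "r2_strength": self.r2_strength,
            "n_specimens": self.n_specimens,
        }


def comparison_stats(
    predicted_stiffness, experimental_stiffness, predicted_strength, experimental_strength
) -> ComparisonStats:
    """Bundle the error and correlation metrics for a specimen set."""
    es = percent_error(predicted_stiffness, experimental_stiffness)
    ef = percent_error(predicted_strength, experimental_strength)
    return ComparisonStats(
        stiffness_percent_error=es,
        strength_percent_error=ef,
        mean_stiffness_error=float(es.mean()),
        mean_strength_error=float(ef.mean()),
        r2_stiffness=coefficient_of_determination(predicted_stiffness, experimental_stiffness),
        r2_strength=coefficient_of_determination(predicted_strength, experimental_strength),
        n_specimens=len(es),
    )


@dataclass
class CalibrationResult:
    scale: float
    objective: float  # mean abs strength percent error at the recovered scale
    objective_at_unit_scale: float
    n_evaluations: int


def calibrate_yield_scale(
    predict_strengths,
    experimental_strengths,
    bounds: tuple[float, float] = (0.2, 10.0),
    xatol_frac: float = 5e-3,
    warm_start: bool = True,
) -> CalibrationResult:
    """Find the yield-strain scale minimizing the strength error.

    ``predict_strengths(scale)`` must return the model strengths (kN) of
    every specimen at that scale; ``experimental_strengths`` are the
    bench values.  The objective is the mean absolute strength percent
    error.  Because the perfectly plastic limit load is (near-)linear in
    the scale, the search is warm-started at
    ``mean(experimental / predicted_at_scale_1)`` and then refined by
    bounded scalar minimization in a bracket around that start.
    """
    exp = np.asarray(experimental_strengths, dtype=float)
    if len(exp) < 1 or np.any(exp <= 0):
        raise ValueError("need >= 1 specimen with positive experimental strength")
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("invalid bounds")

    n_eval = 0
    memo: dict[float, np.ndarray] = {}

    def pred_at(scale: float) -> np.ndarray:
        nonlocal n_eval
        scale = float(scale)
        if scale not in memo:
            n_eval += 1
            memo[scale] = np.asarray(predict_strengths(scale), dtype=float)
        return memo[scale]

    def objective(scale: float) -> float:
        return float(percent_error(pred_at(scale), exp).mean())

    obj_unit = objective(1.0)
    if warm_start:
        s0 = float(np.mean(exp / pred_at(1.0)))
        lo = max(lo, 0.6 * s0)
        hi = min(hi, 1.4 * s0)
        if lo >= hi:
            lo, hi = bounds
    res = minimize_scalar(
        objective,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol_frac * (lo + hi) / 2.0, "maxiter": 30},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter, keep best-so-far
        raise RuntimeError(f"yield-scale calibration failed: {res.message} (best {res.x:.3f})")
    return CalibrationResult(
        scale=float(res.x),
        objective=float(res.fun),
        objective_at_unit_scale=obj_unit,
        n_evaluations=n_eval,
    )
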