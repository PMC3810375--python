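"""Linearizing nonlinear (saturating) growth data.

The autocorrelation estimator assumes the cohort mean grows linearly in
time. Many organisms instead decelerate toward an asymptote; if the mean
follows a saturating exponential

    size(t) = c * (1 - exp(-(b + d t))),

then transforming every measurement through the inverse,
-log(1 - size / c_hat), restores a linear mean trajectory. The transform
is undefined at or above the fitted asymptote, so such measurements are
dropped individually and the dropped fraction reported; cohorts losing
more than a configurable share at any occasion are flagged as unusable.
An exponential grower needs no curve fit at all: log-transforming the
sizes linearizes it directly (``transform="log"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import CohortSizes

__all__ = [
    "GrowthCurveParams",
    "fit_growth_curve",
    "linearize",
    "saturating_exponential",
]


@dataclass(frozen=True)
class GrowthCurveParams:
    """Saturating-exponential mean growth curve size = c (1 - e^-(b + d t)).

    ``c`` is the asymptotic size (size-units, > 0); ``b`` the intercept of
    the exponent (dimensionless); ``d`` its rate per unit time (>= 0 for a
    growing cohort).
    """

    c: float
    b: float
    d: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("asymptotic size c must be positive")

    def mean_size(self, t) -> np.ndarray:
        return saturating_exponential(np.asarray(t, dtype=float), self.c, self.b, self.d)


def saturating_exponential(t, c, b, d):
    return c * -np.expm1(-(b + d * t))


class GrowthCurveFitError(RuntimeError):
    """Nonlinear fit failed; carries the best coarse-grid candidate."""

    def __init__(self, message: str, best_candidate: GrowthCurveParams):
        super().__init__(message)
        self.best_candidate = best_candidate


def fit_growth_curve(mean_sizes: pd.DataFrame | np.ndarray) -> GrowthCurveParams:
    """Nonlinear least-squares fit of the saturating exponential to
    occasion means.

    ``mean_sizes``: two columns (time, mean size), >= 3 rows, positive
    sizes. Starting values scan a coarse grid of asymptotes c in
    (max size, 3 max size]; for each, (b, d) come from regressing
    -log(1 - size/c) on time. The grid keeps every candidate asymptote
    above the data, so the fitted c cannot fall below the largest mean.
    """
    arr = np.asarray(mean_sizes, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("mean_sizes must be (>=3, 2): time and mean size")
    t, y = arr[:, 0], arr[:, 1]
    if np.any(y <= 0):
        raise ValueError("mean sizes must be positive")

    ymax = y.max()
    best = None
    for c_try in ymax * np.linspace(1.05, 3.0, 25):
        z = -np.log1p(-y / c_try)
        d_try, b_try = np.polyfit(t, z, 1)
        resid = y - saturating_exponential(t, c_try, b_try, d_try)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, c_try, b_try, d_try)
    _, c0, b0, d0 = best

    try:
        popt, _ = curve_fit(
            saturating_exponential,
            t,
            y,
            p0=[c0, b0, d0],
            bounds=([ymax * (1.0 + 1e-9), -np.inf, -np.inf], np.inf),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise GrowthCurveFitError(
            f"saturating-exponential fit did not converge: {exc}",
            GrowthCurveParams(c=c0, b=b0, d=d0),
        ) from exc
    return GrowthCurveParams(c=float(popt[0]), b=float(popt[1]), d=float(popt[2]))


def linearize(
    sizes: CohortSizes,
    curve: GrowthCurveParams | None = None,
    transform: str = "saturating",
    max_drop_fraction: float = 0.5,
) -> tuple[CohortSizes, float]:
    """Map a cohort onto the linear latent scale of a fitted growth curve.

    Saturating mode sends each retained size x to -log(1 - x / c_hat);
    measurements with x >= c_hat cannot be transformed and are masked out
    (counted in the returned ``dropped_fraction`` over alive
    measurements). ``transform="log"`` instead log-transforms positive
    sizes (for exponential growers), dropping non-positive ones. The map
    is strictly increasing, so within-occasion ordering is preserved.

    Raises if any occasion loses all measurements, and if any occasion's
    drop fraction exceeds ``max_drop_fraction`` (cohort unusable).
    """
    x = sizes.sizes
    if transform == "log":
        ok = x > 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(ok, np.log(np.where(ok, x, 1.0)), np.nan)
    elif transform == "saturating":
        if curve is None:
            raise ValueError("saturating transform requires a fitted curve")
        ok = x < curve.c
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(ok, -np.log1p(-np.minimum(x, curve.c * (1 - 1e-15)) / curve.c), np.nan)
    else:
        raise ValueError(f"unknown transform {transform!r}")

    alive = sizes.alive & ok
    # dropping is not death: only forbid resurrection that death caused
    n_alive_before = sizes.alive.sum()
    dropped = int(n_alive_before - alive.sum())
    dropped_fraction = dropped / n_alive_before if n_alive_before else 0.0

    per_occasion_before = sizes.alive.sum(axis=0)
    per_occasion_after = alive.sum(axis=0)
    if np.any(per_occasion_after == 0):
        raise ValueError("an occasion lost all measurements in linearization")
    occ_drop = 1.0 - per_occasion_after / per_occasion_before
    if np.any(occ_drop > max_drop_fraction):
        raise ValueError(
            f"drop fraction {occ_drop.max():.2f} exceeds "
            f"{max_drop_fraction:.2f} at some occasion; cohort unusable"
        )

    out = CohortSizes(
        sizes=np.where(alive, z, 0.0),
        alive=alive,
        times=sizes.times,
        individual_ids=sizes.individual_ids,
        allow_gaps=True,
    )
    return out, float(dropped_fraction)
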