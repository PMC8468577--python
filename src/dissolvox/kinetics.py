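"""Release kinetics: Higuchi and Korsmeyer-Peppas fits and regression tests.

The release mechanism of a matrix tablet is read off two linearised plots
over the 20-60 % release window:

* Higuchi:           Q(t) = k_H sqrt(t)      -> Q vs sqrt(t)
* Korsmeyer-Peppas:  Q(t)/Q_inf = k t^n      -> log10 Q vs log10 t

Time is in minutes and release in percent for both plots.  Profiles with
fewer than four points inside the window are excluded from the kinetic
analysis (an exclusion signal, not an error).  For cylinders the exponent n
classifies the transport mechanism: n ~ 0.45 Fickian diffusion,
0.45 < n < 0.89 anomalous transport, n ~ 0.89 and above case-II
(relaxation/erosion controlled).

A predicted profile's regression line is tested against the experimental
one with pooled t-tests (ANCOVA style): first the slopes
(df = n1 + n2 - 4); only when the slopes are not significantly different is
the elevation (intercept) tested under a common slope (df = n1 + n2 - 3) —
otherwise the intercept comparison is not meaningful and is reported as NA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .profile_metrics import DissolutionProfile

__all__ = [
    "KineticFit",
    "RegressionComparison",
    "ProfileExcluded",
    "release_window",
    "fit_higuchi",
    "fit_korsmeyer_peppas",
    "classify_mechanism",
    "compare_regressions",
    "adjusted_r2",
]

Model = Literal["higuchi", "korsmeyer_peppas"]

MIN_WINDOW_POINTS = 4


class ProfileExcluded(Exception):
    """Fewer than four points in the kinetic window: profile excluded.

    Distinct from a failure — the windowing rule simply does not apply,
    e.g. for very fast releasing tablets.
    """


@dataclass
class KineticFit:
    """Ordinary least-squares fit of one linearised release model.

    ``x``/``y`` retain the transformed window data so regression comparisons
    can recover all sums of squares.
    """

    model: Model
    slope: float
    intercept: float
    r2: float
    adjusted_r2: float
    n_points: int
    residual_sum_squares: float
    x: np.ndarray
    y: np.ndarray


@dataclass
class RegressionComparison:
    """Pooled t-tests comparing two regression lines.

    ``t_intercept``/``p_intercept`` are ``None`` when the slope test already
    rejects (reported as NA)."""

    t_slope: float
    p_slope: float
    df_slope: int
    t_intercept: float | None
    p_intercept: float | None
    df_intercept: int | None
    alpha: float

    @property
    def slopes_differ(self) -> bool:
        return self.p_slope < self.alpha


def release_window(
    profile: DissolutionProfile, lo: float = 20.0, hi: float = 60.0
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a profile to the closed release window [lo, hi] percent.

    Returns ``(times, released)`` in original order; the window may be empty
    (the caller applies the four-point exclusion rule).
    """
    sel = (profile.released >= lo) & (profile.released <= hi)
    return profile.times[sel], profile.released[sel]


def _window_arrays(
    profile: DissolutionProfile, lo: float, hi: float
) -> tuple[np.ndarray, np.ndarray]:
    sel = (profile.released >= lo) & (profile.released <= hi)
    n = int(sel.sum())
    if n < MIN_WINDOW_POINTS:
        raise ProfileExcluded(
            f"{n} point(s) in the {lo:g}-{hi:g} % release window "
            f"(need >= {MIN_WINDOW_POINTS}); profile "
            f"{profile.label or '<unlabelled>'} excluded from kinetic analysis"
        )
    return profile.times[sel], profile.released[sel]


def adjusted_r2(r2: float, n_points: int) -> float:
    """Adjusted R^2 for simple linear regression: 1 - (1-R^2)(n-1)/(n-2)."""
    if n_points < 3:
        raise ValueError("adjusted R^2 needs at least 3 points")
    return 1.0 - (1.0 - r2) * (n_points - 1) / (n_points - 2)


def _ols_fit(x: np.ndarray, y: np.ndarray, model: Model) -> KineticFit:
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: no variance in x")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    rss = float(np.sum((y - yhat) ** 2))
    r2 = float(res.rvalue**2)
    return KineticFit(
        model=model,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        adjusted_r2=adjusted_r2(r2, x.size),
        n_points=int(x.size),
        residual_sum_squares=rss,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
    )


def fit_higuchi(
    profile: DissolutionProfile, lo: float = 20.0, hi: float = 60.0
) -> KineticFit:
    """Fit released % against sqrt(time/min) on the release window.

    Raises :class:`ProfileExcluded` when fewer than four window points exist.
    """
    t, q = _window_arrays(profile, lo, hi)
    return _ols_fit(np.sqrt(t), q, "higuchi")


def fit_korsmeyer_peppas(
    profile: DissolutionProfile, lo: float = 20.0, hi: float = 60.0
) -> KineticFit:
    """Fit log10(released %) against log10(time/min) on the release window.

    The slope is the release exponent n; the intercept is log10 k.
    """
    t, q = _window_arrays(profile, lo, hi)
    if np.any(t <= 0) or np.any(q <= 0):
        raise ValueError("Korsmeyer-Peppas fit requires positive times and releases")
    return _ols_fit(np.log10(t), np.log10(q), "korsmeyer_peppas")


def classify_mechanism(n: float, tol: float = 0.02) -> str:
    """Transport mechanism of a cylinder from the release exponent n.

    n <= 0.45 + tol: Fickian diffusion; up to 0.89 - tol: anomalous
    transport; above: case-II (zero-order-like) transport.
    """
    if not math.isfinite(n):
        raise ValueError("release exponent must be finite")
    if n <= 0.45 + tol:
        return "Fickian diffusion"
    if n < 0.89 - tol:
        return "anomalous transport"
    return "case-II transport"


def compare_regressions(
    fit_test: KineticFit, fit_ref: KineticFit, alpha: float = 0.05
) -> RegressionComparison:
    """Test a predicted profile's regression line against the reference one.

    Slope test: pooled residual variance over both fits,
    t = (b1 - b2)/SE, df = n1 + n2 - 4.  The elevation (intercept) test is
    computed only when the slope test does not reject at ``alpha``; it uses
    the common-slope model with df = n1 + n2 - 3.  Otherwise the intercept
    fields are ``None`` and rendered NA in reports.
    """
    x1, y1 = fit_test.x, fit_test.y
    x2, y2 = fit_ref.x, fit_ref.y
    n1, n2 = x1.size, x2.size
    sxx1 = float(np.sum((x1 - x1.mean()) ** 2))
    sxx2 = float(np.sum((x2 - x2.mean()) ** 2))
    if sxx1 == 0 or sxx2 == 0:
        raise ValueError("degenerate x-variance in one of the fits")
    df_s = n1 + n2 - 4
    s2p = (fit_test.residual_sum_squares + fit_ref.residual_sum_squares) / df_s
    se_diff = math.sqrt(s2p * (1.0 / sxx1 + 1.0 / sxx2))
    if se_diff == 0.0:
        t_slope = 0.0 if fit_test.slope == fit_ref.slope else math.inf
    else:
        t_slope = (fit_test.slope - fit_ref.slope) / se_diff
    p_slope = float(2.0 * stats.t.sf(abs(t_slope), df_s))

    if p_slope < alpha:
        return RegressionComparison(
            t_slope=float(t_slope), p_slope=p_slope, df_slope=df_s,
            t_intercept=None, p_intercept=None, df_intercept=None, alpha=alpha,
        )

    # elevation test under a common slope
    sxy1 = float(np.sum((x1 - x1.mean()) * (y1 - y1.mean())))
    sxy2 = float(np.sum((x2 - x2.mean()) * (y2 - y2.mean())))
    syy1 = float(np.sum((y1 - y1.mean()) ** 2))
    syy2 = float(np.sum((y2 - y2.mean()) ** 2))
    sxx_c = sxx1 + sxx2
    b_common = (sxy1 + sxy2) / sxx_c
    # cancellation can leave a tiny negative residual for perfect fits
    rss_common = max(0.0, (syy1 + syy2) - (sxy1 + sxy2) ** 2 / sxx_c)
    df_i = n1 + n2 - 3
    s2c = rss_common / df_i
    num = (y1.mean() - y2.mean()) - b_common * (x1.mean() - x2.mean())
    se_elev = math.sqrt(
        s2c * (1.0 / n1 + 1.0 / n2 + (x1.mean() - x2.mean()) ** 2 / sxx_c)
    )
    t_int = num / se_elev if se_elev > 0 else 0.0
    p_int = float(2.0 * stats.t.sf(abs(t_int), df_i))
    return RegressionComparison(
        t_slope=float(t_slope), p_slope=p_slope, df_slope=df_s,
        t_intercept=float(t_int), p_intercept=p_int, df_intercept=df_i, alpha=alpha,
    )
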