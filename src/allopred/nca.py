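"""Noncompartmental analysis of IV concentration-time profiles.

Turns any :class:`~allopred.profiles_io.ConcProfile` (observed, predicted
or simulated) into AUC(0-last), AUC(0-inf), the terminal rate constant
lambda_z, half-life and clearance.  AUC uses the linear-up/log-down
trapezoid by default (exact on log-linear down segments, the typical
shape of IV biologic tails); lambda_z comes from an OLS fit of ln C vs t
over an automatically selected terminal window.

No back-extrapolation to t = 0 is performed: the AUC starts at the first
sampled point.  Units: AUC in ug.day/mL (= mg.day/L), clearance in L/day
given the dose in mg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import EstimationError, ValidationError
from .profiles_io import ConcProfile

log = logging.getLogger(__name__)

__all__ = ["NCAResult", "fit_lambda_z", "auc_trapezoid", "nca_summary"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class NCAResult:
    """NCA summary for one profile."""

    auc_last: float  # ug.day/mL up to the last sample
    auc_inf: float  # ug.day/mL extrapolated to infinity
    lambda_z: float  # 1/day terminal rate constant
    thalf: float  # days, ln(2)/lambda_z
    clearance: float  # L/day, dose_total / auc_inf
    extrap_fraction: float  # (auc_inf - auc_last)/auc_inf, in [0, 1)
    n_lambda_points: int
    r2_adj: float


def _ols_loglinear(t: np.ndarray, lnc: np.ndarray) -> tuple:
    """OLS slope/intercept/adjusted R^2 of lnc on t."""
    m = len(t)
    tbar = t.mean()
    ybar = lnc.mean()
    sxx = float(((t - tbar) ** 2).sum())
    sxy = float(((t - tbar) * (lnc - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    ss_tot = float(((lnc - ybar) ** 2).sum())
    ss_res = float(((lnc - intercept - slope * t) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 0.0 if ss_res > 0 else 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2) if m > 2 else r2
    return slope, intercept, r2_adj


def fit_lambda_z(
    profile: ConcProfile,
    strategy: str = "best_adj_r2",
    n_points: int | None = None,
    min_points: int = 3,
) -> tuple:
    """Estimate the terminal elimination rate constant.

    Parameters
    ----------
    strategy:
        ``"best_adj_r2"`` scans terminal suffixes (from ``min_points``
        points up to everything after the global Cmax, which is always
        excluded) and keeps the window with the highest adjusted R^2,
        preferring more points on ties.  ``"fixed_n"`` uses the last
        ``n_points`` samples as given.

    Returns
    -------
    (lambda_z, intercept, r2_adj, points_used)
        ``lambda_z`` is the negated (positive) OLS slope of ln C vs t;
        ``intercept`` the fitted ln-concentration at t = 0.

    Raises
    ------
    ValidationError
        Fewer than ``min_points`` candidate points.
    EstimationError
        No declining terminal window exists.
    """
    t = np.asarray(profile.times, dtype=float)
    lnc = np.log(np.asarray(profile.concentrations, dtype=float))
    n = len(t)
    if min_points < 3:
        raise ValidationError(f"min_points must be >= 3, got {min_points}")

    if strategy == "fixed_n":
        if n_points is None:
            raise ValidationError("strategy 'fixed_n' requires n_points")
        if n_points < min_points:
            raise ValidationError(
                f"n_points {n_points} is below the minimum of {min_points}"
            )
        if n_points > n:
            raise ValidationError(
                f"n_points {n_points} exceeds the {n} available points"
            )
        slope, intercept, r2_adj = _ols_loglinear(t[-n_points:], lnc[-n_points:])
        if slope >= 0:
            raise EstimationError("no terminal decline (nonnegative slope)")
        return -slope, intercept, r2_adj, n_points

    if strategy != "best_adj_r2":
        raise ValidationError(f"unknown lambda_z strategy {strategy!r}")

    imax = int(np.argmax(np.asarray(profile.concentrations)))
    first = imax + 1  # Cmax itself is excluded whenever enough points remain
    if n - first < min_points:
        first = n - min_points
    if first < 0:
        raise ValidationError(
            f"profile has {n} point(s); lambda_z needs >= {min_points}"
        )
    best = None
    # longest window first so that ties keep more points
    for start in range(first, n - min_points + 1):
        slope, intercept, r2_adj = _ols_loglinear(t[start:], lnc[start:])
        if slope >= 0:
            continue
        if best is None or r2_adj > best[2]:
            best = (-slope, intercept, r2_adj, n - start)
    if best is None:
        raise EstimationError("no terminal decline (nonnegative slope)")
    return best


def auc_trapezoid(profile: ConcProfile, rule: str = "linear_up_log_down") -> float:
    """AUC from the first to the last sample by the trapezoidal rule.

    ``"linear"`` applies the arithmetic trapezoid everywhere.
    ``"linear_up_log_down"`` uses the logarithmic trapezoid
    dt*(C1 - C2)/ln(C1/C2) on declining segments (exact for
    exponential decay) and falls back to linear on rising or flat ones.
    """
    if profile.n < 2:
        raise ValidationError(f"AUC needs >= 2 points, got {profile.n}")
    if rule not in ("linear", "linear_up_log_down"):
        raise ValidationError(f"unknown AUC rule {rule!r}")
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.concentrations, dtype=float)
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    linear = dt * (c1 + c2) / 2.0
    if rule == "linear":
        return float(linear.sum())
    down = c2 < c1
    seg = linear.copy()
    seg[down] = dt[down] * (c1[down] - c2[down]) / np.log(c1[down] / c2[down])
    return float(seg.sum())


def nca_summary(
    profile: ConcProfile,
    rule: str = "linear_up_log_down",
    strategy: str = "best_adj_r2",
    n_points: int | None = None,
    min_points: int = 3,
) -> NCAResult:
    """Full NCA: AUCs, lambda_z, half-life, clearance.

    AUC(0-inf) = AUC(0-last) + C_last/lambda_z; clearance =
    dose_total/AUC(0-inf).  A warning is logged when more than 20% of
    the AUC is extrapolated.
    """
    lambda_z, _intercept, r2_adj, points_used = fit_lambda_z(
        profile, strategy=strategy, n_points=n_points, min_points=min_points
    )
    auc_last = auc_trapezoid(profile, rule=rule)
    c_last = profile.concentrations[-1]
    auc_inf = auc_last + c_last / lambda_z
    extrap = (auc_inf - auc_last) / auc_inf
    if extrap > 0.2:
        log.warning(
            "extrapolated AUC fraction %.1f%% exceeds 20%%; "
            "terminal sampling may be too short",
            100 * extrap,
        )
    return NCAResult(
        auc_last=auc_last,
        auc_inf=auc_inf,
        lambda_z=lambda_z,
        thalf=LN2 / lambda_z,
        clearance=profile.dose_total / auc_inf,
        extrap_fraction=extrap,
        n_lambda_points=points_used,
        r2_adj=r2_adj,
    )
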