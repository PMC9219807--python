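"""Prediction-performance metrics: fold ratios, range counts, AFE.

A predicted human profile is compared against observed human data by
pairing time points (exact matching within a tolerance, or log-linear
interpolation of the observed curve), forming predicted/observed ratios,
and summarising them as

* counts inside the closed ranges [0.5, 2], [0.5, 1.5] and [0.7, 1.3]
  (overlapping, counted independently) plus the strict tails < 0.5 and
  > 2, and
* the average fold error AFE = 10^(mean log10 ratio), the geometric mean
  of the ratios; 1.0 means no systematic bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .errors import EvaluationError, ValidationError
from .profiles_io import ConcProfile
from .scaling_methods import PredictedProfile

log = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "BIN_KEYS",
    "match_timepoints",
    "fold_ratios",
    "afe",
    "bin_fold_errors",
    "evaluate",
]

BIN_KEYS = ("lt_0.5", "gt_2", "within_0.5_2", "within_0.5_1.5", "within_0.7_1.3")


@dataclass(frozen=True)
class EvaluationReport:
    """Per-timepoint ratios plus their fold-error summary."""

    ratios: tuple  # ((time, predicted/observed), ...)
    n: int
    afe: float
    bin_counts: dict

    def ratio_values(self) -> list:
        return [r for _, r in self.ratios]


def _as_profile(p: Union[ConcProfile, PredictedProfile]) -> ConcProfile:
    return p.base if isinstance(p, PredictedProfile) else p


def match_timepoints(
    predicted: Union[ConcProfile, PredictedProfile],
    observed: ConcProfile,
    policy: str = "exact",
    tol: float = 0.05,
) -> list:
    """Pair predicted and observed points -> [(time, pred, obs), ...].

    ``"exact"`` pairs each predicted point with the nearest unused
    observed point within ``tol`` days (default 0.05); unmatched points
    are dropped with a logged count.  ``"interpolate"`` evaluates the
    observed curve log-linearly at each predicted time inside the
    observed time span; no extrapolation is performed.
    """
    pred = _as_profile(predicted)
    obs = observed
    pairs: list = []
    if policy == "exact":
        used = [False] * obs.n
        for t, c in pred.points:
            best_j, best_dt = -1, tol
            for j, (to, _co) in enumerate(obs.points):
                dt = abs(to - t)
                if not used[j] and dt <= best_dt:
                    best_j, best_dt = j, dt
            if best_j >= 0:
                used[best_j] = True
                pairs.append((t, c, obs.concentrations[best_j]))
        dropped = pred.n - len(pairs)
        if dropped:
            log.info("dropped %d predicted point(s) with no observed match", dropped)
    elif policy == "interpolate":
        t_obs = np.asarray(obs.times, dtype=float)
        lnc_obs = np.log(np.asarray(obs.concentrations, dtype=float))
        for t, c in pred.points:
            if t_obs[0] <= t <= t_obs[-1]:
                pairs.append((t, c, float(math.exp(np.interp(t, t_obs, lnc_obs)))))
        dropped = pred.n - len(pairs)
        if dropped:
            log.info("dropped %d predicted point(s) outside the observed span", dropped)
    else:
        raise ValidationError(f"unknown matching policy {policy!r}")
    if not pairs:
        raise EvaluationError("no overlapping time points between profiles")
    return pairs


def fold_ratios(pairs: Iterable) -> list:
    """Elementwise predicted/observed for (time, pred, obs) triples."""
    out = []
    for _t, pred, obs in pairs:
        if not (pred > 0 and obs > 0):
            raise ValidationError(f"concentrations must be > 0, got ({pred}, {obs})")
        out.append(pred / obs)
    return out


def afe(ratios: Sequence[float]) -> float:
    """Average fold error: 10^(mean log10 ratio) = geometric mean."""
    if len(ratios) == 0:
        raise ValidationError("AFE of an empty ratio set is undefined")
    logs = np.log10(np.asarray(ratios, dtype=float))
    return float(10.0 ** logs.mean())


def bin_fold_errors(ratios: Sequence[float]) -> dict:
    """Count ratios per fold-error range.

    The three inner ranges are closed and overlapping (each counted
    independently); the tails < 0.5 and > 2 are strict, so the tails and
    [0.5, 2] partition the ratios.
    """
    if len(ratios) == 0:
        raise ValidationError("cannot bin an empty ratio set")
    r = np.asarray(ratios, dtype=float)
    return {
        "lt_0.5": int((r < 0.5).sum()),
        "gt_2": int((r > 2.0).sum()),
        "within_0.5_2": int(((r >= 0.5) & (r <= 2.0)).sum()),
        "within_0.5_1.5": int(((r >= 0.5) & (r <= 1.5)).sum()),
        "within_0.7_1.3": int(((r >= 0.7) & (r <= 1.3)).sum()),
    }


def evaluate(
    predicted: Union[ConcProfile, PredictedProfile],
    observed: ConcProfile,
    policy: str = "exact",
    tol: float = 0.05,
) -> EvaluationReport:
    """Match, ratio and summarise one predicted-vs-observed comparison."""
    pairs = match_timepoints(predicted, observed, policy=policy, tol=tol)
    ratios = fold_ratios(pairs)
    return EvaluationReport(
        ratios=tuple((t, pred / obs) for t, pred, obs in pairs),
        n=len(ratios),
        afe=afe(ratios),
        bin_counts=bin_fold_errors(ratios),
    )
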