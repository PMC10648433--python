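"""Survey-weighted estimation: weighted means and quantiles, balanced repeated
replication (BRR) variance with a Fay coefficient, and the non-overlapping-CI
significance rule used throughout the reporting stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SurveyDesign",
    "IntervalEstimate",
    "weighted_mean",
    "weighted_quantile",
    "brr_standard_error",
    "nonoverlap_significant",
]

Z95 = 1.959963984540054  # normal-theory 95% multiplier


@dataclass
class SurveyDesign:
    """Base weights plus R replicate weight vectors and the Fay coefficient.

    ``replicate_weights`` has shape (n_persons, R).  Fay's method perturbs
    half-samples by factors (2 - F) and F; the BRR variance formula divides
    by R(1-F)^2 accordingly.
    """

    person_ids: np.ndarray
    base_weights: np.ndarray
    replicate_weights: np.ndarray
    fay: float = 0.3

    def __post_init__(self) -> None:
        self.person_ids = np.asarray(self.person_ids)
        self.base_weights = np.asarray(self.base_weights, dtype=float)
        self.replicate_weights = np.asarray(self.replicate_weights, dtype=float)
        if np.any(self.base_weights <= 0):
            raise ValueError("base weights must be > 0")
        if self.replicate_weights.ndim != 2 or self.replicate_weights.shape[1] < 2:
            raise ValueError("need at least 2 replicate weight vectors")
        if self.replicate_weights.shape[0] != self.base_weights.shape[0]:
            raise ValueError("replicate weights misaligned with base weights")
        if not (0 <= self.fay < 1):
            raise ValueError("Fay coefficient must lie in [0, 1)")

    @property
    def n_replicates(self) -> int:
        return self.replicate_weights.shape[1]

    def subset(self, person_ids: Sequence) -> "SurveyDesign":
        """Design restricted to (and ordered by) ``person_ids``."""
        index = {pid: i for i, pid in enumerate(self.person_ids)}
        missing = [p for p in person_ids if p not in index]
        if missing:
            raise KeyError(f"person_ids not in design: {missing[:5]}")
        idx = np.array([index[p] for p in person_ids])
        return SurveyDesign(
            person_ids=self.person_ids[idx],
            base_weights=self.base_weights[idx],
            replicate_weights=self.replicate_weights[idx],
            fay=self.fay,
        )


@dataclass
class IntervalEstimate:
    point: float
    se: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper):
            raise ValueError("interval must bracket the point estimate")


def weighted_mean(values, weights) -> float:
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be >= 0")
    total = np.sum(weights)
    if total <= 0:
        raise ValueError("weights must have positive sum")
    # zeros are allowed: BRR replicates with Fay coefficient 0 null out
    # the deselected half-sample entirely
    return float(np.sum(weights * values) / total)


def weighted_quantile(values, weights, q) -> np.ndarray:
    """Weighted quantiles by inverse-CDF interpolation on cumulative weight.

    Uses midpoint plotting positions (cumw - w/2) / sumw so that equal
    weights reproduce ordinary order-statistic interpolation.
    """
    values = np.asarray(values, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    pos = (cw - 0.5 * w) / cw[-1]
    return np.interp(np.atleast_1d(q), pos, v)


def brr_standard_error(
    estimator: Callable[[np.ndarray], float],
    design: SurveyDesign,
) -> IntervalEstimate:
    """Point estimate under base weights; variance by Fay-adjusted BRR.

    Var = 1 / (R (1-F)^2) * sum_r (theta_r - theta)^2, CI = theta +/- 1.96 SE.
    The estimator is any callable of a weight vector; failures on a replicate
    are re-raised with the replicate index attached.
    """
    theta = float(estimator(design.base_weights))
    R, F = design.n_replicates, design.fay
    reps = np.empty(R)
    for r in range(R):
        try:
            reps[r] = float(estimator(design.replicate_weights[:, r]))
        except Exception as exc:  # noqa: BLE001 - contract: annotate replicate
            raise RuntimeError(f"estimator failed on replicate {r}") from exc
    var = float(np.sum((reps - theta) ** 2) / (R * (1.0 - F) ** 2))
    se = float(np.sqrt(var))
    return IntervalEstimate(point=theta, se=se, lower=theta - Z95 * se, upper=theta + Z95 * se)


def nonoverlap_significant(a: IntervalEstimate, b: IntervalEstimate) -> bool:
    """True iff the two 95% CIs do not overlap (strict: a shared endpoint overlaps)."""
    return bool(a.upper < b.lower or b.upper < a.lower)
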