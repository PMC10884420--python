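"""Propensity-score updating of censored competing-risks observations.

This is the package's core procedure. For a competing cause k:

1. Obtain the signs of the cause-specific Cox coefficients (Bayesian
   posterior mean or the maximum partial-likelihood estimate).
2. Build the minimum-hazard reference point X_min over all n subjects:
   coordinate l takes the column minimum when beta_l > 0 and the column
   maximum when beta_l <= 0, so every covariate direction that raises the
   hazard points away from X_min.
3. Score each censored subject r by the weighted squared Euclidean
   distance Delta_r = sum_v w_v (x_v,min - x_v,r)^2, with w_v = 1/s_v^2
   (standardised; s_v the covariate SD over all subjects) or w_v = 1.
4. Flip the status of subject r from censored to cause k iff the empirical
   CDF of Delta_r among censored subjects strictly exceeds the threshold
   probability p (default 0.9) — i.e. the top (1 - p) fraction of censored
   subjects farthest from the low-risk corner are declared dead of cause k.
   The observed time is kept; only the status changes.

The joint variant runs both causes on the original censored set and
resolves double flags by the larger empirical-CDF rank (ties to cause 1),
yielding the transition counts tau_01 and tau_02.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import coefficient_signs
from .datasets import CompetingRisksDataset

__all__ = [
    "ReferencePoint",
    "PropensityUpdate",
    "reference_point",
    "propensity_scores",
    "update_indicators",
    "psm_update_cause",
    "psm_update_joint",
]


@dataclass(frozen=True)
class ReferencePoint:
    """The minimum-hazard corner X_min and the weights used for scoring."""

    x_min: np.ndarray
    signs: np.ndarray
    weights: np.ndarray
    scale_sds: np.ndarray | None


@dataclass(frozen=True)
class PropensityUpdate:
    """Diagnostics of one censored-status update pass for cause k."""

    cause: int
    censored_ids: np.ndarray
    deltas: np.ndarray
    ecdf_ranks: np.ndarray
    threshold_p: float
    delta_quantile: float
    indicators: np.ndarray
    n_updated: int

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.censored_ids,
                "delta": self.deltas,
                "ecdf": self.ecdf_ranks,
                "updated": self.indicators,
            }
        )


def reference_point(X, signs, standardize: bool = True) -> ReferencePoint:
    """Reference point over ALL subjects: column min where the coefficient
    is positive, column max where it is non-positive."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("X must be a non-empty n x m matrix")
    signs = np.asarray(signs, dtype=int)
    if signs.shape != (X.shape[1],):
        raise ValueError("signs must have one entry per covariate column")
    x_min = np.where(signs > 0, X.min(axis=0), X.max(axis=0))
    if standardize:
        sds = X.std(axis=0, ddof=1)
        if np.any(sds == 0):
            raise ValueError("cannot standardise a constant covariate column")
        weights = 1.0 / sds**2
    else:
        sds = None
        weights = np.ones(X.shape[1])
    return ReferencePoint(x_min=x_min, signs=signs, weights=weights, scale_sds=sds)


def propensity_scores(X_censored, ref: ReferencePoint) -> np.ndarray:
    """Weighted squared Euclidean distance of each censored row from X_min.

    The square root is deliberately omitted: only the ranks of the scores
    enter the threshold rule, so the squared form is used verbatim.
    """
    X_censored = np.atleast_2d(np.asarray(X_censored, dtype=float))
    if X_censored.shape[1] != ref.x_min.shape[0]:
        raise ValueError("censored covariates and reference point disagree in dimension")
    diff = ref.x_min[None, :] - X_censored
    return (ref.weights[None, :] * diff**2).sum(axis=1)


def update_indicators(deltas, p: float):
    """Threshold rule: flip subject r iff the empirical CDF of its score
    strictly exceeds p.

    Returns ``(indicators, ecdf_ranks, delta_quantile)`` where the ranks are
    F_hat(Delta_r) = #{Delta_s <= Delta_r} / n over the censored subjects
    and ``delta_quantile`` is the p-th empirical (inverted-CDF) quantile.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("no censored subjects to score")
    if not 0.0 <= p <= 1.0:
        raise ValueError("threshold probability p must lie in [0, 1]")
    order = np.sort(deltas)
    ranks = np.searchsorted(order, deltas, side="right") / deltas.size
    indicators = (ranks > p).astype(int)
    quantile = float(np.quantile(deltas, p, method="inverted_cdf"))
    return indicators, ranks, quantile


def _score_censored(dataset: CompetingRisksDataset, cause: int, p, signs_method, seed, standardize):
    signs = coefficient_signs(dataset, cause, method=signs_method, seed=seed)
    ref = reference_point(dataset.X, signs, standardize=standardize)
    censored = np.flatnonzero(dataset.statuses == 0)
    deltas = propensity_scores(dataset.X[censored], ref)
    indicators, ranks, quantile = update_indicators(deltas, p)
    update = PropensityUpdate(
        cause=cause,
        censored_ids=dataset.ids[censored],
        deltas=deltas,
        ecdf_ranks=ranks,
        threshold_p=p,
        delta_quantile=quantile,
        indicators=indicators,
        n_updated=int(indicators.sum()),
    )
    return censored, update


def _empty_update(cause: int, p: float) -> PropensityUpdate:
    return PropensityUpdate(
        cause=cause,
        censored_ids=np.array([], dtype=str),
        deltas=np.array([]),
        ecdf_ranks=np.array([]),
        threshold_p=p,
        delta_quantile=np.nan,
        indicators=np.array([], dtype=int),
        n_updated=0,
    )


def psm_update_cause(
    dataset: CompetingRisksDataset,
    cause: int,
    p: float = 0.9,
    signs_method: str = "mple",
    seed: int | None = None,
    standardize: bool = True,
) -> tuple[CompetingRisksDataset, PropensityUpdate]:
    """Flip high-score censored subjects to cause ``k``; times unchanged."""
    if not np.any(dataset.statuses == 0):
        warnings.warn("dataset has no censored subjects; nothing to update", stacklevel=2)
        return dataset, _empty_update(cause, p)
    censored, update = _score_censored(dataset, cause, p, signs_method, seed, standardize)
    statuses = dataset.statuses.copy()
    statuses[censored[update.indicators == 1]] = cause
    return dataset.with_statuses(statuses), update


def psm_update_joint(
    dataset: CompetingRisksDataset,
    p: float = 0.9,
    signs_method: str = "mple",
    seed: int | None = None,
    standardize: bool = True,
) -> tuple[CompetingRisksDataset, dict[int, PropensityUpdate]]:
    """Run both cause-specific updates on the original censored set.

    A subject flagged by both causes goes to the cause with the larger
    empirical-CDF rank; exact ties go to cause 1. Returns the jointly
    updated dataset plus per-cause diagnostics whose ``n_updated`` fields
    are the realised transition counts tau_01 and tau_02.
    """
    if not np.any(dataset.statuses == 0):
        warnings.warn("dataset has no censored subjects; nothing to update", stacklevel=2)
        return dataset, {1: _empty_update(1, p), 2: _empty_update(2, p)}
    censored, upd1 = _score_censored(dataset, 1, p, signs_method, seed, standardize)
    _, upd2 = _score_censored(dataset, 2, p, signs_method, seed, standardize)
    flag1 = upd1.indicators.astype(bool)
    flag2 = upd2.indicators.astype(bool)
    to_cause1 = flag1 & (~flag2 | (upd1.ecdf_ranks >= upd2.ecdf_ranks))
    to_cause2 = flag2 & ~to_cause1
    statuses = dataset.statuses.copy()
    statuses[censored[to_cause1]] = 1
    statuses[censored[to_cause2]] = 2
    from dataclasses import replace

    upd1 = replace(upd1, indicators=to_cause1.astype(int), n_updated=int(to_cause1.sum()))
    upd2 = replace(upd2, indicators=to_cause2.astype(int), n_updated=int(to_cause2.sum()))
    return dataset.with_statuses(statuses), {1: upd1, 2: upd2}
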