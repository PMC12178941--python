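"""Regional radiomics similarity network (R2SN) construction.

A subject's R2SN is the region-by-region matrix of Pearson correlations
between regional radiomic feature profiles, computed after per-subject
min-max normalization and cohort-level correlation-based feature
selection (default: retain 25 features, redundancy cap |r| <= 0.90).
"""

from __future__ import annotations

import numpy as np

from .types import FeatureMatrix, R2SN

__all__ = [
    "ConstantFeatureError",
    "DegenerateRegionError",
    "minmax_normalize",
    "select_features",
    "build_r2sn",
]

DEFAULT_TARGET_COUNT = 25
DEFAULT_R_CAP = 0.90


class ConstantFeatureError(ValueError):
    """A feature column has zero range within a subject."""


class DegenerateRegionError(ValueError):
    """A region's selected-feature profile has zero variance."""


def minmax_normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Rescale each feature column to [0, 1] across this subject's regions.

    Raises :class:`ConstantFeatureError` naming the first constant feature;
    the caller may drop such features and retry.
    """
    lo = fm.values.min(axis=0)
    hi = fm.values.max(axis=0)
    rng = hi - lo
    bad = np.flatnonzero(rng == 0)
    if bad.size:
        names = [fm.feature_names[i] for i in bad]
        raise ConstantFeatureError(
            f"constant feature(s) in subject {fm.subject_id!r}: {names}"
        )
    return FeatureMatrix(
        values=(fm.values - lo) / rng,
        region_ids=fm.region_ids,
        feature_names=fm.feature_names,
        subject_id=fm.subject_id,
    )


def _cohort_mean_abs_corr(cohort: list[FeatureMatrix]) -> np.ndarray:
    """Mean over subjects of |Pearson r| between feature columns (across
    regions).  NaN correlations (constant columns) are treated as 0."""
    f = len(cohort[0].feature_names)
    acc = np.zeros((f, f))
    for fm in cohort:
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(fm.values, rowvar=False)
        c = np.nan_to_num(np.abs(np.atleast_2d(c)), nan=0.0)
        acc += c
    acc /= len(cohort)
    np.fill_diagonal(acc, 0.0)
    return acc


def select_features(cohort: list[FeatureMatrix], target_count: int = DEFAULT_TARGET_COUNT,
                    r_cap: float = DEFAULT_R_CAP) -> list[int]:
    """Greedy redundancy elimination on cohort-mean absolute correlations.

    While any surviving pair correlates above ``r_cap`` or more than
    ``target_count`` features remain, drop the feature with the highest
    mean absolute correlation to the other survivors.  Ties are broken by
    original feature index (the lower index is kept).  Returns surviving
    column indices in original order.
    """
    if target_count < 2:
        raise ValueError("target_count must be at least 2")
    if not cohort:
        raise ValueError("feature selection needs a nonempty cohort")
    f = len(cohort[0].feature_names)
    if target_count > f:
        raise ValueError(f"target_count {target_count} exceeds feature count {f}")

    corr = _cohort_mean_abs_corr(cohort)
    alive = np.ones(f, dtype=bool)
    while True:
        idx = np.flatnonzero(alive)
        if idx.size <= target_count:
            sub = corr[np.ix_(idx, idx)]
            if idx.size <= 2 or sub.max() <= r_cap:
                break
        sub = corr[np.ix_(idx, idx)]
        mean_to_rest = sub.sum(axis=1) / (idx.size - 1)
        # argmax returns the first (lowest-index) maximum; we must drop the
        # highest-indexed among tied maxima so the lower index survives
        worst = mean_to_rest.max()
        drop_local = np.flatnonzero(mean_to_rest == worst)[-1]
        alive[idx[drop_local]] = False
    return np.flatnonzero(alive).tolist()


def build_r2sn(fm: FeatureMatrix, selected: list[int] | None = None) -> R2SN:
    """Pairwise Pearson correlation of regional selected-feature profiles.

    The diagonal is set to 1 exactly.  A region whose profile has zero
    variance makes Pearson undefined and raises
    :class:`DegenerateRegionError` naming the region.
    """
    vals = fm.values if selected is None else fm.values[:, selected]
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 selected features to correlate profiles")
    sd = vals.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        regs = fm.region_ids[bad].tolist()
        raise DegenerateRegionError(
            f"zero-variance regional profile(s) in subject {fm.subject_id!r}: "
            f"regions {regs}"
        )
    w = np.corrcoef(vals)
    w = np.clip((w + w.T) / 2, -1.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return R2SN(weights=w, region_ids=fm.region_ids, subject_id=fm.subject_id)
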