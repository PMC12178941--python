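"""Principal Motif Value (PMV): the first principal component of the
triangle-motif census.

Each subject's 20 x N motif-count matrix is standardized per motif type
(mean 0, variance 1 across regions, population-SD convention).  The
cohort model pools the standardized region columns of all subjects as
observations of a 20-dimensional motif variable, eigendecomposes the
20 x 20 covariance (divisor n-1), and keeps the leading eigenvector as
the loading.  A region's PMV is the projection of its standardized
20-type profile onto that loading.

The eigenvector's sign is fixed so that the loading of the homogeneous
weak-short triangle type is nonnegative: a more positive PMV then marks
regions dominated by weaker, shorter connections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .motifs import MotifTypeCatalog, build_catalog
from .types import MotifCountMatrix, PMVMap, PMVModel, N_MOTIF_TYPES

__all__ = [
    "standardize_counts",
    "fit_pmv_model",
    "project_pmv",
    "motif_contributions",
    "per_subject_variance_explained",
    "literal_region_pca",
]


def standardize_counts(mcm: MotifCountMatrix) -> np.ndarray:
    """Standardize each motif-type row to mean 0, variance 1 across the
    regions (population SD, divisor N).  A zero-variance row maps to all
    zeros rather than NaN."""
    x = mcm.counts.astype(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.zeros_like(x)
    ok = sd[:, 0] > 0
    z[ok] = (x[ok] - mu[ok]) / sd[ok]
    return z


def fit_pmv_model(cohort_counts: list[MotifCountMatrix],
                  catalog: MotifTypeCatalog | None = None) -> PMVModel:
    """Fit the cohort-common loading vector.

    Standardized matrices are stacked along the region axis, so the
    pooled observations are region columns (one 20-vector per region per
    subject); the 20 x 20 covariance uses the n-1 divisor.  The loading
    is the eigenvector of the largest eigenvalue, sign-anchored on the
    all weak-short motif type.
    """
    if catalog is None:
        catalog = build_catalog()
    if not cohort_counts:
        raise ValueError("cannot fit a PMV model on an empty cohort")
    z = np.hstack([standardize_counts(m) for m in cohort_counts])  # 20 x (N*S)
    if z.shape[1] < 2:
        raise ValueError("need at least 2 pooled region observations")
    cov = np.cov(z, rowvar=True, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    loading = evecs[:, 0]
    anchor = catalog.all_weak_short_index
    if loading[anchor] < 0 or (loading[anchor] == 0 and loading[np.argmax(np.abs(loading))] < 0):
        loading = -loading
    total = evals.sum()
    ve1 = float(evals[0] / total) if total > 0 else 0.0
    return PMVModel(
        loading=loading,
        eigenvalues=evals,
        variance_explained_1=ve1,
        sign_anchor=anchor,
        catalog_labels=catalog.labels,
    )


def project_pmv(mcm: MotifCountMatrix, model: PMVModel) -> PMVMap:
    """PMV[j] = sum_t standardized(counts)[t, j] * loading[t].

    The subject's own matrix is standardized before projection, keeping
    subjects exchangeable regardless of raw count scale.
    """
    if mcm.counts.shape[0] != model.loading.size:
        raise ValueError(
            f"motif-type count {mcm.counts.shape[0]} does not match model "
            f"loading length {model.loading.size}"
        )
    z = standardize_counts(mcm)
    return PMVMap(values=model.loading @ z, region_ids=mcm.region_ids,
                  subject_id=mcm.subject_id)


def motif_contributions(model: PMVModel) -> pd.DataFrame:
    """Squared loadings per motif type, sorted descending; sums to 1."""
    labels = model.catalog_labels or [f"type{i+1}" for i in range(N_MOTIF_TYPES)]
    df = pd.DataFrame({
        "type_index": np.arange(1, N_MOTIF_TYPES + 1),
        "type_label": labels,
        "loading": model.loading,
        "contribution": model.contributions,
    })
    return df.sort_values("contribution", ascending=False, kind="stable",
                          ignore_index=True)


def per_subject_variance_explained(cohort_counts: list[MotifCountMatrix]) -> np.ndarray:
    """Leading-eigenvalue variance share of each subject's own 20 x 20
    motif covariance (per-subject PCA fits, no pooling)."""
    out = np.empty(len(cohort_counts))
    for i, m in enumerate(cohort_counts):
        z = standardize_counts(m)
        evals = np.linalg.eigvalsh(np.cov(z, rowvar=True, ddof=1))
        total = evals.sum()
        out[i] = evals[-1] / total if total > 0 else 0.0
    return out


def literal_region_pca(mcm: MotifCountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Region-as-variable PCA variant (per-region standardization, N x N
    covariance over the 20 motif observations).

    Provided for comparison only: its projection lives in motif space
    (one value per motif type, not per region) and is not used by the
    pipeline.  Returns (descending eigenvalues, 20-vector projection on
    the leading eigenvector).
    """
    x = mcm.counts.astype(float)
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    z = np.zeros_like(x)
    ok = sd[0] > 0
    z[:, ok] = (x[:, ok] - mu[:, ok]) / sd[:, ok]
    cov = np.cov(z, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    v1 = evecs[:, -1]
    if v1[np.argmax(np.abs(v1))] < 0:
        v1 = -v1
    return evals[::-1], z @ v1
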