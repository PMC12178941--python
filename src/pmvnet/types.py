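"""Core domain containers shared across the pipeline.

The objects here are thin, validated wrappers around numpy arrays and
pandas-friendly metadata: an atlas (region geometry + partition labels),
per-subject feature matrices, the derived region-by-region similarity
network (R2SN), the 20-type triangle-motif census, and the fitted
Principal Motif Value (PMV) model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtlasGeometry",
    "SubjectRecord",
    "EffectSpec",
    "FeatureMatrix",
    "R2SN",
    "ThresholdPair",
    "MotifCountMatrix",
    "PMVModel",
    "PMVMap",
    "SpatialMapSet",
    "ZMap",
]

N_MOTIF_TYPES = 20


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class AtlasGeometry:
    """Region identities, 3-D centroids (mm) and partition labels.

    Fixed across subjects; every other container is ordered to match
    ``region_ids``.
    """

    region_ids: np.ndarray          # (N,) int, unique
    centroids: np.ndarray           # (N, 3) float, mm
    anatomical_label: np.ndarray    # (N,) str  (lobes / "subcortex")
    functional_label: np.ndarray    # (N,) str  (7-network partition / "none")

    def __post_init__(self) -> None:
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        self.centroids = _as_float_array(self.centroids, "centroids")
        self.anatomical_label = np.asarray(self.anatomical_label, dtype=object)
        self.functional_label = np.asarray(self.functional_label, dtype=object)
        n = self.region_ids.size
        if n < 3:
            raise ValueError("an atlas needs at least 3 regions")
        if np.unique(self.region_ids).size != n:
            raise ValueError("region_ids must be unique")
        if self.centroids.shape != (n, 3):
            raise ValueError("centroids must have shape (n_regions, 3)")
        for lab in (self.anatomical_label, self.functional_label):
            if lab.shape != (n,):
                raise ValueError("labels must have one entry per region")

    @property
    def n_regions(self) -> int:
        return self.region_ids.size


@dataclass
class SubjectRecord:
    """One subject: diagnostic group, acquisition site and clinical scores.

    ``clinical`` holds named real-valued scores; missing values are NaN.
    ``effect_dose`` is synthetic-cohort ground truth (0 for unaffected
    subjects) and is never read by the statistical modules.
    """

    subject_id: str
    group: str
    site_id: str = "site0"
    clinical: dict[str, float] = field(default_factory=dict)
    effect_dose: float = 0.0


@dataclass
class EffectSpec:
    """A planted regional perturbation for synthetic cohorts.

    ``strength-shift`` adds a shared profile component to the target
    regions (shifting their R2SN edge weights); ``profile-decorrelation``
    mixes subject-specific noise into the target regions' profiles
    (weakening their correlations with everything else).
    """

    target_regions: np.ndarray
    effect_size: float
    effect_mode: str = "strength-shift"
    groups_affected: tuple[str, ...] = ("AD",)

    _MODES = ("strength-shift", "profile-decorrelation")

    def __post_init__(self) -> None:
        self.target_regions = np.asarray(self.target_regions, dtype=int)
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.effect_mode not in self._MODES:
            raise ValueError(
                f"effect_mode must be one of {self._MODES}, got {self.effect_mode!r}"
            )
        self.groups_affected = tuple(self.groups_affected)

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls(target_regions=np.array([], dtype=int), effect_size=0.0)

    def validate_against(self, atlas: AtlasGeometry) -> None:
        missing = np.setdiff1d(self.target_regions, atlas.region_ids)
        if missing.size:
            raise ValueError(
                f"effect target regions not in atlas: {missing.tolist()}"
            )


@dataclass
class FeatureMatrix:
    """One subject's regions-by-features radiomic profile."""

    values: np.ndarray              # (N, F) float
    region_ids: np.ndarray          # (N,)
    feature_names: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "feature values")
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        self.feature_names = list(self.feature_names)
        n, f = self.values.shape
        if self.region_ids.size != n:
            raise ValueError("region_ids length must match rows of values")
        if len(self.feature_names) != f:
            raise ValueError("feature_names length must match columns of values")


@dataclass
class R2SN:
    """Regional radiomics similarity network: symmetric Pearson matrix,
    unit diagonal, off-diagonal in [-1, 1]."""

    weights: np.ndarray             # (N, N) float
    region_ids: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.weights = _as_float_array(self.weights, "R2SN weights")
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        n = self.region_ids.size
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square and match region_ids")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ValueError("R2SN weights must be symmetric")
        if not np.allclose(np.diag(self.weights), 1.0, atol=1e-10):
            raise ValueError("R2SN diagonal must be 1")

    @property
    def n_regions(self) -> int:
        return self.region_ids.size


@dataclass
class ThresholdPair:
    """Cohort-level binarization thresholds for edge strength (R2SN
    weight) and edge length (inter-centroid Euclidean distance, mm)."""

    strength_median: float
    length_median: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.strength_median) and np.isfinite(self.length_median)):
            raise ValueError("thresholds must be finite")


@dataclass
class MotifCountMatrix:
    """20 x N nonnegative integer triangle-motif census for one subject.

    Every region participates in C(N-1, 2) triangles, so each column sums
    to that constant and the grand total is 3 * C(N, 3).
    """

    counts: np.ndarray              # (20, N) int
    region_ids: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.counts.shape != (N_MOTIF_TYPES, self.region_ids.size):
            raise ValueError("counts must be 20 x n_regions")
        if (self.counts < 0).any():
            raise ValueError("motif counts must be nonnegative")

    @property
    def n_regions(self) -> int:
        return self.region_ids.size


@dataclass
class PMVModel:
    """Cohort-level first-principal-component model over the 20 motif types.

    ``loading`` is the unit-norm eigenvector of the pooled 20x20 motif
    covariance with the largest eigenvalue, sign-fixed so the loading of
    the ``sign_anchor`` motif type (the all weak-short triangle) is >= 0.
    ``contributions`` are squared loadings (the share of the component
    each motif type carries).
    """

    loading: np.ndarray             # (20,) unit norm
    eigenvalues: np.ndarray         # (20,) descending
    variance_explained_1: float
    sign_anchor: int                # catalog index (0-based) anchoring the sign
    catalog_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loading = _as_float_array(self.loading, "loading")
        self.eigenvalues = _as_float_array(self.eigenvalues, "eigenvalues")
        if self.loading.shape != (N_MOTIF_TYPES,):
            raise ValueError("loading must have 20 entries")
        if abs(np.linalg.norm(self.loading) - 1.0) > 1e-8:
            raise ValueError("loading must be unit norm")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be in descending order")
        if self.loading[self.sign_anchor] < 0:
            raise ValueError("loading must be nonnegative at the sign anchor")

    @property
    def contributions(self) -> np.ndarray:
        return self.loading ** 2


@dataclass
class PMVMap:
    """Per-region Principal Motif Value for one subject."""

    values: np.ndarray              # (N,)
    region_ids: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "PMV values")
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.values.shape != (self.region_ids.size,):
            raise ValueError("PMV values must have one entry per region")


@dataclass
class SpatialMapSet:
    """Named per-region spatial maps (gene expression, receptor density)."""

    names: list[str]
    matrix: np.ndarray              # (N, n_maps)
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = _as_float_array(self.matrix, "spatial maps")
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        self.names = list(self.names)
        if self.matrix.shape != (self.region_ids.size, len(self.names)):
            raise ValueError("matrix must be n_regions x n_maps")


@dataclass
class ZMap:
    """Per-region standardized Mann-Whitney Z values for one group contrast."""

    values: np.ndarray              # (N,)
    region_ids: np.ndarray
    group_a: str = ""
    group_b: str = ""
    n_a: int = 0
    n_b: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.values.shape != (self.region_ids.size,):
            raise ValueError("Z values must have one entry per region")

    @property
    def site_n(self) -> int:
        return self.n_a + self.n_b
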