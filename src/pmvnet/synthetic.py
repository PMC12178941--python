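"""Seeded synthetic cohorts with known planted structure.

Every downstream stage (R2SN construction, motif census, PMV, group
statistics, spatial association) is testable without any imaging data:
this module generates a brain-like atlas (ellipsoidal centroid cloud
with an inner subcortical shell, lobe-like anatomical sectors and a
7-network cortical partition), group-structured regional feature
profiles whose correlation networks carry planted regional effects,
clinical scores tied to the planted effect dose, and spatial maps with
controllable correlation to a target map.

Regional profiles are built from a small set of latent spatial gradients
(smooth functions of centroid position) mixed into features, plus
region-specific offsets — this gives the resulting R2SN matrices the
block structure real morphometric similarity networks show, and hence
non-degenerate motif distributions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .types import AtlasGeometry, EffectSpec, FeatureMatrix, SpatialMapSet, SubjectRecord

__all__ = [
    "generate_atlas",
    "generate_cohort",
    "generate_clinical_scores",
    "generate_spatial_maps",
    "YEO7_NETWORKS",
    "DEFAULT_NOISE_SD",
    "DEFAULT_EFFECT_SIZE",
]

YEO7_NETWORKS = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")
LOBES = ("frontal", "parietal", "temporal", "occipital", "limbic")

# Ellipsoid semi-axes (mm) approximating an adult MNI-space brain.
_SEMI_AXES = np.array([65.0, 85.0, 60.0])
# Innermost shell (by quantile of normalized radius) labeled subcortex.
_SUBCORTEX_FRACTION = 0.15
# Shell between subcortex and the outer cortex labeled "limbic" (transitional).
_LIMBIC_FRACTION = 0.30

# Study-condition defaults: subject noise relative to unit-variance
# archetype profiles, and the planted regional effect magnitude used for
# recovery experiments (calibrated once; see docs/methods.md).
DEFAULT_NOISE_SD = 0.30
DEFAULT_EFFECT_SIZE = 3.0
_N_GRADIENTS = 5


def generate_atlas(n_regions: int, seed: int) -> AtlasGeometry:
    """Sample a brain-like atlas: centroids uniform in an ellipsoid, the
    innermost 15% of regions labeled subcortex, cortical regions split
    into lobe-like anatomical sectors and 7 functional networks by
    deterministic spatial rules."""
    if n_regions < 3:
        raise ValueError("n_regions must be at least 3")
    rng = np.random.default_rng(seed)
    # uniform in the unit ball, then scaled to the ellipsoid
    direc = rng.normal(size=(n_regions, 3))
    direc /= np.linalg.norm(direc, axis=1, keepdims=True)
    radius = rng.uniform(size=n_regions) ** (1 / 3)
    unit = direc * radius[:, None]
    centroids = unit * _SEMI_AXES

    r_rank = np.argsort(np.argsort(radius)) / max(n_regions - 1, 1)
    anatomical = np.empty(n_regions, dtype=object)
    functional = np.empty(n_regions, dtype=object)
    azimuth = np.arctan2(unit[:, 1], unit[:, 0])  # [-pi, pi)
    sector = ((azimuth + np.pi) / (2 * np.pi) * len(YEO7_NETWORKS)).astype(int)
    sector = np.clip(sector, 0, len(YEO7_NETWORKS) - 1)
    for i in range(n_regions):
        x, y, z = unit[i]
        if r_rank[i] <= _SUBCORTEX_FRACTION:
            anatomical[i] = "subcortex"
            functional[i] = "none"
            continue
        if r_rank[i] <= _LIMBIC_FRACTION:
            anatomical[i] = "limbic"
        elif y > 0.25:
            anatomical[i] = "frontal"
        elif y < -0.45:
            anatomical[i] = "occipital"
        elif z < -0.2:
            anatomical[i] = "temporal"
        else:
            anatomical[i] = "parietal"
        functional[i] = YEO7_NETWORKS[sector[i]]
    return AtlasGeometry(
        region_ids=np.arange(1, n_regions + 1),
        centroids=centroids,
        anatomical_label=anatomical,
        functional_label=functional,
    )


def _spatial_gradients(atlas: AtlasGeometry) -> np.ndarray:
    """(N, K) smooth latent gradients from centroid geometry, z-scored."""
    c = atlas.centroids / _SEMI_AXES
    r = np.linalg.norm(c, axis=1)
    g = np.column_stack([c[:, 0], c[:, 1], c[:, 2], r, c[:, 0] * c[:, 1]])
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return g / sd


def generate_cohort(atlas: AtlasGeometry, group_sizes: dict[str, int],
                    n_features: int = 47, effect: EffectSpec | None = None,
                    noise_sd: float = DEFAULT_NOISE_SD, seed: int = 0,
                    n_sites: int = 1) -> tuple[list[SubjectRecord], list[FeatureMatrix]]:
    """Generate subject records and regional feature matrices.

    Each subject's matrix is a shared regional archetype (latent spatial
    gradients mixed into features, plus per-feature scale/offset) plus
    the planted group effect plus i.i.d. Gaussian subject noise.  For
    affected subjects the per-subject effect dose is
    ``effect_size * severity`` with severity ~ U(0.5, 1.5); the dose is
    recorded on the SubjectRecord as synthetic ground truth.

    ``strength-shift`` adds a fixed feature-space direction (scaled by the
    dose) to the target regions' rows, shifting their R2SN edge weights;
    ``profile-decorrelation`` adds dose-scaled subject-specific noise to
    the target rows only, eroding their correlations.
    """
    if n_features < 2:
        raise ValueError("n_features must be at least 2")
    if not group_sizes:
        raise ValueError("group_sizes must be nonempty")
    if effect is None:
        effect = EffectSpec.null()
    effect.validate_against(atlas)

    rng = np.random.default_rng(seed)
    n = atlas.n_regions
    g = _spatial_gradients(atlas)                       # (N, K)
    w = rng.normal(size=(g.shape[1], n_features)) / np.sqrt(g.shape[1])
    # a dominant gradient loading positively on every feature, mimicking the
    # shared morphometric component that gives real similarity networks
    # their positive-median edge weights
    w[0] = rng.uniform(1.0, 2.0, size=n_features)
    feat_scale = rng.uniform(0.5, 2.0, size=n_features)
    feat_offset = rng.uniform(0.0, 10.0, size=n_features)
    region_offset = rng.normal(scale=0.5, size=(n, 1))
    # feature-specific regional idiosyncrasy (shared across subjects) keeps
    # features from being mutual near-duplicates of the latent gradients
    idiosyncrasy = rng.normal(scale=0.6, size=(n, n_features))
    archetype = (g @ w + region_offset + idiosyncrasy) * feat_scale + feat_offset

    u = rng.normal(size=n_features)
    u /= np.sqrt(np.mean(u**2))   # shared effect direction, RMS 1 per feature
    id_to_row = {rid: i for i, rid in enumerate(atlas.region_ids)}
    target_rows = np.array([id_to_row[r] for r in effect.target_regions], dtype=int)

    records: list[SubjectRecord] = []
    matrices: list[FeatureMatrix] = []
    k = 0
    for group, size in group_sizes.items():
        for _ in range(size):
            k += 1
            sid = f"sub-{k:04d}"
            affected = group in effect.groups_affected and effect.effect_size > 0
            dose = effect.effect_size * rng.uniform(0.5, 1.5) if affected else 0.0
            vals = archetype + rng.normal(scale=noise_sd, size=(n, n_features)) * feat_scale
            if dose > 0 and target_rows.size:
                if effect.effect_mode == "strength-shift":
                    vals[target_rows] += dose * u * feat_scale
                else:  # profile-decorrelation
                    pert = rng.normal(size=(target_rows.size, n_features))
                    vals[target_rows] += dose * pert * feat_scale
            records.append(SubjectRecord(
                subject_id=sid, group=group,
                site_id=f"site{(k - 1) % n_sites}", effect_dose=dose,
            ))
            matrices.append(FeatureMatrix(
                values=vals, region_ids=atlas.region_ids,
                feature_names=[f"feat{j+1:03d}" for j in range(n_features)],
                subject_id=sid,
            ))
    return records, matrices


def generate_clinical_scores(records: list[SubjectRecord],
                             score_model: dict[str, tuple[float, float, float]],
                             seed: int = 0) -> list[SubjectRecord]:
    """Attach clinical scores: score = baseline + slope * dose + N(0, sd).

    The dose is the subject's recorded planted-effect dose (0 for
    unaffected subjects), so a negative slope produces the usual pattern
    of lower cognitive scores in affected groups.  Returns new records;
    the inputs are not mutated.
    """
    if not score_model:
        raise ValueError("score_model must be nonempty")
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        clinical = dict(rec.clinical)
        for name, (baseline, slope, sd) in score_model.items():
            clinical[name] = baseline + slope * rec.effect_dose + rng.normal(scale=sd)
        out.append(replace(rec, clinical=clinical))
    return out


def generate_spatial_maps(atlas: AtlasGeometry, target_map: np.ndarray,
                          n_maps: int, target_corr: float, seed: int = 0,
                          names: list[str] | None = None,
                          exact_corr: bool = False) -> SpatialMapSet:
    """Maps with expected Pearson correlation ``target_corr`` to a target.

    Mixture construction on z-scored maps:
    map = c * z(target) + sqrt(1 - c^2) * z(noise); at |c| = 1 the map is
    an exact affine image of the target.  Maps are mutually independent
    given the target.

    With ``exact_corr=True`` the noise is first orthogonalized against
    the target (Gram-Schmidt), so every generated map's sample Pearson
    correlation with the target equals ``target_corr`` exactly — useful
    for planted-signal validation fixtures where "uncorrelated" must
    hold in-sample, not just in expectation.
    """
    if abs(target_corr) > 1:
        raise ValueError("target_corr must lie in [-1, 1]")
    target_map = np.asarray(target_map, dtype=float)
    n = atlas.n_regions
    if target_map.shape != (n,):
        raise ValueError(
            f"target_map length {target_map.size} does not match atlas size {n}"
        )
    if names is None:
        names = [f"map{j+1:04d}" for j in range(n_maps)]
    if len(names) != n_maps:
        raise ValueError("names length must equal n_maps")
    rng = np.random.default_rng(seed)
    zt = (target_map - target_map.mean())
    sd = zt.std()
    if sd == 0:
        raise ValueError("target_map is constant")
    zt = zt / sd
    cols = np.empty((n, n_maps))
    resid = np.sqrt(max(0.0, 1.0 - target_corr**2))
    for j in range(n_maps):
        noise = rng.normal(size=n)
        if exact_corr:
            noise = noise - (noise @ zt) / (zt @ zt) * zt
        noise = noise - noise.mean()
        noise = noise / noise.std()
        cols[:, j] = target_corr * zt + resid * noise
    return SpatialMapSet(names=names, matrix=cols, region_ids=atlas.region_ids)
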