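"""Delimited-text readers and writers plus run configuration.

Everything is plain tab-separated text: atlas tables, subject manifests,
per-subject feature tables, square R2SN matrices with a region_id
header, 20 x N motif-count tables, PMV tables and statistic maps.  The
PMV model is a small YAML record.  Region order is always atlas order;
tables arriving in a different row order are silently reordered (and
logged); region sets that do not match the atlas are hard errors naming
the offending file and regions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .motifs import build_catalog
from .types import (
    AtlasGeometry,
    FeatureMatrix,
    MotifCountMatrix,
    PMVModel,
    R2SN,
    SpatialMapSet,
    SubjectRecord,
    ThresholdPair,
)

__all__ = [
    "RunConfig",
    "CohortBundle",
    "read_atlas_table", "write_atlas_table",
    "read_manifest", "write_manifest",
    "read_feature_table", "write_feature_table",
    "read_square_matrix", "write_square_matrix",
    "read_motif_counts", "write_motif_counts",
    "read_pmv_model", "write_pmv_model",
    "read_map_set", "write_map_set",
    "write_thresholds", "read_thresholds",
    "load_cohort",
]

logger = logging.getLogger(__name__)

_SEP = "\t"
_FLOAT_FMT = "%.17g"  # lossless double round-trip
_MANIFEST_FIXED = ("subject_id", "group", "site")


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run.

    Defaults follow the method's standard settings: 25 retained radiomic
    features, redundancy cap 0.90, alpha 0.05, top 500 genes exported
    for enrichment.
    """

    atlas_path: str = ""
    manifest_path: str = ""
    features_dir: str = ""
    gene_maps_path: str = ""
    receptor_maps_path: str = ""
    out_dir: str = "results"
    target_count: int = 25
    r_cap: float = 0.90
    alpha: float = 0.05
    n_perm: int = 1000
    n_boot: int = 1000
    top_k: int = 500
    seed: int = 0
    pca_orientation: str = "motif"          # "motif" (default) or "region" (literal variant)
    tie_corrected_sigma: bool = False
    correlation_method: str = "pearson"
    reference_groups: list[str] = field(default_factory=list)  # empty = all subjects

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


@dataclass
class CohortBundle:
    """A validated, atlas-ordered cohort with per-stage provenance hashes."""

    atlas: AtlasGeometry
    records: list[SubjectRecord]
    features: list[FeatureMatrix]
    hashes: dict[str, str] = field(default_factory=dict)

    @property
    def groups(self) -> pd.Series:
        return pd.Series({r.subject_id: r.group for r in self.records},
                         name="group")


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------- atlas

def write_atlas_table(atlas: AtlasGeometry, path: str | Path) -> None:
    df = pd.DataFrame({
        "region_id": atlas.region_ids,
        "x": atlas.centroids[:, 0],
        "y": atlas.centroids[:, 1],
        "z": atlas.centroids[:, 2],
        "anatomical_label": atlas.anatomical_label,
        "functional_label": atlas.functional_label,
    })
    df.to_csv(path, sep=_SEP, index=False, float_format=_FLOAT_FMT)


def read_atlas_table(path: str | Path) -> AtlasGeometry:
    df = pd.read_csv(path, sep=_SEP)
    required = {"region_id", "x", "y", "z", "anatomical_label", "functional_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing atlas columns {sorted(missing)}")
    return AtlasGeometry(
        region_ids=df["region_id"].to_numpy(),
        centroids=df[["x", "y", "z"]].to_numpy(),
        anatomical_label=df["anatomical_label"].to_numpy(),
        functional_label=df["functional_label"].to_numpy(),
    )


# -------------------------------------------------------------- manifest

def write_manifest(records: list[SubjectRecord], path: str | Path) -> None:
    score_names = sorted({k for r in records for k in r.clinical})
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group, "site": r.site_id,
               "effect_dose": r.effect_dose}
        for s in score_names:
            row[s] = r.clinical.get(s, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_SEP, index=False, float_format=_FLOAT_FMT)


def read_manifest(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep=_SEP)
    missing = set(_MANIFEST_FIXED) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing manifest columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject_id(s) {dupes}")
    score_cols = [c for c in df.columns
                  if c not in _MANIFEST_FIXED and c != "effect_dose"]
    records = []
    for _, row in df.iterrows():
        clinical = {c: float(row[c]) for c in score_cols}
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=str(row["group"]),
            site_id=str(row["site"]), clinical=clinical,
            effect_dose=float(row.get("effect_dose", 0.0)),
        ))
    return records


# -------------------------------------------------------- feature tables

def write_feature_table(fm: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df.insert(0, "region_id", fm.region_ids)
    df.to_csv(path, sep=_SEP, index=False, float_format=_FLOAT_FMT)


def read_feature_table(path: str | Path, atlas: AtlasGeometry | None = None,
                       subject_id: str = "") -> FeatureMatrix:
    df = pd.read_csv(path, sep=_SEP)
    if df.columns[0] != "region_id":
        raise ValueError(f"{path}: first column must be region_id")
    fm = FeatureMatrix(
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        region_ids=df["region_id"].to_numpy(),
        feature_names=list(df.columns[1:]),
        subject_id=subject_id or Path(path).stem,
    )
    if atlas is not None:
        fm = _harmonize_regions(fm, atlas, str(path))
    return fm


def _harmonize_regions(fm: FeatureMatrix, atlas: AtlasGeometry,
                       source: str) -> FeatureMatrix:
    extra = np.setdiff1d(fm.region_ids, atlas.region_ids)
    if extra.size:
        raise ValueError(f"{source}: regions not in atlas: {extra.tolist()}")
    absent = np.setdiff1d(atlas.region_ids, fm.region_ids)
    if absent.size:
        raise ValueError(f"{source}: regions missing: {absent.tolist()}")
    if np.array_equal(fm.region_ids, atlas.region_ids):
        return fm
    logger.info("%s: region rows reordered to atlas order", source)
    pos = {rid: i for i, rid in enumerate(fm.region_ids)}
    order = np.array([pos[rid] for rid in atlas.region_ids])
    return FeatureMatrix(values=fm.values[order], region_ids=atlas.region_ids,
                         feature_names=fm.feature_names, subject_id=fm.subject_id)


# --------------------------------------------------------- square matrix

def write_square_matrix(net: R2SN, path: str | Path) -> None:
    df = pd.DataFrame(net.weights, index=net.region_ids, columns=net.region_ids)
    df.to_csv(path, sep=_SEP, index_label="region_id", float_format=_FLOAT_FMT)


def read_square_matrix(path: str | Path, subject_id: str = "") -> R2SN:
    df = pd.read_csv(path, sep=_SEP, index_col="region_id")
    w = df.to_numpy(dtype=float)
    # serialized Pearson values are rounded; restore exact symmetry/diagonal
    w = (w + w.T) / 2
    np.fill_diagonal(w, 1.0)
    return R2SN(weights=w, region_ids=df.index.to_numpy(dtype=int),
                subject_id=subject_id or Path(path).stem)


# ---------------------------------------------------------- motif counts

def write_motif_counts(mcm: MotifCountMatrix, path: str | Path) -> None:
    catalog = build_catalog()
    df = pd.DataFrame(mcm.counts, index=pd.Index(catalog.labels, name="motif_type"),
                      columns=mcm.region_ids)
    df.to_csv(path, sep=_SEP)


def read_motif_counts(path: str | Path, subject_id: str = "") -> MotifCountMatrix:
    df = pd.read_csv(path, sep=_SEP, index_col="motif_type")
    catalog = build_catalog()
    if list(df.index) != catalog.labels:
        raise ValueError(f"{path}: motif-type rows do not match the 20-type catalog")
    return MotifCountMatrix(counts=df.to_numpy(dtype=np.int64),
                            region_ids=df.columns.to_numpy(dtype=int),
                            subject_id=subject_id or Path(path).stem)


# ------------------------------------------------------------- PMV model

def write_pmv_model(model: PMVModel, path: str | Path) -> None:
    catalog_hash = hashlib.sha256(
        "|".join(model.catalog_labels).encode()).hexdigest()[:16]
    data = {
        "loading": [float(v) for v in model.loading],
        "eigenvalues": [float(v) for v in model.eigenvalues],
        "variance_explained_1": float(model.variance_explained_1),
        "sign_anchor": int(model.sign_anchor),
        "catalog_labels": list(model.catalog_labels),
        "catalog_hash": catalog_hash,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_pmv_model(path: str | Path) -> PMVModel:
    data = yaml.safe_load(Path(path).read_text())
    return PMVModel(
        loading=np.array(data["loading"]),
        eigenvalues=np.array(data["eigenvalues"]),
        variance_explained_1=data["variance_explained_1"],
        sign_anchor=data["sign_anchor"],
        catalog_labels=list(data.get("catalog_labels", [])),
    )


# ------------------------------------------------------------ thresholds

def write_thresholds(thr: ThresholdPair, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump({
        "strength_median": float(thr.strength_median),
        "length_median": float(thr.length_median),
        "provenance": thr.provenance,
    }, sort_keys=False))


def read_thresholds(path: str | Path) -> ThresholdPair:
    data = yaml.safe_load(Path(path).read_text())
    return ThresholdPair(**data)


# --------------------------------------------------------------- map sets

def write_map_set(maps: SpatialMapSet, path: str | Path) -> None:
    df = pd.DataFrame(maps.matrix, columns=maps.names)
    df.insert(0, "region_id", maps.region_ids)
    df.to_csv(path, sep=_SEP, index=False, float_format=_FLOAT_FMT)


def read_map_set(path: str | Path, atlas: AtlasGeometry | None = None) -> SpatialMapSet:
    df = pd.read_csv(path, sep=_SEP)
    if df.columns[0] != "region_id":
        raise ValueError(f"{path}: first column must be region_id")
    sms = SpatialMapSet(names=list(df.columns[1:]),
                        matrix=df.iloc[:, 1:].to_numpy(dtype=float),
                        region_ids=df["region_id"].to_numpy())
    if atlas is not None:
        extra = np.setdiff1d(sms.region_ids, atlas.region_ids)
        if extra.size:
            raise ValueError(f"{path}: regions not in atlas: {extra.tolist()}")
        absent = np.setdiff1d(atlas.region_ids, sms.region_ids)
        if absent.size:
            raise ValueError(f"{path}: regions missing: {absent.tolist()}")
        if not np.array_equal(sms.region_ids, atlas.region_ids):
            pos = {rid: i for i, rid in enumerate(sms.region_ids)}
            order = np.array([pos[rid] for rid in atlas.region_ids])
            sms = SpatialMapSet(names=sms.names, matrix=sms.matrix[order],
                                region_ids=atlas.region_ids)
    return sms


# ------------------------------------------------------------ load_cohort

def load_cohort(config: RunConfig) -> CohortBundle:
    """Read and validate atlas, manifest and per-subject feature tables.

    Feature tables are looked up as ``<features_dir>/<subject_id>.tsv``;
    rows are harmonized to atlas order.  Malformed or mismatched tables
    raise errors naming the file and the offending regions.
    """
    atlas = read_atlas_table(config.atlas_path)
    records = read_manifest(config.manifest_path)
    features = []
    for rec in records:
        path = Path(config.features_dir) / f"{rec.subject_id}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"feature table missing for {rec.subject_id}: {path}")
        features.append(read_feature_table(path, atlas=atlas,
                                           subject_id=rec.subject_id))
    hashes = {
        "atlas": _hash_array(atlas.centroids),
        "features": hashlib.sha256(
            "".join(_hash_array(f.values) for f in features).encode()
        ).hexdigest()[:16],
    }
    return CohortBundle(atlas=atlas, records=records, features=features,
                        hashes=hashes)
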