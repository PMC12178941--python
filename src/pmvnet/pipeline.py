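"""End-to-end orchestration: features -> R2SN -> motif census -> PMV ->
group statistics (-> spatial association when maps are supplied).

`compute_pmv_cohort` is the in-memory core used by tests and the
acceptance script; `run_pipeline` adds file plumbing around it and
writes every stage table plus the resolved configuration into a result
directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .motifs import (
    build_catalog,
    compute_edge_lengths,
    compute_thresholds,
    count_motifs,
    label_edges,
)
from .pmv import fit_pmv_model, motif_contributions, project_pmv
from .r2sn import build_r2sn, minmax_normalize, select_features
from .stats import kruskal_wallis_map, mannwhitney_zmap, pmv_table
from .types import (
    AtlasGeometry,
    FeatureMatrix,
    MotifCountMatrix,
    PMVMap,
    PMVModel,
    R2SN,
    SubjectRecord,
    ThresholdPair,
)

__all__ = ["CohortResult", "compute_pmv_cohort", "analyze_groups", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class CohortResult:
    """All per-stage outputs for one cohort."""

    atlas: AtlasGeometry
    selected_features: list[int]
    networks: list[R2SN]
    thresholds: ThresholdPair
    counts: list[MotifCountMatrix]
    model: PMVModel
    pmv_maps: list[PMVMap]
    pmv: pd.DataFrame = field(default=None)  # subjects x regions

    def __post_init__(self) -> None:
        if self.pmv is None:
            self.pmv = pmv_table(self.pmv_maps)


def compute_pmv_cohort(atlas: AtlasGeometry, features: list[FeatureMatrix],
                       target_count: int = 25, r_cap: float = 0.90,
                       reference_ids: list[str] | None = None,
                       thresholds: ThresholdPair | None = None) -> CohortResult:
    """Run the full biomarker computation for one cohort.

    Feature selection, edge-binarization thresholds and the PMV loading
    are fitted on the reference subjects (``reference_ids``; default all
    subjects) and applied to everyone — so a model fitted on a discovery
    cohort can be applied unchanged to validation subjects.
    Precomputed ``thresholds`` (e.g. from another dataset) override the
    cohort medians.
    """
    if not features:
        raise ValueError("empty cohort")
    norm = [minmax_normalize(fm) for fm in features]
    is_ref = (
        [fm.subject_id in set(reference_ids) for fm in norm]
        if reference_ids is not None else [True] * len(norm)
    )
    if not any(is_ref):
        raise ValueError("no reference subjects found in the cohort")
    ref_norm = [fm for fm, r in zip(norm, is_ref) if r]

    target_count = min(target_count, len(norm[0].feature_names))
    selected = select_features(ref_norm, target_count=target_count, r_cap=r_cap)
    networks = [build_r2sn(fm, selected) for fm in norm]

    distances = compute_edge_lengths(atlas)
    if thresholds is None:
        ref_nets = [net for net, r in zip(networks, is_ref) if r]
        thresholds = compute_thresholds(ref_nets, distances)
    catalog = build_catalog()
    counts = [
        count_motifs(label_edges(net, distances, thresholds), catalog,
                     subject_id=net.subject_id, region_ids=net.region_ids)
        for net in networks
    ]
    ref_counts = [m for m, r in zip(counts, is_ref) if r]
    model = fit_pmv_model(ref_counts, catalog)
    pmv_maps = [project_pmv(m, model) for m in counts]
    return CohortResult(atlas=atlas, selected_features=selected,
                        networks=networks, thresholds=thresholds,
                        counts=counts, model=model, pmv_maps=pmv_maps)


def analyze_groups(pmv: pd.DataFrame, groups: pd.Series, alpha: float = 0.05,
                   tie_correction: bool = False) -> dict:
    """Omnibus Kruskal-Wallis gate, then pairwise Mann-Whitney Z-maps
    restricted to the Bonferroni-significant regions."""
    kw = kruskal_wallis_map(pmv, groups, alpha=alpha)
    significant = kw.index[kw["significant"]].tolist()
    labels = sorted(pd.unique(groups.loc[pmv.index]))
    zmaps, posthoc = {}, {}
    if significant:
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                zm, st = mannwhitney_zmap(pmv, groups, a, b,
                                          restrict_to=significant, alpha=alpha,
                                          tie_correction=tie_correction)
                zmaps[(a, b)] = zm
                posthoc[(a, b)] = st
    return {"kruskal_wallis": kw, "significant_regions": significant,
            "zmaps": zmaps, "posthoc": posthoc}


def run_pipeline(config: pio.RunConfig) -> Path:
    """File-level pipeline: load the cohort, run every stage, write all
    tables, the resolved config and a run summary into ``config.out_dir``.
    Deterministic given the input files and seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = pio.load_cohort(config)
    groups = bundle.groups

    reference_ids = None
    if config.reference_groups:
        reference_ids = [r.subject_id for r in bundle.records
                         if r.group in config.reference_groups]
    try:
        result = compute_pmv_cohort(bundle.atlas, bundle.features,
                                    target_count=config.target_count,
                                    r_cap=config.r_cap,
                                    reference_ids=reference_ids)
    except Exception as exc:
        raise RuntimeError(f"biomarker stage failed: {exc}") from exc

    for net in result.networks:
        pio.write_square_matrix(net, out / f"r2sn_{net.subject_id}.tsv")
    for mcm in result.counts:
        pio.write_motif_counts(mcm, out / f"motifs_{mcm.subject_id}.tsv")
    pio.write_thresholds(result.thresholds, out / "thresholds.yaml")
    pio.write_pmv_model(result.model, out / "pmv_model.yaml")
    result.pmv.to_csv(out / "pmv.tsv", sep="\t", float_format="%.12g")
    motif_contributions(result.model).to_csv(
        out / "motif_contributions.tsv", sep="\t", index=False,
        float_format="%.12g")

    try:
        analysis = analyze_groups(result.pmv, groups, alpha=config.alpha,
                                  tie_correction=config.tie_corrected_sigma)
    except Exception as exc:
        raise RuntimeError(f"group-statistics stage failed: {exc}") from exc
    analysis["kruskal_wallis"].to_csv(out / "kruskal_wallis.tsv", sep="\t",
                                      float_format="%.12g")
    for (a, b), st in analysis["posthoc"].items():
        st.to_csv(out / f"mannwhitney_{a}_vs_{b}.tsv", sep="\t",
                  float_format="%.12g")

    spatial_summary = {}
    if config.gene_maps_path:
        from .spatial import bootstrap_gene_zscores, pls1_association
        gene_maps = pio.read_map_set(config.gene_maps_path, atlas=bundle.atlas)
        target = _default_target(analysis, result.pmv)
        pls = pls1_association(gene_maps, target, n_perm=config.n_perm,
                               seed=config.seed)
        table, top = bootstrap_gene_zscores(gene_maps, target,
                                            n_boot=config.n_boot,
                                            seed=config.seed,
                                            top_k=config.top_k)
        table.to_csv(out / "gene_zscores.tsv", sep="\t", index=False,
                     float_format="%.12g")
        (out / "top_genes.txt").write_text("\n".join(top) + "\n")
        spatial_summary["pls_r"] = pls.r_with_target
        spatial_summary["pls_p_perm"] = pls.p_perm
        spatial_summary["pls_variance_explained"] = pls.variance_explained
    if config.receptor_maps_path:
        from .spatial import map_correlation_panel
        rec_maps = pio.read_map_set(config.receptor_maps_path, atlas=bundle.atlas)
        target = _default_target(analysis, result.pmv)
        panel = map_correlation_panel(target, rec_maps, n_perm=config.n_perm,
                                      seed=config.seed, alpha=config.alpha,
                                      method=config.correlation_method)
        panel.to_csv(out / "receptor_panel.tsv", sep="\t", index=False,
                     float_format="%.12g")

    config_out = dataclasses.replace(config, out_dir=str(out))
    config_out.to_yaml(out / "run_config.yaml")
    summary = {
        "n_subjects": len(bundle.records),
        "n_regions": int(bundle.atlas.n_regions),
        "selected_features": result.selected_features,
        "strength_median": result.thresholds.strength_median,
        "length_median": result.thresholds.length_median,
        "variance_explained_1": result.model.variance_explained_1,
        "n_significant_regions": len(analysis["significant_regions"]),
        "significant_regions": [int(r) for r in analysis["significant_regions"]],
        **spatial_summary,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    logger.info("pipeline complete: %s", out)
    return out


def _default_target(analysis: dict, pmv: pd.DataFrame) -> np.ndarray:
    """Spatial-association target: the NC-vs-AD Z-map when available,
    else the cohort-mean PMV map."""
    for (a, b), zm in analysis["zmaps"].items():
        if {a, b} == {"NC", "AD"}:
            vals = zm.values.copy()
            finite = np.isfinite(vals)
            if finite.all():
                return vals
    return pmv.to_numpy().mean(axis=0)
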