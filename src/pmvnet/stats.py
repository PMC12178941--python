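"""Group-level inference on PMV maps.

Per-region nonparametric testing: Shapiro-Wilk normality screening,
Kruskal-Wallis across diagnostic groups with Bonferroni correction,
post-hoc Mann-Whitney Z-maps, Pearson clinical-correlation maps,
cross-dataset Z-map agreement, Stouffer multi-site meta-analysis, and
partition (lobe / functional-network) summaries.

PMV tables are pandas DataFrames with one row per subject (indexed by
subject_id) and one column per region; group membership is a Series
aligned to the subject index.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import AtlasGeometry, PMVMap, ZMap

__all__ = [
    "pmv_table",
    "normality_screen",
    "kruskal_wallis_map",
    "mannwhitney_zmap",
    "mannwhitney_u_z",
    "clinical_correlation_map",
    "compare_zmaps",
    "stouffer_meta",
    "summarize_by_partition",
]

logger = logging.getLogger(__name__)


def pmv_table(maps: list[PMVMap]) -> pd.DataFrame:
    """Stack per-subject PMV maps into a subjects x regions DataFrame."""
    if not maps:
        raise ValueError("no PMV maps supplied")
    return pd.DataFrame(
        np.vstack([m.values for m in maps]),
        index=pd.Index([m.subject_id for m in maps], name="subject_id"),
        columns=maps[0].region_ids,
    )


def _bonferroni(p: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    p_adj = np.minimum(p * p.size, 1.0)
    return p_adj, p_adj < alpha


def normality_screen(pmv: pd.DataFrame, groups: pd.Series,
                     alpha: float = 0.05) -> tuple[pd.DataFrame, float]:
    """Shapiro-Wilk p-value per (group, region) cell.

    Groups with fewer than 3 subjects are excluded with a warning; a
    constant within-group sample is reported as p = 0 (degenerate, not
    plausibly normal).  Returns the p-value table (groups x regions) and
    the fraction of cells with p < alpha.
    """
    rows = {}
    for g, sub in pmv.groupby(groups):
        if len(sub) < 3:
            warnings.warn(f"group {g!r} has {len(sub)} subjects; "
                          "excluded from normality screening", stacklevel=2)
            continue
        ps = np.empty(pmv.shape[1])
        for j, col in enumerate(sub.columns):
            vals = sub[col].to_numpy()
            if np.ptp(vals) == 0:
                ps[j] = 0.0
            else:
                ps[j] = sps.shapiro(vals).pvalue
        rows[g] = ps
    table = pd.DataFrame(rows, index=pmv.columns).T
    frac = float((table.to_numpy() < alpha).mean()) if table.size else np.nan
    return table, frac


def kruskal_wallis_map(pmv: pd.DataFrame, groups: pd.Series,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis H per region with chi-square p-values,
    Bonferroni-adjusted across regions (per-region threshold alpha/N)."""
    labels = pd.unique(groups.loc[pmv.index])
    if len(labels) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    samples = {g: pmv.loc[groups.loc[pmv.index] == g] for g in labels}
    for g, sub in samples.items():
        if len(sub) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    h = np.empty(pmv.shape[1])
    p = np.empty(pmv.shape[1])
    for j, col in enumerate(pmv.columns):
        res = sps.kruskal(*[sub[col].to_numpy() for sub in samples.values()])
        h[j], p[j] = res.statistic, res.pvalue
    p_adj, sig = _bonferroni(p, alpha)
    return pd.DataFrame(
        {"statistic": h, "p": p, "p_adj": p_adj, "significant": sig},
        index=pd.Index(pmv.columns, name="region_id"),
    ).assign(test="kruskal-wallis", n_tests=p.size, alpha=alpha)


def mannwhitney_u_z(x: np.ndarray, y: np.ndarray,
                    tie_correction: bool = False) -> tuple[float, float]:
    """Mann-Whitney U of the first sample and its standardized Z.

    Z = (U - n1*n2/2) / sqrt(n1*n2*(n1+n2+1)/12); by default sigma_U is
    the no-tie closed form (ties are measure-zero for correlation-derived
    PMV values).  ``tie_correction=True`` switches to the tie-corrected
    sigma_U.
    """
    n1, n2 = len(x), len(y)
    u = float(sps.mannwhitneyu(x, y, alternative="two-sided").statistic)
    mu = n1 * n2 / 2.0
    if tie_correction:
        pooled = np.concatenate([x, y])
        _, t = np.unique(pooled, return_counts=True)
        n = n1 + n2
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - (t**3 - t).sum() / (n * (n - 1)))
    else:
        sigma2 = n1 * n2 * (n1 + n2 + 1) / 12.0
    z = (u - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    return u, float(z)


def mannwhitney_zmap(pmv: pd.DataFrame, groups: pd.Series, group_a: str,
                     group_b: str, restrict_to=None, alpha: float = 0.05,
                     tie_correction: bool = False) -> tuple[ZMap, pd.DataFrame]:
    """Post-hoc two-group Z-map over a (possibly restricted) region set.

    U is oriented as the statistic of ``group_a``; two-sided normal
    p-values are Bonferroni-adjusted over the restricted set.  Regions
    outside the restriction carry Z = NaN in the returned ZMap.
    """
    a = pmv.loc[groups.loc[pmv.index] == group_a]
    b = pmv.loc[groups.loc[pmv.index] == group_b]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    regions = list(pmv.columns) if restrict_to is None else list(restrict_to)
    if not regions:
        warnings.warn("empty restriction set: returning an empty map", stacklevel=2)
    z_full = np.full(pmv.shape[1], np.nan)
    stats_rows = []
    col_pos = {c: i for i, c in enumerate(pmv.columns)}
    for col in regions:
        u, z = mannwhitney_u_z(a[col].to_numpy(), b[col].to_numpy(),
                               tie_correction=tie_correction)
        z_full[col_pos[col]] = z
        p = 2 * sps.norm.sf(abs(z))
        stats_rows.append((col, u, z, p))
    stat = pd.DataFrame(stats_rows, columns=["region_id", "U", "Z", "p"])
    stat = stat.set_index("region_id")
    if len(stat):
        stat["p_adj"], stat["significant"] = _bonferroni(stat["p"].to_numpy(), alpha)
    else:
        stat["p_adj"], stat["significant"] = [], []
    zmap = ZMap(values=z_full, region_ids=np.asarray(pmv.columns),
                group_a=group_a, group_b=group_b, n_a=len(a), n_b=len(b))
    return zmap, stat.assign(test="mann-whitney", n_tests=len(stat), alpha=alpha)


def clinical_correlation_map(pmv: pd.DataFrame, groups: pd.Series,
                             scores: pd.DataFrame, subset: list[str],
                             alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Pearson r between PMV and each clinical score over the pooled
    subject subset, per region, Bonferroni over regions per score.

    ``scores`` is subjects x score-names with NaN for missing; missing
    values are dropped pairwise.  All-missing (or nearly so) scores are
    skipped with a warning.
    """
    mask = groups.loc[pmv.index].isin(subset)
    sub_pmv = pmv.loc[mask]
    sub_scores = scores.loc[sub_pmv.index]
    out: dict[str, pd.DataFrame] = {}
    for name in sub_scores.columns:
        s = sub_scores[name]
        ok = s.notna()
        if ok.sum() < 3:
            warnings.warn(f"score {name!r} has <3 non-missing subjects in "
                          "subset; skipped", stacklevel=2)
            continue
        sv = s[ok].to_numpy()
        r = np.empty(sub_pmv.shape[1])
        p = np.empty(sub_pmv.shape[1])
        for j, col in enumerate(sub_pmv.columns):
            res = sps.pearsonr(sub_pmv.loc[ok, col].to_numpy(), sv)
            r[j], p[j] = res.statistic, res.pvalue
        p_adj, sig = _bonferroni(p, alpha)
        out[name] = pd.DataFrame(
            {"r": r, "p": p, "p_adj": p_adj, "significant": sig},
            index=pd.Index(sub_pmv.columns, name="region_id"),
        ).assign(score=name, n=int(ok.sum()), alpha=alpha)
    return out


def compare_zmaps(za: ZMap, zb: ZMap) -> tuple[float, float]:
    """Pearson correlation between two Z-maps across their common regions."""
    if za.values.size != zb.values.size:
        raise ValueError("Z-maps cover different region sets")
    ok = np.isfinite(za.values) & np.isfinite(zb.values)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly finite regions")
    res = sps.pearsonr(za.values[ok], zb.values[ok])
    return float(res.statistic), float(res.pvalue)


def stouffer_meta(zmaps: list[ZMap], weights=None) -> ZMap:
    """Stouffer weighted-Z combination of per-site Z-maps.

    meta-Z[j] = sum_s w_s Z_s[j] / sqrt(sum_s w_s^2); the default weight
    is sqrt(site sample size).
    """
    if not zmaps:
        raise ValueError("no site maps supplied")
    n = zmaps[0].values.size
    for zm in zmaps:
        if zm.values.size != n:
            raise ValueError("site Z-maps cover different region sets")
    if weights is None:
        weights = [np.sqrt(zm.site_n) if zm.site_n > 0 else 1.0 for zm in zmaps]
    w = np.asarray(weights, dtype=float)
    if w.size != len(zmaps):
        raise ValueError("weight vector length does not match number of sites")
    z = np.vstack([zm.values for zm in zmaps])
    meta = (w[:, None] * z).sum(axis=0) / np.sqrt((w**2).sum())
    total_a = sum(zm.n_a for zm in zmaps)
    total_b = sum(zm.n_b for zm in zmaps)
    return ZMap(values=meta, region_ids=zmaps[0].region_ids,
                group_a=zmaps[0].group_a, group_b=zmaps[0].group_b,
                n_a=total_a, n_b=total_b)


def summarize_by_partition(pmv: pd.DataFrame, atlas: AtlasGeometry,
                           which: str = "anatomical",
                           alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution of the cohort-mean PMV map across partition labels.

    Returns per-label summaries (n, mean, median, quartiles of the mean
    map restricted to that label) and pairwise label comparisons via
    Mann-Whitney with Bonferroni over the label pairs.
    """
    if which == "anatomical":
        labels = atlas.anatomical_label
    elif which == "functional":
        labels = atlas.functional_label
    else:
        raise ValueError(f"unknown partition {which!r}; "
                         "use 'anatomical' or 'functional'")
    mean_map = pmv.to_numpy().mean(axis=0)
    lab = pd.Series(labels, index=pmv.columns, name="label")
    df = pd.DataFrame({"label": lab.to_numpy(), "pmv": mean_map})
    summary = (
        df.groupby("label")["pmv"]
        .agg(n="size", mean="mean", median="median",
             q25=lambda s: s.quantile(0.25), q75=lambda s: s.quantile(0.75))
        .reset_index()
    )
    pairs = []
    uniq = sorted(df["label"].unique())
    for a, b in combinations(uniq, 2):
        xa = df.loc[df["label"] == a, "pmv"].to_numpy()
        xb = df.loc[df["label"] == b, "pmv"].to_numpy()
        if len(xa) == 0 or len(xb) == 0:
            continue
        _, z = mannwhitney_u_z(xa, xb)
        p = 2 * sps.norm.sf(abs(z))
        pairs.append((a, b, z, p))
    pairwise = pd.DataFrame(pairs, columns=["label_a", "label_b", "Z", "p"])
    if len(pairwise):
        pairwise["p_adj"], pairwise["significant"] = _bonferroni(
            pairwise["p"].to_numpy(), alpha)
    return summary, pairwise
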