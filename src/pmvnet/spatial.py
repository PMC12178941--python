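"""Spatial association between a regional target map (typically a group
Z-map) and panels of spatial maps (gene expression, receptor density).

The main tool is a one-component partial-least-squares (PLS1)
correlation between a region x gene expression matrix and the target
map, with permutation significance that accepts precomputed spatial
(spin-style) permutation index sets, a bootstrap gene Z-score ranking
with top-k export for external enrichment services, and a plain Pearson
correlation panel against named maps.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import SpatialMapSet

__all__ = [
    "PLSResult",
    "pls1_association",
    "bootstrap_gene_zscores",
    "map_correlation_panel",
    "AHBA_HIGH_RISK_AD_GENES",
    "parse_gene_panel",
    "high_risk_gene_panel",
]

# Alzheimer's high-risk gene panel as listed on the AHBA website
# (comma-separated, as typically quoted).
_HIGH_RISK_PANEL_TEXT = (
    "A2M, ACE, ACHE, APBA1, APBB2, APLP1, APLP2, APOC1, APP, BACE2, "
    "BCHE, BLMH, CASP3, CHRNA3, CTSB, DBN1, ESR1, GSK3B, IL1B, KCNIP3, "
    "KLK6, LRP1, LRRC15, MAPT, PLAU, PSEN1, PSEN2, and SORL1"
)


def parse_gene_panel(text: str) -> list[str]:
    """Parse a prose gene list ("A2M, ACE, ... and SORL1") into distinct
    uppercase symbols, preserving first-appearance order."""
    tokens = re.split(r"[,;\s]+", text)
    seen: dict[str, None] = {}
    for tok in tokens:
        sym = tok.strip().strip(".").upper()
        if sym in {"", "AND"}:
            continue
        if not re.fullmatch(r"[A-Z0-9\-]+", sym):
            raise ValueError(f"not a gene symbol: {tok!r}")
        seen.setdefault(sym)
    return list(seen)


AHBA_HIGH_RISK_AD_GENES: tuple[str, ...] = tuple(parse_gene_panel(_HIGH_RISK_PANEL_TEXT))


def high_risk_gene_panel() -> list[str]:
    """The 28-symbol AHBA Alzheimer's high-risk gene panel."""
    return list(AHBA_HIGH_RISK_AD_GENES)


@dataclass
class PLSResult:
    """One-component PLS association between a map panel and a target."""

    component_scores: np.ndarray    # (N,) PLS1 regional scores
    gene_weights: np.ndarray        # (G,) predictor weights
    r_with_target: float
    variance_explained: float       # share of predictor-block variance
    p_perm: float
    n_perm: int
    permutation_scheme: str         # "uniform" or "supplied"
    gene_names: list[str] = field(default_factory=list)


def _zscore_cols(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def _pls1(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """First PLS component of standardized predictors against a
    standardized target: (scores, weights, predictor variance share).

    With a single response the first component is closed-form: the
    weight vector is the normalized covariance direction X'y (what NIPALS
    converges to in one step), scores t = Xw, loadings p = X't/(t't);
    the predictor-block variance share is ||t p'||_F^2 / ||X||_F^2.
    """
    w = x.T @ y
    nrm = np.linalg.norm(w)
    if nrm == 0:  # target orthogonal to every predictor
        w = np.zeros_like(w)
        w[0] = 1.0
    else:
        w = w / nrm
    scores = x @ w
    tt = scores @ scores
    total = (x**2).sum()
    if tt == 0 or total == 0:
        return scores, w, 0.0
    loadings = x.T @ scores / tt
    explained = float(tt * (loadings @ loadings) / total)
    return scores, w, explained


def _validate_permutations(perms: np.ndarray, n: int) -> np.ndarray:
    perms = np.asarray(perms, dtype=int)
    if perms.ndim != 2 or perms.shape[1] != n:
        raise ValueError(f"permutation rows must have length {n}")
    ref = np.arange(n)
    for row in perms:
        if not np.array_equal(np.sort(row), ref):
            raise ValueError("a supplied row is not a permutation of 0..N-1")
    return perms


def pls1_association(genes: SpatialMapSet, target: np.ndarray,
                     n_perm: int = 1000, permutations: np.ndarray | None = None,
                     seed: int | None = None) -> PLSResult:
    """PLS1 between a region x gene matrix and a target regional map.

    Predictor columns and the target are z-scored over regions.  The
    reported ``r_with_target`` is the Pearson correlation between the
    PLS1 regional scores and the target; ``variance_explained`` is the
    share of predictor-block variance captured by the component.
    Significance uses the add-one permutation rule
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm), permuting the target
    over regions — with the supplied spatial permutation index rows when
    given (spin-test style), uniformly at random otherwise.
    """
    target = np.asarray(target, dtype=float)
    n = genes.region_ids.size
    if target.shape != (n,):
        raise ValueError("target length must match the map set's region count")
    if n < 3:
        raise ValueError("need at least 3 regions")
    x = _zscore_cols(genes.matrix)
    y = _zscore_cols(target[:, None])[:, 0]

    scores, weights, explained = _pls1(x, y)
    r_obs = float(sps.pearsonr(scores, target).statistic)
    if r_obs < 0:  # PLS1 sign is arbitrary; orient the component along the target
        scores, weights, r_obs = -scores, -weights, -r_obs

    if permutations is not None:
        perms = _validate_permutations(permutations, n)
        scheme = "supplied"
        n_perm = perms.shape[0]
    else:
        rng = np.random.default_rng(seed)
        perms = np.vstack([rng.permutation(n) for _ in range(n_perm)])
        scheme = "uniform"
    exceed = 0
    for row in perms:
        yp = y[row]
        s_p, _, _ = _pls1(x, yp)
        r_p = abs(float(sps.pearsonr(s_p, yp).statistic))
        if r_p >= abs(r_obs):
            exceed += 1
    p_perm = (1 + exceed) / (1 + n_perm)
    return PLSResult(
        component_scores=scores, gene_weights=weights, r_with_target=r_obs,
        variance_explained=explained, p_perm=float(p_perm), n_perm=int(n_perm),
        permutation_scheme=scheme, gene_names=list(genes.names),
    )


def bootstrap_gene_zscores(genes: SpatialMapSet, target: np.ndarray,
                           n_boot: int = 1000, seed: int | None = None,
                           top_k: int = 500) -> tuple[pd.DataFrame, list[str]]:
    """Bootstrap gene Z-scores for the PLS1 weights and the top-k export.

    Regions are resampled with replacement; each replicate's weight
    vector is sign-aligned to the original component; Z_g = original
    weight / bootstrap SE.  Returns the per-gene table sorted by |Z|
    (descending) and the top-k symbol list (k capped at the gene count,
    with a warning), ready to paste into an external enrichment service.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    target = np.asarray(target, dtype=float)
    n = genes.region_ids.size
    x = _zscore_cols(genes.matrix)
    y = _zscore_cols(target[:, None])[:, 0]
    _, w0, _ = _pls1(x, y)
    if float(np.corrcoef(x @ w0, y)[0, 1]) < 0:
        w0 = -w0

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, w0.size))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb = _zscore_cols(genes.matrix[idx])
        yb = _zscore_cols(target[idx, None])[:, 0]
        _, wb, _ = _pls1(xb, yb)
        if wb @ w0 < 0:
            wb = -wb
        boot[b] = wb
    se = boot.std(axis=0, ddof=1)
    se = np.where(se == 0, np.finfo(float).tiny, se)
    z = w0 / se
    table = pd.DataFrame({"gene": genes.names, "weight": w0, "se": se, "Z": z})
    table = table.reindex(table["Z"].abs().sort_values(ascending=False).index)
    table = table.reset_index(drop=True)
    k = top_k
    if k > len(table):
        warnings.warn(f"top_k={top_k} exceeds gene count {len(table)}; "
                      "returning all genes", stacklevel=2)
        k = len(table)
    return table, table["gene"].head(k).tolist()


def map_correlation_panel(target: np.ndarray, maps: SpatialMapSet,
                          n_perm: int = 1000, permutations: np.ndarray | None = None,
                          seed: int | None = None, alpha: float = 0.05,
                          method: str = "pearson") -> pd.DataFrame:
    """Correlate a target map against each named map with permutation
    p-values (add-one rule) and Bonferroni adjustment across the panel.

    ``method`` is "pearson" (default) or "spearman".
    """
    target = np.asarray(target, dtype=float)
    n = maps.region_ids.size
    if target.shape != (n,):
        bad = maps.names[0] if maps.names else "<empty>"
        raise ValueError(
            f"target length {target.size} does not match panel regions {n} "
            f"(first map: {bad!r})"
        )
    corr = sps.pearsonr if method == "pearson" else sps.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")

    if permutations is not None:
        perms = _validate_permutations(permutations, n)
        n_perm = perms.shape[0]
    else:
        rng = np.random.default_rng(seed)
        perms = np.vstack([rng.permutation(n) for _ in range(n_perm)])

    rows = []
    for j, name in enumerate(maps.names):
        m = maps.matrix[:, j]
        r_obs = float(corr(target, m).statistic)
        exceed = sum(
            1 for row in perms
            if abs(float(corr(target[row], m).statistic)) >= abs(r_obs)
        )
        p_perm = (1 + exceed) / (1 + n_perm)
        rows.append((name, r_obs, p_perm))
    out = pd.DataFrame(rows, columns=["name", "r", "p_perm"])
    out["p_adj"] = np.minimum(out["p_perm"] * len(out), 1.0)
    out["significant"] = out["p_adj"] < alpha
    return out
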