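"""Normalization, differential expression, clustering and GO enrichment.

The DE statistic is a transparent negative-binomial Wald test: counts are
normalized with median-of-ratios size factors, the per-gene log2 fold
change is log2((mean_B + c)/(mean_A + c)) with pseudo-count c = 0.5, and
the Wald statistic divides it by a delta-method standard error under the
NB variance mu + alpha * mu^2. The dispersion alpha is a gene-wise
method-of-moments estimate floored at the pooled (common) method-of-moments
estimate across all genes; the floor stabilizes the 4-residual-df gene-wise
estimate enough to keep null p-values approximately uniform at 3-vs-3,
without any empirical-Bayes shrinkage. Exact replication of edgeR/DESeq2
output is a non-goal.

Microarray-mode normalization follows the 75th-percentile shift (each
sample's log2 intensities are shifted so its 75th percentile is 0) followed
by a baseline transformation to the per-gene cross-sample median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .synth import ExpressionMatrix

#: pseudo-count added to group means inside the log2 fold change
PSEUDO_COUNT = 0.5


@dataclass(frozen=True)
class EnrichmentResult:
    """One GO term's enrichment statistics."""

    term: str
    term_size: int
    overlap: int
    p: float
    fdr: float
    enriched: bool


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Genes with a zero count in any sample are dropped from factor
    estimation; an all-zero sample is an error.
    """
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValidationError(f"all-zero sample(s): {bad}")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValidationError("no gene has positive counts in every sample; "
                              "cannot estimate size factors")
    log_ref = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_ref, axis=0)
    return np.exp(ratios.median(axis=0))


def normalize_matrix(matrix: ExpressionMatrix, mode: str | None = None) -> ExpressionMatrix:
    """Normalize an expression matrix.

    ``rnaseq``: divide counts by median-of-ratios size factors.
    ``microarray``: shift each sample so its 75th percentile is 0, then
    center each gene on its cross-sample median.
    """
    mode = mode or matrix.mode
    v = matrix.values
    if mode == "rnaseq":
        if not np.allclose(v.to_numpy(), np.round(v.to_numpy())):
            raise ValidationError("rnaseq mode requires integer counts")
        sf = size_factors(v)
        out = v / sf
    elif mode == "microarray":
        shifted = v - v.quantile(0.75, axis=0)
        out = shifted.sub(shifted.median(axis=1), axis=0)
    else:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    return ExpressionMatrix(values=out, design=matrix.design.copy(), mode=mode)


def _mom_dispersion(groups: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Gene-wise and pooled method-of-moments NB dispersions (floored at 0)."""
    num = np.zeros(groups[0].shape[0])
    den = np.zeros_like(num)
    for g in groups:
        n = g.shape[1]
        m = g.mean(axis=1)
        s2 = g.var(axis=1, ddof=1)
        num += (n - 1) * (s2 - m)
        den += (n - 1) * m**2
    genewise = np.maximum(0.0, num / np.maximum(den, 1e-300))
    pooled = max(0.0, float(num.sum() / max(den.sum(), 1e-300)))
    return genewise, pooled


def de_test(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    normalized: bool = False,
) -> pd.DataFrame:
    """NB Wald differential-expression test for ``contrast = (A, B)``.

    log2FC is B relative to A. Returns a DataFrame indexed by gene with
    columns ``base_mean, log2fc, se, stat, p`` (no adjustment applied; see
    :func:`adjust_pvalues` and :func:`deg_table`).
    """
    group_a, group_b = contrast
    for g in contrast:
        if g not in set(matrix.design):
            raise ValidationError(f"contrast group {g!r} absent from design")
    norm = matrix if normalized else normalize_matrix(matrix)
    a = norm.values[norm.samples_in_group(group_a)].to_numpy(dtype=float)
    b = norm.values[norm.samples_in_group(group_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("need >= 2 replicates per group")

    genewise, pooled = _mom_dispersion([a, b])
    alpha = np.maximum(genewise, pooled)
    n_a, n_b = a.shape[1], b.shape[1]
    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    c = PSEUDO_COUNT
    log2fc = np.log2(m_b + c) - np.log2(m_a + c)
    se2 = (
        (m_a + alpha * m_a**2) / (n_a * (m_a + c) ** 2)
        + (m_b + alpha * m_b**2) / (n_b * (m_b + c) ** 2)
    ) / np.log(2) ** 2
    se = np.sqrt(np.maximum(se2, 1e-300))
    stat = log2fc / se
    p = 2.0 * sps.norm.sf(np.abs(stat))
    return pd.DataFrame(
        {
            "base_mean": (m_a + m_b) / 2.0,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "p": p,
        },
        index=norm.values.index,
    )


def adjust_pvalues(p: Sequence[float], method: str = "BH") -> np.ndarray:
    """Step-up FDR adjustment: ``BH`` or ``BY`` (FDR under dependency)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method.upper())
    if key is None:
        raise ValidationError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def deg_table(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    lfc_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
    method: str = "BH",
) -> pd.DataFrame:
    """DE test + FDR adjustment + direction call in one table."""
    table = de_test(matrix, contrast)
    table["fdr"] = adjust_pvalues(table["p"].to_numpy(), method=method)
    up, down = call_degs(table, lfc_threshold, fdr_threshold)
    direction = pd.Series("ns", index=table.index)
    direction[list(up)] = "up"
    direction[list(down)] = "down"
    table["direction"] = direction
    return table


def call_degs(
    records: pd.DataFrame,
    lfc_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
) -> tuple[set[str], set[str]]:
    """Call DEG sets (up, down) at inclusive thresholds.

    up = {log2FC >= lfc and fdr <= threshold};
    down = {log2FC <= -lfc and fdr <= threshold}. Always disjoint.
    """
    if "fdr" not in records.columns:
        raise ValidationError("records must carry an 'fdr' column")
    sig = records["fdr"] <= fdr_threshold
    up = set(records.index[sig & (records["log2fc"] >= lfc_threshold)])
    down = set(records.index[sig & (records["log2fc"] <= -lfc_threshold)])
    return up, down


def cluster_top_genes(
    matrix: ExpressionMatrix,
    n_top: int = 1000,
    k: int = 2,
    method: str = "kmeans",
    seed: int = 0,
) -> pd.Series:
    """Cluster the ``n_top`` genes ranked by cross-sample SD.

    Rows are z-scored before clustering; constant genes (SD = 0) are
    excluded from the ranking, SD ties break lexicographically by gene id.
    k-means uses 10 restarts with a fixed seed; hierarchical clustering uses
    average linkage on 1 - Pearson correlation.
    """
    v = matrix.values
    if n_top > v.shape[0]:
        raise ValidationError(f"n_top={n_top} exceeds {v.shape[0]} genes")
    sd = v.std(axis=1, ddof=1)
    sd = sd[sd > 0]
    # stable sort after ordering by gene id, so SD ties break lexicographically
    order = sd.loc[sorted(sd.index)].sort_values(ascending=False, kind="mergesort")
    top = order.index[: min(n_top, len(order))]
    x = v.loc[top].to_numpy(dtype=float)
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    if method == "kmeans":
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x)
    elif method == "hierarchical":
        corr = np.corrcoef(x)
        dist = 1.0 - corr[np.triu_indices(len(x), 1)]
        link = hierarchy.linkage(np.maximum(dist, 0.0), method="average")
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust") - 1
    else:
        raise ValidationError(f"unknown clustering method {method!r}")
    return pd.Series(labels, index=top, name="cluster")


def go_enrichment(
    query: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    min_mapping: int = 5,
    method: str = "BY",
) -> list[EnrichmentResult]:
    """One-sided hypergeometric (Fisher) GO-term enrichment.

    Terms with fewer than ``min_mapping`` background genes are excluded.
    Adjustment defaults to Benjamini-Yekutieli (FDR under dependency);
    ``enriched`` flags adjusted p <= alpha. Raises if the query is not a
    subset of the background.
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise ValidationError(f"query genes outside background: {sorted(stray)[:5]}")
    term_to_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        if gene not in background:
            continue
        for t in ([terms] if isinstance(terms, str) else terms):
            term_to_genes.setdefault(t, set()).add(gene)

    rows = []
    n_bg, n_query = len(background), len(query)
    for term, genes in sorted(term_to_genes.items()):
        k_term = len(genes)
        if k_term < min_mapping:
            continue
        overlap = len(genes & query)
        p = float(sps.hypergeom.sf(overlap - 1, n_bg, k_term, n_query))
        rows.append((term, k_term, overlap, min(p, 1.0)))
    if not rows:
        return []
    fdr = adjust_pvalues([r[3] for r in rows], method=method)
    return [
        EnrichmentResult(term=t, term_size=k, overlap=o, p=p,
                         fdr=float(q), enriched=bool(q <= alpha))
        for (t, k, o, p), q in zip(rows, fdr)
    ]


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of :func:`go_enrichment` output."""
    return pd.DataFrame(
        [r.__dict__ for r in results],
        columns=["term", "term_size", "overlap", "p", "fdr", "enriched"],
    )
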