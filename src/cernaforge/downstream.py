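"""Gene-set enrichment and group-wise correlation-pattern comparison.

Enrichment uses the hypergeometric upper tail with Benjamini-Hochberg FDR
across terms; a term is significant iff FDR < 0.05 and p < 0.01 (both
thresholds configurable). The correlation-pattern comparison quantifies the
"parallel vs chaotic" contrast between groups through two summary
statistics of the circRNA x mRNA pairwise-correlation matrix: coherence
(mean correlation over defined entries) and the fraction of positive
entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import ExpressionMatrix


@dataclass
class EnrichmentThresholds:
    p_threshold: float = 0.01
    fdr_threshold: float = 0.05


def hypergeom_enrich(
    query: Iterable[str],
    annotation: Mapping[str, set[str]],
    universe: Iterable[str],
    thresholds: EnrichmentThresholds | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the query set.

    For a term with K of N universe genes, and a query of n genes of which
    k are in the term, p = P(X >= k) with X ~ Hypergeom(N, K, n). Terms are
    BH-adjusted and sorted by p.
    """
    thresholds = thresholds or EnrichmentThresholds()
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError(f"query genes outside the universe: {sorted(query - universe)[:5]}")
    n, big_n = len(query), len(universe)
    rows = []
    for term, genes in annotation.items():
        term_genes = genes & universe
        big_k = len(term_genes)
        if big_k == 0:
            continue
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((term, k, big_k, n, big_n, p))
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p_value"])
    if df.empty:
        df["fdr"] = []
        df["significant"] = []
        return df
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["significant"] = (df["fdr"] < thresholds.fdr_threshold) & (
        df["p_value"] < thresholds.p_threshold
    )
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)


@dataclass
class CorrelationPattern:
    """Pairwise circRNA x mRNA correlations within one group of samples."""

    group: str
    matrix: pd.DataFrame  # circRNAs x mRNAs; NaN marks undefined entries
    coherence: float  # mean over defined entries
    frac_positive: float  # fraction of defined entries > 0


def correlation_pattern(
    circ_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    group: str,
    method: str = "pearson",
) -> CorrelationPattern:
    """Correlation of every (circRNA, mRNA) pair over one group's samples.

    Constant expression vectors give undefined (NaN) entries, excluded from
    the coherence and frac_positive summaries. Requires >= 3 samples.
    """
    samples = [s for s in circ_expr.sample_ids if circ_expr.groups[s] == group]
    if len(samples) < 3:
        raise ValueError(f"need >= 3 samples in group {group!r}, have {len(samples)}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    circ = circ_expr.values[samples].to_numpy(dtype=float)
    mrna = mrna_expr.values[samples].to_numpy(dtype=float)
    if method == "spearman":
        circ = stats.rankdata(circ, axis=1)
        mrna = stats.rankdata(mrna, axis=1)
    circ_c = circ - circ.mean(axis=1, keepdims=True)
    mrna_c = mrna - mrna.mean(axis=1, keepdims=True)
    circ_sd = np.sqrt((circ_c**2).sum(axis=1))
    mrna_sd = np.sqrt((mrna_c**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (circ_c @ mrna_c.T) / np.outer(circ_sd, mrna_sd)
    corr[~np.isfinite(corr)] = np.nan
    corr = np.clip(corr, -1.0, 1.0)
    matrix = pd.DataFrame(corr, index=circ_expr.values.index, columns=mrna_expr.values.index)
    defined = matrix.to_numpy()[np.isfinite(matrix.to_numpy())]
    coherence = float(defined.mean()) if defined.size else float("nan")
    frac_positive = float((defined > 0).mean()) if defined.size else float("nan")
    return CorrelationPattern(group, matrix, coherence, frac_positive)


def pattern_divergence(a: CorrelationPattern, b: CorrelationPattern) -> dict:
    """Compare two groups' correlation patterns on the same pair grid.

    Reports coherence and frac_positive differences (a - b) and the Pearson
    correlation between the vectorized matrices over mutually defined pairs.
    """
    if a.matrix.shape != b.matrix.shape or not a.matrix.index.equals(b.matrix.index) \
            or not a.matrix.columns.equals(b.matrix.columns):
        raise ValueError("patterns must share the same pair grid")
    va = a.matrix.to_numpy().ravel()
    vb = b.matrix.to_numpy().ravel()
    both = np.isfinite(va) & np.isfinite(vb)
    if not both.any():
        raise ValueError("no mutually defined correlation entries")
    if va[both].std() == 0 or vb[both].std() == 0:
        matrix_correlation = float("nan")
    else:
        matrix_correlation = float(np.corrcoef(va[both], vb[both])[0, 1])
    return {
        "coherence_diff": a.coherence - b.coherence,
        "frac_positive_diff": a.frac_positive - b.frac_positive,
        "matrix_correlation": matrix_correlation,
        "n_pairs_compared": int(both.sum()),
    }
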