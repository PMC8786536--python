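"""Differential expression/methylation calls and EI/ES classification.

Tumor and normal groups are compared with the unpaired Wilcoxon
rank-sum test. Differential expression requires |log2 fold change| > 1
and Benjamini-Hochberg q < 0.05; differential promoter methylation
requires raw p < 0.05 in either direction with no effect-size cut.
A gene is epigenetically induced (EI) when expression is up while
promoter methylation is down, epigenetically suppressed (ES) when the
reverse holds; candidates are then filtered to those whose promoter
beta and expression are negatively rank-correlated across all samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import OmicsMatrix

EI = "EI"
ES = "ES"
NONE = "none"

UP = "up"
DOWN = "down"


@dataclass
class DifferentialRecord:
    gene_id: str
    mean_tumor: float
    mean_normal: float
    log2_fold_change: float
    delta_beta: float
    p_value: float
    q_value: float
    direction: str


@dataclass
class EpigeneticCall:
    gene_id: str
    expression_direction: str
    methylation_direction: str
    epigenetic_class: str
    spearman_rho: float | None = None
    passes_correlation_filter: bool | None = None


def wilcoxon_rank_sum(
    group_a, group_b, exact_max_n: int = 10
) -> tuple[float, float]:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney) test.

    When both groups have at most ``exact_max_n`` observations the
    permutation distribution of the U statistic is enumerated exactly
    (midranks handle ties; the two-sided p is the probability of a U at
    least as far from n1*n2/2 as observed). Larger samples use the
    normal approximation with tie and continuity corrections.

    Returns (U statistic for group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size <= exact_max_n and b.size <= exact_max_n:
        return _exact_rank_sum(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _exact_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    # Enumerate all C(n, n_a) group assignments of the pooled sample.
    # U is a linear function of the rank sum, so enumerate rank sums of
    # the chosen midranks. Symmetry of the permutation distribution
    # about n_a*n_b/2 makes the deviation-based two-sided p exact.
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    n_a, n_b = a.size, b.size
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    center = n_a * n_b / 2.0
    dev_obs = abs(u_obs - center)
    total = 0
    hits = 0
    min_offset = n_a * (n_a + 1) / 2.0
    for idx in combinations(range(n_a + n_b), n_a):
        u = ranks[list(idx)].sum() - min_offset
        total += 1
        if abs(u - center) >= dev_obs - 1e-9:
            hits += 1
    return u_obs, hits / total


def bh_adjust(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (or bonferroni)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def _rank_sum_matrix(tumor: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Row-wise asymptotic rank-sum p-values (vectorized over genes)."""
    res = stats.mannwhitneyu(
        tumor, normal, alternative="two-sided", method="asymptotic", axis=1
    )
    return np.asarray(res.pvalue, dtype=float)


def call_differential_expression(
    expr: OmicsMatrix,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    pseudocount: float = 1.0,
    fdr_method: str = "fdr_bh",
) -> dict[str, DifferentialRecord]:
    """Wilcoxon + fold-change screen for differential expression.

    log2FC = log2((mean tumor + pseudocount) / (mean normal + pseudocount));
    up requires log2FC > lfc_threshold and q < fdr_threshold (strict),
    down the mirrored condition.
    """
    tumor, normal = expr.tumor.to_numpy(float), expr.normal.to_numpy(float)
    if tumor.shape[1] == 0 or normal.shape[1] == 0:
        raise ValueError("both tumor and normal samples are required")
    mt, mn = tumor.mean(axis=1), normal.mean(axis=1)
    lfc = np.log2((mt + pseudocount) / (mn + pseudocount))
    p = _rank_sum_matrix(tumor, normal)
    q = bh_adjust(p, method=fdr_method)
    records = {}
    for i, gene in enumerate(expr.features):
        if q[i] < fdr_threshold and lfc[i] > lfc_threshold:
            direction = UP
        elif q[i] < fdr_threshold and lfc[i] < -lfc_threshold:
            direction = DOWN
        else:
            direction = NONE
        records[gene] = DifferentialRecord(
            gene, float(mt[i]), float(mn[i]), float(lfc[i]), math.nan,
            float(p[i]), float(q[i]), direction,
        )
    return records


def call_differential_methylation(
    meth: OmicsMatrix, p_threshold: float = 0.05
) -> dict[str, DifferentialRecord]:
    """Wilcoxon screen on promoter betas: raw p < threshold, signed by
    the tumor-minus-normal mean beta difference; no effect-size cut."""
    tumor, normal = meth.tumor.to_numpy(float), meth.normal.to_numpy(float)
    if tumor.shape[1] == 0 or normal.shape[1] == 0:
        raise ValueError("both tumor and normal samples are required")
    mt, mn = tumor.mean(axis=1), normal.mean(axis=1)
    delta = mt - mn
    p = _rank_sum_matrix(tumor, normal)
    q = bh_adjust(p)
    records = {}
    for i, gene in enumerate(meth.features):
        if p[i] < p_threshold and delta[i] > 0:
            direction = UP
        elif p[i] < p_threshold and delta[i] < 0:
            direction = DOWN
        else:
            direction = NONE
        records[gene] = DifferentialRecord(
            gene, float(mt[i]), float(mn[i]), math.nan, float(delta[i]),
            float(p[i]), float(q[i]), direction,
        )
    return records


def classify_ei_es(
    de: dict[str, DifferentialRecord], dm: dict[str, DifferentialRecord]
) -> dict[str, EpigeneticCall]:
    """EI = expression up & methylation down; ES = the reverse.

    Genes missing from either record set, and all other direction
    combinations, are classed ``none``.
    """
    calls = {}
    for gene in sorted(set(de) | set(dm)):
        e_dir = de[gene].direction if gene in de else NONE
        m_dir = dm[gene].direction if gene in dm else NONE
        if e_dir == UP and m_dir == DOWN:
            cls = EI
        elif e_dir == DOWN and m_dir == UP:
            cls = ES
        else:
            cls = NONE
        calls[gene] = EpigeneticCall(gene, e_dir, m_dir, cls)
    return calls


def spearman_correlation(x, y) -> float | None:
    """Spearman rank correlation with midranks; None for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("inputs must share length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def correlation_filter(
    calls: dict[str, EpigeneticCall],
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    rho_threshold: float = 0.0,
) -> dict[str, EpigeneticCall]:
    """Keep EI/ES candidates whose beta-vs-expression Spearman rho,
    computed over all (tumor + normal) shared samples, is strictly
    below ``rho_threshold``."""
    shared = [s for s in expr.samples if s in set(meth.samples)]
    if len(shared) < 3:
        raise ValueError("expression and methylation share fewer than 3 samples")
    kept = {}
    for gene, call in calls.items():
        if call.epigenetic_class == NONE:
            continue
        if gene not in expr.features or gene not in meth.features:
            continue
        rho = spearman_correlation(
            meth.values.loc[gene, shared], expr.values.loc[gene, shared]
        )
        call.spearman_rho = rho
        call.passes_correlation_filter = rho is not None and rho < rho_threshold
        if call.passes_correlation_filter:
            kept[gene] = call
    return kept


def differential_table(
    de: dict[str, DifferentialRecord],
    dm: dict[str, DifferentialRecord],
    calls: dict[str, EpigeneticCall],
) -> pd.DataFrame:
    """Flat per-gene results table (one row per gene in either screen)."""
    rows = []
    for gene in sorted(set(de) | set(dm)):
        call = calls.get(gene)
        rows.append(
            {
                "gene": gene,
                "log2_fc": de[gene].log2_fold_change if gene in de else np.nan,
                "expr_p": de[gene].p_value if gene in de else np.nan,
                "expr_q": de[gene].q_value if gene in de else np.nan,
                "delta_beta": dm[gene].delta_beta if gene in dm else np.nan,
                "meth_p": dm[gene].p_value if gene in dm else np.nan,
                "class": call.epigenetic_class if call else NONE,
                "rho": call.spearman_rho if call else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
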