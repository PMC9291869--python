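"""Differential expression and differential co-expression between sample groups.

Differential expression between affected and unaffected samples is assessed
per gene and per compartment with the Wilcoxon rank-sum (Mann-Whitney U)
test, Bonferroni-corrected over the genes tested within one compartment and
map (the family size is always recorded in the output).

Differential co-expression compares the two groups' Pearson correlation
matrices over the genes of interest.  Matrix equality is tested with the
Steiger chi-square statistic on Fisher-z-transformed correlations,

    chi2 = sum_{i<j} (z1_ij - z2_ij)^2 / (1/(n1-3) + 1/(n2-3)),
    df   = k (k - 1) / 2,

and individual focus-gene pairs are contrasted with the two-sample Fisher
r-to-z test.  Before the pairwise contrasts, pairs whose correlation is not
Bonferroni-significant are filtered out; whether a pair must be significant
in at least one group (default) or in both is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .atlas_io import ExpressionMatrix
from .errors import AnalysisError
from .spatial_map import SampleClassification

__all__ = [
    "DifferentialResult",
    "FisherContrast",
    "CorrelationComparison",
    "rank_sum_test",
    "bonferroni",
    "differential_expression",
    "pearson_matrix",
    "steiger_matrix_test",
    "fisher_z_compare",
    "coexpression_contrast",
]


@dataclass
class DifferentialResult:
    gene: str
    compartment: str
    map_name: str
    n_affected: int
    n_unaffected: int
    rank_sum_U: float
    mean_diff_z: float  # mean z-scored expression, affected - unaffected
    p_raw: float
    p_bonf: float
    m_tests: int
    significant: bool
    testable: bool = True


@dataclass
class FisherContrast:
    gene_a: str
    gene_b: str
    r1: float
    r2: float
    z: float
    p_raw: float
    p_bonf: float
    significant: bool


@dataclass
class CorrelationComparison:
    genes: list[str]
    compartment: str
    map_name: str
    R_affected: np.ndarray
    R_unaffected: np.ndarray
    n1: int
    n2: int
    pair_p_affected: np.ndarray  # Bonferroni-corrected over k(k-1)/2 pairs
    pair_p_unaffected: np.ndarray
    steiger_chi2: float
    steiger_df: int
    steiger_p: float
    filter_rule: str
    m_pairs: int  # Fisher-stage Bonferroni family (number of retained pairs)
    fisher_results: list[FisherContrast] = field(default_factory=list)
    gated_out: bool = False  # Steiger gate enabled and not passed


# ---------------------------------------------------------------------------
# elementary tests


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U for group ``a`` vs ``b`` with a two-sided p-value.

    Exact enumeration when the pooled size is at most 12 and there are no
    ties; otherwise the normal approximation with tie-corrected variance and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise AnalysisError("rank_sum_test: empty group")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: Sequence[float], m: int) -> np.ndarray:
    """min(1, m * p) per entry; ``m`` is the family size (>= number of tests)."""
    p = np.asarray(p, dtype=float)
    if m < p.size:
        raise AnalysisError(f"Bonferroni family size {m} < number of tests {p.size}")
    if p.size and (np.nanmin(p) <= 0 or np.nanmax(p) > 1):
        raise AnalysisError("p-values must lie in (0, 1]")
    return np.minimum(1.0, m * p)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sample comparison of independent correlations via Fisher's z.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-tailed p
    from the standard normal.
    """
    if n1 <= 3 or n2 <= 3:
        raise AnalysisError("fisher_z_compare requires group sizes > 3")
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise AnalysisError("fisher_z_compare requires |r| < 1")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def steiger_matrix_test(
    R1: np.ndarray, n1: int, R2: np.ndarray, n2: int
) -> tuple[float, int, float]:
    """Steiger chi-square test for equality of two correlation matrices.

    Sums squared differences of Fisher-z-transformed off-diagonal
    correlations, scaled by the pooled sampling variance 1/(n1-3) + 1/(n2-3);
    the statistic is referred to chi-square with k(k-1)/2 degrees of freedom.
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    if R1.shape != R2.shape or R1.ndim != 2 or R1.shape[0] != R1.shape[1]:
        raise AnalysisError("correlation matrices must be square and same-shaped")
    if n1 <= 3 or n2 <= 3:
        raise AnalysisError("steiger_matrix_test requires group sizes > 3")
    k = R1.shape[0]
    iu = np.triu_indices(k, 1)
    r1 = R1[iu]
    r2 = R2[iu]
    if np.any(np.abs(r1) >= 1) or np.any(np.abs(r2) >= 1):
        raise AnalysisError("off-diagonal |r| = 1: Fisher z diverges")
    var = 1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    chi2 = float(np.sum((np.arctanh(r1) - np.arctanh(r2)) ** 2) / var)
    df = k * (k - 1) // 2
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


# ---------------------------------------------------------------------------
# group-level analyses


def _group_columns(
    cls: Iterable[SampleClassification], compartment: str
) -> tuple[list[str], list[str]]:
    affected, unaffected = [], []
    for c in cls:
        if c.excluded or c.compartment != compartment:
            continue
        (affected if c.label == "affected" else unaffected).append(c.sample_id)
    return affected, unaffected


def differential_expression(
    expr_z: ExpressionMatrix,
    cls: Iterable[SampleClassification],
    genes: Sequence[str],
    map_name: str,
    compartments: Sequence[str] = ("subcortex", "cortex"),
    alpha: float = 0.05,
) -> list[DifferentialResult]:
    """Rank-sum test per gene and compartment; Bonferroni over the genes tested
    within one compartment x map.

    A compartment with an empty affected or unaffected group yields results
    flagged ``testable = False`` (p-values NaN), never fabricated numbers.
    """
    if expr_z.value_kind != "z_scored":
        raise AnalysisError(
            f"differential_expression expects z_scored input, got {expr_z.value_kind!r}"
        )
    missing = [g for g in genes if g not in expr_z.row_ids]
    if missing:
        raise AnalysisError(f"gene(s) not in matrix: {missing}")
    cls = list(cls)
    col_index = {c: i for i, c in enumerate(expr_z.col_ids)}
    m = len(genes)
    results: list[DifferentialResult] = []
    for compartment in compartments:
        aff_ids, unaff_ids = _group_columns(cls, compartment)
        aff_ids = [s for s in aff_ids if s in col_index]
        unaff_ids = [s for s in unaff_ids if s in col_index]
        ai = [col_index[s] for s in aff_ids]
        ui = [col_index[s] for s in unaff_ids]
        testable = bool(ai) and bool(ui)
        for gene in genes:
            row = expr_z.values[expr_z.row_ids.index(gene)]
            if not testable:
                results.append(
                    DifferentialResult(
                        gene, compartment, map_name, len(ai), len(ui),
                        float("nan"), float("nan"), float("nan"), float("nan"),
                        m, False, testable=False,
                    )
                )
                continue
            a = row[ai]
            b = row[ui]
            U, p_raw = rank_sum_test(a, b)
            p_bonf = float(min(1.0, m * p_raw))
            results.append(
                DifferentialResult(
                    gene, compartment, map_name, len(ai), len(ui),
                    U, float(a.mean() - b.mean()), p_raw, p_bonf, m,
                    bool(p_bonf < alpha),
                )
            )
    return results


def pearson_matrix(
    expr_z: ExpressionMatrix, sample_subset: Sequence[str], genes: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix over a sample subset, with per-pair p-values.

    p-values are two-sided from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees
    of freedom; the diagonal of the p matrix is NaN.
    """
    n = len(sample_subset)
    if n < 4:
        raise AnalysisError(f"pearson_matrix needs >= 4 samples, got {n}")
    sub = expr_z.subset_columns(list(sample_subset)).subset_rows(list(genes))
    sds = sub.values.std(axis=1, ddof=1)
    zero = [g for g, s in zip(genes, sds) if s == 0]
    if zero:
        raise AnalysisError(f"zero-variance gene(s) within subset: {zero}")
    R = np.corrcoef(sub.values)
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    with np.errstate(divide="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - R**2))
    pair_p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(pair_p, np.nan)
    return R, pair_p


def coexpression_contrast(
    expr_z: ExpressionMatrix,
    cls: Iterable[SampleClassification],
    genes: Sequence[str],
    focus_gene: str,
    compartment: str = "subcortex",
    map_name: str = "map",
    filter_rule: str = "either",
    gate_on_steiger: bool = False,
    alpha: float = 0.05,
) -> CorrelationComparison:
    """Compare focus-gene co-expression between affected and unaffected samples.

    Builds both groups' Pearson matrices, runs the Steiger matrix-equality
    test, filters focus-gene pairs by within-group Bonferroni significance
    (``filter_rule``: "either" keeps a pair significant in at least one group,
    "both" requires both), then applies the Fisher r-to-z contrast to the
    retained pairs with a Bonferroni family equal to their number.  With
    ``gate_on_steiger`` the pairwise stage runs only if the matrices differ
    significantly.
    """
    if focus_gene not in genes:
        raise AnalysisError(f"focus gene {focus_gene!r} not among genes {list(genes)}")
    if filter_rule not in ("either", "both"):
        raise AnalysisError(f"unknown filter_rule {filter_rule!r}")
    genes = list(genes)
    aff_ids, unaff_ids = _group_columns(list(cls), compartment)
    cols = set(expr_z.col_ids)
    aff_ids = [s for s in aff_ids if s in cols]
    unaff_ids = [s for s in unaff_ids if s in cols]
    n1, n2 = len(aff_ids), len(unaff_ids)
    R1, p1 = pearson_matrix(expr_z, aff_ids, genes)
    R2, p2 = pearson_matrix(expr_z, unaff_ids, genes)
    k = len(genes)
    n_pairs = k * (k - 1) // 2
    p1c = np.minimum(1.0, n_pairs * p1)
    p2c = np.minimum(1.0, n_pairs * p2)
    chi2, df, steiger_p = steiger_matrix_test(R1, n1, R2, n2)

    comp = CorrelationComparison(
        genes=genes, compartment=compartment, map_name=map_name,
        R_affected=R1, R_unaffected=R2, n1=n1, n2=n2,
        pair_p_affected=p1c, pair_p_unaffected=p2c,
        steiger_chi2=chi2, steiger_df=df, steiger_p=steiger_p,
        filter_rule=filter_rule, m_pairs=0,
    )
    if gate_on_steiger and steiger_p >= alpha:
        comp.gated_out = True
        return comp

    fi = genes.index(focus_gene)
    retained: list[int] = []
    for j in range(k):
        if j == fi:
            continue
        sig1 = p1c[fi, j] < alpha
        sig2 = p2c[fi, j] < alpha
        keep = (sig1 or sig2) if filter_rule == "either" else (sig1 and sig2)
        if keep:
            retained.append(j)
    m = len(retained)
    comp.m_pairs = m
    for j in retained:
        z, p_raw = fisher_z_compare(float(R1[fi, j]), n1, float(R2[fi, j]), n2)
        p_bonf = float(min(1.0, m * p_raw))
        comp.fisher_results.append(
            FisherContrast(
                focus_gene, genes[j], float(R1[fi, j]), float(R2[fi, j]),
                z, p_raw, p_bonf, bool(p_bonf < alpha),
            )
        )
    return comp
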