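"""Representative-probe selection and RNA-seq validation.

Microarray platforms carry several probes per gene; downstream statistics use
one value per gene per sample, so a representative probe must be chosen.  We
pick the probe with the highest mean intensity across all loaded samples
(ties broken by smallest probe id, for determinism) and, when RNA-seq
measurements for a donor subset are available, confirm that the chosen probe
also has the highest Spearman correlation with the gene's RNA-seq values over
shared samples.  A failed confirmation is reported, not fatal: the
intensity-selected probe is still used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .atlas_io import ExpressionMatrix, ProbeGeneMap
from .errors import AnalysisError

__all__ = ["ProbeSelection", "select_probe_by_intensity", "spearman_rho", "validate_selection"]


@dataclass
class ProbeSelection:
    gene_symbol: str
    selected_probe: str
    mean_intensity: float
    rnaseq_rho: dict[str, float] = field(default_factory=dict)  # probe -> Spearman rho
    validated: bool | None = None  # None until validation is attempted
    validation_skipped: str | None = None  # reason, when validation could not run


def select_probe_by_intensity(
    expr: ExpressionMatrix, pmap: ProbeGeneMap, gene: str
) -> ProbeSelection:
    """Pick the gene's probe with maximal mean expression across all samples."""
    try:
        probes = pmap.probes_for(gene)
    except KeyError as exc:
        raise AnalysisError(str(exc)) from exc
    present = [p for p in probes if p in expr.row_ids]
    if not present:
        raise AnalysisError(f"gene {gene!r}: none of its probes are in the matrix")
    means = {p: float(np.mean(expr.row(p))) for p in present}
    best_mean = max(means.values())
    # exact tie -> lexicographically smallest probe id
    best = min(p for p, m in means.items() if m == best_mean)
    return ProbeSelection(gene_symbol=gene, selected_probe=best, mean_intensity=best_mean)


def spearman_rho(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise AnalysisError("spearman_rho needs two equal-length vectors of length >= 3")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise AnalysisError("spearman_rho: non-finite input")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        raise AnalysisError("spearman_rho undefined: zero rank variance")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def validate_selection(
    selection: ProbeSelection,
    expr: ExpressionMatrix,
    rnaseq: ExpressionMatrix,
    pmap: ProbeGeneMap,
    donor_subset: set[str] | None = None,
    sample_to_donor: dict[str, str] | None = None,
) -> ProbeSelection:
    """Fill ``rnaseq_rho`` for every probe of the gene and set ``validated``.

    Matching is by shared sample_id between the microarray and RNA-seq
    matrices.  When ``donor_subset`` is given (with the ``sample_to_donor``
    mapping), shared samples are further restricted to those donors — RNA-seq
    is typically measured for a donor subset only.  Fewer than 3 shared
    samples yields a flagged validation-skipped outcome rather than an error.
    """
    gene = selection.gene_symbol
    shared = [c for c in expr.col_ids if c in set(rnaseq.col_ids)]
    if donor_subset is not None:
        if sample_to_donor is None:
            raise AnalysisError("donor_subset requires a sample_to_donor mapping")
        shared = [c for c in shared if sample_to_donor.get(c) in donor_subset]
    if len(shared) < 3:
        selection.validated = None
        selection.validation_skipped = (
            f"only {len(shared)} shared sample(s) between microarray and RNA-seq"
        )
        warnings.warn(
            f"gene {gene}: RNA-seq validation skipped ({selection.validation_skipped})",
            stacklevel=2,
        )
        return selection

    if gene not in rnaseq.row_ids:
        selection.validated = None
        selection.validation_skipped = "gene absent from RNA-seq matrix"
        warnings.warn(
            f"gene {gene}: RNA-seq validation skipped (no RNA-seq row)", stacklevel=2
        )
        return selection

    rna_sub = rnaseq.subset_columns(shared).row(gene)
    expr_shared = expr.subset_columns(shared)
    probes = [p for p in pmap.probes_for(gene) if p in expr.row_ids]
    rhos: dict[str, float] = {}
    for probe in probes:
        rhos[probe] = spearman_rho(expr_shared.row(probe), rna_sub)
    selection.rnaseq_rho = rhos
    best_rho = max(rhos.values())
    selection.validated = rhos[selection.selected_probe] == best_rho
    if not selection.validated:
        warnings.warn(
            f"gene {gene}: intensity-selected probe {selection.selected_probe} does not "
            f"maximize Spearman rho with RNA-seq ({rhos})",
            stacklevel=2,
        )
    return selection
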