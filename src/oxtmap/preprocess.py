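"""Donor (batch) effect removal and z-normalization of expression values.

Atlas expression pools tissue samples from several postmortem donors; between
donor offsets would masquerade as regional differences.  Per gene we fit the
additive model

    value = grand_mean + donor_offset + residual

with donor offsets constrained to a count-weighted zero sum, and subtract the
fitted offset from every entry.  The least-squares solution is simply
"subtract the donor's mean, add back the row's grand mean", so after
correction every donor's per-gene mean equals the row's grand mean and the
grand mean itself is preserved exactly.

z-normalization then centers and scales each gene across all retained samples
pooled (both compartments, both labels), using the sample standard deviation
(n - 1 denominator).  Normalizing on the pooled set is deliberate: the
affected-vs-unaffected contrast is measured on this common scale.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .atlas_io import ExpressionMatrix
from .errors import AnalysisError, ValidationError

__all__ = ["BatchDesign", "remove_donor_effects", "z_normalize"]


@dataclass
class BatchDesign:
    """sample_id -> donor_id mapping used as the batch factor."""

    sample_to_donor: dict[str, str]

    @property
    def donors(self) -> list[str]:
        return sorted(set(self.sample_to_donor.values()))

    @classmethod
    def from_samples(cls, samples) -> "BatchDesign":
        return cls({s.sample_id: s.donor_id for s in samples})


def remove_donor_effects(expr: ExpressionMatrix, design: BatchDesign) -> ExpressionMatrix:
    """Remove additive per-donor offsets from every row.

    Requires ``value_kind == "log2_intensity"`` (correction is defined on the
    log scale).  A matrix whose columns all come from one donor is returned
    unchanged (there is no between-donor contrast to remove).
    """
    if expr.value_kind != "log2_intensity":
        raise ValidationError(
            f"batch correction expects log2_intensity input, got {expr.value_kind!r}"
        )
    unmapped = [c for c in expr.col_ids if c not in design.sample_to_donor]
    if unmapped:
        raise ValidationError(f"columns with no donor in the design: {unmapped[:5]}")

    donors = [design.sample_to_donor[c] for c in expr.col_ids]
    values = expr.values.copy()
    unique_donors = sorted(set(donors))
    if len(unique_donors) > 1:
        grand = values.mean(axis=1, keepdims=True)
        donor_arr = np.asarray(donors)
        for d in unique_donors:
            cols = donor_arr == d
            donor_mean = values[:, cols].mean(axis=1, keepdims=True)
            values[:, cols] -= donor_mean - grand
    return ExpressionMatrix(list(expr.row_ids), list(expr.col_ids), values, "batch_corrected")


def z_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each row to mean 0, sample sd 1 over all columns."""
    if expr.value_kind != "batch_corrected":
        raise ValidationError(
            f"z-normalization expects batch_corrected input, got {expr.value_kind!r}"
        )
    if expr.values.shape[1] < 2:
        raise AnalysisError("z-normalization needs at least 2 samples")
    mean = expr.values.mean(axis=1, keepdims=True)
    sd = expr.values.std(axis=1, ddof=1, keepdims=True)
    zero = np.where(sd[:, 0] == 0)[0]
    if zero.size:
        names = [expr.row_ids[i] for i in zero]
        raise AnalysisError(f"zero-variance row(s), z-score undefined: {names}")
    values = (expr.values - mean) / sd
    return ExpressionMatrix(list(expr.row_ids), list(expr.col_ids), values, "z_scored")
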