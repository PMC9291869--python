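"""Threshold statistic maps and classify tissue samples in MNI space.

Each tissue sample carries an MNI-152 world coordinate (mm).  The statistic
map's affine maps voxel indices to mm, so a sample is located in voxel space
by applying the inverse affine, and the map value at that continuous location
is obtained by trilinear interpolation over the 8 surrounding voxels.

A sample is "affected" when the interpolated statistic passes the
significance criterion.  Two classification modes are exposed because the
operational order is ambiguous in practice:

* ``interpolate_then_threshold`` (default): interpolate the continuous
  statistic at the sample coordinate, then apply the single alpha criterion.
* ``threshold_then_interpolate``: binarize the map at alpha first, then call
  a sample affected when the interpolated mask value exceeds
  ``membership_cutoff`` (0 means "any overlap with the mask").

For p-value semantics a stored 0 is treated as background/no-data rather than
p = 0, since statistic maps conventionally zero-fill voxels outside the
analysis mask.  Brainstem and cerebellum samples, and samples falling outside
the volume's support, are excluded with an explicit reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas_io import EXCLUDED_COMPARTMENTS, SampleRecord, StatVolume
from .errors import AnalysisError, ValidationError

__all__ = [
    "SampleClassification",
    "threshold_map",
    "trilinear_sample",
    "classify_samples",
    "count_by_group",
]


@dataclass
class SampleClassification:
    sample_id: str
    compartment: str
    label: str | None  # "affected" / "unaffected"; None when excluded
    interp_value: float
    excluded: bool
    excluded_reason: str | None = None


def threshold_map(
    vol: StatVolume, alpha: float = 0.05, score_cutoff: float | None = None
) -> StatVolume:
    """Binarize a statistic map at the significance criterion.

    p_value semantics: voxel is in the mask iff 0 < p < alpha (0 is
    background).  score semantics: voxel is in the mask iff value >
    ``score_cutoff`` (the caller supplies the cutoff equivalent to alpha for
    the map's scale, e.g. 0.95 for a 1-p map).
    """
    if not 0.0 < alpha < 1.0:
        raise AnalysisError(f"alpha must be in (0, 1), got {alpha}")
    if vol.value_semantics == "p_value":
        mask = (vol.grid > 0) & (vol.grid < alpha)
    elif vol.value_semantics == "score":
        if score_cutoff is None:
            raise AnalysisError("score semantics requires an explicit score_cutoff")
        mask = vol.grid > score_cutoff
    else:
        raise AnalysisError(
            f"cannot threshold a volume with semantics {vol.value_semantics!r}"
        )
    return StatVolume(mask.astype(float), vol.affine.copy(), "binary_mask")


def _world_to_voxel(vol: StatVolume, pts_mm: np.ndarray) -> np.ndarray:
    """Map (n, 3) world mm points to continuous 0-based voxel coordinates."""
    inv = vol.inv_affine
    return pts_mm @ inv[:3, :3].T + inv[:3, 3]


def trilinear_interpolate_many(
    vol: StatVolume, pts_mm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of the volume at (n, 3) mm points.

    Returns ``(values, inside)``; points outside the grid's convex support
    (the box spanned by voxel centers) get value 0 and ``inside = False``.
    """
    pts_mm = np.asarray(pts_mm, dtype=float)
    if pts_mm.ndim == 1:
        pts_mm = pts_mm[None, :]
    if pts_mm.shape[1] != 3:
        raise AnalysisError("points must be (n, 3) mm coordinates")
    if not np.all(np.isfinite(pts_mm)):
        raise AnalysisError("non-finite sample coordinate")

    vox = _world_to_voxel(vol, pts_mm)
    shape = np.asarray(vol.grid.shape)
    inside = np.all((vox >= 0) & (vox <= shape - 1), axis=1)

    values = np.zeros(len(vox), dtype=float)
    if inside.any():
        v = vox[inside]
        # lower corner; at the upper face use the last cell with fraction 1
        i0 = np.minimum(np.floor(v).astype(int), shape - 2)
        i0 = np.maximum(i0, 0)
        f = v - i0  # fractional offset in [0, 1] per axis
        g = vol.grid
        x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
        fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
        acc = np.zeros(len(v), dtype=float)
        for dx in (0, 1):
            wx = fx if dx else 1.0 - fx
            for dy in (0, 1):
                wy = fy if dy else 1.0 - fy
                for dz in (0, 1):
                    wz = fz if dz else 1.0 - fz
                    acc += g[x0 + dx, y0 + dy, z0 + dz] * wx * wy * wz
        values[inside] = acc
    return values, inside


def trilinear_sample(vol: StatVolume, mni: Sequence[float]) -> float:
    """Interpolated map value at one MNI mm coordinate (0 outside the volume)."""
    values, _ = trilinear_interpolate_many(vol, np.asarray(mni, dtype=float))
    return float(values[0])


def _passes_alpha(values: np.ndarray, vol: StatVolume, alpha: float,
                  score_cutoff: float | None) -> np.ndarray:
    if vol.value_semantics == "p_value":
        return (values > 0) & (values < alpha)
    if vol.value_semantics == "score":
        if score_cutoff is None:
            raise AnalysisError("score semantics requires an explicit score_cutoff")
        return values > score_cutoff
    raise AnalysisError(
        f"continuous criterion undefined for semantics {vol.value_semantics!r}"
    )


def classify_samples(
    samples: Iterable[SampleRecord],
    vol: StatVolume,
    mode: str = "interpolate_then_threshold",
    alpha: float = 0.05,
    membership_cutoff: float = 0.0,
    score_cutoff: float | None = None,
) -> list[SampleClassification]:
    """Label every sample affected/unaffected (or excluded, with a reason).

    Brainstem and cerebellum samples are excluded a priori; samples outside
    the volume's support are excluded with reason ``outside-volume`` rather
    than silently counted as unaffected.
    """
    if mode not in ("interpolate_then_threshold", "threshold_then_interpolate"):
        raise AnalysisError(f"unknown classification mode {mode!r}")
    samples = list(samples)
    out: list[SampleClassification] = []

    todo_idx = [
        i for i, s in enumerate(samples) if s.compartment not in EXCLUDED_COMPARTMENTS
    ]
    results: dict[int, SampleClassification] = {}
    for i, s in enumerate(samples):
        if s.compartment in EXCLUDED_COMPARTMENTS:
            results[i] = SampleClassification(
                s.sample_id, s.compartment, None, float("nan"), True, s.compartment
            )

    if todo_idx:
        pts = np.array([samples[i].mni for i in todo_idx], dtype=float)
        if mode == "interpolate_then_threshold":
            values, inside = trilinear_interpolate_many(vol, pts)
            affected = _passes_alpha(values, vol, alpha, score_cutoff)
        else:
            mask = threshold_map(vol, alpha=alpha, score_cutoff=score_cutoff)
            values, inside = trilinear_interpolate_many(mask, pts)
            affected = values > membership_cutoff
        for j, i in enumerate(todo_idx):
            s = samples[i]
            if not inside[j]:
                results[i] = SampleClassification(
                    s.sample_id, s.compartment, None, float(values[j]), True,
                    "outside-volume",
                )
            else:
                results[i] = SampleClassification(
                    s.sample_id,
                    s.compartment,
                    "affected" if affected[j] else "unaffected",
                    float(values[j]),
                    False,
                )
    out = [results[i] for i in range(len(samples))]
    assert len(out) == len(samples)
    return out


def count_by_group(classifications: Iterable[SampleClassification]) -> pd.DataFrame:
    """Affected/unaffected counts per compartment (excluded samples not counted)."""
    counts = pd.DataFrame(
        0,
        index=pd.Index(["subcortex", "cortex"], name="compartment"),
        columns=["affected", "unaffected"],
    )
    for c in classifications:
        if c.excluded:
            continue
        if c.compartment not in counts.index:
            raise ValidationError(
                f"non-excluded sample {c.sample_id!r} in compartment {c.compartment!r}"
            )
        counts.loc[c.compartment, c.label] += 1
    return counts


def classification_table(classifications: Iterable[SampleClassification]) -> pd.DataFrame:
    """Audit table: one row per sample with interpolated value and label."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "compartment": c.compartment,
                "interp_value": c.interp_value,
                "label": c.label if c.label is not None else "",
                "excluded_reason": c.excluded_reason if c.excluded else "",
            }
            for c in classifications
        ],
        columns=["sample_id", "compartment", "interp_value", "label", "excluded_reason"],
    )
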