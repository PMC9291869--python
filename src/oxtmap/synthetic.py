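"""Synthetic atlas-scale test data with known ground truth.

Generates everything the pipeline consumes — a multi-donor sample annotation
table, a probe x sample expression matrix with a probe-to-gene map, an
RNA-seq companion matrix for a donor subset, and a p-statistic NIfTI volume
containing suprathreshold clusters — from a single seed, so every stage of
the analysis can be exercised and checked against planted truth without
downloading any atlas or imaging data.

Geometry.  The volume is a centred grid (default 40 x 48 x 40 voxels at 4 mm)
whose affine is diagonal scaling plus a centring translation, so world mm
coordinates are symmetric about the origin.  Compartments are axis-aligned
boxes: a central "subcortex" box, a surrounding "cortex" shell, and a ventral
box for brainstem/cerebellum samples (which the analysis must exclude).
"Affected" regions are spheres in mm space — the simplest geometry with a
closed-form membership oracle.  Samples are placed at least
``boundary_margin_mm`` away from every sphere boundary, so trilinear
interpolation of the p-volume agrees exactly with point-in-sphere membership
and planted affected counts are exact.

Expression.  Per gene and sample: baseline + additive donor offset
(N(0, donor_offset_sd)) + planted affected-region shift + noise.  Planted
effect sizes ``effect_z`` are expressed in post-normalization z units; the
generator converts them to raw shifts analytically, accounting for the
variance the shift itself adds and for the selected probe's measurement
noise.  Planted co-expression is induced by correlating the noise of a gene
pair within affected samples at the requested Pearson r.  Each gene gets
``probes_per_gene`` probes (gene signal plus probe noise); one designated
probe has both the highest mean intensity and the lowest noise, so
intensity-based selection and RNA-seq validation should both recover it.
The RNA-seq companion is a monotone transform of the gene signal for the
first two donors' samples.  The last donor is tagged female so the male-only
analysis path (dropping one donor) is testable.

Default sample counts mirror the scale of a six-donor human atlas analysis:
986 subcortical (177 affected), 1762 cortical (147 affected), 150 excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas_io import (
    ExpressionMatrix,
    ProbeGeneMap,
    SampleRecord,
    StatVolume,
    write_expression,
    write_probe_map,
    write_samples,
    write_stat_volume,
)
from .errors import ValidationError

__all__ = ["Cluster", "SyntheticConfig", "SyntheticDataset", "generate_dataset",
           "truth_report", "write_dataset"]

DEFAULT_GENES = ("OXT", "OXTR", "CD38", "AVPR1A", "AVPR1B", "AVPR2")

_BASELINES = {"OXT": 7.5, "OXTR": 5.5, "CD38": 6.5,
              "AVPR1A": 5.0, "AVPR1B": 4.5, "AVPR2": 4.0}

_ACRONYMS = {
    "subcortex": ("GPi", "LHA", "VMH", "AHA", "DBv", "nbM", "PrOR", "LHT"),
    "cortex": ("FroL", "ParL", "TemL", "OccL", "CgG", "Ins"),
    "brainstem": ("PnR", "MedR"),
    "cerebellum": ("CbCx", "DtN"),
}

# compartment sampling boxes, mm half-widths (symmetric about the origin)
_SUBCORTEX_BOX = np.array([32.0, 32.0, 24.0])
_CORTEX_BOX = np.array([70.0, 86.0, 64.0])
_CORTEX_INNER_CLEARANCE = 8.0  # cortex shell starts this far outside the subcortex box
_EXCLUDED_BOX_LO = np.array([-20.0, -20.0, -72.0])
_EXCLUDED_BOX_HI = np.array([20.0, 20.0, -44.0])
_SUPPORT_INFLATE_MM = 8.0  # brain support = compartment boxes inflated by this much


@dataclass(frozen=True)
class Cluster:
    """A spherical affected region in world mm coordinates."""

    center: tuple[float, float, float]
    radius_mm: float
    compartment: str  # "subcortex" or "cortex"


def _default_clusters() -> list[Cluster]:
    return [
        Cluster(center=(12.0, 8.0, 0.0), radius_mm=14.0, compartment="subcortex"),
        Cluster(center=(48.0, 48.0, 36.0), radius_mm=16.0, compartment="cortex"),
    ]


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_donors: int = 6
    volume_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 4.0
    n_subcortical: int = 986
    n_cortical: int = 1762
    n_excluded: int = 150
    n_subcortical_affected: int = 177
    n_cortical_affected: int = 147
    clusters: list[Cluster] = field(default_factory=_default_clusters)
    genes: tuple[str, ...] = DEFAULT_GENES
    probes_per_gene: int = 3
    effect_z: dict[str, float] = field(default_factory=dict)  # z-unit shift in clusters
    coexpr_effect: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    donor_offset_sd: float = 0.5
    noise_sd: float = 1.0
    probe_noise_sd: float = 0.5
    selected_probe_noise_sd: float = 0.15
    intensity_boost: float = 1.0
    rnaseq_noise_sd: float = 0.05
    p_floor: float = 0.01
    # sample-to-sphere-boundary clearance; None -> sqrt(3) * voxel_size, the
    # largest distance from a point to one of its 8 interpolation neighbours,
    # which makes interpolated membership equal exact point-in-sphere membership
    boundary_margin_mm: float | None = None

    @property
    def margin_mm(self) -> float:
        if self.boundary_margin_mm is not None:
            return self.boundary_margin_mm
        return float(np.sqrt(3.0) * self.voxel_size_mm)

    def validate(self) -> None:
        shape = np.asarray(self.volume_shape)
        half_extent = self.voxel_size_mm * (shape - 1) / 2.0
        for cl in self.clusters:
            if cl.radius_mm <= 0:
                raise ValidationError(f"cluster radius must be > 0, got {cl.radius_mm}")
            if cl.compartment not in ("subcortex", "cortex"):
                raise ValidationError(f"cluster compartment {cl.compartment!r} invalid")
            c = np.asarray(cl.center)
            if np.any(np.abs(c) + cl.radius_mm > half_extent):
                raise ValidationError(f"cluster {cl} extends outside the volume")
            if cl.radius_mm <= self.margin_mm:
                raise ValidationError(
                    f"cluster radius {cl.radius_mm} must exceed the boundary margin"
                )
        for (pair, r) in self.coexpr_effect:
            if not abs(r) < 1:
                raise ValidationError(f"target correlation |r| must be < 1, got {r}")
            for g in pair:
                if g not in self.genes:
                    raise ValidationError(f"co-expression gene {g!r} not in gene list")
        for g in self.effect_z:
            if g not in self.genes:
                raise ValidationError(f"effect gene {g!r} not in gene list")
        for count in (self.n_subcortical, self.n_cortical, self.n_excluded,
                      self.n_subcortical_affected, self.n_cortical_affected):
            if count < 0:
                raise ValidationError("sample counts must be >= 0")
        if self.n_subcortical_affected > self.n_subcortical:
            raise ValidationError("affected count exceeds subcortical total")
        if self.n_cortical_affected > self.n_cortical:
            raise ValidationError("affected count exceeds cortical total")
        if not 0 < self.p_floor < 0.05:
            raise ValidationError("p_floor must lie in (0, 0.05)")
        if self.n_donors < 1:
            raise ValidationError("need at least one donor")
        if self.n_subcortical_affected and not any(
            c.compartment == "subcortex" for c in self.clusters
        ):
            raise ValidationError("subcortical affected samples need a subcortex cluster")
        if self.n_cortical_affected and not any(
            c.compartment == "cortex" for c in self.clusters
        ):
            raise ValidationError("cortical affected samples need a cortex cluster")


@dataclass
class SyntheticTruth:
    """Ground truth: per-sample membership and per-gene planted effects."""

    samples: pd.DataFrame  # sample_id, donor_id, compartment, in_cluster
    gene_effects: pd.DataFrame  # gene, effect_z, raw_shift, baseline
    coexpr: list[tuple[tuple[str, str], float]]
    female_donor: str
    designated_probes: dict[str, str]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    samples: list[SampleRecord]
    expression: ExpressionMatrix  # probe x sample, log2_intensity
    probe_map: ProbeGeneMap
    rnaseq: ExpressionMatrix  # gene x sample (donor subset), rnaseq
    stat_volume: StatVolume  # p_value semantics
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# geometry helpers


def _affine(cfg: SyntheticConfig) -> np.ndarray:
    v = cfg.voxel_size_mm
    shape = np.asarray(cfg.volume_shape)
    aff = np.diag([v, v, v, 1.0])
    aff[:3, 3] = -v * (shape - 1) / 2.0
    return aff


def _in_any_cluster(pts: np.ndarray, clusters: Sequence[Cluster], pad: float) -> np.ndarray:
    """True where a point lies within radius+pad of any cluster centre."""
    hit = np.zeros(len(pts), dtype=bool)
    for cl in clusters:
        d = np.linalg.norm(pts - np.asarray(cl.center), axis=1)
        hit |= d <= cl.radius_mm + pad
    return hit


def _sample_in_sphere(rng: np.random.Generator, center, radius: float, n: int) -> np.ndarray:
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return np.asarray(center) + direction * r


def _sample_in_box(rng: np.random.Generator, lo: np.ndarray, hi: np.ndarray,
                   n: int, accept) -> np.ndarray:
    """Rejection-sample n points uniform in [lo, hi] satisfying ``accept``."""
    out = np.empty((0, 3))
    while len(out) < n:
        batch = rng.uniform(lo, hi, size=(max(4 * (n - len(out)), 64), 3))
        ok = accept(batch)
        out = np.vstack([out, batch[ok]])
    return out[:n]


def _place_compartment(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    compartment: str,
    n_total: int,
    n_affected: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates (n, 3) and boolean in-cluster flags for one compartment."""
    margin = cfg.margin_mm
    own = [c for c in cfg.clusters if c.compartment == compartment]
    coords = []
    flags = []
    if n_affected:
        per = np.full(len(own), n_affected // len(own))
        per[: n_affected % len(own)] += 1
        for cl, k in zip(own, per):
            coords.append(_sample_in_sphere(rng, cl.center, cl.radius_mm - margin, int(k)))
            flags.append(np.ones(int(k), dtype=bool))
    n_bg = n_total - n_affected
    if n_bg:
        if compartment == "subcortex":
            lo, hi = -_SUBCORTEX_BOX, _SUBCORTEX_BOX

            def accept(p):
                return ~_in_any_cluster(p, cfg.clusters, margin)

        else:  # cortex shell: outer box minus inflated subcortex box
            lo, hi = -_CORTEX_BOX, _CORTEX_BOX
            inner = _SUBCORTEX_BOX + _CORTEX_INNER_CLEARANCE

            def accept(p):
                inside_inner = np.all(np.abs(p) <= inner, axis=1)
                return ~inside_inner & ~_in_any_cluster(p, cfg.clusters, margin)

        coords.append(_sample_in_box(rng, lo, hi, n_bg, accept))
        flags.append(np.zeros(n_bg, dtype=bool))
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=bool)
    return np.vstack(coords), np.concatenate(flags)


def _build_volume(cfg: SyntheticConfig) -> StatVolume:
    """p-statistic volume: p_floor inside clusters, 1 in the brain support, 0 outside."""
    shape = cfg.volume_shape
    aff = _affine(cfg)
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    centers = idx.reshape(-1, 3) @ aff[:3, :3].T + aff[:3, 3]

    pad = _SUPPORT_INFLATE_MM
    support = np.all(np.abs(centers) <= _SUBCORTEX_BOX + pad, axis=1)
    support |= np.all(np.abs(centers) <= _CORTEX_BOX + pad, axis=1) & ~np.all(
        np.abs(centers) <= _SUBCORTEX_BOX, axis=1
    )
    support |= np.all(
        (centers >= _EXCLUDED_BOX_LO - pad) & (centers <= _EXCLUDED_BOX_HI + pad), axis=1
    )
    grid = np.where(support, 1.0, 0.0)
    in_cluster = _in_any_cluster(centers, cfg.clusters, 0.0)
    grid[in_cluster] = cfg.p_floor
    return StatVolume(grid.reshape(shape), aff, "p_value")


# ---------------------------------------------------------------------------
# expression model


def _raw_shift(cfg: SyntheticConfig, effect_z: float, frac_in: float) -> float:
    """Convert a z-unit planted effect into a raw expression shift.

    The shift itself inflates the pooled variance the z-normalization divides
    by; solving  delta / sqrt(sigma^2 + p(1-p) delta^2) = effect_z  for delta
    (sigma^2 = gene noise + selected-probe noise) keeps effect_z on the
    post-normalization scale.
    """
    if effect_z == 0:
        return 0.0
    sigma2 = cfg.noise_sd**2 + cfg.selected_probe_noise_sd**2
    denom = 1.0 - frac_in * (1.0 - frac_in) * effect_z**2
    if denom <= 0:
        raise ValidationError(
            f"effect_z = {effect_z} is unattainable at in-cluster fraction {frac_in:.3f}"
        )
    return float(effect_z * np.sqrt(sigma2 / denom))


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the full synthetic bundle; all randomness flows from cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- sample placement -------------------------------------------------
    sub_xyz, sub_in = _place_compartment(
        rng, cfg, "subcortex", cfg.n_subcortical, cfg.n_subcortical_affected
    )
    cor_xyz, cor_in = _place_compartment(
        rng, cfg, "cortex", cfg.n_cortical, cfg.n_cortical_affected
    )
    n_bs = cfg.n_excluded // 2
    n_cb = cfg.n_excluded - n_bs
    exc_xyz = rng.uniform(_EXCLUDED_BOX_LO, _EXCLUDED_BOX_HI, size=(cfg.n_excluded, 3))

    compartments = (
        ["subcortex"] * cfg.n_subcortical
        + ["cortex"] * cfg.n_cortical
        + ["brainstem"] * n_bs
        + ["cerebellum"] * n_cb
    )
    xyz = np.vstack([sub_xyz, cor_xyz, exc_xyz])
    in_cluster = np.concatenate(
        [sub_in, cor_in, np.zeros(cfg.n_excluded, dtype=bool)]
    )
    n_samples = len(compartments)

    donors = [f"D{i + 1}" for i in range(cfg.n_donors)]
    donor_of = rng.integers(0, cfg.n_donors, size=n_samples)
    sample_ids = [f"S{i + 1:05d}" for i in range(n_samples)]

    records: list[SampleRecord] = []
    for i in range(n_samples):
        comp = compartments[i]
        acro = str(rng.choice(_ACRONYMS[comp]))
        records.append(
            SampleRecord(
                sample_id=sample_ids[i],
                donor_id=donors[donor_of[i]],
                structure_acronym=acro,
                structure_name=f"synthetic {comp} structure {acro}",
                compartment=comp,
                mni=tuple(float(v) for v in xyz[i]),
            )
        )

    # --- gene-level signal -------------------------------------------------
    genes = list(cfg.genes)
    n_genes = len(genes)
    retained = np.array([c in ("subcortex", "cortex") for c in compartments])
    frac_in = (in_cluster & retained).sum() / max(1, retained.sum())

    baselines = np.array([_BASELINES.get(g, 6.0) for g in genes])
    donor_offsets = rng.normal(0.0, cfg.donor_offset_sd, size=(n_genes, cfg.n_donors))
    noise = rng.normal(0.0, cfg.noise_sd, size=(n_genes, n_samples))

    # plant pairwise co-expression inside clusters by mixing the pair's noise;
    # the mixing coefficient is raised analytically so that r_target is hit on
    # the measured scale, i.e. after the selected probe's noise attenuates the
    # gene-level correlation by noise_sd^2 / (noise_sd^2 + probe_sd^2)
    atten = cfg.noise_sd**2 / (cfg.noise_sd**2 + cfg.selected_probe_noise_sd**2)
    for (g1, g2), r in cfg.coexpr_effect:
        r_plant = r / atten
        if not abs(r_plant) < 1:
            raise ValidationError(
                f"target correlation {r} for {g1}-{g2} is unattainable given the "
                f"selected probe noise (needs gene-level r = {r_plant:.3f})"
            )
        i1, i2 = genes.index(g1), genes.index(g2)
        cols = in_cluster
        noise[i2, cols] = (
            r_plant * noise[i1, cols] + np.sqrt(1 - r_plant**2) * noise[i2, cols]
        )

    shifts = np.array([_raw_shift(cfg, cfg.effect_z.get(g, 0.0), frac_in) for g in genes])
    signal = (
        baselines[:, None]
        + donor_offsets[:, donor_of]
        + shifts[:, None] * in_cluster[None, :]
        + noise
    )

    # --- probes ------------------------------------------------------------
    probe_ids: list[str] = []
    probe_to_gene: dict[str, str] = {}
    designated: dict[str, str] = {}
    probe_values = np.empty((n_genes * cfg.probes_per_gene, n_samples))
    row = 0
    for gi, g in enumerate(genes):
        designated_idx = 1 if cfg.probes_per_gene >= 2 else 0
        for j in range(cfg.probes_per_gene):
            pid = f"{g}_p{j + 1}"
            probe_ids.append(pid)
            probe_to_gene[pid] = g
            if j == designated_idx:
                designated[g] = pid
                sd, boost = cfg.selected_probe_noise_sd, cfg.intensity_boost
            else:
                sd, boost = cfg.probe_noise_sd, 0.0
            probe_values[row] = signal[gi] + boost + rng.normal(0.0, sd, size=n_samples)
            row += 1
    expression = ExpressionMatrix(probe_ids, sample_ids, probe_values, "log2_intensity")

    # --- RNA-seq companion (first two donors, monotone transform of signal) -
    rnaseq_donors = set(donors[: min(2, cfg.n_donors)])
    rna_cols = [i for i in range(n_samples) if donors[donor_of[i]] in rnaseq_donors]
    rna_values = 2.0 ** (0.5 * signal[:, rna_cols]) + rng.normal(
        0.0, cfg.rnaseq_noise_sd, size=(n_genes, len(rna_cols))
    )
    rnaseq = ExpressionMatrix(
        genes, [sample_ids[i] for i in rna_cols], rna_values, "rnaseq"
    )

    vol = _build_volume(cfg)

    truth = SyntheticTruth(
        samples=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "donor_id": [donors[d] for d in donor_of],
                "compartment": compartments,
                "in_cluster": in_cluster,
            }
        ),
        gene_effects=pd.DataFrame(
            {
                "gene": genes,
                "effect_z": [cfg.effect_z.get(g, 0.0) for g in genes],
                "raw_shift": shifts,
                "baseline": baselines,
            }
        ),
        coexpr=list(cfg.coexpr_effect),
        female_donor=donors[-1],
        designated_probes=designated,
    )
    return SyntheticDataset(cfg, records, expression, ProbeGeneMap(probe_to_gene),
                            rnaseq, vol, truth)


def truth_report(truth: SyntheticTruth) -> dict[str, pd.DataFrame]:
    """Ground-truth tables for test harnesses (lossless round-trip via TSV)."""
    return {
        "samples": truth.samples.copy(),
        "genes": truth.gene_effects.copy(),
        "coexpr": pd.DataFrame(
            [
                {"gene_a": a, "gene_b": b, "r_target": r}
                for (a, b), r in truth.coexpr
            ],
            columns=["gene_a", "gene_b", "r_target"],
        ),
    }


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in exactly the formats atlas_io reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": out_dir / "samples.csv",
        "expression": out_dir / "expression.tsv",
        "probe_map": out_dir / "probe_map.tsv",
        "rnaseq": out_dir / "rnaseq.tsv",
        "stat_map": out_dir / "stat_map.nii.gz",
        "truth_samples": out_dir / "truth_samples.tsv",
        "truth_genes": out_dir / "truth_genes.tsv",
        "truth_coexpr": out_dir / "truth_coexpr.tsv",
    }
    write_samples(ds.samples, paths["samples"])
    write_expression(ds.expression, paths["expression"])
    write_probe_map(ds.probe_map, paths["probe_map"])
    write_expression(ds.rnaseq, paths["rnaseq"])
    write_stat_volume(ds.stat_volume, paths["stat_map"])
    report = truth_report(ds.truth)
    report["samples"].to_csv(paths["truth_samples"], sep="\t", index=False)
    report["genes"].to_csv(paths["truth_genes"], sep="\t", index=False)
    report["coexpr"].to_csv(paths["truth_coexpr"], sep="\t", index=False)
    return paths
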