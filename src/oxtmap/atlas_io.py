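"""Readers and writers for atlas-style tabular inputs and NIfTI statistic volumes.

This module does no statistics.  It loads the four kinds of input the
analysis needs — a sample annotation table (one row per tissue sample with an
MNI-152 coordinate), a probe x sample expression matrix, a probe-to-gene
annotation table, and a volumetric statistic map — validates their invariants,
and writes the result tables the pipeline produces.

Sample tables are delimiter-separated text with a header row; the delimiter is
auto-detected among comma and tab.  Volumes are NIfTI-1, read through nibabel;
the 4x4 affine is the single source of truth for the voxel-to-mm mapping.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import LoadError, ValidationError

COMPARTMENTS = ("cortex", "subcortex", "brainstem", "cerebellum")
#: compartments dropped from every analysis
EXCLUDED_COMPARTMENTS = ("brainstem", "cerebellum")

VALUE_KINDS = ("log2_intensity", "rnaseq", "batch_corrected", "z_scored")
VALUE_SEMANTICS = ("p_value", "score", "binary_mask")


@dataclass(frozen=True)
class SampleRecord:
    """One tissue sample: donor, anatomical labels, compartment, MNI coordinate (mm)."""

    sample_id: str
    donor_id: str
    structure_acronym: str
    structure_name: str
    compartment: str
    mni: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: compartment {self.compartment!r} "
                f"not one of {COMPARTMENTS}"
            )
        if len(self.mni) != 3 or not all(math.isfinite(c) for c in self.mni):
            raise ValidationError(
                f"sample {self.sample_id!r}: non-finite MNI coordinate {self.mni}"
            )


@dataclass
class ExpressionMatrix:
    """Rows (probes or genes) x columns (samples) matrix of expression values.

    ``value_kind`` tracks provenance through the pipeline:
    log2_intensity -> batch_corrected -> z_scored (rnaseq for sequencing data).
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    value_kind: str = "log2_intensity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} col ids"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValidationError("duplicate row identifiers")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValidationError("duplicate column identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite entries")

    # -- convenience accessors -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, row_id: str) -> np.ndarray:
        try:
            return self.values[self.row_ids.index(row_id)]
        except ValueError:
            raise KeyError(f"row {row_id!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def subset_columns(self, col_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.col_ids.index(c) for c in col_ids]
        return ExpressionMatrix(
            list(self.row_ids), list(col_ids), self.values[:, idx], self.value_kind
        )

    def subset_rows(self, row_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.row_ids.index(r) for r in row_ids]
        return ExpressionMatrix(
            list(row_ids), list(self.col_ids), self.values[idx, :], self.value_kind
        )


@dataclass
class ProbeGeneMap:
    """Many-to-one mapping from microarray probes to gene symbols."""

    probe_to_gene: dict[str, str]

    def genes(self) -> list[str]:
        return sorted(set(self.probe_to_gene.values()))

    def probes_for(self, gene: str) -> list[str]:
        probes = sorted(p for p, g in self.probe_to_gene.items() if g == gene)
        if not probes:
            raise KeyError(f"gene {gene!r} has no probes in the map")
        return probes


@dataclass
class StatVolume:
    """3-D scalar grid with a 4x4 affine mapping (i, j, k, 1) voxel indices to MNI mm.

    ``value_semantics`` declares the voxel polarity: ``p_value`` (small is
    significant, 0 is background/no-data), ``score`` (large is significant) or
    ``binary_mask``.
    """

    grid: np.ndarray
    affine: np.ndarray
    value_semantics: str = "p_value"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise ValidationError(f"volume must be 3-D, got {self.grid.ndim}-D")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValidationError("affine is singular (not invertible)")
        if self.value_semantics not in VALUE_SEMANTICS:
            raise ValidationError(f"unknown value_semantics {self.value_semantics!r}")
        finite = self.grid[np.isfinite(self.grid)]
        if self.value_semantics == "p_value":
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValidationError("p_value volume has entries outside [0, 1]")
        elif self.value_semantics == "binary_mask":
            if finite.size and not np.isin(finite, (0.0, 1.0)).all():
                raise ValidationError("binary_mask volume has entries outside {0, 1}")

    @property
    def inv_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)


# ---------------------------------------------------------------------------
# readers


def _sniff_sep(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


_SAMPLE_COL_ALIASES = {
    "sample_id": ("sample_id", "well_id"),
    "donor_id": ("donor_id", "donor"),
    "structure_acronym": ("structure_acronym", "acronym"),
    "structure_name": ("structure_name",),
    "compartment": ("compartment",),
    "mni_x": ("mni_x",),
    "mni_y": ("mni_y",),
    "mni_z": ("mni_z",),
}


def read_samples(
    path: str | Path,
    compartment_lookup: Mapping[str, str] | None = None,
) -> list[SampleRecord]:
    """Load a sample annotation table into a list of :class:`SampleRecord`.

    The compartment is taken from an explicit ``compartment`` column when
    present; otherwise each ``structure_acronym`` is resolved through
    ``compartment_lookup``.  Row order is preserved and no row is silently
    dropped.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"sample table not found: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)

    cols: dict[str, str] = {}
    for canonical, aliases in _SAMPLE_COL_ALIASES.items():
        found = next((a for a in aliases if a in df.columns), None)
        if found is not None:
            cols[canonical] = found
    required = ("sample_id", "donor_id", "structure_acronym", "mni_x", "mni_y", "mni_z")
    missing = [c for c in required if c not in cols]
    if missing:
        raise LoadError(f"sample table {path} is missing required column(s): {missing}")

    have_compartment = "compartment" in cols
    if not have_compartment and compartment_lookup is None:
        raise LoadError(
            f"sample table {path} has no 'compartment' column and no lookup was given"
        )

    records: list[SampleRecord] = []
    unresolved: list[str] = []
    for _, row in df.iterrows():
        acro = str(row[cols["structure_acronym"]])
        if have_compartment:
            compartment = str(row[cols["compartment"]])
        else:
            compartment = compartment_lookup.get(acro)  # type: ignore[union-attr]
            if compartment is None:
                unresolved.append(acro)
                continue
        try:
            mni = tuple(float(row[cols[f"mni_{ax}"]]) for ax in "xyz")
        except (TypeError, ValueError) as exc:
            raise LoadError(
                f"sample {row[cols['sample_id']]!r}: non-numeric MNI coordinate"
            ) from exc
        if not all(math.isfinite(c) for c in mni):
            raise LoadError(
                f"sample {row[cols['sample_id']]!r}: non-finite MNI coordinate {mni}"
            )
        name = str(row[cols["structure_name"]]) if "structure_name" in cols else acro
        try:
            records.append(
                SampleRecord(
                    sample_id=str(row[cols["sample_id"]]),
                    donor_id=str(row[cols["donor_id"]]),
                    structure_acronym=acro,
                    structure_name=name,
                    compartment=compartment,
                    mni=mni,  # type: ignore[arg-type]
                )
            )
        except ValidationError as exc:
            raise LoadError(str(exc)) from exc
    if unresolved:
        raise LoadError(
            "structure acronym(s) not resolvable to a compartment: "
            + ", ".join(sorted(set(unresolved)))
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise LoadError(f"duplicate sample_id(s): {dupes}")
    return records


def read_expression(path: str | Path, value_kind: str = "log2_intensity") -> ExpressionMatrix:
    """Load a rectangular numeric table (row ids in the first column)."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"expression table not found: {path}")
    try:
        df = pd.read_csv(
            path, sep=_sniff_sep(path), index_col=0, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise LoadError(f"malformed expression table {path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise LoadError(f"duplicate row id(s) in {path}: {dupes}")
    if df.columns.has_duplicates:
        raise LoadError(f"duplicate column id(s) in {path}")
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise LoadError(f"non-numeric cells in expression table {path}")
    try:
        return ExpressionMatrix(
            [str(r) for r in df.index],
            [str(c) for c in df.columns],
            values.astype(float),
            value_kind,
        )
    except ValidationError as exc:
        raise LoadError(f"{path}: {exc}") from exc


def read_probe_map(path: str | Path) -> ProbeGeneMap:
    """Load a probe -> gene annotation table (columns probe_id, gene_symbol)."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"probe map not found: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    for col in ("probe_id", "gene_symbol"):
        if col not in df.columns:
            raise LoadError(f"probe map {path} is missing column {col!r}")
    mapping: dict[str, str] = {}
    for probe, gene in zip(df["probe_id"], df["gene_symbol"]):
        if probe in mapping and mapping[probe] != gene:
            raise LoadError(f"probe {probe!r} annotated to multiple genes")
        mapping[str(probe)] = str(gene)
    return ProbeGeneMap(mapping)


def read_compartment_lookup(path: str | Path) -> dict[str, str]:
    """Load an acronym -> compartment lookup table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    for col in ("structure_acronym", "compartment"):
        if col not in df.columns:
            raise LoadError(f"lookup table {path} is missing column {col!r}")
    return dict(zip(df["structure_acronym"], df["compartment"]))


def read_stat_volume(path: str | Path, value_semantics: str) -> StatVolume:
    """Load a 3-D NIfTI-1 statistic map.

    The file does not self-describe its polarity, so the caller declares
    ``value_semantics`` (``p_value``, ``score`` or ``binary_mask``).
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"statistic map not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise LoadError(f"statistic map {path} is {data.ndim}-D; a 3-D volume is required")
    try:
        return StatVolume(data, np.asarray(img.affine, dtype=float), value_semantics)
    except ValidationError as exc:
        raise LoadError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# writers


def write_samples(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "donor_id": r.donor_id,
            "structure_acronym": r.structure_acronym,
            "structure_name": r.structure_name,
            "compartment": r.compartment,
            "mni_x": r.mni[0],
            "mni_y": r.mni[1],
            "mni_z": r.mni[2],
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "donor_id",
            "structure_acronym",
            "structure_name",
            "compartment",
            "mni_x",
            "mni_y",
            "mni_z",
        ],
    ).to_csv(path, index=False)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    expr.to_frame().to_csv(path, sep=sep, index_label="row_id")


def write_probe_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(pmap.probe_to_gene.items()), columns=["probe_id", "gene_symbol"]
    )
    df.to_csv(path, sep="\t" if str(path).endswith(".tsv") else ",", index=False)


def write_stat_volume(vol: StatVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.grid.astype(np.float64), vol.affine)
    nib.save(img, str(path))


_DIFF_COLUMNS = [
    "map",
    "compartment",
    "gene",
    "n_affected",
    "n_unaffected",
    "mean_diff_z",
    "rank_sum_U",
    "p_raw",
    "p_bonf",
    "m_tests",
    "significant",
    "testable",
]

_PAIR_COLUMNS = [
    "map",
    "compartment",
    "gene_a",
    "gene_b",
    "r_affected",
    "r_unaffected",
    "pair_p_affected_bonf",
    "pair_p_unaffected_bonf",
    "retained",
    "fisher_z",
    "p_raw",
    "p_bonf",
    "significant",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_results(
    differential_rows: Sequence[Mapping],
    pair_rows: Sequence[Mapping],
    summary: Mapping,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the result bundle: two TSV tables plus a JSON summary.

    Column order is fixed, floats are rendered with pandas' exact shortest
    representation and the JSON is key-sorted, so re-running on identical
    inputs yields byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise LoadError(f"cannot create output directory {out_dir}: {exc}") from exc

    paths = {
        "differential": out_dir / "differential_expression.tsv",
        "pairs": out_dir / "coexpression_pairs.tsv",
        "summary": out_dir / "summary.json",
    }
    pd.DataFrame(list(differential_rows), columns=_DIFF_COLUMNS).to_csv(
        paths["differential"], sep="\t", index=False
    )
    pd.DataFrame(list(pair_rows), columns=_PAIR_COLUMNS).to_csv(
        paths["pairs"], sep="\t", index=False
    )
    with open(paths["summary"], "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
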