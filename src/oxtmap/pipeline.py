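"""End-to-end analysis: load inputs, select probes, preprocess, classify,
test differential expression per map, and contrast co-expression.

The run is configured by :class:`RunConfig` (built directly or from a YAML
file).  Every configurable decision — map polarity, classification mode,
alpha, pair filter rule, Bonferroni family sizes, dropped donors — is written
to a JSON manifest next to the result tables, even when defaulted, so a run
can be audited and reproduced bit-for-bit from the manifest plus the inputs.

Stage order is fixed: probe selection (and optional RNA-seq validation) ->
optional male-only column drop -> donor batch correction -> z-normalization
over all retained samples -> per-map sample classification -> per-map,
per-compartment rank-sum differential expression -> co-expression contrast
on one designated map.  Results are held in memory and written at the end,
so a failing stage leaves no partial output behind.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas_io import (
    ExpressionMatrix,
    read_compartment_lookup,
    read_expression,
    read_probe_map,
    read_samples,
    read_stat_volume,
    write_results,
)
from .errors import OxtmapError
from .group_stats import coexpression_contrast, differential_expression
from .preprocess import BatchDesign, remove_donor_effects, z_normalize
from .probe_select import select_probe_by_intensity, validate_selection
from .spatial_map import classification_table, classify_samples, count_by_group

log = logging.getLogger("oxtmap")

DEFAULT_GENES = ("OXT", "OXTR", "CD38", "AVPR1A", "AVPR1B", "AVPR2")


@dataclass
class MapSpec:
    name: str
    path: str
    value_semantics: str = "p_value"


@dataclass
class RunConfig:
    samples: str
    expression: str
    probe_map: str
    maps: list[MapSpec]
    rnaseq: str | None = None
    compartment_lookup: str | None = None
    genes: tuple[str, ...] = DEFAULT_GENES
    alpha: float = 0.05
    mode: str = "interpolate_then_threshold"
    membership_cutoff: float = 0.0
    score_cutoff: float | None = None
    male_only: bool = False
    female_donors: tuple[str, ...] = ()
    focus_gene: str = "OXTR"
    coexpr_map: str | None = None  # default: first map
    coexpr_compartments: tuple[str, ...] = ("subcortex", "cortex")
    filter_rule: str = "either"
    gate_on_steiger: bool = False
    out_dir: str = "oxtmap_results"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.maps:
            raise OxtmapError("at least one statistic map is required")
        if not self.genes:
            raise OxtmapError("gene list must be nonempty")
        for attr in ("samples", "expression", "probe_map"):
            if not Path(getattr(self, attr)).exists():
                raise OxtmapError(f"{attr} file not found: {getattr(self, attr)}")
        for m in self.maps:
            if not Path(m.path).exists():
                raise OxtmapError(f"map {m.name!r} file not found: {m.path}")
        if self.male_only and not self.female_donors:
            raise OxtmapError("male_only requires female_donors to be listed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        maps = [MapSpec(**m) for m in raw.pop("maps")]
        for key in ("genes", "female_donors", "coexpr_compartments"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(maps=maps, **raw)


@dataclass
class RunResult:
    out_dir: Path
    counts: dict[str, pd.DataFrame]
    differential: list  # DifferentialResult
    comparisons: list  # CorrelationComparison
    selections: dict
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except OxtmapError as exc:
                raise OxtmapError(f"[stage: {name}] {exc}") from exc

        return wrapper

    return deco


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full analysis and write the result bundle to cfg.out_dir."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.validate()

    # ---- load -------------------------------------------------------------
    lookup = read_compartment_lookup(cfg.compartment_lookup) if cfg.compartment_lookup else None
    samples = _stage("load")(read_samples)(cfg.samples, lookup)
    expr = _stage("load")(read_expression)(cfg.expression)
    pmap = _stage("load")(read_probe_map)(cfg.probe_map)
    rnaseq = (
        _stage("load")(read_expression)(cfg.rnaseq, value_kind="rnaseq")
        if cfg.rnaseq
        else None
    )
    volumes = {
        m.name: _stage("load")(read_stat_volume)(m.path, m.value_semantics)
        for m in cfg.maps
    }
    log.info("loaded %d samples, %s expression matrix, %d maps",
             len(samples), expr.shape, len(volumes))

    # ---- probe selection --------------------------------------------------
    sample_to_donor = {s.sample_id: s.donor_id for s in samples}
    selections = {}
    for gene in cfg.genes:
        sel = _stage("probe_selection")(select_probe_by_intensity)(expr, pmap, gene)
        if rnaseq is not None:
            rnaseq_donors = {
                sample_to_donor[c] for c in rnaseq.col_ids if c in sample_to_donor
            }
            sel = validate_selection(
                sel, expr, rnaseq, pmap, rnaseq_donors, sample_to_donor
            )
        selections[gene] = sel
    gene_expr = ExpressionMatrix(
        list(cfg.genes),
        list(expr.col_ids),
        np.vstack([expr.row(selections[g].selected_probe) for g in cfg.genes]),
        "log2_intensity",
    )

    # ---- retained samples & optional male-only drop ----------------------
    dropped_donors: list[str] = []
    retained = [
        s for s in samples
        if s.compartment in ("subcortex", "cortex") and s.sample_id in set(expr.col_ids)
    ]
    if cfg.male_only:
        dropped_donors = sorted(set(cfg.female_donors))
        retained = [s for s in retained if s.donor_id not in set(dropped_donors)]
        log.info("male-only analysis: dropped donor(s) %s", dropped_donors)
    retained_ids = [s.sample_id for s in retained]
    gene_expr = gene_expr.subset_columns(retained_ids)

    # ---- preprocess -------------------------------------------------------
    design = BatchDesign.from_samples(retained)
    corrected = _stage("batch_correction")(remove_donor_effects)(gene_expr, design)
    z = _stage("z_normalization")(z_normalize)(corrected)

    # ---- per-map classification and differential expression --------------
    cls_by_map = {}
    counts = {}
    differential = []
    for name, vol in volumes.items():
        cls = _stage("classification")(classify_samples)(
            samples, vol,
            mode=cfg.mode, alpha=cfg.alpha,
            membership_cutoff=cfg.membership_cutoff, score_cutoff=cfg.score_cutoff,
        )
        if cfg.male_only:
            keep = {s.sample_id for s in retained}
            cls = [c for c in cls if c.sample_id in keep or c.excluded]
        cls_by_map[name] = cls
        counts[name] = count_by_group(
            [c for c in cls if c.sample_id in set(retained_ids) or c.excluded]
        )
        differential.extend(
            _stage("differential_expression")(differential_expression)(
                z, cls, cfg.genes, name, alpha=cfg.alpha
            )
        )

    # ---- co-expression contrast on the designated map ---------------------
    coexpr_map = cfg.coexpr_map or cfg.maps[0].name
    if coexpr_map not in cls_by_map:
        raise OxtmapError(f"[stage: coexpression] unknown map {coexpr_map!r}")
    comparisons = []
    for compartment in cfg.coexpr_compartments:
        comparisons.append(
            _stage("coexpression")(coexpression_contrast)(
                z, cls_by_map[coexpr_map], cfg.genes, cfg.focus_gene,
                compartment=compartment, map_name=coexpr_map,
                filter_rule=cfg.filter_rule, gate_on_steiger=cfg.gate_on_steiger,
                alpha=cfg.alpha,
            )
        )

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "oxtmap_version": __version__,
        "config": {
            **{k: v for k, v in dataclasses.asdict(cfg).items() if k != "maps"},
            "maps": [dataclasses.asdict(m) for m in cfg.maps],
        },
        "value_kind_chain": ["log2_intensity", "batch_corrected", "z_scored"],
        "dropped_donors": dropped_donors,
        "n_retained_samples": len(retained_ids),
        "bonferroni_families": {
            "differential_expression_per_compartment_map": len(cfg.genes),
            "pairwise_correlation": len(cfg.genes) * (len(cfg.genes) - 1) // 2,
            "fisher_contrasts": {
                c.compartment: c.m_pairs for c in comparisons
            },
        },
        "probe_selection": {
            g: {
                "selected_probe": s.selected_probe,
                "mean_intensity": s.mean_intensity,
                "validated": s.validated,
                "validation_skipped": s.validation_skipped,
                "rnaseq_rho": s.rnaseq_rho,
            }
            for g, s in selections.items()
        },
        "counts": {name: c.to_dict() for name, c in counts.items()},
    }

    # ---- write bundle (all-or-nothing) ------------------------------------
    out_dir = Path(cfg.out_dir)
    written: list[Path] = []
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        diff_rows = [
            {
                "map": r.map_name, "compartment": r.compartment, "gene": r.gene,
                "n_affected": r.n_affected, "n_unaffected": r.n_unaffected,
                "mean_diff_z": r.mean_diff_z, "rank_sum_U": r.rank_sum_U,
                "p_raw": r.p_raw, "p_bonf": r.p_bonf, "m_tests": r.m_tests,
                "significant": r.significant, "testable": r.testable,
            }
            for r in differential
        ]
        pair_rows = []
        for comp in comparisons:
            fi = comp.genes.index(cfg.focus_gene)
            fisher_by_gene = {f.gene_b: f for f in comp.fisher_results}
            for j, g in enumerate(comp.genes):
                if j == fi:
                    continue
                f = fisher_by_gene.get(g)
                pair_rows.append(
                    {
                        "map": comp.map_name, "compartment": comp.compartment,
                        "gene_a": cfg.focus_gene, "gene_b": g,
                        "r_affected": float(comp.R_affected[fi, j]),
                        "r_unaffected": float(comp.R_unaffected[fi, j]),
                        "pair_p_affected_bonf": float(comp.pair_p_affected[fi, j]),
                        "pair_p_unaffected_bonf": float(comp.pair_p_unaffected[fi, j]),
                        "retained": f is not None,
                        "fisher_z": f.z if f else float("nan"),
                        "p_raw": f.p_raw if f else float("nan"),
                        "p_bonf": f.p_bonf if f else float("nan"),
                        "significant": f.significant if f else False,
                    }
                )
        summary = {
            "steiger": {
                comp.compartment: {
                    "map": comp.map_name, "chi2": comp.steiger_chi2,
                    "df": comp.steiger_df, "p": comp.steiger_p,
                    "n_affected": comp.n1, "n_unaffected": comp.n2,
                    "filter_rule": comp.filter_rule, "m_pairs": comp.m_pairs,
                    "gated_out": comp.gated_out,
                }
                for comp in comparisons
            },
            "counts": {name: c.to_dict() for name, c in counts.items()},
        }
        paths = write_results(diff_rows, pair_rows, summary, out_dir)
        written.extend(paths.values())
        for name, cls in cls_by_map.items():
            p = out_dir / f"classification_{name}.tsv"
            classification_table(cls).to_csv(p, sep="\t", index=False)
            written.append(p)
            pc = out_dir / f"counts_{name}.tsv"
            counts[name].to_csv(pc, sep="\t")
            written.append(pc)
        mp = out_dir / "manifest.json"
        with open(mp, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        written.append(mp)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise

    return RunResult(out_dir, counts, differential, comparisons, selections, manifest)


# ---------------------------------------------------------------------------
# reporting


def summarize(out_dir: str | Path) -> str:
    """Human-readable report assembled from a completed run's result bundle."""
    out_dir = Path(out_dir)
    diff_path = out_dir / "differential_expression.tsv"
    pair_path = out_dir / "coexpression_pairs.tsv"
    summary_path = out_dir / "summary.json"
    for p in (diff_path, pair_path, summary_path):
        if not p.exists():
            raise OxtmapError(f"result bundle incomplete: missing {p}")
    diff = pd.read_csv(diff_path, sep="\t")
    pairs = pd.read_csv(pair_path, sep="\t")
    with open(summary_path) as fh:
        summary = json.load(fh)

    lines: list[str] = ["oxtmap run report", "=" * 60, ""]
    lines.append("Differential expression (affected - unaffected, z units)")
    lines.append("-" * 60)
    if diff.empty:
        lines.append("no tests performed")
    else:
        for (map_name, compartment), grp in diff.groupby(["map", "compartment"], sort=True):
            lines.append(f"map={map_name}  compartment={compartment}")
            for _, r in grp.iterrows():
                if not r["testable"]:
                    lines.append(f"  {r['gene']:<8} untestable (empty group)")
                    continue
                star = " *" if r["significant"] else ""
                lines.append(
                    f"  {r['gene']:<8} mean_diff_z={r['mean_diff_z']:+.3f}  "
                    f"p_bonf={r['p_bonf']:.3g}{star}"
                )
            lines.append("")
    lines.append("Co-expression contrast (Steiger matrix test + Fisher r-to-z)")
    lines.append("-" * 60)
    if not summary.get("steiger"):
        lines.append("no tests performed")
    for compartment, s in sorted(summary.get("steiger", {}).items()):
        lines.append(
            f"{compartment}: chi2={s['chi2']:.2f} df={s['df']} p={s['p']:.3g} "
            f"(n={s['n_affected']}/{s['n_unaffected']}, map={s['map']})"
        )
        sub = pairs[(pairs["compartment"] == compartment) & pairs["retained"]]
        if sub.empty:
            lines.append("  no retained pairs")
        for _, r in sub.iterrows():
            star = " *" if r["significant"] else ""
            lines.append(
                f"  {r['gene_a']}-{r['gene_b']}: r={r['r_affected']:+.3f} vs "
                f"{r['r_unaffected']:+.3f}  z={r['fisher_z']:+.2f}  "
                f"p_bonf={r['p_bonf']:.3g}{star}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
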