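# Methods

## Problem and model

The analysis asks whether tissue samples that fall inside fMRI-derived
"affected" brain regions express oxytocin-pathway genes differently from
samples outside those regions. Its inputs are point measurements (tissue
samples with MNI-152 mm coordinates and microarray expression) and fields
(volumetric p-statistic maps with a 4x4 voxel-to-mm affine). The statistical
model is deliberately simple: samples are treated as independent
observations (samples pooled across donors; no spatial autocorrelation
model), donor identity is an additive per-gene batch effect, and group
contrasts are nonparametric (rank-sum) for means and normal-theory
(Fisher z / Steiger) for correlations.

## Spatial classification

World mm coordinates are mapped to continuous 0-based voxel coordinates
through the full inverse affine (oblique and anisotropic grids are handled;
there is no nearest-neighbour fallback), and the map is evaluated by
trilinear interpolation of the 8 surrounding voxel values. Points outside
the box spanned by voxel centers return 0 and are excluded with reason
`outside-volume` rather than silently counted as unaffected; brainstem and
cerebellum samples are excluded a priori.

Two operational readings of "the sample falls inside the thresholded map"
are exposed and recorded in the run manifest:

* `interpolate_then_threshold` (default) — interpolate the continuous
  statistic and apply the single criterion 0 < p̂ < α. This needs no second
  tuning constant.
* `threshold_then_interpolate` — binarize at α first, then call a sample
  affected when the interpolated mask value exceeds `membership_cutoff`
  (default 0, i.e. any overlap).

In p-value semantics a stored 0 is background/no-data, not p = 0, because
statistic maps conventionally zero-fill voxels outside the analysis mask.
Map polarity does not self-describe, so the caller declares `p_value`
(small = significant) or `score` (large = significant, with an explicit
cutoff).

## Probe selection

"Highest expression" is operationalized as the arithmetic mean of the
probe's row over all loaded samples; exact ties break to the
lexicographically smallest probe id, for determinism. RNA-seq validation
computes Spearman's ρ (average ranks for ties) between each of the gene's
probes and the gene's RNA-seq row over shared sample ids, restricted to the
donors with RNA-seq data; validation failure demotes to a warning — the
intensity-selected probe is still used, since the RNA-seq check is
confirmatory. Fewer than 3 shared samples yields a flagged
"validation skipped" outcome.

## Preprocessing

Donor correction fits, per gene, `value = grand_mean + donor_offset +
residual` with count-weighted sum-to-zero offsets; the least-squares solution
is "subtract the donor's empirical mean, add back the grand mean", which
preserves each row's grand mean exactly and equalizes per-donor means to it
(both to < 1e-10, covered by tests). Only the donor factor is modelled — no
further covariates. z-normalization divides by the sample standard deviation
(n−1) computed over **all** retained samples pooled (both compartments, both
labels): normalizing per compartment or per group would erase the very
contrast being tested. Normalization happens after excluding
brainstem/cerebellum samples (and, in the male-only path, after dropping the
female donor's columns — before batch correction). Zero-variance genes are a
hard error naming the gene.

## Group statistics

* **Rank-sum test**: exact enumeration when the pooled size is ≤ 12 with no
  ties, otherwise normal approximation with tie-corrected variance and
  continuity correction (dispatch and exactness are property-tested against
  an enumeration oracle).
* **Bonferroni families** are always explicit in the output: differential
  expression corrects over the genes tested within one compartment x map
  (6 by default); within-group correlation p-values correct over
  k(k−1)/2 pairs; the Fisher stage corrects over the number of retained
  pairs. The family sizes are written to the manifest because the choice of
  family is the least reproducible part of analyses of this kind.
* **Pair filtering** before the Fisher r-to-z stage defaults to retaining a
  focus-gene pair significant in *at least one* group ("either"); a strict
  "both" mode exists. The default preserves the ability to detect a
  correlation present in only one group — exactly the situation of interest
  when a pair co-expresses only inside affected regions. An optional gate
  runs the pairwise stage only when the Steiger matrix test is itself
  significant; it is off by default, so both statistics are always reported.
* Degenerate situations are flagged, not fabricated: an empty affected or
  unaffected group yields `testable = false` results with NaN p-values; no
  retained pairs is a valid outcome with an empty contrast list.

## Synthetic data generator

The generator emulates the *structure* of a multi-donor atlas crossed with a
statistic map, not real anatomy: compartments are axis-aligned boxes in a
centred 40x48x40 grid of 4 mm voxels, affected regions are spheres in mm
space (closed-form membership), the p-volume holds `p_floor` (0.01) inside
cluster voxels and 1.0 elsewhere within a brain-shaped support, zero-filled
outside. Samples are placed uniformly within their compartment, at least
√3 x voxel-size (≈ 6.9 mm) from every sphere boundary — the largest distance
from a point to one of its 8 interpolation neighbours — so interpolated
membership provably equals geometric membership and planted affected counts
are exact. Default counts (986 subcortical with 177 affected, 1762 cortical
with 147 affected, 150 excluded, 6 donors with the last tagged female)
mirror the scale of a six-donor human atlas analysis.

Expression is `baseline + donor offset + planted shift + noise`, with
N(0, 0.5) donor offsets per gene x donor and N(0, 1) gene noise. Planted
effects `effect_z` are expressed in post-normalization z units: the raw
shift δ solves δ / √(σ² + p(1−p)δ²) = effect_z, where σ² is the gene noise
plus the designated probe's noise and p the in-cluster fraction of retained
samples, because the shift itself inflates the pooled variance that
z-normalization divides by. Planted co-expression mixes the pair's noise
within affected samples at a coefficient raised by (σ²+τ²)/σ² (τ = selected
probe noise) so the *measured* correlation converges to the requested r.
Each gene has 3 probes; the designated one has +1.0 intensity and noise sd
0.15 versus 0.5 for the decoys, so intensity selection and RNA-seq
validation (RNA-seq = 2^(signal/2) plus small noise for the first two
donors) both recover it. All randomness flows from the single seed; the same
seed reproduces the dataset byte-for-byte.

What passing tests on this generator do **not** show: robustness to the
spatial autocorrelation of real expression data, to anatomically structured
sampling, to non-additive donor effects, or to probe sets where the
highest-intensity probe is not the best-performing one. The independence
assumptions shared by the generator and the tests are exactly the
assumptions of the analysis itself.

## Problem sizes and numerical choices

Simulation-based tests use a 980-sample subcortical design (180 affected /
800 unaffected) over 200 seeds, 1,000 Monte-Carlo draws for rank-sum
calibration, and 20-seed averages for generator-recovery checks; the
acceptance script runs the full-scale default (2,898 samples) once. Voxel
values interpolate exactly at voxel centers (< 1e-12); `atanh` of |r| = 1 is
a hard error; Bonferroni caps at 1; correlation p-values use the
t-transform with n−2 df. Result tables have fixed column order and the
manifest is key-sorted JSON, so identical inputs and config reproduce the
bundle byte-for-byte.

## Known limitations

* Correlation tests assume bivariate normality after z-scoring; rank-based
  alternatives are not implemented.
* Sample pooling across donors overstates the effective n for the
  correlation comparisons, as it does in the analysis design this package
  implements.
* No cluster-extent thresholding, smoothing, spatial resampling, or
  ontology-graph handling: compartments come from an explicit column or a
  caller-supplied acronym lookup, and maps arrive precomputed in the same
  space as the sample coordinates.
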