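# Methods

This note documents the models, conventions and design choices behind
`fmtrack`: what each statistic computes, what the synthetic-data generator
does and does not emulate, and the numerical details that affect results.

## Provenance classification and engraftment

**Unique vs common.** For each donor inoculum, an ASV is *common* if it has
at least one read in at least one pre-inoculation (PND21) recipient sample,
and *unique* if it has zero reads in every baseline sample. "Absent from
all recipients at baseline" is the only reading under which unique and
common partition the inoculum (unique + common = donor richness), so it is
a fixed semantic of `classify_inoculum_asvs`, not an option. The
*shared-unique* stratum is the intersection of the donors' unique sets;
detection reports always separate source-specific-unique from shared-unique
ASVs, because a shared-unique ASV detected in a recipient cannot be
attributed to one donor.

**Inclusion filter.** Before classification, features with a total count
below 3 — summed over *all* samples loaded for the run (inocula plus every
piglet sample) — are removed. The global scope errs toward keeping rare
features that are corroborated by several samples; computing the filter
per-timepoint is possible via `filter_low_count_features` on subsets but is
not the default.

**Detection.** An ASV in a stratum counts as engrafted in a (group,
timepoint) if it has ≥ 1 read in ≥ 1 sample of that group at that
timepoint (the floor is configurable via `min_count`). Detection is scoped
strictly by timepoint: an ASV seen only at PND27 is not in the PND48 set.
Engrafted relative abundance per sample is
`100 · Σ_{f∈detected} count(f) / Σ_all count`, summarized as (min, mean,
max) over the group's samples.

**Fisher exact test.** Two-sided p-values use the minimum-likelihood rule:
conditioning on the margins, sum the hypergeometric probabilities of every
table whose point probability does not exceed the observed one. Point
probabilities are compared as exact integers (hypergeometric numerators
over a common denominator, via `math.comb`), so inclusion decisions are
float-free and the result is exact up to one final division. The odds
ratio is the sample odds ratio `ad/bc` (∞ when `bc = 0` with `ad > 0`, NaN
when both vanish); no conditional-MLE odds ratio is computed since only
p-values are contrasted downstream. `compare_engraftment_success` takes the
two contrast cells explicitly (source, stratum, group, timepoint), builds
the 2×2 (engrafted / not-engrafted) table, and returns the table with the
statistics so the exact contrast is auditable; cells whose ASV strata
partially overlap are rejected (they would double-count features).

## Community ecology statistics

- **Rarefaction** draws each retained sample without replacement to a
  common depth (one multivariate-hypergeometric draw per sample);
  samples shallower than the target are dropped with a warning.
- **Alpha diversity** is computed on proportions: observed richness,
  Shannon entropy `−Σ p ln p` in natural-log units (the convention of the
  common ecology toolchains; the log base only rescales), and Simpson's
  index `1 − Σ p²`.
- **Kruskal–Wallis** uses average ranks for ties and the standard tie
  correction, with p from the χ² (k−1 df) approximation; the degenerate
  all-values-identical case is defined as H = 0, p = 1. **Dunn's post-hoc**
  z-statistics use the pooled-rank variance `N(N+1)/12 − Σ(t³−t)/(12(N−1))`
  with two-sided normal p and optional Benjamini–Hochberg adjustment over
  the pair family.
- **Bray–Curtis** is computed on raw counts by default (proportions by
  option); it is bounded in [0, 1], zero for identical and one for
  support-disjoint samples.
- **PCoA** eigendecomposes `−½ J D² J`. Axes with positive eigenvalues are
  kept and scaled by `√λ`; negative eigenvalues are dropped (their total
  magnitude is logged) rather than corrected — Cailliez/Lingoes corrections
  change distances and were judged unnecessary for the analyses here.
  Proportion explained is relative to the positive-eigenvalue total. For
  Euclidean input the embedding reproduces the distances exactly
  (Gower's theorem), which the tests assert to 1e-9.
- **PERMANOVA** partitions `SS_T = (1/n)Σ_{i<j} d²ᵢⱼ` into within/between
  components and permutes raw group labels; p uses the `(x+1)/(N+1)`
  estimator so it is never zero, and an exhaustive mode enumerates all
  distinct labelings for small n. Pen/litter structure is *not* used as a
  permutation stratum — a documented limitation relative to mixed-model
  designs.
- **PERMDISP** embeds samples by PCoA (positive axes), measures each
  sample's distance to its group centroid, and permutes those distances
  across groups around a one-way ANOVA F.

## Metabolome integration

Concentrations below the limit of detection are imputed as LOD/2, then
log-transformed (natural log default, log10 optional) and autoscaled
(mean 0, unit sample variance per metabolite). PLS-DA regresses a centered
one-hot group response on the autoscaled matrix by NIPALS with X-deflation
(components therefore have orthogonal scores); two components by default,
matching the common metabolomics-workbench default, with the count
configurable. VIP scores use the per-component response sum of squares
captured, `SSY_a = (tᵀt)(qᵀq)`, and unit-norm weight vectors, which makes
the mean squared VIP identically 1. Spearman correlation ranks each column
(average ranks), applies Pearson on the ranks, and derives two-sided
p-values from the t approximation with n−2 df; the BH family is all pairs
tested in one call, and pairs involving a constant variable are reported
as missing and excluded from the family. Procrustes analysis is symmetric:
both coordinate matrices are centered and scaled to unit sum of squares
(the narrower one zero-padded), the optimal rotation comes from the SVD of
the cross-product, `m² = 1 − (Σσ)²` and `r = √(1 − m²)`; PROTEST permutes
the rows of one configuration and counts permutations with `m²` at most
the observed. The ordinations fed to Procrustes are the full
positive-eigenvalue PCoA coordinate matrices of each data set's distance
matrix (Bray–Curtis for the microbiome, Euclidean on the autoscaled
metabolite matrix), which we take as the concrete meaning of comparing the
two data sets' principal-coordinate geometries.

## The synthetic-data generator

The generator's defaults are the study conditions: donors WB and Sow with
439 and 275 ASVs, of which 101 and 98 are shared with the baseline cohort
and 42 are unique-but-shared between the donors; 4 recipient groups
(Control, Sow, WB, Mix) × 12 piglets; fecal samples at PND21/27/48 plus a
PND48 cecal sample; a 70-metabolite cecal panel. Per-sample sequencing
depths are not published, so they are generator choices: Poisson around
50,000 reads for piglet samples and 300,000 for the deeply sequenced
inocula, with log-normal (σ = 1) latent relative abundances renormalized
per sample and read counts drawn multinomially.

Two count-level guarantees are built in. Every planted inoculum member
receives at least 3 reads in its inoculum column, and every donor-common
ASV at least one read in at least one baseline piglet. These floors emulate
the premise of the design — the inocula are sequenced deeply enough that
membership is fully observed, and "common" means actually observed in the
cohort — and make the planted unique/common partition exactly recoverable
regardless of the multinomial draw. Without them, a vanishing but nonzero
dropout probability would make recovery tests flaky in a direction
(present-but-unobserved) that carries no scientific information.

Engraftment is modeled at the group level: for each (group, source), each
source-unique ASV engrafts with the configured probability (defaults:
0.3 for the matched single-source groups, 0.15 for WB-origin ASVs in the
Mix group, 0 for sow-specific ASVs in Mix and for all sources in Control —
mirroring the observed pattern that roughly a third of a source's unique
pool established and that sow-specific ASVs failed in the mixed group).
Engrafted ASVs are carried by every recipient of the group and jointly
receive a fixed 5% share of each recipient's community; baseline membership
persists across timepoints with abundances redrawn independently (no
within-host dynamics are modeled — the study provides no dynamic model, so
anything richer would be invention). Consequences to keep in mind: the
synthetic data have no piglet-to-piglet variation in *which* ASVs engraft,
no contamination or cross-group leakage, no compositional competition
between engrafted mass and specific baseline taxa, and no litter/pen
effects on composition. Passing recovery tests therefore demonstrate the
correctness of the bookkeeping and statistics, not robustness to those
real-data phenomena.

The metabolome is log-normal per metabolite (log-mean drawn around
log 100, σ = 0.5) with additive log-scale group shifts of 0.7 applied to
disjoint blocks of 5 metabolites per treated group — large enough to be
seen by PLS-DA at n = 12/group yet far from separability. One metabolite
is coupled to a designated ubiquitous baseline taxon's PND48 relative
abundance through a Gaussian copula with the Pearson parameter
`2 sin(π ρ_S / 6)` chosen to hit the target Spearman ρ_S = 0.8. Each
metabolite's LOD sits 2 σ below its log-mean, censoring roughly the bottom
2% of control-level values to missing.

## Problem sizes and tolerances in the test suite

Recovery and calibration tests run at the design's native scale (48
piglets, ~1,000 features) or smaller: the Fisher oracle sweep enumerates
all 2×2 tables with total ≤ 40 against an independent implementation at
1e-12; engraftment-probability recovery uses 20 seeds against the exact
binomial 99% interval; permutation-test calibration uses 1,000 replicates
of 199 (PERMANOVA) or 99 (PROTEST) permutations with a
Kolmogorov–Smirnov uniformity check at the 1% level; Kruskal–Wallis
type-I error uses 10,000 null replicates at 4 × 12 samples. Euclidean
PCoA embeddings are asserted to 1e-9, VIP normalization to 1e-9, and the
Procrustes identity r = √(1 − m²) to 1e-9.

## Known limitations

- Strain-level resolution is out of reach of ASV identity; a recipient
  ASV identical to a donor ASV may still be an independent acquisition.
- PERMANOVA permutes labels freely; designs with pens/litters as random
  effects need restricted permutation that is not implemented.
- No compositional (log-ratio) treatment of counts; analyses mirror the
  relative-abundance conventions of the standard amplicon toolchain.
- The Fisher enumeration is exact but O(support) per table with big-int
  arithmetic; for margins in the tens of thousands a normal approximation
  would be preferable.
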