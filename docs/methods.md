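# Methods

This note documents the scoring model, the synthetic-data generator, the
numerical choices and the open design decisions of `cretrace`.

## Scoring model

**Master list.** All sample peaks are union-merged with single linkage at
≥ 1 bp overlap (bookended intervals stay separate; the minimum overlap is a
parameter). The merge rule used by the original analyses of this kind is
rarely reported; union-merge is the conventional default and the provenance
table keeps every contributing (sample, peak) pair so alternative rules can
be re-derived. Coordinates are 0-based half-open throughout; GTF-like input
is converted at ingestion.

**Clonality Index.** Within one sample, every detected master region gets
`Nscore = ((read count / region size) · 10⁻⁶) · 10⁻³ / total mapped reads`.
The two powers of ten are kept for fidelity with the published formula; CI is
a percentile rank and therefore invariant to them. Detected regions are
ranked descending by Nscore and binned as `ceil(100 · rank / n_detected)`
with ties sharing the bin of their minimum rank (a stable sort on region id
breaks residual order). Percentiles are computed over the sample's detected
repertoire only, not over all master regions. CI 0 marks absence.

The verbatim orientation (1 = most clonal) places the most active peaks
numerically next to absent ones (0). Wherever an analysis tracks *increases*
in clonality — the dynamic-CRE selection, the CI–PI association — scores are
mapped to the inverted scale `101 − CI` for detected regions (0 stays 0), so
that larger = more clonal. This is a reporting transform only; the stored CI
keeps the verbatim orientation, and `invert_ci` / `use_inverted_ci` expose
the choice.

**Penetrance Index.** PI of a region is the number of in-scope samples whose
repertoire overlaps it by ≥ 1 bp (read from master-list provenance). Bands:
private = 1, low = 2…14, high > 14; the low cut is configurable. The
group-vs-group observed/expected table allocates pooled detection events
(A-detected plus B-detected regions at a PI value) to each group in
proportion to its overall share of detection events; empty PI levels are
reported missing, not zero.

**TMM and differential testing.** TMM follows the standard definition: the
reference sample is the one whose 75th-percentile count fraction is closest
to the mean; each sample's factor is `2^f` with `f` the precision-weighted
mean of M-values after two-sided trimming of 30 % on M and 5 % on A, weights
the inverse asymptotic variances; factors are rescaled to geometric mean 1.
The implementation reproduces the Bioconductor edgeR reference to ≤ 1e-6
(cross-checked in the test suite via Rscript). Normalised accessibility is
`log2((count + 0.5) / (lib · factor) · 10⁶)`; the 0.5 pseudocount avoids
−∞ at minimal bias. The differential engine is a per-region Welch two-sample
test with BH adjustment — the original engine behind the published
differential counts is unnamed, so Welch/BH is the package's default and a
label-permutation p-value (≥ 1,000 permutations) is available as a
robustness mode. Calls require both |log₂FC| > 0.7 and FDR below the cut.
Rows with zero variance in both groups and equal means are clean nulls
(p = 1).

**Resampling null.** Each iteration draws disjoint pseudo-groups of the true
group sizes from the whole cohort without replacement and reruns the
identical differential test. `oe_ratio` = observed count / mean null count;
when no null iteration reaches significance the null total is floored at one
count, making the reported ratio a finite lower bound on the enrichment.

**Dynamic-CRE selection.** A region is kept iff (a) it is detected in at
least `min_pi_disease` disease-stage samples (default 15, judged across the
pooled onset/remission/relapse samples), (b) detected in at most
`max_healthy_ci_fraction` of healthy samples (default 1/3), and (c) the range
of its per-stage median clonality (inverted scale, absent = 0) is at least
`min_ci_delta` CI bins (default 20). The published selection arrived at its
site list with unstated thresholds; these defaults are documented stand-ins
and every threshold is configurable. Tightening any threshold can only
shrink the set (tested property).

**Clustering.** Selected regions are row-z-scaled (constant rows dropped
with a warning) and clustered with Ward linkage on Euclidean distances; the
tree is cut at k = 4 (clusters C1–C4) and k = 2 (clades). The algorithm
behind the published heatmap is unstated; Ward/Euclidean is the conventional
heatmap default and the linkage is configurable. Cluster *names* are
assigned deterministically: the clade whose clusters have the highest mean
z-score over a caller-chosen `order_by` sample set (the pipeline passes the
onset samples) becomes clade 1, and clusters are numbered by that mean within
clades — so C1/C2 are the disease-active clusters by construction, matching
the heatmap convention of the field.

**Chromatin module score.** Accessibility is z-scored within each unit
(sample or cell) across regions, averaged over the module's region set, and
reduced by the mean over a size-matched background set drawn once with a
fixed seed from the complement. Per-unit standardisation makes the score
invariant to unit-level shifts; an all-constant matrix scores 0.

**eRNA.** The exon union is subtracted from each CRE at base level and
fragments are counted when they overlap the remaining eligible bases by
≥ 1 bp; a fragment touching only the exonic bases of a CRE is not counted,
and a fragment spanning several eligible pieces of one CRE counts once.
Productivity calls reuse the Welch/BH machinery on log₂
fragments-per-million (totals from the fragment files, pseudocount 0.5).

**Loops and targets.** Loop anchors are labelled promoter when they overlap
any TSS ± 5 kb window (an anchor overlapping both a promoter window and a
CRE counts as promoter), giving the three mutually exclusive classes.  Loop
distance is between anchor midpoints — resolution-independent;
trans-chromosomal loops are labelled but excluded from the distance
histogram, which keeps a dedicated < 50 kb bin. Enhancer–gene links prefer
loop evidence (one anchor on the CRE, one on a gene's promoter window; an
anchor spanning two promoters links both genes); CREs without loop evidence
fall back to all genes with |TSS − CRE midpoint| ≤ 10 kb; remaining CREs are
reported unlinked.

**Dependency ranking.** Genes are ranked by the number of
lineage-of-interest cell lines inside their most-dependent set. Both
published procedures ("top 100" and "top 10 %") are implemented; the default
is `top_fraction = 0.10` with the set size `ceil(fraction · n)` over
non-missing scores, and boundary ties are included rather than arbitrarily
cut. Counts are invariant to monotone transforms of a gene's score row.

## Synthetic cohort generator

The generator emulates the statistical structure of a 32-sample four-stage
ATAC-seq cohort (6 healthy / 11 onset / 7 remission / 8 relapse by default):

- **Peak classes.** `core` peaks present in every sample (PI = cohort size,
  NB mean boosted ×2 so that penetrance and clonality correlate positively);
  per-stage `stage` peaks present only in one stage at the planted
  `effect_fold`; four `dynamic` healthy-silent patterns; onset low-penetrance
  peaks; and per-sample private peaks. The number of onset low-penetrance
  peaks is solved so that the configured fraction (default 0.6) of
  onset-detected peaks is private or low-penetrant (PI ≤ 14) — the
  stage-composition signature the analysis is designed to expose.
- **Dynamic patterns.** Detection support separates the two clades and
  intensity separates clusters within a clade: onset+relapse strong
  (1.0/1.0) and onset-dominant (1.0/0.35) form the disease-active clade that
  hosts the planted eRNA-productive CREs; relapse+remission (0.25/1.0/1.0)
  and disease-wide (1.0/1.0/1.0 across all disease stages) form the other.
  All are fully healthy-silent and detected in ≥ 15 disease samples, so the
  selection funnel retains exactly the dynamic classes.
- **Counts.** Per (peak, sample) negative binomial with variance
  `μ + φμ²` (defaults μ = 50, φ = 0.3) on presence, zero and omitted from
  the sample's peak file otherwise; present peaks keep a count ≥ 1. Stage
  effects act multiplicatively on μ; per-sample depth is log-normal
  (σ = 0.25). Peaks are placed disjointly (≥ 1 bp gaps) with 20 % of them
  within 5 kb of a synthetic TSS, so master-list merging is unambiguous and
  the promoter-like fraction matches the observed ~20 %.
- **RNA fragments.** Fixed 75 bp intervals (paired ends collapsed):
  exon-derived baseline in every sample, enhancer-derived baseline on the
  non-exonic CRE bases, elevated ×4 at flagged productive CREs in onset
  samples.
- **Loops / dependency.** Planted CRE→promoter BEDPE anchors (tagged with a
  5/10/25 kb resolution) among random promoter–promoter and CRE–CRE loops; a
  genes × 120-cell-line score matrix with 11 labelled B-ALL lines whose
  scores for loop-linked genes are shifted down by a configurable offset —
  a deliberate scale-down of a genome-wide screen (~1,000 lines) that keeps
  the labelled-subset size of the real resource.

Everything is byte-deterministic under the config seed (child seeds are
spawned per component).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: mapping artifacts and blacklist regions, GC and
accessibility-dependent coverage bias, correlated fragment placement,
subclonal copy-number effects on counts, inter-sample batch structure, and
the unknown true selection thresholds behind the published site list. The
generator's distributional choices are stand-ins (the source analyses state
no generative model) and remain fully configurable.

## Numerical choices and degenerate inputs

- Overlap semantics everywhere: ≥ 1 bp, strict (bookended intervals do not
  touch); interval arithmetic delegated to pyranges with a negative-slack
  merge to enforce strictness.
- Region–TSS distance is measured from the integer region midpoint, signed
  positive when the TSS lies downstream on the gene's strand and zero when a
  TSS falls inside the region; nearest-TSS ties resolve toward the smaller
  coordinate, then the smaller gene id.
- Percentages in cohort summaries round half-up to integers, as clinical
  summary tables print them.
- CI ties share the minimum-rank bin; empty repertoires yield an all-zero CI
  column rather than an error.
- Welch p-values that are undefined (zero variance in both groups) resolve
  to 1 when means agree, 0 otherwise.
- All-zero samples are rejected by TMM; empty fragment files produce zero
  eRNA columns; impossible selection thresholds yield an empty selection,
  not an error; constant rows are dropped (with a warning) before
  clustering.

## Known limitations

- The Welch/BH engine will not numerically reproduce differential counts
  produced by count-model engines (edgeR/DESeq2-style shrinkage); the
  published headline counts also depend on the deposited cohort and are out
  of scope at synthetic scale.
- No covariate adjustment, batch correction or dispersion shrinkage across
  regions.
- eRNA calling is strand-agnostic and does not assemble transcription units;
  deep (~200 M read) eRNA detection regimes are not modelled.
- Loop calling itself (from contact maps) is out of scope; each call-set
  resolution is processed independently.
- The problem sizes used by the test suite and the acceptance script
  (~2,300 master regions, 2,000-region null simulations, 100–200 replicates,
  a 120-line dependency matrix) are the package's chosen desk-scale study
  conditions; statistical tolerances are set for those sizes.
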