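# Methods

## Model overview

`rnam5c` treats m⁵C prediction as binary classification of a cytosine
from its flanking sequence alone. The core assumptions are:

1. the methylation signal is local — a window of a few dozen nucleotides
   around the site carries the discriminative information;
2. negatives drawn near positives with matched window GC content make
   the learned signal sequence-specific rather than compositional;
3. scores from forests trained on balanced positive/negative splits can
   be averaged into a single calibrated score, and operating points are
   best expressed as specificities on cross-validation negatives rather
   than as a fixed probability cutoff.

## Methylation calling

Level P = (C + Ψ)/(T + C), Ψ = 1/8 pseudo-counts; the pseudo-count keeps
deeply covered unmethylated sites at a small positive level and is not
applied to the denominator. A site is positive when P ≥ `level_min`
(default 0.01) and FDR ≤ `fdr_max` (default 0.3); both boundaries
inclusive. Zero-coverage sites have no level and can never be called.

The per-site significance is a stand-in, since upstream pipelines differ
in how they compute it: a one-sided binomial tail P(X ≥ C) with
X ~ Binomial(C+T, `conversion_error`), the error rate defaulting to
0.005 (0.5% non-conversion is typical of RNA bisulfite libraries),
followed by Benjamini–Hochberg adjustment across all covered cytosines.
A pre-computed `fdr` column in the input count table takes precedence.

## Dataset construction

Windows are `upstream + 1 + downstream` nt (default 21 + 1 + 21 = 43),
border positions filled with `N`; the central base must be an actual C
in the transcript (the N rule applies to flanks only). Negatives per
positive: up to 10 cytosines within ±100 nt, not themselves called
positive, with |ΔGC| ≤ 0.05 where GC is computed on the same 43-nt
window used for the samples (window-level GC is the testable reading of
"matched around the positive"); selection among eligible candidates is
uniform under the configured seed, and a shortfall is logged rather than
padded. Coordinates are 0-based internally and 1-based in all emitted
TSVs.

## Feature encoding

* **Binary**: A→1000, C→0100, G→0010, U→0001, N→0000 per position,
  5′→3′. The constant central C is included; downstream feature
  selection discards constants at zero cost, and keeping it makes the
  block a pure function of the window.
* **k-mer**: occurrence frequencies for k ∈ {1,2,3} (84 features);
  denominators count only substrings free of N, so each k-block sums to
  1 on clean windows and to ≤ 1 otherwise.
* **PseDNC** (type-I pseudo components): d_u = f_u/(Σf + wΣθ) for the 16
  adjacent dinucleotide frequencies and d_{16+j} = wθ_j/(Σf + wΣθ),
  j = 1..λ, where θ_j is the mean squared distance between the
  standardized physicochemical property vectors of dinucleotides j
  positions apart. Defaults λ = 6 and w = 0.1 (λ is forced by the
  4·L + 106 total; w is the conventional default and is logged as such).
  The packaged property table holds six structural properties of RNA
  dinucleotide steps (shift, slide, rise, tilt, roll, twist; literature
  consensus values), standardized to mean 0/sd 1 across the 16
  dinucleotides; it can be replaced by a TSV. N-containing dinucleotides
  are skipped in both the f and θ sums; a θ_j with no available pair
  (separation longer than the window allows, or everything N-masked) is
  0, so the vector keeps its 16 + λ length for every window length ≥ 2
  and the encoding stays defined across the whole L = 5..43 optimization
  sweep. All PseDNC features are non-negative and sum to 1 (or all are
  0 for a fully masked window).

Feature order is binary block, then k-mer (k ascending, lexicographic),
then PseDNC — fixed so that ranked feature lists are reproducible.

## Ensemble and thresholds

Negatives are shuffled (seeded) and split into 10 near-equal parts
(`numpy.array_split`: earlier parts one larger); forest i trains on all
positives + part i. Forests are scikit-learn `RandomForestClassifier`
with 100 trees, bootstrap resampling, √(#features) candidates per split
and unlimited depth — only the tree count is a fixed design choice, the
rest are common random-forest defaults and configurable. The sample
score is the arithmetic mean of the ten positive-class probabilities
(continuous scores are required for arbitrary-specificity thresholds; a
hard majority vote is not).

Thresholds: for target specificity s, t is the smallest value such that
the fraction of pooled out-of-fold negative scores strictly below t is
≥ s (higher-interpolation empirical quantile; if even the largest
negative score fails this, the next representable float above it).
Classification is strictly `score > t`, so the calibration scores always
achieve ≥ s, and t(VH) ≥ t(H) ≥ t(N) ≥ t(L) by quantile monotonicity.
Thresholds are computed on scores pooled across folds (not per-fold then
averaged): pooling uses every negative exactly once and gives the
tightest empirical quantile.

## Cross-validation and optimization

Stratified 10-fold; per fold the full ensemble is retrained on the other
nine folds and the held-out samples are scored; the reported AUC is the
mean of the ten per-fold AUCs, while pooled out-of-fold scores feed the
threshold calibration. Feature ranking is by information gain —
H(label) − H(label | feature) with continuous features discretized into
up to 10 equal-frequency bins, few-valued features used as-is, ties
broken by canonical feature order. By default the ranking is computed
once per geometry on the full optimization dataset, matching the
optimization procedure's shape; `leakage_free=True` re-ranks inside each
training fold for a stricter estimate. The default feature-count grid is
geometric (2, 4, 8, …, all) because the exhaustive integer sweep is
quadratic in L and meant for cluster runs; `feature_grid="exhaustive"`
restores it. Asymmetric geometries (L_u ≠ L_d) are allowed.

## Annotation conventions

* Context from the two downstream bases: CG, else CHG, else CHH; NA only
  when the needed downstream bases are missing (configurable to call CG
  from a single downstream base).
* mRNA regions use the half-open CDS interval: position < cds_start →
  5′UTR, < cds_end → CDS, else 3′UTR; noncoding classes → "noncoding".
* Distance to the translational start is `position − cds_start + 1`,
  anchoring the A of AUG at 1, so the C of AUGC is +4; upstream
  positions are negative. (Under this formula the base immediately 5′ of
  the start codon is 0; the anchor and the +4 convention are what the
  downstream analyses depend on.)
* The metagene profile maps each site to a fractional position within
  its region and aggregates into equal-width bins (default 30 per
  region), alongside the background density of all cytosines, which is
  the correct null when cytosine availability differs between regions.
* GFF3 ingestion is a minimal internal parser: exon/CDS features grouped
  by `Parent`, spliced in genomic order, minus-strand transcripts
  reverse-complemented, CDS endpoints mapped into transcript space.
  GFF3 coordinates are 1-based inclusive; internal 0-based half-open.

## Synthetic data

The generator emulates: i.i.d. background transcripts (default uniform
A/C/G/U, 50 transcripts of 500–2000 nt), planted positives at interior
cytosines (≥ 11 nt apart so flank redraws never collide), flanks redrawn
from a positional weight model that interpolates with ε between
background and a G-enriched profile (weight 0.9 on G at offsets ±1..±3;
real m⁵C flanks are G-biased near the site), optional forcing of a
programmed CG/CHG/CHH mix at the +1/+2 positions, and per-cytosine
bisulfite counts with negative-binomial coverage (mean 100, dispersion
5) and binomial C-counts at the planted level (default 0.3) or the
non-conversion error (0.005). ε = 0 produces flanks statistically
indistinguishable from background by construction.

It deliberately does **not** emulate: transcript-specific composition,
splice isoforms, read-level errors, positional coverage bias, partial
methylation heterogeneity across molecules, or any real motif beyond the
single-knob G enrichment. Passing tests therefore demonstrate that the
pipeline recovers signals of the planted form at the simulated sizes —
not field performance on real bisulfite data.

## Problem sizes used by the test suite and acceptance script

Synthetic cross-validation experiments use 500 positives / 5,000
negatives (11-nt windows, 150 features) — large enough that the null AUC
concentrates within ±0.05 of 0.5 and a strong planted signal clears 0.9,
small enough to run in tens of seconds per condition on one CPU. The
calling-recovery experiment uses 200 planted sites at coverage ≥ 50; the
context-mix round-trip uses 10,000 planted sites; the end-to-end smoke
path uses a 50-transcript cohort.

## Degenerate inputs and numerical conventions

* Metrics with zero denominators are reported as undefined (`None`),
  never 0; report tables round half-up to 3 decimals, raw values are
  kept internally.
* ROC AUC is the tie-aware rank statistic (P(s⁺ > s⁻) + ½P(tie)); PR
  area uses right-continuous steps (no linear interpolation of
  precision).
* The positional base-usage test is a two-sided rank-sum on 0/1
  indicators in its tie-corrected Mann–Whitney form without continuity
  correction — on indicators the correction distorts p-values away from
  the exact permutation law; the per-feature test is Welch's t (unequal
  variances, the safer default when only "two-sample t-test" is
  specified).
* Score ties at a threshold classify negative (strict `>`).
* Model archives are versioned; loading a mismatched version fails
  loudly rather than guessing.

## Known limitations

* The binomial/BH significance is a generic stand-in for whatever
  statistic produced the FDR column of a real pipeline; with very low
  coverage its discreteness makes the FDR filter conservative.
* Thresholds calibrated on GC-matched negatives transfer only
  approximately to transcriptome-wide scanning, where the negative
  distribution differs; the VH mode remains the recommended default for
  genome-scale runs.
* The exhaustive optimization sweep at full window range is
  computationally heavy by design; the geometric grid preserves the
  argmax in practice but is not guaranteed to.
* Streaming is per-transcript: memory scales with the largest single
  transcript, not the transcriptome.
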