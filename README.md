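# rnam5c

Prediction and transcriptome-wide annotation of RNA 5-methylcytosine
(m⁵C) sites from flanking sequence.

m⁵C is a post-transcriptional cytosine modification involved in RNA
localization and translational fidelity. Bisulfite sequencing can map it
at single-nucleotide resolution — unmethylated C reads as T, methylated C
stays C — but such maps are condition-specific snapshots. `rnam5c` is for
epitranscriptomics researchers who want to (a) call methylated cytosines
from bisulfite count tables, (b) train a sequence-based classifier on
those calls, and (c) annotate candidate m⁵C sites across a whole
transcriptome.

## The method

**Calling.** Per cytosine, the methylation level is the pseudo-counted
proportion P = (C + Ψ)/(T + C) with Ψ = 1/8, where C and T are the read
counts. Sites with P ≥ 1% and FDR ≤ 0.3 are positives. Evidence against
the non-conversion null is a one-sided binomial test of the C count at a
configurable error rate (default 0.005), Benjamini–Hochberg adjusted.

**Training data.** Each sample is a fixed-width RNA window centered on a
cytosine (borders N-filled). Per positive, 10 negative cytosines are
drawn from the surrounding 200-nt region with window GC content within
5%, so the classifier cannot shortcut via composition bias.

**Features.** A window of L nt maps to 4·L + 106 features: one-hot
binary encoding (4·L), k-mer frequencies for k ∈ {1,2,3} (84), and
pseudo dinucleotide composition — the 16 adjacent-dinucleotide
frequencies plus λ = 6 pseudo components θ_j built from physicochemical
correlations of dinucleotides j apart, weighted by w = 0.1 and
normalized to sum to 1 (16 + λ).

**Classifier.** The 10:1 class imbalance is handled by balanced bagging:
negatives are split into ten parts and ten random forests (100 trees
each) are trained, each on all positives plus one part; the prediction
score is the mean of the ten positive-class probabilities. Four
operating thresholds are anchored at 99/95/90/85% empirical specificity
on pooled cross-validation negative scores, defining the VH/H/N/L
confidence modes. Window geometry (L_u, L_d) and the number of
top-information-gain features are optimized by grid search over 10-fold
cross-validated AUC.

**Annotation.** Every cytosine of every transcript is scored and tagged
with its CG/CHG/CHH context (H ∈ {A, C, U}), its mRNA region
(5′UTR/CDS/3′UTR from GFF3), and its distance to the translational start
(A of AUG = 1), plus aggregate views: per-RNA-class tallies,
candidate-vs-background context proportions, and a length-normalized
metagene profile.

A synthetic-data module generates transcripts with planted positives
whose flanks are G-enriched with a tunable effect strength ε (real m⁵C
flanks are G-biased), and simulates the corresponding bisulfite counts —
so the entire pipeline is testable without any external data.

## Worked example

```python
import rnam5c as r

cfg = r.SimConfig(n_transcripts=50, length_range=(500, 1000),
                  n_positives=100, epsilon=1.0, seed=42)
transcripts, truth = r.simulate_dataset(cfg)
windows, labels = r.labeled_windows_from_simulation(
    transcripts, truth, neg_per_pos=10, upstream=5, downstream=5, seed=42)
X = r.encode_windows(windows)
names = r.feature_names(11)
print(f"{labels.sum()} positives, {(labels == 0).sum()} negatives, "
      f"{X.shape[1]} features per 11-nt window")

auc, pooled, pooled_labels, _ = r.cross_validate(X, labels, seed=42, folds=10)
print(f"10-fold cross-validated AUC: {auc:.3f}")

model = r.train_ensemble(X[labels == 1], X[labels == 0], seed=42,
                         feature_names=names, upstream=5, downstream=5)
model.thresholds = r.determine_thresholds(pooled, pooled_labels)
for mode, t in model.thresholds.items():
    print(f"{mode}: threshold {t:.3f}")

tms = [r.TranscriptModel(tid, seq) for tid, seq in transcripts.items()]
annotations = list(r.scan_transcripts(model, tms))
n_vh = sum(1 for a in annotations if "VHmode" in a.modes_passed)
print(f"scanned {len(annotations)} cytosines; {n_vh} pass VHmode")
```

prints

```
100 positives, 1000 negatives, 150 features per 11-nt window
10-fold cross-validated AUC: 0.988
VHmode: threshold 0.804
HMode: threshold 0.516
NMode: threshold 0.349
LMode: threshold 0.243
scanned 8726 cytosines; 151 pass VHmode
```

The AUC of 0.988 reflects the strong planted flanking signal (ε = 1);
the four thresholds decrease with the anchored specificity, and at the
strictest mode the scan recovers roughly the planted site count (100
planted among 8,726 cytosines, 151 called, i.e. a ~1.7% call rate at
99% specificity).

The same pipeline is available from the shell:

```sh
rnam5c simulate --seed 1 --fasta tx.fa --truth truth.tsv --counts counts.tsv
rnam5c call --counts counts.tsv --out called.tsv
rnam5c build-dataset --counts counts.tsv --fasta tx.fa \
    --upstream 5 --downstream 5 --out-fasta ds.fa --out-tsv ds.tsv
rnam5c train --fasta ds.fa --out model.joblib
rnam5c evaluate --model model.joblib --fasta ds.fa --out report.tsv
rnam5c annotate --model model.joblib --fasta tx.fa --out sites.tsv \
    --out-tallies tallies.tsv --out-contexts ctx.tsv --out-metagene meta.tsv
```

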