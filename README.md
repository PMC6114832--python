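# pseui

Pseudouridine (Ψ) site prediction from RNA sequence.

Pseudouridine is the most abundant post-transcriptional RNA modification,
an isomer of uridine installed by pseudouridine synthases in tRNA, rRNA,
snRNA and mRNA of essentially all organisms. Experimental mapping (e.g.
CMC-based Ψ-seq) is costly, so sequence-based classifiers are used to
prioritize candidate sites. `pseui` is a library and command-line tool for
building and evaluating such classifiers: given a fixed-length RNA segment
centered on a uridine, it predicts whether that uridine is pseudouridylated.
It is aimed at computational biologists who want a transparent,
reproducible baseline predictor with a leakage-safe evaluation protocol.

## The model

A candidate site is a segment R_ξ(U) = N₋ξ…N₋₁ U N₊₁…N₊ξ of length
L = 2ξ+1 (ξ=10 for the human/mouse models, ξ=15 for yeast). Segments are
encoded by any combination of five feature types:

* **NC** (4-dim) and **DC** (16-dim): mono- and overlapping dinucleotide
  frequencies.
* **pseDNC** (16+λ dim): DC augmented with λ tier-correlation factors
  θ_j = mean_i Θ(D_i, D_{i+j}), where Θ is the mean squared difference of
  z-scored physicochemical properties (free energy, hydrophilicity,
  stacking energy) of the two dinucleotides, weighted by w and jointly
  normalized with the frequencies.
* **PSNP** (2ξ+1 dim): position-specific nucleotide propensity. From the
  training classes, per-position nucleotide frequency matrices Z⁺ (positives)
  and Z⁻ (negatives) are fitted and the propensity Z_PSNP = Z⁺ − Z⁻ is used
  as a lookup table: component j of the encoding is Z_PSNP[N_j, j].
* **PSDP** (2ξ dim): the dinucleotide analog, a 16×2ξ propensity matrix.

The classifier is an RBF-kernel SVM, K(x,y) = exp(−‖x−y‖²/s²), with
kernel scale s and box constraint c tuned by grid search (γ-parameterized
libraries: γ = 1/s²). Feature subsets are chosen by sequential forward
selection (SFS) with jackknife-scored rounds. Performance is reported as
Sen, Spe, Acc and MCC in class-total form (N⁺, N⁻, false negatives N⁺₋,
false positives N⁻₊), plus ROC/AUC from the decision scores.

**Leakage-safe jackknife.** PSNP/PSDP are *trained* features, so
leave-one-out evaluation refits the propensity matrices inside every fold
from the n−1 training samples only; both the training samples and the
held-out sample are encoded with those fold-local matrices. Fitting the
matrices once on all n samples would leak the held-out label into its own
encoding and inflate every metric.

## Benchmark FASTA dialect

Labeled datasets are plain FASTA of fixed-length segments with the class in
the header: `>pos_1 … >pos_N` for validated Ψ sites, `>neg_1 … >neg_N` for
unvalidated central uridines. T is accepted and read as U. A custom header
convention can be supplied as a regex with a `(?P<label>pos|neg)` group
(`--label-regex` on the CLI). Published supplements distributed as
word-processor documents must be converted to this dialect once (copy each
sequence under a `>pos_i`/`>neg_i` header).

## Worked example

```bash
# a synthetic benchmark: 21-nt segments, planted positional bias
pseui synth --xi 10 --n-pos 30 --n-neg 30 --bias 0.8 --seed 7 -o bench.fasta
# wrote 60 segments (30+/30-) to bench.fasta

pseui train bench.fasta --xi 10 --recipe PSNP+DC --c 8 --s 2 -o model.joblib
# trained on bench (N+=30, N-=30); bundle 09f6c391ce13 -> model.joblib

pseui eval bench.fasta --xi 10 --recipe PSNP+DC --c 8 --s 2 --format json
```

prints the leakage-safe jackknife report

```json
{
  "metrics": {"Sen": 1.0, "Spe": 0.9667, "Acc": 0.9833, "MCC": 0.9672, "AUC": 1.0},
  "counts": {"N_plus": 30, "N_minus": 30, "FN": 0, "FP": 1}
}
```

i.e. all 30 positives and 29 of 30 negatives were classified correctly in
leave-one-out, with perfect ranking (AUC 1) — expected here because the
planted bias at strength 0.8 makes the classes nearly separable. Scanning
a query RNA scores every uridine (mirror-padding windows at the termini):

```bash
pseui predict query.fasta -b model.joblib
# sequence_id  position  score    label    segment
# q1           4         -0.8939  not-Psi  UGCAUGCACGUACGUACGUAC
# q1           8         -0.8883  not-Psi  UGCACGUACGUACGUACGUAC
```

`position` is the 1-based coordinate of the U on the input; `score` is the
SVM decision value (Ψ is called when it exceeds 0).

Shipped species presets (`pseui.classifier.load_species_preset`) carry the
per-species window sizes, optimal feature subsets and SVM hyperparameters:
human ξ=10 PSNP+DC (s=2, c=8), yeast ξ=15 DC+PSNP+pseDNC (s=0.25, c=2),
mouse ξ=10 PSNP+DC (s=1, c=2).

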