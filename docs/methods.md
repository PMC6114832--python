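# Methods

## Problem and model

`pseui` decides whether a uridine in an RNA sequence is pseudouridylated
(Ψ). The unit of analysis is the fixed-length window R_ξ(U): ξ nucleotides
on each side of the candidate U, length L = 2ξ+1. Classification is binary
(Ψ / not-Ψ) with an RBF-kernel SVM over one of five sequence encodings or
their concatenations.

The composition encoders (NC, DC, pseDNC) are functions of the segment
alone. The propensity encoders (PSNP, PSDP) are *fitted*: per-position
occurrence-frequency matrices Z⁺ and Z⁻ are estimated from the positive
and negative training segments separately, and the difference Z = Z⁺ − Z⁻
is used as a lookup table, so a segment's encoding at position j is the
propensity of its own nucleotide (or dinucleotide) at that position.
Frequencies are plain maximum-likelihood counts without pseudocounts;
smoothing would change every downstream number and the balanced benchmark
sizes (hundreds per class) do not need it. Columns of Z⁺/Z⁻ are probability
vectors, so columns of Z sum to 0, entries lie in [−1, 1], and the PSNP
center column is identically zero (the center is U in every sample of both
classes); the always-zero center component is kept so the encoding length
equals the matrix width, and a constant feature is inert for an SVM.

### pseDNC

The pseudo dinucleotide composition augments the 16 dinucleotide
frequencies f_u with λ tier-correlation factors

    θ_j = (1/(L−1−j)) Σ_i Θ(D_i, D_{i+j}),   j = 1..λ
    Θ(D, D′) = (1/μ) Σ_k (P_k(D) − P_k(D′))²

over μ selected physicochemical properties P_k, and normalizes jointly:
d_u = f_u/(Σf + wΣθ) for u ≤ 16, d_{16+j} = wθ_j/(Σf + wΣθ). The output is
a probability vector whose first 16 entries are proportional to DC, and
λ = 0 reduces exactly to DC. Properties (free energy, hydrophilicity,
stacking energy of the 16 RNA dinucleotides) ship as a CSV resource and
are z-scored per property across the 16 dinucleotides before use — the raw
scales differ by two orders of magnitude and would otherwise make Θ a
stacking-energy measure only. Defaults λ=2, w=0.5: the benchmark protocol
fixes K=2 and the three properties but leaves λ and w open, so modest
values are the default and both are exposed in `PseDNCConfig`; λ is capped
at L−2 (tier λ needs at least one dinucleotide pair).

## Leakage-safe jackknife

Leave-one-out evaluation refits the propensity matrices inside every fold:
the held-out sample contributes to neither Z⁺ nor Z⁻, and both the n−1
training samples and the held-out sample are encoded with the fold-local
matrices before the fold's SVM is trained and the held-out sample scored.
The implementation accumulates class-conditional occurrence counts once
and subtracts the held-out sample's contribution per fold, which is
numerically identical to recounting the n−1 samples (a regression test
checks this) and keeps the n-fold loop O(n·L) instead of O(n²·L) for the
counting. Verdicts are aggregated into class-total confusion counts; AUC
is computed from the n held-out decision scores. For recipes without
PSNP/PSDP the refit is a no-op and the jackknife is ordinary LOO-CV.

## Classifier and hyperparameters

The SVM uses K(x,y) = exp(−‖x−y‖²/s²) with kernel scale s and box
constraint c — the parameterization in which the species presets' values
are stated. scikit-learn's SVC backs the implementation with γ = 1/s²;
the conversion is centralized in `SVMConfig.gamma` because quoting s-values
to a γ-parameterized library silently changes every result. Solver
tolerance is 1e−3 (libsvm default); per-sample decision scores therefore
agree only to that order when sample order changes, though aggregated
verdict counts are permutation-invariant. Features are not standardized
before the SVM: the encoders already emit values in [−1, 1], and silent
rescaling would detach results from the presets' printed hyperparameters.
Classes carry equal weight (benchmarks are balanced by construction).
Decision threshold for calling Ψ is 0; ROC scores are the raw decision
values, not calibrated posteriors — deterministic and sufficient for
ranking.

Grid search evaluates the jackknife at every (c, s) cell; the default grid
is powers of two, s ∈ {2⁻³..2¹⁰} and c ∈ {2⁻⁵..2¹⁰}, wide enough to express
every preset and the extreme values (0.03125, 1024) seen in benchmark
tuning. Ties break toward higher Acc, then smaller c, then larger s — the
smoother, more regularized model.

## Sequential forward selection

A greedy wrapper over the five feature types: round 1 scores each type
alone, each later round scores every one-type extension of the incumbent,
and every candidate recipe in every round gets its own grid search (the
per-subset optima genuinely differ). Continuation requires *strict*
improvement of the criterion; equality stops — "converged" is otherwise
undefined. The criterion defaults to MCC with Acc as tie-breaker, MCC
being the decisive column in the benchmark tables. The full trace
(candidates, metrics, chosen hyperparameters per round) is retained and
exportable as a TSV with the benchmark tables' column layout.

## Evaluation metrics

Sen, Spe, Acc and MCC are computed in class-total form (N⁺, N⁻, false
negatives N⁺₋, false positives N⁻₊), which is algebraically identical to
the textbook TP/TN/FP/FN Matthews coefficient — the suite verifies the
identity on 10⁴ random confusion tables. A degenerate MCC denominator
(all-positive or all-negative predictions) is reported as 0 with an
explicit flag rather than NaN. AUC uses the rank/midpoint tie convention
so it equals the Mann–Whitney statistic P(s⁺ > s⁻) + ½P(tie); a brute-force
O(n²) pair-counting oracle in the tests cross-checks the library-backed
implementation.

## Mirror padding and site scanning

Scanning a query RNA produces one segment per uridine. A U closer than ξ
to a terminus lacks a full flank; the deficit is filled by reflecting the
sequence about its terminal nucleotide with the terminus excluded from the
reflection (no boundary-base doubling), repeating the reflection when the
sequence is shorter than the deficit — i.e. index i maps to the mirror
index of period 2(n−1). Query sequences must be at least 2ξ+1 nt (21 for
ξ=10, 31 for ξ=15); DNA-style T is converted to U silently, any other
symbol is an error rather than being skipped, so ambiguity codes fail
loudly. All reported coordinates are 1-based positions of the U on the
input sequence.

## Synthetic benchmark generator

The generator emulates the structure of the Ψ benchmarks: balanced classes
of fixed-length central-U segments. Positives carry a motif-like
class-conditional skew: at each biased position the planted nucleotide has
probability 1/4 + 3b/4 (bias strength b ∈ [0,1], so b=0 is uniform and b=1
a point mass), the other three sharing the remainder equally; negatives
and all unbiased positions are uniform. Defaults — the package's standard
study conditions, fixed once: ξ=10, 100 segments per class, b=0.6, biased
positions at center±1..±4 with planted nucleotides cycling A,C,G,U. The
eight-position span reflects the local recognition context of
pseudouridine synthases and guide RNAs (a few nucleotides around the
modified U), and the A,C,G,U cycling keeps aggregate composition matched
between classes so that positional encoders, not composition, carry the
signal. Under these conditions the PSNP jackknife accuracy is ≈0.85
(Bayes-optimal for the planted model is ≈0.84 by a Gaussian approximation
to the match-count statistic) and ≈0.5 at b=0.

What the generator does *not* emulate: real Ψ contexts have correlated
positions, secondary-structure constraints, class imbalance in genomic
scanning, and redundancy between related transcripts. Passing tests on
synthetic data therefore demonstrate the correctness of the machinery
(encodings, leakage-safe protocol, selection, scanning), not the field
accuracy of a model trained on real benchmarks.

## Problem sizes and numerical choices

Tests and the acceptance script run jackknifes at n ≤ 200 and selection at
n ≤ 100 with reduced grids (2×2), sizes at which the planted-signal
effects are unambiguous while a full run remains a few seconds; the
default grid (224 cells) is intended for real benchmark runs. Bundle
persistence uses joblib with a format-version field checked on load;
corrupt or truncated files raise a load error. Tolerances: property
z-scoring and matrix invariants are asserted at 1e−9; metric identities at
1e−10; SVM-score reproducibility at the solver tolerance.

## Known limitations

* The real benchmark datasets are not redistributed here; reproduction
  checks against their published numbers require a one-time conversion of
  the supplementary files to the documented FASTA dialect (see README).
  Cross-solver differences of ~1–2 accuracy points are expected even then.
* No probability calibration, no model classes besides the RBF-SVM, no
  K-fold/bootstrap evaluation (jackknife and independent tests only), no
  backward/floating selection, and no PseKNC beyond K=2.
* The propensity features assume balanced, same-length, central-U
  segments; the package validates these invariants rather than coping with
  violations.
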