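# Methods

## Problem

Protein–protein interfaces are mediated by a minority of surface residues.
Given one chain, the task is per-residue binary classification: does this
residue belong to a binding site? The classifier sees no coordinates of the
partner — only profiles computable from the chain itself: evolutionary
conservation (PSSM from iterative database search, match-emission
probabilities from a profile HMM) and predicted/assigned local structure
(DSSP states, backbone torsions, solvent accessibility). Labels are consumed
as input; defining them from complex structures is out of scope.

## Feature encoding

Each residue is a 54-dimensional composite held as three blocks:

* **PSSM (20)** — integer log-odds from the PSI-BLAST ASCII matrix (the
  first 20 columns; the weighted-percentage block is ignored). Min–max
  scaled per column to [0, 1] with extrema taken over *all residues of the
  training set*. Values outside the training range at test time are clamped
  into [0, 1]; a constant column maps to 0.
* **HMM (20)** — `.hhm` stores match emissions as `-1000·log2 p`; we decode
  `s → 2^(-s/1000)` (strictly decreasing in `s`), map the `*` absent cell to
  probability 0, then min–max scale exactly as for the PSSM, with extrema
  fitted on the probability scale and absent cells excluded from the fit.
* **DSSP (14)** — a 9-way one-hot over the eight DSSP states
  (H, G, I, T, B, E, S, and blank = loop) plus a ninth *absent* state for
  residues DSSP skipped; sin/cos of φ and ψ rescaled from [-1, 1] to [0, 1]
  by `(v+1)/2`, with DSSP's 360.0 "undefined" sentinel mapped to the neutral
  0.5; and relative solvent accessibility `acc / maxASA(residue)`, capped at
  1. `maxASA` is the Tien et al. (2013) theoretical scale; unknown residue
  types (X) fall back to the 20-residue mean. Missing residues get the
  absent one-hot, neutral torsions and RSA 0. DSSP features are bounded by
  construction and are not refitted.

Keeping the blank structure column as *loop* and reserving the ninth state
for residues absent from DSSP output follows the eight-plus-absence reading
of the state set; the distinction matters only for chains whose DSSP run
dropped residues.

Normalization statistics are a first-class object with a provenance tag
(which training split produced them) and a JSON serialization that
round-trips bit-identically, so leakage is auditable.

## Windows

Residue `i` is represented by the feature rows `i−a … i+a` (window
`n = 2a+1`, default `a = 9`, `n = 19`). Rows beyond the termini are zero
vectors: zero padding is the minimal-information choice and keeps batch
shapes uniform; chains shorter than the window are legal. Row `a` of every
window is the residue's own feature row (asserted by tests).

## Architecture

Three parallel convolutional branches, one per feature type, in fixed order
(PSSM, DSSP, HMM):

| stage | shape (window 19, PSSM branch) |
|---|---|
| input | 19 × 20 |
| conv k=5, 64 filters, ReLU | 15 × 64 |
| conv k=3, 32 filters, ReLU | 13 × 32 |
| conv k=3, 16 filters, ReLU | 11 × 16 |
| layer norm → dropout → flatten | 176 |

Convolutions are 1-D along the window axis with features as channels,
stride 1, no padding ("valid") — borders are already handled by window
padding, and valid extents make the flattened widths well-defined. Layer
normalization acts per sample over (position, channel) of the final conv
output; dropout rates are branch-specific: 0.1 (PSSM), 0.3 (DSSP),
0.2 (HMM). The three 176-wide branch outputs are concatenated in branch
order (528 wide) and classified by dense layers 256 → 128 → 64 → 1, ReLU on
hidden layers and a sigmoid output. The dense head carries no dropout.
A window must satisfy `n ≥ 9` for the default kernel stack.

All layers (convolution, layer norm, dropout, dense) and their backward
passes are implemented in NumPy inside `ppisite.nn`; gradients are verified
against central finite differences to ~1e-6 in the test suite.

## Training

Binary cross-entropy, minimized by SGD with classical momentum. Scores are
clipped 1e-7 inside (0, 1) before logs so the loss is always finite; the
logit-space gradient is computed in closed form. Library defaults: learning
rate 0.01, momentum 0.9, batch 256, up to 150 epochs. When a validation
batch is supplied, early stopping watches validation AUPRC (patience 15
default) and restores the best-epoch weights; a single-class validation
split falls back to validation loss. Dropout uses its own seeded stream;
two runs with the same seeds are bit-identical. No class weighting by
default; an optional positive-class weight is exposed.

For the ~5,000-residue synthetic study scale used by the cross-validation,
window-scan and ablation runs shipped with the package, the schedule is
learning rate 0.02, batch 128, at most 40 epochs, patience 10: at this data
size the network reaches its held-out optimum within ~15–30 epochs and then
memorizes, so longer schedules only add runtime.

## Evaluation

Splitting is always by whole protein. Residue-level splits would place
near-identical overlapping windows on both sides of the split;
normalization statistics are refitted inside every training split for the
same reason, and their provenance tags are asserted in tests. Folds are a
seeded shuffle followed by round-robin assignment.

Thresholded metrics (ACC, precision, recall, F1, MCC) come from the
confusion counts at `score ≥ threshold` (default 0.5; an option tunes the
threshold to maximize F1 on the validation carve-out). AUROC is the ranking
statistic (ties ½); AUPRC is step-wise precision–recall integration without
trapezoid interpolation (optimism-free). Degenerate cases are explicit: MCC
with a zero marginal is reported as 0 and flagged; AUROC/AUPRC on a
single-class fold are NaN, flagged, and excluded from fold means with a
warning. All seven metrics are checked against an exhaustive brute-force
oracle (explicit loops, all-pairs AUROC) to 1e-10.

Feature ablation trains reduced models — evolutionary (PSSM+HMM branches),
structural (DSSP branch), all — on a shared protein-level train/test split
so the comparison is paired.

## Synthetic data

The generator writes real dialects (PSI-BLAST ASCII PSSM, `.hhm`, classic
fixed-column DSSP, FASTA, label TSV) that byte-identically round-trip
through the package's parsers, with ground-truth arrays kept in the
manifest. Default conditions: 50 chains of 60–140 residues (~5,000
windows), 18% positive residues, `.hhm` absent-cell rate 2%, PSSM integers
in [-8, 12], `.hhm` scores in [0, 6000], secondary structure from a
run-length Markov chain (stay probability 0.8), torsions from
Ramachandran-like mixtures per state (chain-end angles undefined, values
quantized to the 0.1° the DSSP format carries).

Labels are drawn from a logistic model on the relative-accessibility
channel averaged over ±8 neighbors, standardized across the dataset, with
effect size 8 and the intercept calibrated by root finding so the expected
prevalence hits the target. RSA is the natural channel for a planted
positive control — real interfaces are exposed surface patches — and the
±8 span makes window size causally relevant: a 19-residue window covers the
signal's support, a 9-residue window does not. The effect size is chosen so
the generator's own Bayes-optimal scorer reaches AUROC ≈ 0.99, leaving
clear headroom between "model recovers the signal" and "model at chance".
Signal on evolutionary columns (and multi-channel mixtures) is available
through `signal_channels`.

What passing these tests shows: the pipeline is plumbing-correct end to end
and the classifier can learn a strong localized signal at desk scale. What
it does not show: performance on real interfaces, where conservation
patterns are structured, features are correlated, and effect sizes are far
smaller — the published benchmark numbers require the real datasets and
profile databases and are out of scope here.

## Numerical choices

* float32 forward/backward by default (float64 for gradient checking).
* He initialization for conv/dense weights (ReLU follows each).
* Layer-norm epsilon 1e-5.
* BCE clipping at 1e-7 from both ends of (0, 1).
* MCC computed in float to avoid integer overflow on large counts.
* Residue-letter agreement between profiles tolerates X on either side and
  up to 5% mismatches before alignment fails.
* Sigmoid computed in the numerically stable split form; predicted scores
  clipped to the open interval so downstream logs are safe.

## Known limitations

* The NumPy training loop is single-threaded BLAS-bound; it is sized for
  desk-scale experiments (thousands of residues), not the full benchmark
  corpora.
* The `.hhm` parser reads match emissions only; transition and diversity
  columns are discarded by design.
* DSSP parsing targets the classic fixed-column dialect (as emitted by
  mkdssp ≤ 3.x and this package's writer); mmCIF-style DSSP output is not
  supported.
* The generator's chains are independent draws — no homology, no
  redundancy structure — so protein-level fold splitting is sufficient for
  leakage control on synthetic data; on real data redundancy reduction
  between folds would additionally be required.
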