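# ppisite

Per-residue prediction of protein–protein binding sites from sequence-derived
profiles, for structural bioinformaticians who have (or can compute)
PSI-BLAST PSSMs, HHblits `.hhm` profiles and DSSP output for a chain and want
a trainable, inspectable classifier over them.

## The model

Each residue *i* of a chain is described by three aligned profile rows:

* **PSSM** — 20 log-odds scores from iterative sequence search, min–max
  normalized to [0, 1] with training-set extrema;
* **HMM** — 20 match-emission probabilities decoded from the `.hhm` encoding
  *p* = 2^(−s/1000), normalized the same way;
* **DSSP** — a 14-dimensional structural vector: 9-way one-hot secondary
  structure (8 DSSP states + an absent state), sin/cos of φ and ψ rescaled to
  [0, 1], and relative solvent accessibility acc / maxASA.

A sliding window of *n* = 2a+1 residues (default 19) centred on *i* gives
three m×n matrices (m = 20, 20, 14). Each feeds its own convolutional branch
— kernels 5, 3, 3 with 64, 32, 16 filters, stride 1, ReLU, then layer
normalization and branch-specific dropout (0.1 / 0.3 / 0.2 for
PSSM / DSSP / HMM). The flattened branch outputs (3 × 176 = 528 at n = 19)
are concatenated and classified by dense layers 256 → 128 → 64 → 1 with a
sigmoid output:

    ReLU(f) = max(0, f)        σ(f) = 1 / (1 + e^(−f))
    BCE = −(1/n) Σ [ aᵢ log bᵢ + (1 − aᵢ) log(1 − bᵢ) ]

trained by SGD with momentum. Evaluation is protein-level k-fold
cross-validation with ACC, precision, recall, F1, MCC, AUROC and AUPRC;
normalization statistics are refitted inside each training split.

The network and its training loop are implemented in NumPy in
`ppisite.nn` / `ppisite.model`, with gradients verified against finite
differences in the test suite. See `docs/methods.md` for the full account.

## Worked example

A synthetic dataset generator emits all input formats with labels coupled to
the features (see `docs/methods.md`), so the pipeline runs with no external
tools:

```sh
ppisite simulate --n-proteins 12 --seed 7 --out-dir demo
ppisite featurize demo --labels demo/labels.tsv --out demo/windows.npz
echo '{"training": {"max_epochs": 20, "batch_size": 64}}' > train_cfg.json
ppisite train demo/windows.npz --config train_cfg.json --seed 1 --out-dir demo/run
ppisite predict demo/run/checkpoint.npz demo/windows.npz --out demo/pred.tsv
ppisite eval demo/pred.tsv
```

`featurize` reports 1,287 windows (12 chains); `predict` writes one row per
residue:

```
protein_id  position  residue  score                   label  call
S000A       1         Y        3.276648033185683e-05   0      0
S000A       2         A        0.0010537173162102494   0      0
S000A       3         I        0.0004041176668222119   0      0
```

and `eval` prints the metrics of those predictions — here training-set
metrics of a short run, so they are optimistic by construction:

```
acc 0.984  precision 0.946  recall 0.966  f1 0.956  mcc 0.946
auroc 0.998  auprc 0.992   (threshold 0.5; TP 227 TN 1039 FP 13 FN 8)
```

Held-out numbers come from `scan` / `ablate` or the library's
`cross_validate`, which never score a protein seen in training.

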