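"""Protein-level cross-validation, window scanning, ablation and metrics.

Splitting is always by whole protein: residues of one chain are windows over
heavily overlapping feature rows, so residue-level splits would leak
near-duplicates between training and validation. Normalization statistics
are refitted inside every training split for the same reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .features import NormalizationStats, encode_chain, fit_normalization
from .model import BindingSiteCNN, ModelConfig, TrainConfig, build_model
from .profile_io import AlignedProfiles
from .windows import BRANCH_ORDER, WindowBatch, WindowConfig, extract_windows

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "CVResult",
    "FEATURE_SUBSETS",
    "make_folds",
    "compute_metrics",
    "best_f1_threshold",
    "cross_validate",
    "window_scan",
    "ablate_features",
    "write_predictions",
]

#: Feature-set ablation subsets -> model branches.
FEATURE_SUBSETS: dict[str, tuple[str, ...]] = {
    "evolutionary": ("pssm", "hmm"),
    "structural": ("dssp",),
    "all": BRANCH_ORDER,
}


@dataclass(frozen=True)
class FoldSplit:
    """A k-way partition of protein ids (disjoint, covering)."""

    folds: tuple[tuple[str, ...], ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_ids(self, fold: int) -> tuple[str, ...]:
        return tuple(pid for i, f in enumerate(self.folds) if i != fold for pid in f)


def make_folds(proteins: Sequence[str], k: int, seed: int) -> FoldSplit:
    """Seeded shuffle followed by round-robin assignment to k folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(proteins) < k:
        raise ValueError(f"{len(proteins)} proteins cannot fill {k} folds")
    if len(set(proteins)) != len(proteins):
        raise ValueError("duplicate protein ids")
    order = list(proteins)
    np.random.default_rng(seed).shuffle(order)
    folds = tuple(tuple(order[i::k]) for i in range(k))
    return FoldSplit(folds, seed)


@dataclass
class MetricsReport:
    """Thresholded confusion metrics plus threshold-free ranking metrics.

    Metrics whose defining ratio is degenerate on this data (e.g. MCC with a
    zero marginal, AUROC with a single class) are reported as the stated
    fallback and named in ``degenerate``.
    """

    acc: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auroc: float
    auprc: float
    threshold: float
    tp: int
    tn: int
    fp: int
    fn: int
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "acc": self.acc, "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "mcc": self.mcc, "auroc": self.auroc,
            "auprc": self.auprc, "threshold": self.threshold,
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "degenerate": list(self.degenerate),
        }


def compute_metrics(labels: np.ndarray, scores: np.ndarray,
                    threshold: float = 0.5) -> MetricsReport:
    """Confusion-count metrics at ``score >= threshold`` plus AUROC/AUPRC.

    ACC = (TP+TN)/total, recall = TP/(TP+FN), precision = TP/(TP+FP),
    F1 = 2TP/(2TP+FP+FN), MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    AUROC is the rank statistic over all thresholds (ties count 1/2); AUPRC is
    the step-wise precision-recall integral (no trapezoid interpolation).
    """
    y = np.asarray(labels).ravel().astype(int)
    s = np.asarray(scores, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    pred = s >= threshold
    pos = y == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    degenerate: list[str] = []

    acc = (tp + tn) / y.size
    if tp + fp == 0:
        precision = 0.0
        degenerate.append("precision")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        degenerate.append("recall")
    else:
        recall = tp / (tp + fn)
    if 2 * tp + fp + fn == 0:
        f1 = 0.0
        degenerate.append("f1")
    else:
        f1 = 2 * tp / (2 * tp + fp + fn)

    denom = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        mcc = 0.0
        degenerate.append("mcc")
    else:
        mcc = (float(tp) * tn - float(fp) * fn) / np.sqrt(denom)

    if y.min() == y.max():
        auroc = float("nan")
        auprc = float("nan")
        degenerate += ["auroc", "auprc"]
    else:
        auroc = float(roc_auc_score(y, s))
        auprc = float(average_precision_score(y, s))

    return MetricsReport(acc, precision, recall, f1, mcc, auroc, auprc,
                         threshold, tp, tn, fp, fn, tuple(degenerate))


def best_f1_threshold(labels: np.ndarray, scores: np.ndarray) -> float:
    """Threshold (among observed scores) maximizing F1; ties -> lowest."""
    y = np.asarray(labels).ravel().astype(int)
    s = np.asarray(scores, dtype=float).ravel()
    candidates = np.unique(s)
    best_t, best_f1 = 0.5, -1.0
    for t in candidates:
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        denom = 2 * tp + int(np.sum(pred & (y == 0))) + int(np.sum(~pred & (y == 1)))
        f1 = 2 * tp / denom if denom else 0.0
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t


# ---------------------------------------------------------------------------
# dataset plumbing


def _dataset_windows(
    chains: Sequence[AlignedProfiles],
    stats: NormalizationStats,
    wcfg: WindowConfig,
) -> WindowBatch:
    batches = []
    for chain in chains:
        feats = encode_chain(chain.pssm, chain.hmm, chain.dssp, stats)
        batches.append(
            extract_windows(feats, wcfg, protein_id=chain.record.protein_id,
                            labels=chain.record.labels)
        )
    return WindowBatch.concatenate(batches)


def _fit_split(
    train_chains: Sequence[AlignedProfiles],
    wcfg: WindowConfig,
    model_config: ModelConfig,
    train_config: TrainConfig,
    seed: int,
    provenance: str,
    val_fraction: float = 0.1,
) -> tuple[BindingSiteCNN, NormalizationStats, WindowBatch | None]:
    """Fit normalization and model on a training split, with an internal
    protein-level validation carve-out for early stopping."""
    rng = np.random.default_rng(seed)
    ids = [c.record.protein_id for c in train_chains]
    order = rng.permutation(len(ids))
    n_val = max(1, int(round(val_fraction * len(ids)))) if len(ids) > 3 else 0
    val_idx = set(order[:n_val].tolist())
    tr = [c for i, c in enumerate(train_chains) if i not in val_idx]
    va = [c for i, c in enumerate(train_chains) if i in val_idx]

    stats = fit_normalization([c.pssm for c in tr], [c.hmm for c in tr],
                              provenance=provenance)
    train_batch = _dataset_windows(tr, stats, wcfg)
    val_batch = _dataset_windows(va, stats, wcfg) if va else None
    model = build_model(model_config, seed=int(rng.integers(2**31)))
    model.fit(train_batch, val_batch, train_config)
    return model, stats, val_batch


@dataclass
class CVResult:
    """Per-fold reports plus their means (degenerate folds excluded)."""

    folds: FoldSplit
    reports: list[MetricsReport]
    stats_provenance: list[str]
    mean: dict[str, float] = field(init=False)

    _METRICS = ("acc", "precision", "recall", "f1", "mcc", "auroc", "auprc")

    def __post_init__(self) -> None:
        self.mean = {}
        for name in self._METRICS:
            vals = [getattr(r, name) for r in self.reports
                    if name not in r.degenerate]
            if len(vals) < len(self.reports):
                warnings.warn(
                    f"metric {name!r} degenerate in "
                    f"{len(self.reports) - len(vals)} fold(s); excluded from mean"
                )
            self.mean[name] = float(np.mean(vals)) if vals else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() | {"fold": i} for i, r in enumerate(self.reports)]
        return pd.DataFrame(rows).set_index("fold")


def cross_validate(
    dataset: Sequence[AlignedProfiles],
    window_config: WindowConfig | None = None,
    train_config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    threshold: float | str = 0.5,
    branches: tuple[str, ...] = BRANCH_ORDER,
) -> CVResult:
    """k-fold cross-validation with protein-level splits.

    Each fold trains on the other k-1 folds (normalization statistics
    refitted on that training split only) and is scored on the held-out
    proteins. ``threshold`` may be a number or ``"tune"`` to pick the
    F1-maximizing threshold on the internal validation carve-out.
    """
    wcfg = window_config or WindowConfig()
    tcfg = train_config or TrainConfig()
    for chain in dataset:
        if chain.record.labels is None:
            raise ValueError(f"{chain.record.protein_id}: no labels")
    by_id = {c.record.protein_id: c for c in dataset}
    split = make_folds(list(by_id), k, seed)
    mcfg = ModelConfig(window=wcfg.window, branches=branches)

    reports, provenances = [], []
    for fold in range(k):
        train_chains = [by_id[p] for p in split.train_ids(fold)]
        test_chains = [by_id[p] for p in split.folds[fold]]
        provenance = f"cv-seed{seed}-fold{fold}-train"
        model, stats, val_batch = _fit_split(
            train_chains, wcfg, mcfg, tcfg,
            seed=seed + 7919 * (fold + 1), provenance=provenance,
        )
        test_batch = _dataset_windows(test_chains, stats, wcfg)
        scores = model.predict_proba(test_batch)
        if threshold == "tune":
            if val_batch is None:
                raise ValueError("threshold tuning needs a validation carve-out")
            thr = best_f1_threshold(val_batch.labels,
                                    model.predict_proba(val_batch))
        else:
            thr = float(threshold)
        reports.append(compute_metrics(test_batch.labels, scores, thr))
        provenances.append(stats.provenance)
    return CVResult(split, reports, provenances)


def window_scan(
    dataset: Sequence[AlignedProfiles],
    a_values: Iterable[int],
    train_config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate once per window half-width; returns (a, n, acc, auroc)."""
    rows = []
    for a in a_values:
        result = cross_validate(dataset, WindowConfig(a), train_config,
                                k=k, seed=seed)
        rows.append({
            "half_width": a,
            "window": 2 * a + 1,
            "mean_acc": result.mean["acc"],
            "mean_auroc": result.mean["auroc"],
        })
    return pd.DataFrame(rows, columns=["half_width", "window",
                                       "mean_acc", "mean_auroc"])


def ablate_features(
    dataset: Sequence[AlignedProfiles],
    subsets: Sequence[str] = ("evolutionary", "structural", "all"),
    window_config: WindowConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    test_fraction: float = 0.2,
    threshold: float = 0.5,
) -> dict[str, dict]:
    """Train reduced models (named branches only) and score a held-out set.

    The train/test split is protein-level and shared across subsets so the
    comparison is paired.
    """
    wcfg = window_config or WindowConfig()
    tcfg = train_config or TrainConfig()
    for name in subsets:
        if name not in FEATURE_SUBSETS:
            raise ValueError(
                f"unknown feature subset {name!r}; choose from "
                f"{sorted(FEATURE_SUBSETS)}"
            )
    rng = np.random.default_rng(seed)
    chains = list(dataset)
    order = rng.permutation(len(chains))
    n_test = max(1, int(round(test_fraction * len(chains))))
    test_idx = set(order[:n_test].tolist())
    train_chains = [c for i, c in enumerate(chains) if i not in test_idx]
    test_chains = [c for i, c in enumerate(chains) if i in test_idx]

    out: dict[str, dict] = {}
    for name in subsets:
        branches = FEATURE_SUBSETS[name]
        mcfg = ModelConfig(window=wcfg.window, branches=branches)
        name_salt = sum(ord(ch) for ch in name)  # stable across processes
        model, stats, _ = _fit_split(
            train_chains, wcfg, mcfg, tcfg, seed=seed + name_salt,
            provenance=f"ablate-{name}-seed{seed}-train",
        )
        test_batch = _dataset_windows(test_chains, stats, wcfg)
        scores = model.predict_proba(test_batch)
        out[name] = {
            "branches": branches,
            "report": compute_metrics(test_batch.labels, scores, threshold),
        }
    return out


def write_predictions(
    path: str | Path,
    batch: WindowBatch,
    scores: np.ndarray,
    threshold: float = 0.5,
    residue_letters: dict[str, str] | None = None,
) -> None:
    """Write per-residue predictions as TSV (positions 1-based)."""
    rows = []
    for (pid, pos), score in zip(batch.residue_ids, scores):
        if residue_letters is not None:
            letter = residue_letters[pid][pos]
        elif batch.letters is not None:
            letter = str(batch.letters[len(rows)])
        else:
            letter = "."
        rows.append({
            "protein_id": pid,
            "position": pos + 1,
            "residue": letter,
            "score": float(score),
            "label": int(batch.labels[len(rows)]) if batch.labels is not None else ".",
            "call": int(score >= threshold),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
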