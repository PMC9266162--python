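"""Fold construction, metric formulas against brute force, CV plumbing."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppisite.model import ModelConfig, TrainConfig
from ppisite.train_eval import (
    FEATURE_SUBSETS,
    ablate_features,
    best_f1_threshold,
    compute_metrics,
    cross_validate,
    make_folds,
    window_scan,
)
from ppisite.windows import WindowConfig

# ---------------------------------------------------------------------------
# brute-force metric oracle


def oracle_metrics(labels, scores, threshold):
    """Exhaustive reference: explicit loops, all-pairs AUROC (ties = 1/2),
    step-wise AUPRC."""
    tp = tn = fp = fn = 0
    for y, s in zip(labels, scores):
        call = s >= threshold
        if y == 1 and call:
            tp += 1
        elif y == 1:
            fn += 1
        elif call:
            fp += 1
        else:
            tn += 1
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn) - (fp * fn)) / denom if denom else 0.0

    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    if pos and neg:
        wins = 0.0
        for p in pos:
            for n in neg:
                wins += 1.0 if p > n else (0.5 if p == n else 0.0)
        auroc = wins / (len(pos) * len(neg))
        # step integration over descending unique thresholds
        order = sorted(set(scores), reverse=True)
        auprc = 0.0
        r_prev = 0.0
        tp_c = fp_c = 0
        for t in order:
            for y, s in zip(labels, scores):
                if s == t:
                    if y == 1:
                        tp_c += 1
                    else:
                        fp_c += 1
            prec = tp_c / (tp_c + fp_c)
            rec = tp_c / len(pos)
            auprc += (rec - r_prev) * prec
            r_prev = rec
    else:
        auroc = auprc = float("nan")
    return dict(acc=acc, precision=precision, recall=recall, f1=f1, mcc=mcc,
                auroc=auroc, auprc=auprc, tp=tp, tn=tn, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# folds


def test_even_folds():
    split = make_folds([f"p{i}" for i in range(10)], 5, 0)
    assert sorted(len(f) for f in split.folds) == [2] * 5


def test_fold_determinism_and_partition():
    ids = [f"p{i}" for i in range(13)]
    s1 = make_folds(ids, 5, 3)
    s2 = make_folds(ids, 5, 3)
    assert s1.folds == s2.folds
    flat = [p for f in s1.folds for p in f]
    assert sorted(flat) == sorted(ids)


def test_remainder_rule():
    split = make_folds([f"p{i}" for i in range(11)], 5, 1)
    assert sorted(len(f) for f in split.folds) == [2, 2, 2, 2, 3]


def test_too_few_proteins():
    with pytest.raises(ValueError):
        make_folds(["a", "b"], 5, 0)


# ---------------------------------------------------------------------------
# metrics


def test_perfect_separation():
    y = np.array([1] * 10 + [0] * 30)
    s = np.where(y == 1, 0.9, 0.1)
    r = compute_metrics(y, s, 0.5)
    for name in ("acc", "precision", "recall", "f1", "mcc", "auroc", "auprc"):
        assert getattr(r, name) == 1.0
    assert (r.tp, r.tn, r.fp, r.fn) == (10, 30, 0, 0)


def test_null_classifier_auroc_near_half():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 10_000)
    s = rng.random(10_000)
    r = compute_metrics(y, s, 0.5)
    assert abs(r.auroc - 0.5) < 0.02


def test_metrics_match_oracle_seed9():
    rng = np.random.default_rng(9)
    y = rng.integers(0, 2, 500)
    s = np.round(rng.random(500), 2)  # ties on purpose
    r = compute_metrics(y, s, 0.4)
    want = oracle_metrics(y.tolist(), s.tolist(), 0.4)
    for name, value in want.items():
        assert abs(getattr(r, name) - value) < 1e-10, name


def test_confusion_identities():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 200)
    s = rng.random(200)
    r = compute_metrics(y, s, 0.3)
    assert r.tp + r.tn + r.fp + r.fn == 200
    assert r.acc == (r.tp + r.tn) / 200
    assert r.f1 == 2 * r.tp / (2 * r.tp + r.fp + r.fn)


def test_degenerate_single_class_flagged():
    y = np.zeros(10, dtype=int)
    s = np.linspace(0.1, 0.4, 10)
    r = compute_metrics(y, s, 0.5)
    assert r.mcc == 0.0
    assert {"mcc", "auroc", "auprc"} <= set(r.degenerate)
    assert math.isnan(r.auroc)


def test_empty_input_is_error():
    with pytest.raises(ValueError):
        compute_metrics(np.array([]), np.array([]), 0.5)


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_auroc_label_score_swap_invariance(seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, 60)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    s = np.round(rng.random(60), 2)
    a1 = compute_metrics(y, s, 0.5).auroc
    a2 = compute_metrics(1 - y, 1.0 - s, 0.5).auroc
    assert abs(a1 - a2) < 1e-12


def test_best_f1_threshold():
    y = np.array([0, 0, 1, 1])
    s = np.array([0.1, 0.4, 0.6, 0.9])
    t = best_f1_threshold(y, s)
    assert 0.4 < t <= 0.6


# ---------------------------------------------------------------------------
# cross-validation plumbing (tiny problem sizes)


_FAST = TrainConfig(max_epochs=2, patience=2, batch_size=64, seed=0)


def test_cross_validate_deterministic_and_leak_tagged(small_manifest):
    ds = small_manifest.dataset()[:8]
    kw = dict(window_config=WindowConfig(4), train_config=_FAST, k=4, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = cross_validate(ds, **kw)
        r2 = cross_validate(ds, **kw)
    assert r1.folds == r2.folds
    assert r1.mean == r2.mean
    for fold, tag in enumerate(r1.stats_provenance):
        assert tag == f"cv-seed2-fold{fold}-train"


def test_cross_validate_requires_labels(small_manifest):
    from ppisite.profile_io import AlignedProfiles, ProteinRecord

    chain = small_manifest.dataset()[0]
    bare = AlignedProfiles(
        ProteinRecord(chain.record.protein_id, chain.record.sequence),
        chain.pssm, chain.hmm, chain.dssp,
    )
    with pytest.raises(ValueError, match="labels"):
        cross_validate([bare] * 5, k=5)


def test_window_scan_bookkeeping(small_manifest):
    ds = small_manifest.dataset()[:8]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = window_scan(ds, [4, 5], _FAST, k=4, seed=0)
    assert list(table["half_width"]) == [4, 5]
    assert list(table["window"]) == [9, 11]
    empty = window_scan(ds, [], _FAST, k=4, seed=0)
    assert empty.empty


def test_ablate_branch_counts_and_unknown_subset(small_manifest):
    ds = small_manifest.dataset()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = ablate_features(ds, ("evolutionary", "structural"),
                              WindowConfig(4), _FAST, seed=0)
    assert out["evolutionary"]["branches"] == ("pssm", "hmm")
    assert out["structural"]["branches"] == ("dssp",)
    with pytest.raises(ValueError, match="unknown feature subset"):
        ablate_features(ds, ("bogus",), WindowConfig(4), _FAST)


def test_feature_subset_table_is_three_way():
    assert set(FEATURE_SUBSETS) == {"evolutionary", "structural", "all"}
    assert FEATURE_SUBSETS["all"] == ("pssm", "dssp", "hmm")
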