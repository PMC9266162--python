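"""Feature encoding: min-max normalization, HMM decoding, 14-d DSSP vector."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppisite.features import (
    MAX_ASA,
    NormalizationStats,
    encode_chain,
    encode_dssp,
    encode_hmm,
    encode_pssm,
    fit_normalization,
    hhm_score_to_probability,
)
from ppisite.profile_io import DsspResidue, RawDssp, RawHmm, RawPssm


def _stats(pssm_lo=-8, pssm_hi=12, hmm_lo=0.0, hmm_hi=1.0):
    return NormalizationStats(
        np.full(20, float(pssm_lo)), np.full(20, float(pssm_hi)),
        np.full(20, hmm_lo), np.full(20, hmm_hi),
    )


# ---------------------------------------------------------------------------
# normalization statistics


def test_constant_column_encodes_to_zero():
    raw = RawPssm(np.full((1, 20), 3, dtype=int), "M")
    stats = fit_normalization([raw], [RawHmm(np.zeros((1, 20)), "M")])
    np.testing.assert_array_equal(stats.pssm_min, stats.pssm_max)
    np.testing.assert_array_equal(encode_pssm(raw, stats), np.zeros((1, 20)))


def test_extrema_over_two_residues():
    scores = np.zeros((2, 20), dtype=int)
    scores[0, 0], scores[1, 0] = -2, 6
    stats = fit_normalization(
        [RawPssm(scores, "MK")], [RawHmm(np.zeros((2, 20)), "MK")]
    )
    assert stats.pssm_min[0] == -2 and stats.pssm_max[0] == 6


def test_extrema_match_brute_force_oracle():
    rng = np.random.default_rng(3)
    pssms = [RawPssm(rng.integers(-8, 13, (L, 20)), "M" * L)
             for L in (5, 9, 14)]
    hmm_scores = [rng.integers(0, 6001, (L, 20)).astype(float)
                  for L in (5, 9, 14)]
    for s in hmm_scores:
        s[rng.random(s.shape) < 0.1] = np.nan
    hmms = [RawHmm(s, "M" * s.shape[0]) for s in hmm_scores]
    stats = fit_normalization(pssms, hmms)

    # brute force: explicit loops over every residue of every chain
    lo = np.full(20, np.inf)
    hi = np.full(20, -np.inf)
    for p in pssms:
        for row in p.scores:
            for c in range(20):
                lo[c] = min(lo[c], row[c])
                hi[c] = max(hi[c], row[c])
    np.testing.assert_array_equal(stats.pssm_min, lo)
    np.testing.assert_array_equal(stats.pssm_max, hi)

    lo_h = np.full(20, np.inf)
    hi_h = np.full(20, -np.inf)
    for h in hmms:
        for row in h.match_scores:
            for c in range(20):
                if not math.isnan(row[c]):
                    p = 2.0 ** (-row[c] / 1000.0)
                    lo_h[c] = min(lo_h[c], p)
                    hi_h[c] = max(hi_h[c], p)
    np.testing.assert_allclose(stats.hmm_min, lo_h, rtol=1e-12)
    np.testing.assert_allclose(stats.hmm_max, hi_h, rtol=1e-12)


def test_empty_collection_is_error():
    with pytest.raises(ValueError):
        fit_normalization([], [])


def test_stats_json_round_trip_bit_identical(tmp_path):
    rng = np.random.default_rng(0)
    lo = rng.normal(size=20)
    stats = NormalizationStats(lo, lo + rng.random(20),
                               np.zeros(20), rng.random(20), provenance="t")
    path = tmp_path / "stats.json"
    stats.to_json(path)
    back = NormalizationStats.from_json(path)
    for name in ("pssm_min", "pssm_max", "hmm_min", "hmm_max"):
        np.testing.assert_array_equal(getattr(stats, name), getattr(back, name))
    assert back.provenance == "t"


# ---------------------------------------------------------------------------
# PSSM / HMM encoding


def test_pssm_endpoints_midpoint_and_clamp():
    stats = _stats(-8, 12)
    raw = RawPssm(np.array([[-8] * 20, [12] * 20, [2] * 20, [-20] * 20]), "MKVL")
    enc = encode_pssm(raw, stats)
    np.testing.assert_array_equal(enc[0], 0.0)
    np.testing.assert_array_equal(enc[1], 1.0)
    np.testing.assert_allclose(enc[2], 0.5)
    np.testing.assert_array_equal(enc[3], 0.0)  # below training min -> clamp


def test_hhm_decoding_closed_forms():
    scores = np.array([[0.0, 1000.0, np.nan] + [2000.0] * 17])
    probs = hhm_score_to_probability(scores)
    assert probs[0, 0] == 1.0
    assert probs[0, 1] == 0.5
    assert probs[0, 2] == 0.0  # absent


def test_hhm_probability_strictly_decreasing():
    s = np.arange(0, 6001, 50, dtype=float)[None, :]
    p = hhm_score_to_probability(s)
    assert (np.diff(p[0]) < 0).all()


def test_hhm_negative_score_is_error():
    with pytest.raises(ValueError):
        hhm_score_to_probability(np.array([[-1.0]]))


def test_training_set_self_encoding_spans_unit_interval(small_manifest):
    """Fit+apply on the training set itself: all values in [0, 1] and each
    non-constant column attains both 0 and 1."""
    chains = small_manifest.chains
    stats = fit_normalization([c.pssm for c in chains], [c.hmm for c in chains])
    enc = np.vstack([encode_pssm(c.pssm, stats) for c in chains])
    assert enc.min() >= 0.0 and enc.max() <= 1.0
    varying = stats.pssm_max > stats.pssm_min
    np.testing.assert_allclose(enc.min(axis=0)[varying], 0.0)
    np.testing.assert_allclose(enc.max(axis=0)[varying], 1.0)
    enc_h = np.vstack([encode_hmm(c.hmm, stats) for c in chains])
    assert enc_h.min() >= 0.0 and enc_h.max() <= 1.0


# ---------------------------------------------------------------------------
# DSSP encoding


def test_dssp_exact_trigonometry():
    res = DsspResidue("A", "H", -90.0, 90.0, MAX_ASA["A"])
    row = encode_dssp(RawDssp([res]))[0]
    assert row.shape == (14,)
    assert row[0] == 1.0 and row[1:9].sum() == 0.0  # H one-hot
    np.testing.assert_allclose(row[9], 0.0, atol=1e-12)   # sin(-90) -> 0
    np.testing.assert_allclose(row[10], 0.5, atol=1e-12)  # cos(-90) -> 0.5
    np.testing.assert_allclose(row[11], 1.0, atol=1e-12)  # sin(90) -> 1
    np.testing.assert_allclose(row[12], 0.5, atol=1e-12)
    assert row[13] == 1.0


def test_dssp_missing_residue_gets_absence_state():
    row = encode_dssp(RawDssp([DsspResidue.missing("K")]))[0]
    assert row[8] == 1.0 and row[:8].sum() == 0.0
    np.testing.assert_array_equal(row[9:13], 0.5)  # neutral torsions
    assert row[13] == 0.0


def test_dssp_raw_torsion_variant():
    res = DsspResidue("A", "H", -90.0, 90.0, 0.0)
    row = encode_dssp(RawDssp([res]), rescale_torsions=False)[0]
    np.testing.assert_allclose(row[9:13], [-1.0, 0.0, 1.0, 0.0], atol=1e-12)
    missing = encode_dssp(RawDssp([DsspResidue.missing("A")]),
                          rescale_torsions=False)[0]
    np.testing.assert_array_equal(missing[9:13], 0.0)


def test_dssp_rsa_capped_at_one():
    row = encode_dssp(RawDssp([DsspResidue("G", "E", 0.0, 0.0, 9999.0)]))[0]
    assert row[13] == 1.0


def test_unknown_ss_code_is_error():
    res = DsspResidue("A", "H", 0.0, 0.0, 1.0)
    res.ss_code = "Z"  # bypass constructor validation
    with pytest.raises(ValueError, match="Z"):
        encode_dssp(RawDssp([res]))


@settings(deadline=None, max_examples=50)
@given(
    ss=st.sampled_from(["H", "G", "I", "T", "B", "E", "S", "-", None]),
    phi=st.one_of(st.just(math.nan), st.floats(-180, 180)),
    psi=st.one_of(st.just(math.nan), st.floats(-180, 180)),
    acc=st.floats(0, 400),
    aa=st.sampled_from("ARNDCQEGHILKMFPSTWYVX"),
)
def test_dssp_row_properties(ss, phi, psi, acc, aa):
    """Every encoded row: length 14, one-hot sums to exactly 1, all in [0,1]."""
    row = encode_dssp(RawDssp([DsspResidue(aa, ss, phi, psi, acc)]))[0]
    assert row.shape == (14,)
    assert row[:9].sum() == 1.0
    assert set(np.unique(row[:9])) <= {0.0, 1.0}
    assert (row >= 0.0).all() and (row <= 1.0).all()


def test_encode_chain_shapes(toy):
    chains = toy.chains
    stats = fit_normalization([c.pssm for c in chains], [c.hmm for c in chains])
    feats = encode_chain(chains[0].pssm, chains[0].hmm, chains[0].dssp, stats)
    L = len(chains[0].record)
    assert feats.pssm_feat.shape == (L, 20)
    assert feats.hmm_feat.shape == (L, 20)
    assert feats.dssp_feat.shape == (L, 14)
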