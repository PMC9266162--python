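"""Per-residue feature encoding.

Raw profiles become three fixed-width real matrices per chain:

* PSSM: L x 20 log-odds, min-max scaled to [0, 1] with extrema taken over the
  whole training set, one pair per column.
* HMM: the .hhm integer score ``s`` is first decoded to the match-emission
  probability ``2**(-s/1000)`` (absent cells -> 0), then min-max scaled the
  same way on the probability scale.
* DSSP: L x 14 = 9-d one-hot secondary structure (8 DSSP states + a 9th
  "absent" state for residues DSSP skipped) + sin/cos of phi and psi rescaled
  from [-1, 1] to [0, 1] + relative solvent accessibility (absolute area over
  the residue type's theoretical maximum, capped at 1).

DSSP features are bounded by construction and are not refitted; only the two
evolutionary feature types carry :class:`NormalizationStats`. Values seen at
test time outside the training extrema are clamped into [0, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .profile_io import DsspResidue, RawDssp, RawHmm, RawPssm, SS_CODES

__all__ = [
    "MAX_ASA",
    "NormalizationStats",
    "ResidueProfileSet",
    "fit_normalization",
    "hhm_score_to_probability",
    "encode_pssm",
    "encode_hmm",
    "encode_dssp",
    "encode_chain",
]

# Theoretical maximum solvent-accessible surface area per residue type
# (Tien et al. 2013), in A^2. 'X' falls back to the 20-residue mean.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
_MEAN_MAX_ASA = float(np.mean(list(MAX_ASA.values())))

#: One-hot order of the 14-d structural vector's first block:
#: 8 DSSP states, then the "no structure assigned" state.
SS_ONE_HOT_ORDER = SS_CODES + (None,)


@dataclass
class NormalizationStats:
    """Columnwise training-set extrema for the two evolutionary feature types."""

    pssm_min: np.ndarray
    pssm_max: np.ndarray
    hmm_min: np.ndarray
    hmm_max: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in ("pssm_min", "pssm_max", "hmm_min", "hmm_max"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (20,):
                raise ValueError(f"{name} must have shape (20,), got {v.shape}")
            setattr(self, name, v)
        if (self.pssm_max < self.pssm_min).any() or (self.hmm_max < self.hmm_min).any():
            raise ValueError("max < min in normalization stats")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "pssm": {"min": self.pssm_min.tolist(), "max": self.pssm_max.tolist()},
            "hmm": {"min": self.hmm_min.tolist(), "max": self.hmm_max.tolist()},
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        doc = json.loads(Path(path).read_text())
        return cls(
            pssm_min=np.array(doc["pssm"]["min"], dtype=float),
            pssm_max=np.array(doc["pssm"]["max"], dtype=float),
            hmm_min=np.array(doc["hmm"]["min"], dtype=float),
            hmm_max=np.array(doc["hmm"]["max"], dtype=float),
            provenance=doc.get("provenance", ""),
        )


@dataclass
class ResidueProfileSet:
    """The three encoded feature matrices of one chain, row-aligned."""

    pssm_feat: np.ndarray  # L x 20 in [0, 1]
    hmm_feat: np.ndarray   # L x 20 in [0, 1]
    dssp_feat: np.ndarray  # L x 14

    def __post_init__(self) -> None:
        Ls = {m.shape[0] for m in (self.pssm_feat, self.hmm_feat, self.dssp_feat)}
        if len(Ls) != 1:
            raise ValueError("feature matrices disagree on chain length")
        for name, m, width in (
            ("pssm_feat", self.pssm_feat, 20),
            ("hmm_feat", self.hmm_feat, 20),
            ("dssp_feat", self.dssp_feat, 14),
        ):
            if m.ndim != 2 or m.shape[1] != width:
                raise ValueError(f"{name} must be L x {width}, got {m.shape}")
            if not np.isfinite(m).all():
                raise ValueError(f"{name} contains non-finite entries")

    def __len__(self) -> int:
        return self.pssm_feat.shape[0]


def hhm_score_to_probability(scores: np.ndarray) -> np.ndarray:
    """Decode .hhm integer scores to emission probabilities.

    ``s -> 2**(-s/1000)``; NaN (absent, the ``*`` cell) -> 0. Strictly
    decreasing in ``s`` for present cells.
    """
    scores = np.asarray(scores, dtype=float)
    present = ~np.isnan(scores)
    if (scores[present] < 0).any():
        raise ValueError("negative .hhm score: upstream parse contract violated")
    probs = np.zeros_like(scores, dtype=float)
    probs[present] = np.exp2(-scores[present] / 1000.0)
    return probs


def fit_normalization(
    pssms: Iterable[RawPssm],
    hmms: Iterable[RawHmm],
    provenance: str = "",
) -> NormalizationStats:
    """Columnwise min/max over every residue of every training chain.

    HMM extrema are taken on the probability scale with absent cells excluded;
    a column that is absent everywhere gets min = max = 0 (and will encode
    to 0, like any constant column).
    """
    pssm_stack = [np.asarray(p.scores, dtype=float) for p in pssms]
    hmm_stack = [hhm_prob for h in hmms
                 for hhm_prob in (_present_probs(h),)]
    if not pssm_stack or not hmm_stack:
        raise ValueError("fit_normalization needs at least one chain per feature type")
    pssm_all = np.vstack(pssm_stack)
    hmm_all = np.vstack(hmm_stack)  # NaN where absent
    with np.errstate(all="ignore"):
        hmm_min = np.nanmin(hmm_all, axis=0)
        hmm_max = np.nanmax(hmm_all, axis=0)
    all_absent = np.isnan(hmm_min)
    hmm_min[all_absent] = 0.0
    hmm_max[all_absent] = 0.0
    return NormalizationStats(
        pssm_min=pssm_all.min(axis=0),
        pssm_max=pssm_all.max(axis=0),
        hmm_min=hmm_min,
        hmm_max=hmm_max,
        provenance=provenance,
    )


def _present_probs(h: RawHmm) -> np.ndarray:
    """Probabilities with absent cells left as NaN (excluded from extrema)."""
    probs = hhm_score_to_probability(h.match_scores)
    probs[h.absent_mask] = np.nan
    return probs


def _minmax(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    out = np.zeros_like(x, dtype=float)
    ok = span > 0
    out[:, ok] = (x[:, ok] - lo[ok]) / span[ok]
    return np.clip(out, 0.0, 1.0)


def encode_pssm(raw: RawPssm, stats: NormalizationStats) -> np.ndarray:
    """Min-max scale log-odds columnwise; out-of-range values clamp to [0, 1]."""
    return _minmax(np.asarray(raw.scores, dtype=float), stats.pssm_min, stats.pssm_max)


def encode_hmm(raw: RawHmm, stats: NormalizationStats) -> np.ndarray:
    """Decode scores to probabilities (absent -> 0), then min-max scale."""
    probs = hhm_score_to_probability(raw.match_scores)
    return _minmax(probs, stats.hmm_min, stats.hmm_max)


def _trig(angle_deg: float, rescale: bool) -> tuple[float, float]:
    """(sin, cos) of an angle; optionally rescaled from [-1, 1] to [0, 1].

    Undefined angles (NaN) map to the neutral value: 0.5 rescaled, 0 raw.
    """
    if math.isnan(angle_deg):
        return (0.5, 0.5) if rescale else (0.0, 0.0)
    rad = math.radians(angle_deg)
    s, c = math.sin(rad), math.cos(rad)
    if rescale:
        return (s + 1.0) / 2.0, (c + 1.0) / 2.0
    return s, c


def encode_dssp(raw: RawDssp, rescale_torsions: bool = True) -> np.ndarray:
    """Encode DSSP records into the 14-d structural feature matrix.

    Columns 0-8: one-hot over the 8 DSSP states plus the absent state;
    columns 9-12: (sin phi, cos phi, sin psi, cos psi), by default rescaled
    to [0, 1] with undefined angles at the neutral 0.5 (set
    ``rescale_torsions=False`` to keep the raw [-1, 1] values); column 13:
    relative solvent accessibility, capped at 1.
    """
    out = np.zeros((len(raw), 14), dtype=float)
    for i, res in enumerate(raw.residues):
        if res.ss_code is not None and res.ss_code not in SS_CODES:
            raise ValueError(f"unknown structure code {res.ss_code!r}")
        out[i, SS_ONE_HOT_ORDER.index(res.ss_code)] = 1.0
        s_phi, c_phi = _trig(res.phi, rescale_torsions)
        s_psi, c_psi = _trig(res.psi, rescale_torsions)
        out[i, 9:13] = (s_phi, c_phi, s_psi, c_psi)
        max_asa = MAX_ASA.get(res.residue_letter.upper(), _MEAN_MAX_ASA)
        out[i, 13] = min(res.acc / max_asa, 1.0)
    return out


def encode_chain(pssm: RawPssm, hmm: RawHmm, dssp: RawDssp,
                 stats: NormalizationStats) -> ResidueProfileSet:
    """Encode one chain's three raw profiles into a ResidueProfileSet."""
    return ResidueProfileSet(
        pssm_feat=encode_pssm(pssm, stats),
        hmm_feat=encode_hmm(hmm, stats),
        dssp_feat=encode_dssp(dssp),
    )
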