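"""Synthetic chains with full ground truth, written in the real file dialects.

The generator emits, per chain, a FASTA file, a PSI-BLAST ASCII PSSM, an
HHblits ``.hhm`` profile and a classic DSSP file, plus a label line — all in
the exact dialects :mod:`ppisite.profile_io` reads — so the whole pipeline is
testable without running any external tool.

Labels are not noise: they are drawn from a logistic model on a handful of
feature channels averaged over a ±span residue neighborhood. Wider windows
therefore genuinely see more of the label-relevant signal, which is what
makes window-size scans on this data meaningful. The generator keeps its own
Bayes-optimal score per residue (the logistic it sampled from), giving an
upper bound any trained model can be compared against.

What it does not emulate: real evolutionary conservation (PSSM/HMM entries
are independent draws), real fold geometry (secondary structure is a
run-length Markov chain, torsions are Ramachandran-like mixtures), or the
interface label definition used on real complexes.
"""

from __future__ import annotations

import json
import math
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .features import MAX_ASA
from .profile_io import (
    AlignedProfiles,
    DsspResidue,
    HHM_ALPHABET,
    PSSM_ALPHABET,
    ProteinRecord,
    RawDssp,
    RawHmm,
    RawPssm,
    SS_CODES,
    align_profiles,
    read_dssp,
    read_fasta,
    read_hhm,
    read_labels,
    read_pssm,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticChain",
    "Manifest",
    "generate",
    "worked_toy",
    "load_generated",
    "write_pssm_file",
    "write_hhm_file",
    "write_dssp_file",
]

AMINO_ACIDS = PSSM_ALPHABET  # 20 standard residues


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults give ~50 chains x ~100 residues (~5,000 windows), 18% positive
    residues, and a label signal carried by the relative solvent
    accessibility averaged over +/-8 neighbors — interface residues on real
    complexes are exposed surface patches, so accessibility is the natural
    channel for a planted positive control. Evolutionary columns can carry
    signal too via ``signal_channels``.
    """

    n_proteins: int = 50
    length_range: tuple[int, int] = (60, 140)
    positive_fraction: float = 0.18
    signal_channels: tuple[tuple[str, object], ...] = (("dssp", "rsa"),)
    effect_size: float = 8.0
    span: int = 8
    absent_rate: float = 0.02  # fraction of '*' cells in .hhm
    seed: int = 0
    lengths: tuple[int, ...] | None = None  # exact lengths override

    def __post_init__(self) -> None:
        if self.lengths is None:
            if self.n_proteins < 1 or self.length_range[0] < 1:
                raise ValueError("invalid size specification")
            if self.length_range[1] < self.length_range[0]:
                raise ValueError("length_range must be (min, max)")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.span < 0 or self.effect_size < 0:
            raise ValueError("span and effect_size must be >= 0")


@dataclass
class SyntheticChain:
    """One generated chain: parsed-equivalent ground truth plus file paths."""

    record: ProteinRecord
    pssm: RawPssm
    hmm: RawHmm
    dssp: RawDssp
    bayes_score: np.ndarray
    files: dict[str, Path] = field(default_factory=dict)

    def aligned(self) -> AlignedProfiles:
        return AlignedProfiles(self.record, self.pssm, self.hmm, self.dssp)


@dataclass
class Manifest:
    """Everything needed to check any downstream stage against ground truth."""

    spec: SyntheticSpec
    chains: list[SyntheticChain]
    intercept: float
    achieved_positive_fraction: float
    out_dir: Path

    def dataset(self) -> list[AlignedProfiles]:
        return [c.aligned() for c in self.chains]

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate([c.record.labels for c in self.chains])

    @property
    def bayes_scores(self) -> np.ndarray:
        return np.concatenate([c.bayes_score for c in self.chains])

    def write_json(self) -> Path:
        doc = {
            "spec": {
                "n_proteins": self.spec.n_proteins,
                "length_range": list(self.spec.length_range),
                "positive_fraction": self.spec.positive_fraction,
                "signal_channels": [list(c) for c in self.spec.signal_channels],
                "effect_size": self.spec.effect_size,
                "span": self.spec.span,
                "absent_rate": self.spec.absent_rate,
                "seed": self.spec.seed,
                "lengths": list(self.spec.lengths) if self.spec.lengths else None,
            },
            "intercept": self.intercept,
            "achieved_positive_fraction": self.achieved_positive_fraction,
            "chains": [
                {
                    "protein_id": c.record.protein_id,
                    "length": len(c.record),
                    "labels": "".join(map(str, c.record.labels.tolist())),
                    "files": {k: str(v) for k, v in c.files.items()},
                }
                for c in self.chains
            ],
        }
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(doc, indent=1))
        return path


# ---------------------------------------------------------------------------
# file writers (the dialects profile_io reads)


def write_pssm_file(path: Path, letters: str, scores: np.ndarray) -> None:
    """Write a PSI-BLAST ``-out_ascii_pssm``-style file."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(PSSM_ALPHABET) + "   "
        + "   ".join(PSSM_ALPHABET),
    ]
    for i, (aa, row) in enumerate(zip(letters, scores), start=1):
        log_odds = "".join(f"{int(v):4d}" for v in row)
        # plausible percentage block derived from the scores
        perc = "".join(f"{min(max(int(v) * 4 + 20, 0), 100):4d}" for v in row)
        lines.append(f"{i:5d} {aa}  {log_odds} {perc}  {0.36:5.2f} {1.00:9.2f}")
    lines += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1347     0.3195",
        "Standard Gapped      0.0410     0.2670",
        "PSI Ungapped         0.1347     0.3195",
        "PSI Gapped           0.0410     0.2670",
    ]
    path.write_text("\n".join(lines) + "\n")


def write_hhm_file(path: Path, name: str, letters: str,
                   match_scores: np.ndarray) -> None:
    """Write an HHblits ``.hhm``-style profile (NaN cells become ``*``)."""

    def cell(v: float) -> str:
        return "*" if math.isnan(v) else str(int(v))

    L = len(letters)
    lines = [
        "HHsearch 1.5",
        f"NAME  {name}",
        f"LENG  {L} match states, {L} columns in multiple alignment",
        "FILT  filtered MSA",
        "NEFF  4.2",
        "#",
        "NULL   " + "\t".join(["3706"] * 20),
        "HMM    " + "\t".join(HHM_ALPHABET),
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D",
        "       0\t*\t*\t0\t*\t0\t*\t*\t*\t*",
    ]
    for i, (aa, row) in enumerate(zip(letters, match_scores), start=1):
        lines.append(f"{aa} {i}    " + "\t".join(cell(v) for v in row)
                     + f"\t{i}")
        lines.append("       0\t*\t*\t*\t*\t*\t*\t4200\t0\t0")
    lines.append("//")
    path.write_text("\n".join(lines) + "\n")


def _dssp_row(idx: int, resseq: int | None, chain: str, aa: str, ss: str,
              acc: int, phi: float, psi: float) -> str:
    """One fixed-column DSSP body row (break rows have a blank residue number)."""
    resseq_s = f"{resseq:5d}" if resseq is not None else "     "
    line = f"{idx:5d}{resseq_s} {chain} {aa}  {ss}"  # cols 0-16
    line += " " * 8                                   # structure detail, 17-24
    line += f"{0:4d}{0:4d} "                          # BP1, BP2 + sheet label
    line += f"{acc:4d}"                               # ACC at [34:38]
    line += f"{0:7d},{0.0:4.1f}"                      # N-H-->O  [38:45],[46:50]
    line += f"{0:6d},{0.0:4.1f}" * 3                  # remaining H-bond slots
    line += f"{0.0:8.3f}"                             # TCO
    line += f"{360.0:6.1f}{360.0:6.1f}"               # KAPPA, ALPHA
    phi_v = 360.0 if math.isnan(phi) else phi
    psi_v = 360.0 if math.isnan(psi) else psi
    line += f"{phi_v:6.1f}{psi_v:6.1f}"               # PHI [103:109], PSI [109:115]
    line += f"{0.0:7.1f}{0.0:7.1f}{0.0:7.1f}"         # CA coordinates
    return line


def write_dssp_file(path: Path, chain_id: str, residues: Sequence[DsspResidue],
                    break_after: Sequence[int] = ()) -> None:
    """Write a classic DSSP text file for one chain.

    ``break_after`` lists residue indices after which a ``!`` chain-break row
    is inserted.
    """
    lines = [
        "==== Secondary Structure Definition by the program DSSP, "
        "NKI version 3.1.4                    ==== DATE=2022-01-01        .",
        "REFERENCE W. KABSCH AND C.SANDER, BIOPOLYMERS 22 (1983) 2577-2637 .",
        f"  {len(residues):4d}  1  0  0  0 TOTAL NUMBER OF RESIDUES, NUMBER "
        "OF CHAINS, NUMBER OF SS-BRIDGES(TOTAL,INTRACHAIN,INTERCHAIN) .",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    idx = 0
    breaks = set(break_after)
    for i, res in enumerate(residues):
        idx += 1
        ss = " " if res.ss_code in (None, "-") else res.ss_code
        lines.append(_dssp_row(idx, i + 1, chain_id, res.residue_letter, ss,
                               int(round(res.acc)), res.phi, res.psi))
        if i in breaks:
            idx += 1
            lines.append(_dssp_row(idx, None, " ", "!", " ", 0,
                                   math.nan, math.nan))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# generation


_HELIX = {"H", "G", "I"}
_STRAND = {"E", "B"}


def _markov_ss(L: int, rng: np.random.Generator, stay: float = 0.8) -> list[str]:
    """Run-length secondary structure: stay in the current state w.p. 0.8."""
    codes = list(SS_CODES)
    state = codes[rng.integers(len(codes))]
    out = [state]
    for _ in range(L - 1):
        if rng.random() >= stay:
            state = codes[rng.integers(len(codes))]
        out.append(state)
    return out


def _torsions(ss: Sequence[str], rng: np.random.Generator
              ) -> tuple[np.ndarray, np.ndarray]:
    """Ramachandran-like phi/psi per state; chain-end angles undefined."""
    L = len(ss)
    phi = np.empty(L)
    psi = np.empty(L)
    for i, code in enumerate(ss):
        if code in _HELIX:
            phi[i] = rng.normal(-60.0, 12.0)
            psi[i] = rng.normal(-45.0, 12.0)
        elif code in _STRAND:
            phi[i] = rng.normal(-120.0, 20.0)
            psi[i] = rng.normal(130.0, 20.0)
        else:
            phi[i] = rng.uniform(-180.0, 180.0)
            psi[i] = rng.uniform(-180.0, 180.0)
    np.clip(phi, -180.0, 180.0, out=phi)
    np.clip(psi, -180.0, 180.0, out=psi)
    # quantize to the 0.1 degree the DSSP text format carries, so the stored
    # ground truth round-trips exactly through the written file
    phi = np.round(phi, 1)
    psi = np.round(psi, 1)
    phi[0] = math.nan   # DSSP cannot define phi of the first residue
    psi[-1] = math.nan  # nor psi of the last
    return phi, psi


def _neighborhood_mean(x: np.ndarray, span: int) -> np.ndarray:
    """Mean of x over [i-span, i+span], truncated at the chain ends."""
    if span == 0:
        return x.astype(float)
    c = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    n = x.size
    lo = np.maximum(np.arange(n) - span, 0)
    hi = np.minimum(np.arange(n) + span + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def _channel_latent(chain_feats: dict, channel: tuple[str, object]) -> np.ndarray:
    """A [0, 1] per-residue latent for one signal channel."""
    kind, key = channel
    if kind == "dssp" and key == "rsa":
        return chain_feats["rsa"]
    if kind == "pssm":
        return (chain_feats["pssm"][:, int(key)] + 8.0) / 20.0
    if kind == "hmm":
        s = chain_feats["hmm"][:, int(key)]
        out = np.zeros_like(s)
        present = ~np.isnan(s)
        out[present] = np.exp2(-s[present] / 1000.0)
        return out
    raise ValueError(f"unknown signal channel {channel!r}")


def generate(spec: SyntheticSpec, out_dir: str | Path) -> Manifest:
    """Generate a dataset under ``out_dir`` and return its manifest.

    Fully deterministic given ``spec.seed`` (byte-identical files).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    if spec.lengths is not None:
        lengths = list(spec.lengths)
    else:
        lo, hi = spec.length_range
        lengths = rng.integers(lo, hi + 1, size=spec.n_proteins).tolist()

    raw_chains = []
    z_parts = []
    for ci, L in enumerate(lengths):
        seq = "".join(AMINO_ACIDS[j] for j in rng.integers(20, size=L))
        pssm = rng.integers(-8, 13, size=(L, 20)).astype(np.int64)
        hmm = rng.integers(0, 6001, size=(L, 20)).astype(float)
        hmm[rng.random((L, 20)) < spec.absent_rate] = np.nan
        ss = _markov_ss(L, rng)
        phi, psi = _torsions(ss, rng)
        rsa = rng.uniform(0.0, 1.0, size=L)
        acc = np.round(rsa * np.array([MAX_ASA[a] for a in seq])).astype(int)
        rsa_eff = acc / np.array([MAX_ASA[a] for a in seq])  # post-rounding

        feats = {"pssm": pssm, "hmm": hmm, "rsa": rsa_eff}
        z = np.mean(
            [_neighborhood_mean(_channel_latent(feats, ch), spec.span)
             for ch in spec.signal_channels],
            axis=0,
        )
        z_parts.append(z)
        raw_chains.append((f"S{ci:03d}A", seq, pssm, hmm, ss, phi, psi, acc))

    z_all = np.concatenate(z_parts)
    sd = z_all.std()
    if spec.effect_size == 0.0 or sd == 0.0:
        z_std = np.zeros_like(z_all)
    else:
        z_std = (z_all - z_all.mean()) / sd
    beta = spec.effect_size

    def prevalence(alpha: float) -> float:
        return float(np.mean(expit(alpha + beta * z_std)))

    lo_a, hi_a = -30.0, 30.0
    if not (prevalence(lo_a) - spec.positive_fraction) * (
            prevalence(hi_a) - spec.positive_fraction) < 0:
        raise ValueError(
            f"positive fraction {spec.positive_fraction} unreachable by "
            "intercept calibration on this signal"
        )
    alpha = float(brentq(lambda a: prevalence(a) - spec.positive_fraction,
                         lo_a, hi_a, xtol=1e-10))
    bayes_all = expit(alpha + beta * z_std)
    labels_all = (rng.random(bayes_all.size) < bayes_all).astype(np.int8)

    chains: list[SyntheticChain] = []
    offset = 0
    label_lines = []
    for pid, seq, pssm_m, hmm_m, ss, phi, psi, acc in raw_chains:
        L = len(seq)
        lab = labels_all[offset : offset + L]
        bayes = bayes_all[offset : offset + L]
        offset += L
        record = ProteinRecord(pid, seq, lab)
        dssp = RawDssp([
            DsspResidue(seq[i], ss[i], float(phi[i]), float(psi[i]),
                        float(acc[i]))
            for i in range(L)
        ])
        files = {
            "fasta": out_dir / f"{pid}.fasta",
            "pssm": out_dir / f"{pid}.pssm",
            "hhm": out_dir / f"{pid}.hhm",
            "dssp": out_dir / f"{pid}.dssp",
        }
        files["fasta"].write_text(f">{pid}\n{seq}\n")
        write_pssm_file(files["pssm"], seq, pssm_m)
        write_hhm_file(files["hhm"], pid, seq, hmm_m)
        write_dssp_file(files["dssp"], pid[-1], dssp.residues)
        label_lines.append(f"{pid}\t" + "".join(map(str, lab.tolist())))
        chains.append(SyntheticChain(
            record, RawPssm(pssm_m, seq), RawHmm(hmm_m, seq), dssp,
            bayes_score=bayes, files=files,
        ))
    (out_dir / "labels.tsv").write_text("\n".join(label_lines) + "\n")

    manifest = Manifest(
        spec=spec,
        chains=chains,
        intercept=alpha,
        achieved_positive_fraction=float(labels_all.mean()),
        out_dir=out_dir,
    )
    manifest.write_json()
    return manifest


def worked_toy(out_dir: str | Path | None = None) -> Manifest:
    """A fixed 3-chain fixture (lengths 12, 19, 40) used in docs and tests."""
    if out_dir is None:
        out_dir = tempfile.mkdtemp(prefix="ppisite_toy_")
    spec = SyntheticSpec(n_proteins=3, lengths=(12, 19, 40), seed=42)
    return generate(spec, out_dir)


def load_generated(out_dir: str | Path) -> list[AlignedProfiles]:
    """Re-read a generated dataset from its files through profile_io."""
    out_dir = Path(out_dir)
    doc = json.loads((out_dir / "manifest.json").read_text())
    labels = read_labels(out_dir / "labels.tsv")
    dataset = []
    for entry in doc["chains"]:
        pid = entry["protein_id"]
        seq = read_fasta(out_dir / f"{pid}.fasta")[0].sequence
        record = ProteinRecord(pid, seq, labels[pid])
        dataset.append(align_profiles(
            record,
            read_pssm(out_dir / f"{pid}.pssm"),
            read_hhm(out_dir / f"{pid}.hhm"),
            read_dssp(out_dir / f"{pid}.dssp"),
        ))
    return dataset
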