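"""Readers for the per-residue profile formats used by the pipeline.

Three standard text formats describe a protein chain one residue at a time:

* PSI-BLAST ASCII PSSM (``-out_ascii_pssm``): per-residue log-odds scores for
  the 20 amino acids (first 20 numeric columns) followed by the weighted
  observed percentages (next 20, unused here).
* HHblits ``.hhm`` profile: per-residue match-emission scores, stored as
  ``-1000 * log2(p)`` rounded to an integer, with ``*`` marking an emission
  probability too small to record.
* Classic DSSP output: one fixed-column row per residue carrying the
  secondary-structure state, backbone torsion angles and absolute
  solvent-accessible surface area.

All readers return the file verbatim as raw matrices/records; numeric
encoding and normalization live in :mod:`ppisite.features`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB.DSSP import make_dssp_dict

__all__ = [
    "ProfileParseError",
    "AlignmentError",
    "ProteinRecord",
    "RawPssm",
    "RawHmm",
    "RawDssp",
    "DsspResidue",
    "AlignedProfiles",
    "PSSM_ALPHABET",
    "HHM_ALPHABET",
    "SS_CODES",
    "read_pssm",
    "read_hhm",
    "read_dssp",
    "read_fasta",
    "read_labels",
    "align_profiles",
]

#: Column order of the PSI-BLAST ASCII PSSM header.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
#: Column order of the .hhm match-emission block (alphabetical one-letter codes).
HHM_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: DSSP structure states; '-' is loop/irregular (a blank structure column).
SS_CODES = ("H", "G", "I", "T", "B", "E", "S", "-")

#: Sentinel for phi/psi DSSP cannot define (chain ends); DSSP prints 360.0.
UNDEFINED_ANGLE = math.nan


class ProfileParseError(ValueError):
    """A profile file does not follow its dialect."""


class AlignmentError(ValueError):
    """Profiles that should describe one chain disagree."""


@dataclass
class ProteinRecord:
    """A chain: identifier, sequence, and optional per-residue binding labels."""

    protein_id: str
    sequence: str
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (len(self.sequence),):
                raise ValueError(
                    f"{self.protein_id}: {self.labels.size} labels for "
                    f"{len(self.sequence)} residues"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError(f"{self.protein_id}: labels must be 0/1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RawPssm:
    """L x 20 integer log-odds matrix in PSI-BLAST column order."""

    scores: np.ndarray
    residue_letters: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(f"PSSM must be L x 20, got {self.scores.shape}")
        if self.scores.shape[0] != len(self.residue_letters):
            raise ValueError("PSSM row count != residue letter count")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class RawHmm:
    """L x 20 match-emission scores from a .hhm file.

    Scores are the file's non-negative integers (``-1000*log2 p``); absent
    cells (``*``) are stored as NaN.
    """

    match_scores: np.ndarray
    residue_letters: str

    def __post_init__(self) -> None:
        self.match_scores = np.asarray(self.match_scores, dtype=float)
        if self.match_scores.ndim != 2 or self.match_scores.shape[1] != 20:
            raise ValueError(f"HMM must be L x 20, got {self.match_scores.shape}")
        if self.match_scores.shape[0] != len(self.residue_letters):
            raise ValueError("HMM row count != residue letter count")
        present = ~np.isnan(self.match_scores)
        if (self.match_scores[present] < 0).any():
            raise ValueError("negative .hhm match score")

    @property
    def absent_mask(self) -> np.ndarray:
        return np.isnan(self.match_scores)

    def __len__(self) -> int:
        return self.match_scores.shape[0]


@dataclass
class DsspResidue:
    """One DSSP residue row (or a placeholder for a residue DSSP skipped)."""

    residue_letter: str
    ss_code: str | None  # one of SS_CODES, or None when absent from DSSP
    phi: float  # degrees, NaN when undefined
    psi: float
    acc: float  # absolute solvent-accessible area, A^2

    def __post_init__(self) -> None:
        if self.ss_code is not None and self.ss_code not in SS_CODES:
            raise ValueError(f"unknown DSSP structure code {self.ss_code!r}")
        if self.acc < 0:
            raise ValueError(f"negative accessibility {self.acc}")

    @classmethod
    def missing(cls, residue_letter: str) -> "DsspResidue":
        """Placeholder for a residue present in sequence but absent from DSSP."""
        return cls(residue_letter, None, math.nan, math.nan, 0.0)


@dataclass
class RawDssp:
    """Residue records of one chain from a DSSP file, in file order."""

    residues: list[DsspResidue]
    n_breaks: int = 0

    @property
    def residue_letters(self) -> str:
        return "".join(r.residue_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignedProfiles:
    """The three raw profiles verified against one chain's sequence."""

    record: ProteinRecord
    pssm: RawPssm
    hmm: RawHmm
    dssp: RawDssp

    def __len__(self) -> int:
        return len(self.record)


def read_pssm(path: str | Path) -> RawPssm:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first 20 numeric columns (the log-odds block) are kept; the
    percentage block and trailing information-content columns are discarded.
    """
    path = Path(path)
    letters: list[str] = []
    rows: list[list[int]] = []
    in_body = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tokens = line.split()
        if not in_body:
            # the column header repeats the 20-letter alphabet twice
            if len(tokens) == 40 and "".join(tokens[:20]) == PSSM_ALPHABET:
                in_body = True
            continue
        if not tokens:
            break  # blank line ends the body, statistics follow
        if len(tokens) < 2 or not tokens[0].isdigit():
            break
        body = tokens[2:]
        if len(body) < 40:
            raise ProfileParseError(
                f"{path}:{lineno}: expected 40 score columns, found {len(body)}"
            )
        try:
            scores = [int(v) for v in body[:20]]
        except ValueError as exc:
            raise ProfileParseError(f"{path}:{lineno}: {exc}") from None
        letters.append(tokens[1])
        rows.append(scores)
    if not rows:
        raise ProfileParseError(f"{path}: no PSSM body found")
    return RawPssm(np.array(rows, dtype=np.int64), "".join(letters))


def read_hhm(path: str | Path) -> RawHmm:
    """Parse the match-emission block of an HHblits ``.hhm`` profile.

    Transition/diversity lines are skipped; ``*`` cells become NaN (absent).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    length: int | None = None
    start = None
    for i, line in enumerate(lines):
        if line.startswith("LENG"):
            length = int(line.split()[1])
        if line.strip() == "#":
            start = i + 1
            break
    if start is None:
        raise ProfileParseError(f"{path}: no '#' delimiter before the HMM body")

    letters: list[str] = []
    rows: list[list[float]] = []
    i = start
    while i < len(lines):
        tokens = lines[i].split()
        i += 1
        if not tokens or tokens[0] in ("//",):
            continue
        # residue block first line: <aa> <pos> <20 scores> <pos>
        if len(tokens) >= 22 and len(tokens[0]) == 1 and tokens[1].isdigit():
            cells = tokens[2:22]
            try:
                row = [math.nan if c == "*" else float(int(c)) for c in cells]
            except ValueError as exc:
                raise ProfileParseError(f"{path}: residue {tokens[1]}: {exc}") from None
            letters.append(tokens[0])
            rows.append(row)
            i += 1  # skip the transition line that follows each residue
    if not rows:
        raise ProfileParseError(f"{path}: no residue blocks after '#'")
    if length is not None and len(rows) != length:
        raise ProfileParseError(
            f"{path}: header LENG {length} but {len(rows)} residue blocks"
        )
    return RawHmm(np.array(rows, dtype=float), "".join(letters))


def read_dssp(path: str | Path, chain: str | None = None) -> RawDssp:
    """Parse a classic DSSP text file into per-residue records.

    Parameters
    ----------
    path:
        DSSP output file.
    chain:
        Chain identifier to extract; ``None`` keeps every chain (the usual
        case for single-chain files).

    Notes
    -----
    Chain-break pseudo-residues (``!`` rows) are excluded from the residue
    list and counted in ``n_breaks``. A blank structure column is the DSSP
    loop state and is recorded as ``'-'``. The 360.0 torsion sentinel becomes
    NaN (undefined).
    """
    path = Path(path)
    try:
        dssp_dict, keys = make_dssp_dict(str(path))
    except Exception as exc:  # biopython raises bare ValueError on bad rows
        raise ProfileParseError(f"{path}: {exc}") from exc

    n_breaks = 0
    body = False
    for line in path.read_text().splitlines():
        if line.lstrip().startswith("#  RESIDUE"):
            body = True
            continue
        if body and len(line) > 13 and line[13] == "!":
            n_breaks += 1

    residues: list[DsspResidue] = []
    for key in keys:
        chain_id = key[0]
        if chain is not None and chain_id != chain:
            continue
        aa, ss, acc, phi, psi = dssp_dict[key][:5]
        if ss == " ":
            ss = "-"
        if ss not in SS_CODES:
            raise ProfileParseError(f"{path}: unknown structure code {ss!r}")
        phi = UNDEFINED_ANGLE if phi == 360.0 else float(phi)
        psi = UNDEFINED_ANGLE if psi == 360.0 else float(psi)
        residues.append(DsspResidue(aa, ss, phi, psi, float(acc)))
    if not residues:
        raise ProfileParseError(f"{path}: no residue rows" + (f" for chain {chain!r}" if chain else ""))
    return RawDssp(residues, n_breaks=n_breaks)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects (no labels)."""
    records = [
        ProteinRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ProfileParseError(f"{path}: no FASTA records")
    return records


def read_labels(path: str | Path) -> dict[str, np.ndarray]:
    """Read a label TSV: one ``chain_id<TAB>0/1-string`` line per chain."""
    labels: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            pid, bits = line.split("\t")
        except ValueError:
            raise ProfileParseError(f"{path}:{lineno}: expected 'id<TAB>labels'") from None
        if set(bits) - {"0", "1"}:
            raise ProfileParseError(f"{path}:{lineno}: labels must be 0/1")
        labels[pid] = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    if not labels:
        raise ProfileParseError(f"{path}: no label lines")
    return labels


def _letter_mismatches(a: str, b: str) -> int:
    """Case-insensitive mismatch count with X as a wildcard on either side."""
    n = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in ("X",) or y in ("X",):
            continue
        if x != y:
            n += 1
    return n


def align_profiles(
    record: ProteinRecord,
    pssm: RawPssm,
    hmm: RawHmm,
    dssp: RawDssp,
    max_mismatch_frac: float = 0.05,
) -> AlignedProfiles:
    """Bind the three raw profiles to a chain after consistency checks.

    All four inputs must have the same length, and the residue letters echoed
    by each profile must match the sequence (case-insensitive, ``X`` tolerated
    on either side) at >= 95% of positions.
    """
    L = len(record)
    lengths = (L, len(pssm), len(hmm), len(dssp))
    if len(set(lengths)) != 1:
        raise AlignmentError(
            f"{record.protein_id}: length mismatch "
            f"(sequence {L}, pssm {lengths[1]}, hmm {lengths[2]}, dssp {lengths[3]})"
        )
    for name, letters in (
        ("pssm", pssm.residue_letters),
        ("hmm", hmm.residue_letters),
        ("dssp", dssp.residue_letters),
    ):
        mism = _letter_mismatches(record.sequence, letters)
        if mism > max_mismatch_frac * L:
            raise AlignmentError(
                f"{record.protein_id}: {name} residue letters disagree with the "
                f"sequence at {mism}/{L} positions (> {max_mismatch_frac:.0%})"
            )
    return AlignedProfiles(record, pssm, hmm, dssp)
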