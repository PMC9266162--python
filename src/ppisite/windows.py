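"""Sliding-window extraction of local per-residue context.

For residue ``i`` of a chain of length ``L`` the window collects feature rows
``i-a .. i+a`` (window length ``n = 2a+1``, the residue itself at the center
row ``a``). Rows that would fall outside the chain are zero vectors, so every
window has the same shape and chains shorter than the window are legal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .features import ResidueProfileSet

__all__ = ["WindowConfig", "WindowBatch", "extract_windows", "BRANCH_ORDER"]

#: Branch order of the model: sub-architectures 1..3 take PSSM, DSSP, HMM.
BRANCH_ORDER = ("pssm", "dssp", "hmm")


@dataclass(frozen=True)
class WindowConfig:
    """Window geometry. ``half_width`` is the neighbor count on each side."""

    half_width: int = 9

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")

    @property
    def window(self) -> int:
        """Window length n = 2a + 1 (odd by construction; default 19)."""
        return 2 * self.half_width + 1


@dataclass
class WindowBatch:
    """Per-residue windows of one or more chains, one array per branch.

    ``arrays[name]`` has shape (N, n, m) with m = 20 (pssm), 14 (dssp),
    20 (hmm); row ``half_width`` of each window is the residue's own feature
    row.
    """

    arrays: dict[str, np.ndarray]
    config: WindowConfig
    residue_ids: list[tuple[str, int]] = field(default_factory=list)
    labels: np.ndarray | None = None
    letters: np.ndarray | None = None  # residue one-letter codes per window

    def __post_init__(self) -> None:
        sizes = {a.shape[0] for a in self.arrays.values()}
        if len(sizes) != 1:
            raise ValueError("branch arrays disagree on batch size")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != next(iter(sizes)):
                raise ValueError("labels length != batch size")

    def __len__(self) -> int:
        return next(iter(self.arrays.values())).shape[0]

    @staticmethod
    def concatenate(batches: list["WindowBatch"]) -> "WindowBatch":
        if not batches:
            raise ValueError("no batches to concatenate")
        cfg = batches[0].config
        arrays = {
            k: np.concatenate([b.arrays[k] for b in batches], axis=0)
            for k in batches[0].arrays
        }
        ids = [rid for b in batches for rid in b.residue_ids]
        labels = None
        if all(b.labels is not None for b in batches):
            labels = np.concatenate([b.labels for b in batches])
        letters = None
        if all(b.letters is not None for b in batches):
            letters = np.concatenate([b.letters for b in batches])
        return WindowBatch(arrays, cfg, ids, labels, letters)

    def save_npz(self, path: str | Path) -> None:
        """Persist windows (one dataset per branch, plus labels) for reuse."""
        payload: dict[str, np.ndarray] = {f"x_{k}": v for k, v in self.arrays.items()}
        payload["half_width"] = np.array(self.config.half_width)
        payload["protein_ids"] = np.array([pid for pid, _ in self.residue_ids])
        payload["positions"] = np.array([pos for _, pos in self.residue_ids])
        if self.labels is not None:
            payload["labels"] = self.labels
        if self.letters is not None:
            payload["letters"] = self.letters
        np.savez_compressed(path, **payload)

    @classmethod
    def load_npz(cls, path: str | Path) -> "WindowBatch":
        with np.load(path, allow_pickle=False) as data:
            arrays = {
                k[2:]: data[k] for k in data.files if k.startswith("x_")
            }
            cfg = WindowConfig(int(data["half_width"]))
            ids = list(zip(data["protein_ids"].tolist(), data["positions"].tolist()))
            labels = data["labels"] if "labels" in data.files else None
            letters = data["letters"] if "letters" in data.files else None
            return cls(arrays, cfg, ids, labels, letters)


def _windows_1d(mat: np.ndarray, a: int) -> np.ndarray:
    """All n=2a+1 windows of an L x m matrix, termini zero-padded: (L, n, m)."""
    L, m = mat.shape
    padded = np.zeros((L + 2 * a, m), dtype=mat.dtype)
    padded[a : a + L] = mat
    # view (L, m, n) -> copy to (L, n, m)
    view = sliding_window_view(padded, 2 * a + 1, axis=0)
    return np.ascontiguousarray(np.swapaxes(view, 1, 2))


def extract_windows(
    features: ResidueProfileSet,
    config: WindowConfig,
    protein_id: str = "",
    labels: np.ndarray | None = None,
    sequence: str | None = None,
) -> WindowBatch:
    """Extract one window per residue from each of the three feature matrices."""
    L = len(features)
    a = config.half_width
    arrays = {
        "pssm": _windows_1d(features.pssm_feat, a),
        "dssp": _windows_1d(features.dssp_feat, a),
        "hmm": _windows_1d(features.hmm_feat, a),
    }
    ids = [(protein_id, i) for i in range(L)]
    letters = np.array(list(sequence)) if sequence is not None else None
    return WindowBatch(arrays, config, ids, labels, letters)
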