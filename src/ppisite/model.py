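"""The three-branch convolutional binding-site classifier.

Each feature type (PSSM, DSSP, HMM — sub-architectures 1 to 3) gets its own
stack of three valid 1-D convolutions along the window axis (kernel sizes
5, 3, 3 with 64, 32, 16 filters, stride 1, ReLU), followed by layer
normalization over the stack's output and a branch-specific dropout
(0.1, 0.3, 0.2). The branch outputs are flattened, concatenated in branch
order, and classified by dense layers of 256, 128, 64 and 1 units — ReLU on
the hidden layers, sigmoid on the output. Training minimizes binary
cross-entropy with SGD + momentum.

With the default window of 19 residues the convolution extents are
19 -> 15 -> 13 -> 11, so each branch flattens to 11 x 16 = 176 values and the
concatenated vector entering the dense head has width 3 x 176 = 528.
"""

from __future__ import annotations

import copy
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score

from . import nn
from .windows import BRANCH_ORDER, WindowBatch

__all__ = ["ModelConfig", "TrainConfig", "BindingSiteCNN", "build_model"]

_FEATURE_DIMS = {"pssm": 20, "dssp": 14, "hmm": 20}
_DROPOUT = {"pssm": 0.1, "dssp": 0.3, "hmm": 0.2}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; the defaults are the published ones."""

    window: int = 19
    branches: tuple[str, ...] = BRANCH_ORDER
    conv_filters: tuple[int, ...] = (64, 32, 16)
    conv_kernels: tuple[int, ...] = (5, 3, 3)
    dropout: tuple[float, ...] | None = None  # per branch, in branch order
    dense: tuple[int, ...] = (256, 128, 64, 1)

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        unknown = set(self.branches) - set(_FEATURE_DIMS)
        if unknown:
            raise ValueError(f"unknown branches {sorted(unknown)}")
        if len(self.conv_filters) != len(self.conv_kernels):
            raise ValueError("conv_filters and conv_kernels differ in length")
        if self.dense[-1] != 1:
            raise ValueError("the final dense layer must have 1 unit")
        shrink = sum(k - 1 for k in self.conv_kernels)
        if self.window - shrink < 1:
            raise ValueError(
                f"window {self.window} too small for kernels {self.conv_kernels} "
                f"(needs >= {shrink + 1})"
            )
        if self.dropout is None:
            object.__setattr__(
                self, "dropout", tuple(_DROPOUT[b] for b in self.branches)
            )
        elif len(self.dropout) != len(self.branches):
            raise ValueError("one dropout rate per branch required")

    @property
    def conv_output_length(self) -> int:
        """Window extent after the valid-convolution stack (15, 13, 11 chain)."""
        return self.window - sum(k - 1 for k in self.conv_kernels)

    @property
    def branch_width(self) -> int:
        """Flattened width of one branch output."""
        return self.conv_output_length * self.conv_filters[-1]

    @property
    def concat_width(self) -> int:
        """Width of the concatenated vector entering the dense head."""
        return self.branch_width * len(self.branches)

    def feature_dim(self, branch: str) -> int:
        return _FEATURE_DIMS[branch]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelConfig":
        doc = json.loads(Path(path).read_text())
        return cls(
            window=doc["window"],
            branches=tuple(doc["branches"]),
            conv_filters=tuple(doc["conv_filters"]),
            conv_kernels=tuple(doc["conv_kernels"]),
            dropout=tuple(doc["dropout"]),
            dense=tuple(doc["dense"]),
        )


@dataclass(frozen=True)
class TrainConfig:
    """SGD schedule. Early stopping watches validation AUPRC when given."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 256
    max_epochs: int = 150
    patience: int = 15
    pos_weight: float = 1.0
    seed: int = 0


class BindingSiteCNN:
    """Three-branch CNN with explicit forward/backward passes."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 dtype=np.float32) -> None:
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

        self.branches: dict[str, nn.Sequential] = {}
        for branch, p_drop in zip(config.branches, config.dropout):
            layers: list[nn.Layer] = []
            in_ch = config.feature_dim(branch)
            for filters, kernel in zip(config.conv_filters, config.conv_kernels):
                layers.append(nn.Conv1D(in_ch, filters, kernel, rng, dtype=dtype))
                layers.append(nn.ReLU())
                in_ch = filters
            layers.append(
                nn.LayerNorm((config.conv_output_length, config.conv_filters[-1]),
                             dtype=dtype)
            )
            layers.append(nn.Dropout(p_drop, self._dropout_rng))
            layers.append(nn.Flatten())
            self.branches[branch] = nn.Sequential(layers)

        head_layers: list[nn.Layer] = []
        width = config.concat_width
        for i, units in enumerate(config.dense):
            head_layers.append(nn.Dense(width, units, rng, dtype=dtype))
            if i < len(config.dense) - 1:
                head_layers.append(nn.ReLU())
            width = units
        self.head = nn.Sequential(head_layers)

        self.params = [p for b in self.branches.values() for p in b.params]
        self.params += self.head.params
        self.grads = [g for b in self.branches.values() for g in b.grads]
        self.grads += self.head.grads
        self.epoch_log: list[dict] = []

    # ---- forward / backward -------------------------------------------------

    def _check_batch(self, batch: WindowBatch) -> None:
        for branch in self.config.branches:
            if branch not in batch.arrays:
                raise ValueError(f"batch lacks branch {branch!r}")
            n, m = batch.arrays[branch].shape[1:]
            if n != self.config.window or m != self.config.feature_dim(branch):
                raise ValueError(
                    f"branch {branch!r}: window batch is {n}x{m}, model expects "
                    f"{self.config.window}x{self.config.feature_dim(branch)}"
                )

    def _forward_logits(self, arrays: dict[str, np.ndarray],
                        train: bool = False) -> np.ndarray:
        outs = [
            self.branches[b].forward(arrays[b].astype(self.dtype, copy=False),
                                     train=train)
            for b in self.config.branches
        ]
        self._branch_widths = [o.shape[1] for o in outs]
        z = np.concatenate(outs, axis=1)
        return self.head.forward(z, train=train).ravel()

    def _backward_logits(self, grad_logits: np.ndarray) -> None:
        gz = self.head.backward(grad_logits[:, None])
        offset = 0
        for branch, width in zip(self.config.branches, self._branch_widths):
            self.branches[branch].backward(gz[:, offset : offset + width])
            offset += width

    def predict_proba(self, batch: WindowBatch, chunk: int = 8192) -> np.ndarray:
        """Per-residue scores in the open interval (0, 1); dropout inert."""
        self._check_batch(batch)
        out = np.empty(len(batch), dtype=float)
        for start in range(0, len(batch), chunk):
            arrays = {k: v[start : start + chunk] for k, v in batch.arrays.items()}
            logits = self._forward_logits(arrays, train=False)
            out[start : start + len(logits)] = nn.sigmoid(logits)
        return np.clip(out, nn.EPS_CLIP, 1.0 - nn.EPS_CLIP)

    # ---- training -----------------------------------------------------------

    def fit(self, batch: WindowBatch, val_batch: WindowBatch | None = None,
            train_config: TrainConfig | None = None) -> list[dict]:
        """Train on a labelled window batch; returns the epoch log.

        If ``val_batch`` is given, training stops once its AUPRC has not
        improved for ``patience`` epochs and the best-epoch weights are
        restored.
        """
        cfg = train_config or TrainConfig()
        self._check_batch(batch)
        if batch.labels is None:
            raise ValueError("training batch has no labels")
        y = np.asarray(batch.labels, dtype=float)
        opt = nn.SGD(self.params, self.grads, lr=cfg.learning_rate,
                     momentum=cfg.momentum)
        rng = np.random.default_rng(cfg.seed)
        n = len(batch)
        best_score, best_params, since_best = -np.inf, None, 0
        for epoch in range(cfg.max_epochs):
            t0 = time.perf_counter()
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                arrays = {k: v[idx] for k, v in batch.arrays.items()}
                logits = self._forward_logits(arrays, train=True)
                probs = nn.sigmoid(logits)
                loss = nn.bce_loss(y[idx], probs, pos_weight=cfg.pos_weight)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {loss}"
                    )
                opt.zero_grad()
                self._backward_logits(
                    nn.bce_grad(y[idx], probs, pos_weight=cfg.pos_weight
                                ).astype(self.dtype)
                )
                opt.step()
                epoch_loss += loss
                n_batches += 1
            entry = {
                "epoch": epoch,
                "train_loss": epoch_loss / n_batches,
                "seconds": time.perf_counter() - t0,
            }
            if val_batch is not None and val_batch.labels is not None:
                val_scores = self.predict_proba(val_batch)
                val_y = np.asarray(val_batch.labels)
                entry["val_loss"] = nn.bce_loss(val_y, val_scores)
                if val_y.min() != val_y.max():
                    entry["val_auprc"] = float(
                        average_precision_score(val_y, val_scores)
                    )
                    score = entry["val_auprc"]
                else:  # degenerate validation split: fall back to loss
                    score = -entry["val_loss"]
                if score > best_score:
                    best_score, since_best = score, 0
                    best_params = [p.copy() for p in self.params]
                else:
                    since_best += 1
                self.epoch_log.append(entry)
                if since_best >= cfg.patience:
                    break
            else:
                self.epoch_log.append(entry)
        if best_params is not None:
            for p, best in zip(self.params, best_params):
                p[...] = best
        return self.epoch_log

    # ---- persistence --------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def save(self, path: str | Path) -> None:
        """Write weights as .npz with a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **{f"param_{i}": p for i, p in enumerate(self.params)})
        self.config.to_json(path.with_suffix(".config.json"))

    @classmethod
    def load(cls, path: str | Path, config: ModelConfig | None = None
             ) -> "BindingSiteCNN":
        path = Path(path)
        if config is None:
            config = ModelConfig.from_json(path.with_suffix(".config.json"))
        model = cls(config)
        with np.load(path if path.suffix == ".npz" else str(path)) as data:
            for i, p in enumerate(model.params):
                saved = data[f"param_{i}"]
                if saved.shape != p.shape:
                    raise ValueError(
                        f"checkpoint param {i} has shape {saved.shape}, "
                        f"model expects {p.shape}"
                    )
                p[...] = saved
        return model


def build_model(config: ModelConfig | None = None, seed: int = 0) -> BindingSiteCNN:
    """Construct the classifier; two builds with one seed are identical."""
    return BindingSiteCNN(config or ModelConfig(), seed=seed)
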