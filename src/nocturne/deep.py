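"""Convolutional-biLSTM-attention estimator of imminent-wetting probability.

Architecture (one 10-minute block in, one probability out):

1. three separate 1-D convolution branches — one per modality (bladder 5-dim,
   heart 9-dim, movement 7-dim) — each with kernels spanning the branch's
   *full* feature dimension and a short time extent, so every kernel reads
   the whole modality at once (the multi-channel design used for EEG-style
   multichannel signals);
2. branch outputs are concatenated per time step and fed to a bi-directional
   LSTM, capturing the block's temporal structure in both directions;
3. additive attention over the LSTM's per-step outputs pools the sequence
   into a context vector, letting the model weight the informative part of
   the block;
4. a sigmoid head maps the context to a probability in [0, 1].

Training minimizes mean-squared error against the linear probability
targets, with Adam, split by night (never by block) to avoid leakage, and is
deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nnet
from .estimators import BLOCK_WINDOWS, make_blocks
from .features import ALL_FEATURES, BV_FEATURES, LM_FEATURES
from .heart import HRV_FEATURES
from .labels import NEProbabilityCurve

__all__ = ["DEConfig", "DeepEstimator", "TrainingLog", "train_de", "de_estimate"]

_BRANCHES = {
    "bv": list(BV_FEATURES),
    "hr": list(HRV_FEATURES),
    "lm": list(LM_FEATURES),
}


@dataclass(frozen=True)
class DEConfig:
    conv_channels: int = 6
    conv_kernel: int = 3          # time extent; feature extent = full branch dim
    hidden: int = 12              # per direction
    attention_dim: int = 12
    learning_rate: float = 0.02
    epochs: int = 10
    batch_size: int = 256
    seed: int = 0
    val_fraction: float = 0.25
    alarm_threshold: float = 0.85

    def __post_init__(self) -> None:
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.conv_kernel < 1 or self.conv_kernel > BLOCK_WINDOWS:
            raise ValueError("conv_kernel must be within the block length")


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)   # per epoch
    val_loss: list[float] = field(default_factory=list)
    n_train_blocks: int = 0
    n_val_blocks: int = 0
    train_nights: list[str] = field(default_factory=list)
    val_nights: list[str] = field(default_factory=list)


class DeepEstimator:
    """The trained model: branch convolutions + biLSTM + attention + head."""

    def __init__(self, config: DEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        C, K = config.conv_channels, config.conv_kernel
        self.conv = {
            name: nnet.Linear(K * len(cols), C, rng) for name, cols in _BRANCHES.items()
        }
        n_concat = C * len(_BRANCHES)
        self.fwd = nnet.LSTMCell(n_concat, config.hidden, rng)
        self.bwd = nnet.LSTMCell(n_concat, config.hidden, rng)
        self.attn_proj = nnet.Linear(2 * config.hidden, config.attention_dim, rng)
        self.attn_v = nnet.Linear(config.attention_dim, 1, rng)
        self.head = nnet.Linear(2 * config.hidden, 1, rng)
        # feature normalization (set from training data)
        self.feat_mean = np.zeros(len(ALL_FEATURES))
        self.feat_std = np.ones(len(ALL_FEATURES))

    # -- parameters --------------------------------------------------------
    def params(self) -> list[nnet.Tensor]:
        out = []
        for lin in self.conv.values():
            out += lin.params()
        out += self.fwd.params() + self.bwd.params()
        out += self.attn_proj.params() + self.attn_v.params() + self.head.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    # -- forward -----------------------------------------------------------
    def _normalize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feat_mean) / self.feat_std

    def forward(self, X: np.ndarray) -> nnet.Tensor:
        """Probability for a batch of raw blocks ``X`` (B, 20, 21)."""
        X = self._normalize(np.asarray(X, dtype=np.float64))
        K = self.config.conv_kernel
        T_out = BLOCK_WINDOWS - K + 1
        col_idx = {name: [ALL_FEATURES.index(c) for c in cols]
                   for name, cols in _BRANCHES.items()}
        steps: list[nnet.Tensor] = []
        for t in range(T_out):
            branch_outs = []
            for name in _BRANCHES:
                xb = X[:, t : t + K, :][:, :, col_idx[name]]  # (B, K, F)
                flat = xb.reshape(xb.shape[0], -1)
                branch_outs.append(nnet.tanh(self.conv[name](flat)))
            steps.append(nnet.concat(branch_outs, axis=-1))

        B = X.shape[0]
        H = self.config.hidden
        zeros = nnet.Tensor(np.zeros((B, H)))
        h, c = zeros, zeros
        fwd_out: list[nnet.Tensor] = []
        for t in range(T_out):
            h, c = self.fwd(steps[t], h, c)
            fwd_out.append(h)
        h, c = zeros, zeros
        bwd_out: list[nnet.Tensor | None] = [None] * T_out
        for t in reversed(range(T_out)):
            h, c = self.bwd(steps[t], h, c)
            bwd_out[t] = h
        seq = [nnet.concat([fwd_out[t], bwd_out[t]], axis=-1) for t in range(T_out)]

        scores = [self.attn_v(nnet.tanh(self.attn_proj(a))) for a in seq]  # (B,1) each
        alpha = nnet.softmax(nnet.concat(scores, axis=-1), axis=-1)        # (B,T)
        context = None
        for t in range(T_out):
            term = nnet.mul(nnet.slice_cols(alpha, t, t + 1), seq[t])
            context = term if context is None else nnet.add(context, term)
        return nnet.sigmoid(self.head(context))  # (B, 1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Probabilities for raw blocks, as a flat ndarray."""
        return self.forward(X).data.ravel()

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        arrays["feat_mean"] = self.feat_mean
        arrays["feat_std"] = self.feat_std
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "DeepEstimator":
        with np.load(path, allow_pickle=False) as z:
            config = DEConfig(**json.loads(str(z["config"])))
            model = cls(config)
            for i, p in enumerate(model.params()):
                p.data = z[f"p{i}"]
            model.feat_mean = z["feat_mean"]
            model.feat_std = z["feat_std"]
        return model


def _blocks_and_targets(
    frame: pd.DataFrame, curve: NEProbabilityCurve
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block feature stacks, target probabilities (at each block's last
    window), and a usability mask (complete block, unmasked target)."""
    blocks = make_blocks(frame)
    if not blocks:
        return np.empty((0, BLOCK_WINDOWS, len(ALL_FEATURES))), np.empty(0), np.empty(0, bool)
    X = np.stack([b.features[list(ALL_FEATURES)].to_numpy() for b in blocks])
    last = np.array([b.start_window + BLOCK_WINDOWS - 1 for b in blocks])
    y = curve.p[last]
    usable = np.array(
        [b.complete and curve.target_mask[l] for b, l in zip(blocks, last)]
    ) & ~np.isnan(X).any(axis=(1, 2))
    return X, y, usable


def train_de(
    nights: list[tuple[pd.DataFrame, NEProbabilityCurve]],
    config: DEConfig = DEConfig(),
) -> tuple[DeepEstimator, TrainingLog]:
    """Train the deep estimator on (feature frame, probability curve) pairs.

    The train/validation split is by night.  Requires at least two enuretic
    and two dry nights in the training split.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(len(nights))
    n_val = int(round(config.val_fraction * len(nights)))
    val_idx = set(order[:n_val].tolist())

    def split(indices):
        Xs, ys = [], []
        ids = []
        for i in indices:
            frame, curve = nights[i]
            X, y, usable = _blocks_and_targets(frame, curve)
            Xs.append(X[usable])
            ys.append(y[usable])
            ids.append(str(frame.attrs.get("night_id", i)))
        if Xs:
            return np.concatenate(Xs), np.concatenate(ys), ids
        return np.empty((0, BLOCK_WINDOWS, len(ALL_FEATURES))), np.empty(0), ids

    train_nights = [i for i in range(len(nights)) if i not in val_idx]
    ne_flags = [bool(nights[i][0].attrs.get("is_ne_day")) for i in train_nights]
    if sum(ne_flags) < 2 or len(ne_flags) - sum(ne_flags) < 2:
        raise ValueError(
            "degenerate split: need >= 2 enuretic and >= 2 dry nights in training"
        )
    X_train, y_train, train_ids = split(train_nights)
    X_val, y_val, val_ids = split(sorted(val_idx))

    model = DeepEstimator(config)
    flat = X_train.reshape(-1, len(ALL_FEATURES))
    model.feat_mean = flat.mean(axis=0)
    model.feat_std = np.where(flat.std(axis=0) > 1e-9, flat.std(axis=0), 1.0)

    opt = nnet.Adam(model.params(), lr=config.learning_rate)
    log = TrainingLog(
        n_train_blocks=len(y_train), n_val_blocks=len(y_val),
        train_nights=train_ids, val_nights=val_ids,
    )
    n = len(y_train)
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            pred = model.forward(X_train[idx])
            target = y_train[idx].reshape(-1, 1)
            diff = nnet.sub(pred, target)
            loss = nnet.mean_all(nnet.mul(diff, diff))
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        log.train_loss.append(epoch_loss / n)
        if len(y_val):
            val_pred = model.predict(X_val)
            log.val_loss.append(float(np.mean((val_pred - y_val) ** 2)))
    return model, log


def de_estimate(model: DeepEstimator, block_features: np.ndarray) -> float:
    """Probability for a single complete block (20, 21); NaN blocks raise."""
    X = np.asarray(block_features, dtype=np.float64)[None, ...]
    if np.isnan(X).any():
        raise ValueError("incomplete block: decision missing")
    return float(model.predict(X)[0])
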