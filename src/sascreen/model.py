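"""Sequence-to-activity regression model for SaCas9 target contexts.

The regressor is a dual-branch network over one-hot encoded DNA:

* a shared 1-D convolution block (128 filters, window 3, 'same' padding,
  LeakyReLU, max-pool 2, dropout 0.3), feeding
* branch 1: three further convolution blocks, flattened into two dense
  blocks (128 then 64 units, LeakyReLU, dropout 0.3) converging to size 1;
* branch 2: a bidirectional GRU (128 units, recurrent dropout 0.2) into the
  same two dense blocks converging to size 1;
* the two scalar branch outputs concatenated into a final size-1 linear head.

Training minimises mean squared error with Adam.  The input window is the
21-nt spacer plus configurable upstream (PAM-distal) and downstream context,
where downstream counts the 6-nt PAM first and then the [+1], [+2], ...
flanking positions; the default window is spacer + PAM + 2 flanks (N = 29).
Model selection uses five-fold cross-validation on the training split only;
the 20% test split is quarantined from all fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, train_test_split

from . import nn
from .targets import TargetSite, matches_iupac

BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(BASES)}


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode DNA as a 4-by-N binary matrix (rows A, C, G, T)."""
    seq = sequence.upper()
    mat = np.zeros((4, len(seq)), dtype=np.int8)
    for j, b in enumerate(seq):
        if b not in _B2I:
            raise ValueError(f"ambiguous base {b!r} at position {j}")
        mat[_B2I[b], j] = 1
    return mat


def one_hot_decode(matrix: np.ndarray) -> str:
    if not np.all(matrix.sum(axis=0) == 1):
        raise ValueError("matrix columns are not one-hot")
    return "".join(BASES[i] for i in matrix.argmax(axis=0))


def encode_dataset(sequences: Sequence[str]) -> np.ndarray:
    """Stack sequences into a float32 (n, N, 4) channels-last tensor."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths {sorted(lengths)}")
    return np.stack([one_hot_encode(s).T for s in sequences]).astype(np.float32)


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``downstream_nt`` counts the PAM first: 6 = spacer+PAM, 8 adds [+1][+2].
    Batch size, learning rate and epochs are the tunables explored by the
    cross-validation harness.
    """

    upstream_nt: int = 0
    spacer_nt: int = 21
    downstream_nt: int = 8
    conv_filters: int = 128
    conv_window: int = 3
    pool_size: int = 2
    dropout: float = 0.3
    bgru_size: int = 128
    bgru_recurrent_dropout: float = 0.2
    dense_sizes: tuple[int, int] = (128, 64)
    leaky_alpha: float = 0.01
    batch_size: int = 64
    learning_rate: float = 1e-3
    epochs: int = 50
    split_state: int = 1
    train_fraction: float = 0.8

    @property
    def input_length(self) -> int:
        return self.upstream_nt + self.spacer_nt + self.downstream_nt

    def __post_init__(self):
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if min(self.conv_filters, self.bgru_size, *self.dense_sizes) <= 0:
            raise ValueError("layer sizes must be positive")
        if self.input_length < self.conv_window:
            raise ValueError("input window shorter than convolution window")


class ActivityModel:
    """Dual-branch CNN / BGRU regressor over one-hot DNA windows."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.rng = np.random.default_rng(seed)
        c = config
        r = self.rng
        self.conv_shared = nn.Conv1D(r, 4, c.conv_filters, c.conv_window)
        self.convs_branch1 = [
            nn.Conv1D(r, c.conv_filters, c.conv_filters, c.conv_window)
            for _ in range(3)
        ]
        L = c.input_length
        for _ in range(4):  # shared block + 3 branch blocks each pool by 2
            L = -(-L // c.pool_size)
        d1, d2 = c.dense_sizes
        self.dense_branch1 = [
            nn.Dense(r, L * c.conv_filters, d1),
            nn.Dense(r, d1, d2),
            nn.Dense(r, d2, 1),
        ]
        self.bgru = nn.BiGRU(r, c.conv_filters, c.bgru_size,
                             c.bgru_recurrent_dropout)
        self.dense_branch2 = [
            nn.Dense(r, 2 * c.bgru_size, d1),
            nn.Dense(r, d1, d2),
            nn.Dense(r, d2, 1),
        ]
        self.head = nn.Dense(r, 2, 1)

    def parameters(self):
        params = self.conv_shared.parameters()
        for layer in self.convs_branch1:
            params += layer.parameters()
        for layer in self.dense_branch1 + self.dense_branch2:
            params += layer.parameters()
        params += self.bgru.parameters()
        params += self.head.parameters()
        return params

    @property
    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _conv_block(self, layer, x, train):
        c = self.config
        h = nn.leaky_relu(layer(x), c.leaky_alpha)
        h = nn.max_pool1d_same(h, c.pool_size)
        return nn.dropout(h, c.dropout, self.rng, train)

    def _dense_blocks(self, layers, x, train):
        c = self.config
        h = x
        for layer in layers[:-1]:
            h = nn.leaky_relu(layer(h), c.leaky_alpha)
            h = nn.dropout(h, c.dropout, self.rng, train)
        return layers[-1](h)  # size-1 linear convergence

    def forward(self, x: np.ndarray, train: bool = False) -> nn.Tensor:
        if x.shape[1] != self.config.input_length or x.shape[2] != 4:
            raise ValueError(
                f"expected input (B, {self.config.input_length}, 4), got {x.shape}"
            )
        shared = self._conv_block(self.conv_shared, nn.Tensor(x), train)
        h1 = shared
        for layer in self.convs_branch1:
            h1 = self._conv_block(layer, h1, train)
        B = x.shape[0]
        h1 = nn.reshape(h1, (B, h1.data.shape[1] * h1.data.shape[2]))
        o1 = self._dense_blocks(self.dense_branch1, h1, train)
        h2 = self.bgru(shared, self.rng, train)
        o2 = self._dense_blocks(self.dense_branch2, h2, train)
        return self.head(nn.concat([o1, o2], axis=1))

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i:i + batch_size], train=False).data)
        return np.concatenate(out).ravel()


def build_model(config: ModelConfig, seed: int = 0) -> ActivityModel:
    """Instantiate the dual-branch architecture with seeded initialisation."""
    return ActivityModel(config, seed=seed)


def train_model(
    sequences: Sequence[str] | np.ndarray,
    scores: Sequence[float],
    config: ModelConfig,
    seed: int = 0,
    model: ActivityModel | None = None,
) -> tuple[ActivityModel, dict]:
    """Fit the regressor by minibatch Adam on mean squared error.

    Returns the fitted model and a history dict with per-epoch training loss.
    Aborts with diagnostics if the loss becomes non-finite.
    """
    x = sequences if isinstance(sequences, np.ndarray) else encode_dataset(sequences)
    y = np.asarray(scores, dtype=np.float32)
    if len(x) != len(y):
        raise ValueError("sequences and scores differ in length")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite activity scores")
    if model is None:
        model = build_model(config, seed=seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(seed + 1)
    history = {"loss": []}
    n = len(x)
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            opt.zero_grad()
            pred = model.forward(x[idx], train=True)
            loss = nn.mse_loss(pred, y[idx][:, None])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // config.batch_size}: "
                    f"loss={float(loss.data)!r}, lr={config.learning_rate}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["loss"].append(float(np.mean(losses)))
    return model, history


def split_train_test(
    items: Sequence,
    train_fraction: float = 0.8,
    state: int = 1,
) -> tuple[list, list]:
    """Deterministic 80/20 split; disjoint and exhaustive for a fixed state."""
    items = list(items)
    if len(items) < 10:
        raise ValueError("need at least 10 examples to split")
    train, test = train_test_split(
        items, test_size=1.0 - train_fraction, random_state=state, shuffle=True
    )
    return train, test


def assert_quarantine(train_ids: Sequence, test_ids: Sequence) -> None:
    """Audit that no test example can leak into training."""
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise AssertionError(f"test-set quarantine violated: {sorted(overlap)[:5]}")


def cross_validate(
    x: np.ndarray,
    y: Sequence[float],
    config: ModelConfig,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold cross-validation on the training set only.

    Folds partition the data; each fold's model is trained from scratch and
    scored by Spearman correlation on the held-out fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y, dtype=np.float32)
    if min(np.bincount(np.arange(len(x)) % k)) < 1:
        raise ValueError("fold smaller than 1 example")
    rows = []
    for rep in range(repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for fold, (tr, te) in enumerate(kf.split(x)):
            model, _ = train_model(x[tr], y[tr], config, seed=seed + 101 * rep + fold)
            pred = model.predict(x[te])
            rho = stats.spearmanr(pred, y[te]).statistic
            rows.append({"repeat": rep, "fold": fold, "n": len(te),
                         "spearman": float(rho)})
    return pd.DataFrame(rows)


def input_length_scan(
    sites: Sequence[TargetSite],
    activities: Sequence[float],
    config: ModelConfig,
    windows: Sequence[tuple[int, int]],
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    pam6: str | None = None,
) -> pd.DataFrame:
    """Cross-validate nested input windows to find the informative context.

    ``windows`` is a list of (upstream_nt, downstream_nt) pairs, downstream
    counting PAM nucleotides before flanks.  ``pam6`` restricts the scan to
    sites with that final PAM nucleotide (the stratified variant).  Every
    site must carry enough flank for the largest window; offenders are
    reported.
    """
    y = np.asarray(activities, dtype=np.float32)
    if len(sites) != len(y):
        raise ValueError("sites and activities differ in length")
    if pam6 is not None:
        keep = [i for i, s in enumerate(sites) if s.pam[5] == pam6]
        sites = [sites[i] for i in keep]
        y = y[keep]
    max_up = max(w[0] for w in windows)
    max_down = max(w[1] for w in windows)
    bad = [s.sgrna_id or s.spacer for s in sites
           if len(s.upstream_flank) < max_up
           or len(s.pam + s.downstream_flank) < max_down]
    if bad:
        raise ValueError(f"insufficient flank for scan: {bad[:10]}")
    rows = []
    for up, down in sorted(windows, key=lambda w: (w[0] + w[1], w)):
        seqs = [s.window(up, down) for s in sites]
        cfg = replace(config, upstream_nt=up, downstream_nt=down)
        cv = cross_validate(encode_dataset(seqs), y, cfg, k=k,
                            repeats=repeats, seed=seed)
        rows.append({
            "upstream_nt": up, "downstream_nt": down,
            "window_nt": cfg.input_length,
            "cv_spearman_mean": float(cv["spearman"].mean()),
            "cv_spearman_sd": float(cv["spearman"].std(ddof=1)),
        })
    return pd.DataFrame(rows)


def evaluate(
    model: ActivityModel,
    sites: Sequence[TargetSite],
    activities: Sequence[float],
    subset_pattern: str | None = None,
) -> tuple[float, float, int]:
    """Spearman/Pearson between predictions and observed activity.

    ``subset_pattern`` is an IUPAC pattern applied to the PAM and, if longer
    than 6 nt, the downstream flank (e.g. ``NNGRRV`` or ``NNGRRTH``).
    """
    y = np.asarray(activities, dtype=np.float32)
    idx = list(range(len(sites)))
    if subset_pattern is not None:
        idx = [i for i in idx if matches_iupac(
            (sites[i].pam + sites[i].downstream_flank)[:len(subset_pattern)],
            subset_pattern)]
    if len(idx) < 3:
        raise ValueError(f"fewer than 3 sites after subsetting ({len(idx)})")
    c = model.config
    seqs = [sites[i].window(c.upstream_nt, c.downstream_nt) for i in idx]
    pred = model.predict(encode_dataset(seqs))
    rho = stats.spearmanr(pred, y[idx]).statistic
    r = stats.pearsonr(pred, y[idx]).statistic
    return float(rho), float(r), len(idx)
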