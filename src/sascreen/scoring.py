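"""Compositional activity scoring of pooled-screen count tables.

Sequencing counts are compositional: only relative abundances are
informative.  Following the Dirichlet Monte-Carlo CLR approach, each
replicate column is converted into ``n_instances`` posterior probability
vectors drawn from Dirichlet(counts + 0.5) (a Jeffreys-style prior that also
handles zeros), log2-transformed, and centred so every instance vector sums
to zero.  Per-sgRNA statistics are then medians over instances:

* ``rab_all``  — median CLR relative abundance over all replicates,
* ``diff_btw`` — median between-condition difference of replicate-mean CLR
  (log2 units; the absolute effect size),
* ``diff_win`` — the larger of the two conditions' median absolute CLR
  difference between randomly paired replicates (within-condition
  dispersion).

The on-target activity score is ``diff_btw`` for enrichment screens and
``-diff_btw`` for depletion screens, so that higher activity is always a
larger score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class ActivityRecord:
    sgrna_id: str
    rab_all: float
    diff_btw: float
    diff_win: float
    activity: float | None = None


CONTROL, EXPERIMENTAL = "control", "experimental"


def condition_of(column: str) -> str:
    """Parse the condition from a 'condition:replicate' column label."""
    cond = column.split(":", 1)[0]
    if cond not in (CONTROL, EXPERIMENTAL):
        raise ValueError(f"column {column!r} has unknown condition {cond!r}")
    return cond


def clr_instances(
    table: pd.DataFrame,
    n_instances: int = 128,
    seed: int = 0,
    prior: float = 0.5,
) -> np.ndarray:
    """Monte-Carlo CLR values, shape (n_features, n_replicates, n_instances).

    Each instance is one Dirichlet(counts + prior) posterior draw per
    replicate, log2-transformed and centred over features (every CLR vector
    sums to zero).
    """
    if n_instances < 2:
        raise ValueError("n_instances must be >= 2")
    if table.empty:
        raise ValueError("empty count table")
    counts = table.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("all-zero replicate column")
    rng = np.random.default_rng(seed)
    n_feat, n_rep = counts.shape
    out = np.empty((n_feat, n_rep, n_instances))
    for j in range(n_rep):
        p = rng.dirichlet(counts[:, j] + prior, size=n_instances)  # (inst, feat)
        logp = np.log2(p)
        clr = logp - logp.mean(axis=1, keepdims=True)
        out[:, j, :] = clr.T
    return out


def condition_statistics(
    clr: np.ndarray,
    columns: Sequence[str],
    sgrna_ids: Sequence[str],
    seed: int = 0,
) -> list[ActivityRecord]:
    """Reduce per-instance CLR values to rab.all / diff.btw / diff.win."""
    conds = [condition_of(c) for c in columns]
    ctrl = [i for i, c in enumerate(conds) if c == CONTROL]
    expt = [i for i, c in enumerate(conds) if c == EXPERIMENTAL]
    if not ctrl or not expt:
        raise ValueError("both control and experimental replicates required")
    n_feat, n_rep, n_inst = clr.shape
    if n_rep != len(columns):
        raise ValueError("clr replicate axis does not match columns")

    mean_ctrl = clr[:, ctrl, :].mean(axis=1)  # (feat, inst)
    mean_expt = clr[:, expt, :].mean(axis=1)
    diff_btw = np.median(mean_expt - mean_ctrl, axis=1)
    rab_all = np.median(clr.reshape(n_feat, -1), axis=1)

    rng = np.random.default_rng(seed)
    win_parts = []
    for group in (ctrl, expt):
        if len(group) < 2:
            continue
        # one random distinct replicate pair per MC instance
        a = rng.integers(0, len(group), size=n_inst)
        b = (a + 1 + rng.integers(0, len(group) - 1, size=n_inst)) % len(group)
        ga = clr[:, group, :][:, a, np.arange(n_inst)]
        gb = clr[:, group, :][:, b, np.arange(n_inst)]
        win_parts.append(np.median(np.abs(ga - gb), axis=1))
    if win_parts:
        diff_win = np.max(np.stack(win_parts), axis=0)
    else:
        diff_win = np.full(n_feat, np.nan)

    return [
        ActivityRecord(sgrna_id=sid, rab_all=float(rab_all[i]),
                       diff_btw=float(diff_btw[i]), diff_win=float(diff_win[i]))
        for i, sid in enumerate(sgrna_ids)
    ]


def to_activity(records: list[ActivityRecord], mode: str) -> list[ActivityRecord]:
    """Fix the sign convention: activity = diff.btw (enrichment) or its inverse
    (depletion), so higher activity always means a more active sgRNA."""
    if mode not in ("enrichment", "depletion"):
        raise ValueError(f"mode must be enrichment or depletion, got {mode!r}")
    sign = 1.0 if mode == "enrichment" else -1.0
    for r in records:
        r.activity = sign * r.diff_btw
    return records


def score_table(
    table: pd.DataFrame,
    mode: str,
    n_instances: int = 128,
    seed: int = 0,
    prior: float = 0.5,
) -> pd.DataFrame:
    """End-to-end scoring of a count table into an ActivityRecord frame."""
    clr = clr_instances(table, n_instances=n_instances, seed=seed, prior=prior)
    records = condition_statistics(clr, list(table.columns),
                                   list(table.index), seed=seed + 1)
    records = to_activity(records, mode)
    return pd.DataFrame([r.__dict__ for r in records]).set_index("sgrna_id")
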