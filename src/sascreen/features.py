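"""Positional nucleotide-preference statistics over target-site windows.

Summarises how activity depends on sequence position: per-position mean
activity for single nucleotides or adjacent (overlapping) dinucleotides
across a fixed analysis window — 4 nt upstream, the 21-nt spacer, the 6-nt
PAM and 8 nt downstream — and the grouping of activity by the tetranucleotide
at PAM positions 4, 5, 6 and flank [+1], which exposes both the T-richness
preference around the PAM/flank junction and the low-activity GATC group.

Axis labels: ``u-4..u-1`` (upstream), ``s1..s21`` (spacer), ``p1..p6``
(PAM), ``f+1..f+8`` (downstream flank).  Empty cells stay NaN (flagged, not
zero-filled), so weighted cell means always reconstruct the global mean.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .targets import TargetSite

UPSTREAM_NT, SPACER_NT, PAM_NT, DOWNSTREAM_NT = 4, 21, 6, 8

BASES = list("ACGT")
DINUCS = [a + b for a in BASES for b in BASES]


def axis_labels(upstream=UPSTREAM_NT, spacer=SPACER_NT, pam=PAM_NT,
                downstream=DOWNSTREAM_NT) -> list[str]:
    return ([f"u-{i}" for i in range(upstream, 0, -1)]
            + [f"s{i}" for i in range(1, spacer + 1)]
            + [f"p{i}" for i in range(1, pam + 1)]
            + [f"f+{i}" for i in range(1, downstream + 1)])


def _window_sequences(sites: Sequence[TargetSite]) -> list[str]:
    seqs = []
    for s in sites:
        if (len(s.upstream_flank) < UPSTREAM_NT
                or len(s.downstream_flank) < DOWNSTREAM_NT
                or len(s.spacer) != SPACER_NT):
            raise ValueError(
                f"{s.sgrna_id}: window requires {UPSTREAM_NT} nt upstream and "
                f"{DOWNSTREAM_NT} nt downstream flank around a {SPACER_NT}-nt spacer"
            )
        seqs.append(s.upstream_flank[-UPSTREAM_NT:] + s.spacer + s.pam
                    + s.downstream_flank[:DOWNSTREAM_NT])
    return seqs


def positional_means(
    sites: Sequence[TargetSite],
    activities: Mapping[str, float],
    order: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean activity per (position, nucleotide) or (position-pair, dinucleotide).

    Returns (means, counts) frames; rows are nucleotides (order 1) or
    dinucleotides (order 2), columns are positions — dinucleotide columns are
    indexed by their left position.  Cells with no observations are NaN.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    seqs = _window_sequences(sites)
    y = np.array([activities[s.sgrna_id] for s in sites], dtype=float)
    labels = axis_labels()
    cols = labels if order == 1 else [
        f"{a}|{b}" for a, b in zip(labels[:-1], labels[1:])
    ]
    rows = BASES if order == 1 else DINUCS
    sums = pd.DataFrame(0.0, index=rows, columns=cols)
    counts = pd.DataFrame(0, index=rows, columns=cols)
    arr = np.array([list(s) for s in seqs])
    for j, col in enumerate(cols):
        keys = arr[:, j] if order == 1 else arr[:, j] + arr[:, j + 1]
        for key in np.unique(keys):
            mask = keys == key
            sums.loc[key, col] = y[mask].sum()
            counts.loc[key, col] = int(mask.sum())
    means = sums / counts.replace(0, np.nan)
    return means, counts


def pam_tetranucleotide_groups(
    sites: Sequence[TargetSite],
    activities: Mapping[str, float],
    min_n: int = 5,
) -> pd.DataFrame:
    """Activity distribution per tetranucleotide at PAM 4, 5, 6 and [+1].

    Reports n, mean, median and quartiles for each of the up-to-256 groups
    (keyed by the four bases); groups below ``min_n`` are retained in the
    table but flagged so violin-style summaries can drop them.
    """
    rows = []
    values: dict[tuple, list[float]] = {}
    for s in sites:
        if len(s.downstream_flank) < 1:
            raise ValueError(f"{s.sgrna_id}: [+1] flank required")
        key = (s.pam[3], s.pam[4], s.pam[5], s.downstream_flank[0])
        values.setdefault(key, []).append(activities[s.sgrna_id])
    for key in sorted(values):
        v = np.array(values[key])
        rows.append({
            "pam4": key[0], "pam5": key[1], "pam6": key[2], "plus1": key[3],
            "n": len(v), "mean": v.mean(), "median": float(np.median(v)),
            "q25": float(np.quantile(v, 0.25)), "q75": float(np.quantile(v, 0.75)),
            "reportable": len(v) >= min_n,
        })
    return pd.DataFrame(rows)
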