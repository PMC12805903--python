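"""Amplicon read demultiplexing, sgRNA counting, and count-table I/O.

Merged amplicon reads carry a 12-mer replicate barcode at a fixed offset
from the read start.  Demultiplexing is exact-match by default (a mismatch
tolerance is exposed but defaults to 0, since no error correction is
assumed), and sgRNA counting increments a spacer when it occurs exactly
once among the pool's spacers in the read or its reverse complement;
ambiguous (>= 2 spacers) and unmatched reads are discarded but tallied so
that assigned + unassigned always equals the input.

Count tables are TSV with an ``sgrna_id`` index column and replicate columns
labelled ``condition:replicate``.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .scoring import condition_of
from .targets import reverse_complement

BARCODE_LEN = 12


def _read_seq(read) -> str:
    return str(read.seq).upper() if hasattr(read, "seq") else str(read).upper()


def demultiplex(
    reads: Iterable,
    barcode_map: Mapping[str, str],
    offset: int = 0,
    max_mismatch: int = 0,
) -> tuple[dict[str, list], int]:
    """Assign reads to replicates by their barcode at a fixed offset.

    Returns (replicate -> reads, n_unassigned).  Each read goes to at most
    one replicate; with ``max_mismatch`` > 0 a read is assigned only when a
    single barcode is within tolerance.  ``barcode_map`` may be a mapping or
    an iterable of (barcode, label) pairs; duplicate barcodes are rejected.
    """
    if not isinstance(barcode_map, Mapping):
        pairs = list(barcode_map)
        barcodes_seen = [b for b, _ in pairs]
        if len(set(barcodes_seen)) != len(barcodes_seen):
            raise ValueError("duplicate barcodes in map")
        barcode_map = dict(pairs)
    barcodes = list(barcode_map)
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in map")
    if any(len(b) != BARCODE_LEN for b in barcodes):
        raise ValueError(f"barcodes must be {BARCODE_LEN}-mers")
    exact = {b.upper(): lab for b, lab in barcode_map.items()}
    out: dict[str, list] = {lab: [] for lab in barcode_map.values()}
    unassigned = 0
    for read in reads:
        seq = _read_seq(read)
        bc = seq[offset:offset + BARCODE_LEN]
        if max_mismatch == 0:
            lab = exact.get(bc)
        else:
            hits = [lab for b, lab in exact.items()
                    if sum(x != y for x, y in zip(b, bc)) <= max_mismatch]
            lab = hits[0] if len(hits) == 1 else None
        if lab is None:
            unassigned += 1
        else:
            out[lab].append(read)
    return out, unassigned


def count_sgrnas(reads: Iterable, pool: Sequence[str]) -> tuple[pd.Series, dict]:
    """Count exact spacer occurrences in reads (either orientation).

    A read increments exactly one spacer; reads matching no spacer or more
    than one distinct spacer are discarded and tallied.
    """
    pool = [s.upper() for s in pool]
    if not pool:
        raise ValueError("empty spacer pool")
    if len(set(pool)) != len(pool):
        raise ValueError("pool spacers must be unique")
    counts = dict.fromkeys(pool, 0)
    stats = {"assigned": 0, "unmatched": 0, "ambiguous": 0}
    for read in reads:
        seq = _read_seq(read)
        both = seq + "#" + reverse_complement(seq)
        hits = [s for s in pool if s in both]
        if len(hits) == 1:
            counts[hits[0]] += 1
            stats["assigned"] += 1
        elif not hits:
            stats["unmatched"] += 1
        else:
            stats["ambiguous"] += 1
    return pd.Series(counts, name="count"), stats


def read_fastx(path, fmt: str | None = None) -> list:
    """Load merged reads from FASTA or FASTQ (format inferred from suffix)."""
    if fmt is None:
        p = str(path).lower()
        fmt = "fastq" if p.endswith(("fastq", "fq")) else "fasta"
    return list(SeqIO.parse(str(path), fmt))


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    if (table.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if table.index.duplicated().any():
        raise ValueError("duplicate sgrna_id rows")
    conds = {condition_of(c) for c in table.columns}
    if conds != {"control", "experimental"}:
        raise ValueError("need >= 1 replicate per condition "
                         f"(found conditions: {sorted(conds)})")
    return table


def write_count_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="sgrna_id")


def read_count_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="sgrna_id")
    return validate_count_table(table.astype(int))
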