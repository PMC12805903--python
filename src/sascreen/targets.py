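"""PAM-site scanning, target-context extraction, and sequence-based curation.

SaCas9 requires a 5'-NNGRRN-3' protospacer adjacent motif (PAM) immediately
3' of a 21- or 22-nt protospacer.  This module scans genomes/plasmids on both
strands for PAM matches, extracts the protospacer together with upstream
(PAM-distal) and downstream (PAM-proximal, positions [+1], [+2], ...) flanks,
counts near-matches of a spacer elsewhere in a genome, and applies the count-
and off-target-based curation filters used when preparing pooled-screen data
for modelling.

Coordinates are 0-based half-open on the forward strand of the contig.  For
minus-strand sites all stored sequences are reverse-complemented so that the
PAM always reads 5'->3' downstream of the spacer.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

DEFAULT_PAM = "NNGRRN"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC nucleotide pattern into a regex over {A,C,G,T}."""
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def matches_iupac(seq: str, pattern: str) -> bool:
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC[p] for b, p in zip(seq.upper(), pattern.upper()))


@dataclass(frozen=True)
class TargetSite:
    """One sgRNA target locus: spacer + PAM + flanking context.

    ``pam`` positions are numbered 1..6; ``downstream_flank`` holds positions
    [+1], [+2], ... 3' of the PAM; ``upstream_flank`` is PAM-distal sequence
    5' of the spacer.  On strand '-' every sequence field is the reverse
    complement of the forward-strand genome so the site always reads
    upstream-spacer-PAM-downstream in its own 5'->3' orientation.
    """

    contig: str
    strand: str
    spacer_start: int
    spacer_end: int
    spacer: str
    pam: str
    upstream_flank: str = ""
    downstream_flank: str = ""
    sgrna_id: str = field(default="", compare=False)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.pam) != 6:
            raise ValueError("PAM must be 6 nt")

    @property
    def context(self) -> str:
        """upstream + spacer + PAM + downstream in site orientation."""
        return self.upstream_flank + self.spacer + self.pam + self.downstream_flank

    def window(self, upstream_nt: int, downstream_nt: int) -> str:
        """Spacer plus ``upstream_nt`` 5' context and ``downstream_nt`` 3' context.

        ``downstream_nt`` counts the PAM first: downstream_nt=6 is spacer+PAM,
        downstream_nt=8 is spacer+PAM+[+1][+2].
        """
        if upstream_nt > len(self.upstream_flank):
            raise ValueError(
                f"{self.sgrna_id or self.spacer}: only "
                f"{len(self.upstream_flank)} nt upstream flank available"
            )
        down = self.pam + self.downstream_flank
        if downstream_nt > len(down):
            raise ValueError(
                f"{self.sgrna_id or self.spacer}: only {len(down)} nt "
                "downstream context available"
            )
        up = self.upstream_flank[len(self.upstream_flank) - upstream_nt:] if upstream_nt else ""
        return up + self.spacer + down[:downstream_nt]


def scan_pam_sites(
    genome: str,
    contig: str = "contig",
    pam_pattern: str = DEFAULT_PAM,
    spacer_len: int = 21,
    flank_up: int = 10,
    flank_down: int = 10,
) -> list[TargetSite]:
    """Find every protospacer adjacent to a PAM match on both strands.

    Only sites whose full window (upstream flank + spacer + PAM + downstream
    flank) lies inside the contig are returned; overlapping matches are all
    reported.  Sites are sorted by (contig, spacer_start, strand).  Windows
    containing non-ACGT characters are skipped with a warning.
    """
    if spacer_len not in (21, 22):
        raise ValueError(f"spacer_len must be 21 or 22, got {spacer_len}")
    pat = iupac_regex(pam_pattern)
    genome = genome.upper()
    pam_len = len(pam_pattern)
    sites: list[TargetSite] = []
    n_skipped = 0

    for strand, seq in (("+", genome), ("-", reverse_complement(genome))):
        L = len(seq)
        # overlapping matches via manual restart
        pos = 0
        while True:
            m = pat.search(seq, pos)
            if m is None:
                break
            p = m.start()
            pos = p + 1
            win_start = p - spacer_len - flank_up
            win_end = p + pam_len + flank_down
            if win_start < 0 or win_end > L:
                continue
            window = seq[win_start:win_end]
            if not set(window) <= set("ACGT"):
                n_skipped += 1
                continue
            spacer = seq[p - spacer_len:p]
            pam = seq[p:p + pam_len]
            up = seq[win_start:p - spacer_len]
            down = seq[p + pam_len:win_end]
            if strand == "+":
                s0, s1 = p - spacer_len, p
            else:  # map local (revcomp) coords back to forward strand
                s0, s1 = L - p, L - (p - spacer_len)
            sites.append(TargetSite(
                contig=contig, strand=strand,
                spacer_start=s0, spacer_end=s1,
                spacer=spacer, pam=pam,
                upstream_flank=up, downstream_flank=down,
            ))
    if n_skipped:
        warnings.warn(f"{n_skipped} candidate sites skipped (ambiguous bases)")
    sites.sort(key=lambda s: (s.contig, s.spacer_start, s.strand))
    return [
        TargetSite(**{**site.__dict__, "sgrna_id": f"{contig}_{i:05d}"})
        for i, site in enumerate(sites)
    ]


_BASE2INT = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE2INT[b] for b in seq), dtype=np.int8, count=len(seq))
    except KeyError as e:
        raise ValueError(f"non-ACGT character {e.args[0]!r} in sequence") from None


def hamming_matches(
    query: str,
    genome: str,
    max_mismatch: int = 0,
    pam_pattern: str | None = None,
) -> int:
    """Count loci on both strands within ``max_mismatch`` of the query spacer.

    The Hamming distance is computed over the spacer only.  If ``pam_pattern``
    is given, a locus only counts when the sequence immediately 3' of the
    spacer matches the pattern (off-target cleavage requires a PAM).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    q = _encode(query.upper())
    genome = genome.upper()
    if len(query) > len(genome):
        raise ValueError("query longer than genome")
    total = 0
    pam_re = iupac_regex(pam_pattern) if pam_pattern else None
    for seq in (genome, reverse_complement(genome)):
        g = _encode(seq) if set(seq) <= set("ACGT") else None
        if g is None:
            raise ValueError("genome contains non-ACGT characters")
        windows = np.lib.stride_tricks.sliding_window_view(g, len(q))
        mm = (windows != q).sum(axis=1)
        hits = np.flatnonzero(mm <= max_mismatch)
        if pam_re is None:
            total += len(hits)
        else:
            plen = len(pam_pattern)
            for h in hits:
                pam = seq[h + len(q): h + len(q) + plen]
                if len(pam) == plen and pam_re.fullmatch(pam):
                    total += 1
    return total


def curate_sites(
    sites: Sequence[TargetSite],
    counts: pd.DataFrame,
    control_columns: Sequence[str],
    host_genome: str | None = None,
    offtarget_genome: str | None = None,
    min_control_count: int = 20,
    max_mismatch: int = 3,
    mode: str = "enrichment",
    pam_pattern: str = DEFAULT_PAM,
) -> tuple[list[TargetSite], pd.DataFrame]:
    """Apply the count- and off-target-based curation filters.

    Removes sgRNAs that (a) have any control-condition replicate count at or
    below ``min_control_count`` (inclusive boundary: "20 or fewer"),
    (b) exactly match the off-target genome anywhere (both strands), or
    (c) for depletion screens, match the host genome with ``max_mismatch`` or
    fewer mismatches at loci other than the intended target.  Returns the
    surviving sites and an exclusion log with one row per removal.
    """
    by_id = {s.sgrna_id: s for s in sites}
    orphans = [i for i in counts.index if i not in by_id]
    if orphans:
        raise ValueError(f"count rows without matching sites: {orphans[:10]}")

    log: list[dict] = []
    removed: set[str] = set()
    for sid, site in by_id.items():
        if sid in counts.index:
            ctrl = counts.loc[sid, list(control_columns)]
            if (ctrl <= min_control_count).any():
                log.append({"sgrna_id": sid, "rule": "low_control_count",
                            "detail": f"min control count {int(ctrl.min())}"})
                removed.add(sid)
                continue
        if offtarget_genome is not None:
            if hamming_matches(site.spacer, offtarget_genome, 0) > 0:
                log.append({"sgrna_id": sid, "rule": "offtarget_exact_match",
                            "detail": "exact spacer match in off-target genome"})
                removed.add(sid)
                continue
        if mode == "depletion" and host_genome is not None:
            # intended target counts as one locus; any additional near-match removes
            n = hamming_matches(site.spacer, host_genome, max_mismatch,
                                pam_pattern=pam_pattern)
            if n > 1:
                log.append({"sgrna_id": sid, "rule": "host_near_match",
                            "detail": f"{n - 1} additional loci with <={max_mismatch} mismatches"})
                removed.add(sid)
    kept = [s for s in sites if s.sgrna_id not in removed]
    return kept, pd.DataFrame(log, columns=["sgrna_id", "rule", "detail"])


def sites_to_frame(sites: Iterable[TargetSite]) -> pd.DataFrame:
    """Tabulate sites (one row each) for TSV export."""
    return pd.DataFrame([{
        "sgrna_id": s.sgrna_id, "contig": s.contig, "strand": s.strand,
        "spacer_start": s.spacer_start, "spacer_end": s.spacer_end,
        "spacer": s.spacer, "pam": s.pam,
        "upstream_flank": s.upstream_flank, "downstream_flank": s.downstream_flank,
    } for s in sites])


def frame_to_sites(df: pd.DataFrame) -> list[TargetSite]:
    return [TargetSite(
        contig=r.contig, strand=r.strand,
        spacer_start=int(r.spacer_start), spacer_end=int(r.spacer_end),
        spacer=r.spacer, pam=r.pam,
        upstream_flank="" if pd.isna(r.upstream_flank) else r.upstream_flank,
        downstream_flank="" if pd.isna(r.downstream_flank) else r.downstream_flank,
        sgrna_id=r.sgrna_id,
    ) for r in df.itertuples()]


def sites_to_bed(sites: Iterable[TargetSite]) -> pd.DataFrame:
    """BED6 frame of spacer intervals (name = sgrna_id)."""
    return pd.DataFrame([{
        "chrom": s.contig, "chromStart": s.spacer_start, "chromEnd": s.spacer_end,
        "name": s.sgrna_id, "score": 0, "strand": s.strand,
    } for s in sites])
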