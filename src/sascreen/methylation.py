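"""GATC adenine-methylation annotation of sgRNA target sites.

In *E. coli* and relatives the Dam methyltransferase adds m6A to the adenine
of GATC on both strands of the palindrome.  This module parses bedMethyl
modification-call tables (downstream of base-calling), decides whether a
motif occurrence is methylated under a fraction-modified cutoff (default
75%, inclusive), locates GATC occurrences relative to each sgRNA's PAM, and
classifies sites into the categories used to associate methylation with
activity:

* ``gatc_pam_methylated`` — GATC spans PAM positions 4-6 and flank [+1]
  (PAM = NNGGAT, [+1] = C) and is methylated;
* ``gatc_single_change`` — one substitution away from GATC at that register;
* ``crrna_methylation_only`` — methylated adenines only within the spacer;
* ``no_methylation`` — no methylated call in spacer, PAM or [+1][+2] flank;
* ``other`` — anything else (e.g. methylation elsewhere in the PAM window).

Positions are 0-based; a missing call at an adenine is treated as
unmethylated (conservative for penalty detection) and counted separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .targets import TargetSite

MOD_CODES = {
    "a": "m6A", "m": "m5C", "21839": "m4C",
    "m6A": "m6A", "m5C": "m5C", "m4C": "m4C",
}

CATEGORIES = (
    "gatc_pam_methylated",
    "gatc_single_change",
    "crrna_methylation_only",
    "no_methylation",
    "other",
)


@dataclass(frozen=True)
class MethylationCall:
    contig: str
    position: int  # 0-based
    strand: str
    mod_code: str
    fraction_modified: float
    coverage: int

    def __post_init__(self):
        if not 0.0 <= self.fraction_modified <= 1.0:
            raise ValueError("fraction_modified must be in [0, 1]")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")


def read_bedmethyl(path) -> list[MethylationCall]:
    """Parse a bedMethyl table (9+ columns, percent-modified dialect).

    Columns: chrom, start, end, mod code, score, strand, thickStart,
    thickEnd, color, [valid coverage, percent modified, ...].  When the
    coverage/percent columns are absent the score column is used as coverage
    and percent is taken from column 5 onward heuristics fail -> malformed.
    Malformed lines are reported with their line numbers; unknown
    modification codes are skipped with a warning.
    """
    calls: list[MethylationCall] = []
    bad: list[int] = []
    unknown: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 9:
                bad.append(lineno)
                continue
            try:
                code = f[3]
                if code not in MOD_CODES:
                    unknown.add(code)
                    continue
                if len(f) >= 11:
                    coverage, percent = int(f[9]), float(f[10])
                else:
                    coverage, percent = int(f[4]), float(f[4])
                calls.append(MethylationCall(
                    contig=f[0], position=int(f[1]), strand=f[5],
                    mod_code=MOD_CODES[code],
                    fraction_modified=percent / 100.0,
                    coverage=coverage,
                ))
            except (ValueError, IndexError):
                bad.append(lineno)
    if bad:
        warnings.warn(f"rejected {len(bad)} malformed bedMethyl lines: {bad[:10]}")
    if unknown:
        warnings.warn(f"skipped unknown modification codes: {sorted(unknown)}")
    return calls


def write_bedmethyl(calls: Iterable[MethylationCall], path) -> None:
    code_of = {"m6A": "a", "m5C": "m", "m4C": "21839"}
    with open(path, "w") as fh:
        for c in calls:
            pct = c.fraction_modified * 100.0
            fh.write("\t".join(map(str, [
                c.contig, c.position, c.position + 1, code_of[c.mod_code],
                c.coverage, c.strand, c.position, c.position + 1, "255,0,0",
                c.coverage, f"{pct:.2f}",
            ])) + "\n")


def _call_index(calls: Iterable[MethylationCall]) -> Mapping:
    return {(c.contig, c.position, c.strand, c.mod_code): c for c in calls}


def call_motif_methylated(
    fraction_plus: float | None,
    fraction_minus: float | None,
    cutoff: float = 0.75,
) -> dict:
    """Methylation status of one palindromic motif occurrence.

    A strand is methylated iff its fraction-modified is at or above the
    cutoff (inclusive); a missing call counts as unmethylated.  The combined
    status requires both strands.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    plus = fraction_plus is not None and fraction_plus >= cutoff
    minus = fraction_minus is not None and fraction_minus >= cutoff
    return {"plus": plus, "minus": minus, "both": plus and minus,
            "n_missing": (fraction_plus is None) + (fraction_minus is None)}


def _gatc_occurrences(site: TargetSite) -> list[int]:
    """Local offsets (0 = PAM position 1) of GATC starts overlapping
    PAM[1..6] or flanks [+1][+2]."""
    window = site.pam + site.downstream_flank[:2]
    return [i for i in range(len(window) - 3)
            if window[i:i + 4] == "GATC" and i < 8]


def _local_to_genomic(site: TargetSite, offset: int) -> int:
    """Forward-strand start of a 4-mer at local offset from PAM position 1."""
    if site.strand == "+":
        return site.spacer_end + offset
    return site.spacer_start - offset - 4


def _gatc_adenine_positions(site: TargetSite, offset: int) -> tuple[int, int]:
    """Genomic positions of the two adenines of a GATC occurrence
    (plus-strand A, minus-strand A); GATC is its own reverse complement."""
    g = _local_to_genomic(site, offset)
    return g + 1, g + 2


def gatc_register_status(site: TargetSite) -> str:
    """Relation of the headline register (PAM 4-6 + [+1]) to GATC."""
    if len(site.downstream_flank) < 1:
        raise ValueError(f"{site.sgrna_id}: [+1] flank required")
    register = site.pam[3:6] + site.downstream_flank[0]
    dist = sum(a != b for a, b in zip(register, "GATC"))
    if dist == 0:
        return "gatc"
    if dist == 1:
        return "single_change"
    return "other"


@dataclass
class PamMethylAnnotation:
    sgrna_id: str
    category: str
    gatc_offsets: tuple[int, ...]  # local offsets from PAM position 1
    pam_register: str  # gatc | single_change | other
    methylated_both: bool
    methylated_plus: bool
    methylated_minus: bool
    n_missing_calls: int
    cytosine_methylated_pam12: bool


def annotate_sites(
    sites: Sequence[TargetSite],
    calls: Sequence[MethylationCall],
    cutoff: float = 0.75,
) -> list[PamMethylAnnotation]:
    """Classify each site's methylation context relative to its PAM.

    Categories are mutually exclusive and exhaustive; precedence is
    methylated GATC-in-PAM > single-nucleotide change from GATC > spacer-only
    methylation > no methylation > other.  Cytosine methylation (m5C/m4C) at
    PAM positions 1-2 is annotated separately and does not enter the
    category.
    """
    m6a_by_contig: dict[str, set[int]] = {}
    cyt_by_contig: dict[str, set[int]] = {}
    for c in calls:
        if c.fraction_modified >= cutoff:
            if c.mod_code == "m6A":
                m6a_by_contig.setdefault(c.contig, set()).add(c.position)
            else:
                cyt_by_contig.setdefault(c.contig, set()).add(c.position)
    call_idx = _call_index(calls)
    out: list[PamMethylAnnotation] = []
    for site in sites:
        m6a = m6a_by_contig.get(site.contig, set())
        register = gatc_register_status(site)
        offsets = tuple(_gatc_occurrences(site))

        meth_plus = meth_minus = False
        n_missing = 0
        if register == "gatc":
            a_plus, a_minus = _gatc_adenine_positions(site, 3)
            cp = call_idx.get((site.contig, a_plus, "+", "m6A"))
            cm = call_idx.get((site.contig, a_minus, "-", "m6A"))
            status = call_motif_methylated(
                cp.fraction_modified if cp else None,
                cm.fraction_modified if cm else None,
                cutoff,
            )
            meth_plus, meth_minus = status["plus"], status["minus"]
            n_missing = status["n_missing"]

        # genomic extent of spacer vs PAM+[+1][+2] window
        if site.strand == "+":
            spacer_iv = (site.spacer_start, site.spacer_end)
            pam_iv = (site.spacer_end, site.spacer_end + 8)
        else:
            spacer_iv = (site.spacer_start, site.spacer_end)
            pam_iv = (site.spacer_start - 8, site.spacer_start)
        in_spacer = any(p in m6a for p in range(*spacer_iv))
        in_pam = any(p in m6a for p in range(*pam_iv))

        if register == "gatc" and meth_plus and meth_minus:
            category = "gatc_pam_methylated"
        elif register == "single_change":
            category = "gatc_single_change"
        elif in_spacer and not in_pam:
            category = "crrna_methylation_only"
        elif not in_spacer and not in_pam:
            category = "no_methylation"
        else:
            category = "other"

        # cytosine methylation at PAM positions 1-2
        if site.strand == "+":
            pam12 = {site.spacer_end, site.spacer_end + 1}
        else:
            pam12 = {site.spacer_start - 1, site.spacer_start - 2}
        cyt = cyt_by_contig.get(site.contig, set())
        out.append(PamMethylAnnotation(
            sgrna_id=site.sgrna_id, category=category,
            gatc_offsets=offsets, pam_register=register,
            methylated_both=meth_plus and meth_minus,
            methylated_plus=meth_plus, methylated_minus=meth_minus,
            n_missing_calls=n_missing,
            cytosine_methylated_pam12=bool(pam12 & cyt),
        ))
    return out


def methylation_activity_summary(
    annotations: Sequence[PamMethylAnnotation],
    activities: Mapping[str, float],
) -> pd.DataFrame:
    """Per-category activity summaries plus contrasts against reference sets.

    For each category reports n, mean, median and quartiles of the activity
    score (log2 effect-size units), the contrast of the category mean against
    the all-sites mean, and the corresponding linear-scale fold change
    2**(mean difference).  Empty categories appear with n = 0.
    """
    if not annotations:
        raise ValueError("no annotations")
    act = pd.Series({a.sgrna_id: activities[a.sgrna_id] for a in annotations},
                    dtype=float)
    cat = pd.Series({a.sgrna_id: a.category for a in annotations})
    overall = act.mean()
    rows = []
    for name in CATEGORIES:
        vals = act[cat == name]
        row = {"category": name, "n": int(len(vals))}
        if len(vals):
            row.update({
                "mean": vals.mean(), "median": vals.median(),
                "q25": vals.quantile(0.25), "q75": vals.quantile(0.75),
                "mean_vs_all": vals.mean() - overall,
                "fold_vs_all": float(2.0 ** (vals.mean() - overall)),
            })
        rows.append(row)
    rows.append({"category": "all_sites", "n": int(len(act)),
                 "mean": overall, "median": act.median(),
                 "q25": act.quantile(0.25), "q75": act.quantile(0.75),
                 "mean_vs_all": 0.0, "fold_vs_all": 1.0})
    return pd.DataFrame(rows).set_index("category")


def matched_register_contrast(
    sites: Sequence[TargetSite],
    annotations: Sequence[PamMethylAnnotation],
    activities: Mapping[str, float],
) -> float:
    """Methylated-GATC-PAM mean minus the mean of sequence-matched controls.

    Controls share the PAM6 = T and [+1] = C composition (so sequence bonuses
    cancel) but do not carry a GATC at the PAM 4-6/[+1] register; the
    contrast therefore isolates the methylation penalty itself rather than
    the penalty confounded with base-composition effects.
    """
    ann = {a.sgrna_id: a for a in annotations}
    meth, ctrl = [], []
    for s in sites:
        a = ann.get(s.sgrna_id)
        if a is None or len(s.downstream_flank) < 1:
            continue
        same_comp = s.pam[5] == "T" and s.downstream_flank[0] == "C"
        if a.category == "gatc_pam_methylated":
            meth.append(activities[s.sgrna_id])
        elif same_comp and a.pam_register != "gatc":
            ctrl.append(activities[s.sgrna_id])
    if not meth or not ctrl:
        raise ValueError("matched contrast requires both groups populated")
    return float(np.mean(meth) - np.mean(ctrl))
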