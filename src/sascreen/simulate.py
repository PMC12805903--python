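"""Synthetic screen generator with planted, recoverable effects.

Every downstream stage of the pipeline (counting, compositional scoring,
sequence modelling, motif/methylation association, kinetics fitting) is
testable without external data by planting a known ground truth:

* a uniform-composition random genome carrying NNGRRN PAM sites;
* an additive log2 activity model over site sequence features — a bonus for
  T at PAM position 6, a bonus for a pyrimidine at flank [+1], a smaller
  bonus for T at [+2], and a penalty when a methylated GATC spans PAM
  positions 4-6 and [+1] (default -log2(10), i.e. ten-fold) — plus Gaussian
  noise on the log2 scale;
* screen read counts in which a guide's expected abundance change is
  exponential in activity x generations (log-linear growth, default 3
  effective doublings), sampled multinomially per replicate;
* per-strand m6A fraction-modified tracks in which GATC motifs are
  methylated (the Dam pattern), written/read as bedMethyl;
* exponential plasmid-decay time courses for kinetics fitting.

The generator emulates sampling noise only: no sequencing-error or PCR-bias
model, and no replicate overdispersion beyond the multinomial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylation import MethylationCall, call_motif_methylated, gatc_register_status
from .targets import TargetSite, iupac_regex, reverse_complement, scan_pam_sites


@dataclass
class EffectModel:
    """Additive log2 ground-truth activity model for planted effects."""

    baseline: float = 0.0
    pam6_T_bonus: float = 1.0
    plus1_pyrimidine_bonus: float = 0.5
    plus2_T_bonus: float = 0.25
    gatc_pam_penalty: float = -np.log2(10.0)  # ~10-fold reduction
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for f in (self.baseline, self.pam6_T_bonus, self.plus1_pyrimidine_bonus,
                  self.plus2_T_bonus, self.gatc_pam_penalty):
            if not np.isfinite(f):
                raise ValueError("all effects must be finite")


@dataclass
class ScreenDesign:
    """Shape of a pooled enrichment or depletion screen."""

    mode: str = "depletion"
    n_replicates_per_condition: int = 3
    read_depth: int = 1_000_000
    generations: float = 3.0

    def __post_init__(self):
        if self.mode not in ("enrichment", "depletion"):
            raise ValueError("mode must be enrichment or depletion")
        if self.n_replicates_per_condition < 1:
            raise ValueError("need >= 1 replicate per condition")
        if self.read_depth <= 0 or self.generations <= 0:
            raise ValueError("read_depth and generations must be positive")


def simulate_genome(length_bp: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """Random genome of exact length with the given expected GC content."""
    if length_bp < 100:
        raise ValueError("length_bp must be >= 100")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at, gc = (1.0 - gc_fraction) / 2.0, gc_fraction / 2.0
    return "".join(rng.choice(list("ACGT"), size=length_bp, p=[at, gc, gc, at]))


def _site_deterministic_activity(
    site: TargetSite,
    model: EffectModel,
    methylated_registers: set[str],
) -> float:
    if len(site.downstream_flank) < 2:
        raise ValueError(f"{site.sgrna_id}: site needs >= 2 nt downstream flank")
    a = model.baseline
    if site.pam[5] == "T":
        a += model.pam6_T_bonus
    if site.downstream_flank[0] in "CT":
        a += model.plus1_pyrimidine_bonus
    if site.downstream_flank[1] == "T":
        a += model.plus2_T_bonus
    if gatc_register_status(site) == "gatc" and site.sgrna_id in methylated_registers:
        a += model.gatc_pam_penalty
    return a


def _methylated_register_ids(
    sites: Sequence[TargetSite],
    methylome: Sequence[MethylationCall],
    cutoff: float = 0.75,
) -> set[str]:
    """sgRNA ids whose PAM 4-6/[+1] GATC is methylated on both strands."""
    frac = {(c.contig, c.position, c.strand): c.fraction_modified
            for c in methylome if c.mod_code == "m6A"}
    out = set()
    for s in sites:
        if len(s.downstream_flank) < 1 or gatc_register_status(s) != "gatc":
            continue
        g = s.spacer_end + 3 if s.strand == "+" else s.spacer_start - 7
        status = call_motif_methylated(
            frac.get((s.contig, g + 1, "+")), frac.get((s.contig, g + 2, "-")),
            cutoff,
        )
        if status["both"]:
            out.add(s.sgrna_id)
    return out


def assign_true_activity(
    sites: Sequence[TargetSite],
    model: EffectModel,
    methylome: Sequence[MethylationCall] = (),
    cutoff: float = 0.75,
) -> dict[str, float]:
    """Planted true log2 activity per sgRNA: additive effects plus noise.

    The GATC penalty applies only when the GATC at PAM positions 4-6/[+1]
    is methylated on both strands under the fraction-modified cutoff.
    """
    rng = np.random.default_rng(model.seed)
    methylated = _methylated_register_ids(sites, methylome, cutoff)
    truth = {}
    for s in sites:
        det = _site_deterministic_activity(s, model, methylated)
        noise = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
        truth[s.sgrna_id] = det + noise
    return truth


def simulate_screen_counts(
    truth: Mapping[str, float],
    design: ScreenDesign,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial count table from planted activities.

    Control replicates draw from uniform expected proportions; experimental
    replicates from proportions scaled by 2**(s * generations * activity)
    with s = +1 for enrichment and -1 for depletion.  Columns are labelled
    'condition:replicate'.
    """
    if not truth:
        raise ValueError("empty truth map")
    ids = list(truth)
    a = np.array([truth[i] for i in ids], dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite activities")
    rng = np.random.default_rng(seed)
    n = len(ids)
    sgn = 1.0 if design.mode == "enrichment" else -1.0
    w = np.exp2(sgn * design.generations * a)
    p_ctrl = np.full(n, 1.0 / n)
    p_expt = w / w.sum()
    cols = {}
    for r in range(1, design.n_replicates_per_condition + 1):
        cols[f"control:{r}"] = rng.multinomial(design.read_depth, p_ctrl)
    for r in range(1, design.n_replicates_per_condition + 1):
        cols[f"experimental:{r}"] = rng.multinomial(design.read_depth, p_expt)
    return pd.DataFrame(cols, index=pd.Index(ids, name="sgrna_id"))


def simulate_methylome(
    genome: str,
    motif: str = "GATC",
    fraction_modified: float = 0.98,
    mod_code: str = "m6A",
    mod_offset: int = 1,
    contig: str = "contig",
    coverage: int = 50,
    seed: int = 0,
) -> list[MethylationCall]:
    """One modification call per motif occurrence per strand.

    ``mod_offset`` is the index of the modified base within the motif (1 for
    the A of GATC).  For palindromic motifs like GATC both strands of each
    occurrence yield a call, emulating Dam which methylates both adenines.
    Coverage is Poisson-distributed around the given mean.
    """
    if not 0.0 <= fraction_modified <= 1.0:
        raise ValueError("fraction_modified must be in [0, 1]")
    pat = iupac_regex(motif)
    genome = genome.upper()
    L = len(genome)
    rng = np.random.default_rng(seed)
    calls = []

    def emit(position, strand):
        calls.append(MethylationCall(
            contig=contig, position=position, strand=strand,
            mod_code=mod_code, fraction_modified=fraction_modified,
            coverage=int(max(1, rng.poisson(coverage))),
        ))

    pos = 0
    while (m := pat.search(genome, pos)) is not None:
        emit(m.start() + mod_offset, "+")
        pos = m.start() + 1
    rc = reverse_complement(genome)
    pos = 0
    while (m := pat.search(rc, pos)) is not None:
        emit(L - 1 - (m.start() + mod_offset), "-")
        pos = m.start() + 1
    calls.sort(key=lambda c: (c.position, c.strand))
    return calls


def simulate_decay_series(
    k_true: float,
    s0: float = 1.0,
    timepoints: Sequence[float] = (0, 2, 4, 8, 16, 32),
    noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential substrate-disappearance time course with Gaussian noise.

    Returns a frame with columns time_min and fraction; values are clipped
    at zero, matching gel-quantified supercoiled-fraction data.
    """
    t = np.asarray(timepoints, dtype=float)
    if t.size == 0:
        raise ValueError("empty timepoints")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be non-negative and increasing")
    if k_true < 0:
        raise ValueError("k_true must be >= 0")
    rng = np.random.default_rng(seed)
    vals = s0 * np.exp(-k_true * t)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=t.size)
    return pd.DataFrame({"time_min": t, "fraction": np.clip(vals, 0.0, None)})


@dataclass
class SyntheticScreen:
    """Bundle of one simulated screen: genome, sites, methylome, truth, counts."""

    genome: str
    sites: list[TargetSite]
    methylome: list[MethylationCall]
    truth: dict[str, float]
    counts: pd.DataFrame
    design: ScreenDesign
    effects: EffectModel


def simulate_screen(
    n_sites: int = 5000,
    genome_bp: int = 236_000,
    effects: EffectModel | None = None,
    design: ScreenDesign | None = None,
    seed: int = 0,
    methylated: bool = True,
) -> SyntheticScreen:
    """End-to-end synthetic screen: genome -> PAM sites -> methylome ->
    planted activities -> multinomial counts.

    Sites are sampled without replacement from all full-window NNGRRN sites
    in the genome (the genome length defaults to the scale of a bacterial
    contig, which carries far more candidate sites than are drawn).
    """
    effects = effects or EffectModel(seed=seed + 1)
    design = design or ScreenDesign()
    genome = simulate_genome(genome_bp, 0.5, seed=seed)
    sites = scan_pam_sites(genome, contig="synth", flank_up=10, flank_down=10)
    if len(sites) < n_sites:
        raise ValueError(f"genome yields only {len(sites)} sites (< {n_sites})")
    rng = np.random.default_rng(seed + 2)
    pick = sorted(rng.choice(len(sites), size=n_sites, replace=False))
    sites = [sites[i] for i in pick]
    methylome = simulate_methylome(
        genome, "GATC", 0.98 if methylated else 0.0, contig="synth",
        seed=seed + 3,
    )
    truth = assign_true_activity(sites, effects, methylome)
    counts = simulate_screen_counts(truth, design, seed=seed + 4)
    return SyntheticScreen(genome=genome, sites=sites, methylome=methylome,
                           truth=truth, counts=counts, design=design,
                           effects=effects)
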