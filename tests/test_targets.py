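"""PAM scanning, near-match counting, and curation filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sascreen import simulate
from sascreen.targets import (IUPAC, curate_sites, hamming_matches,
                              reverse_complement, scan_pam_sites)

DNA = st.text(alphabet="ACGT", min_size=60, max_size=200)


def brute_force_scan(genome, pam="NNGRRN", spacer_len=21, flank_up=0, flank_down=0):
    """Independent oracle: character-class sliding window on both strands."""
    found = []
    for strand, seq in (("+", genome), ("-", reverse_complement(genome))):
        for p in range(len(seq) - len(pam) + 1):
            window = seq[p:p + len(pam)]
            if all(b in IUPAC[c] for b, c in zip(window, pam)):
                if p - spacer_len - flank_up >= 0 and p + len(pam) + flank_down <= len(seq):
                    found.append((strand, seq[p - spacer_len:p], window))
    return sorted(found)


def test_scan_matches_brute_force_on_random_sequences():
    rng = np.random.default_rng(3)
    for trial in range(8):
        genome = "".join(rng.choice(list("ACGT"), 2000))
        sites = scan_pam_sites(genome, flank_up=0, flank_down=0)
        got = sorted((s.strand, s.spacer, s.pam) for s in sites)
        assert got == brute_force_scan(genome)


def test_scan_single_planted_site():
    # a TTGAAT window is a valid NNGRRN PAM; no other match planted
    rng = np.random.default_rng(7)
    spacer = "".join(rng.choice(list("AC"), 21))  # AC-only: cannot host a G at pos 3
    genome = "CC" + spacer + "TTGAAT" + "CC"
    sites = [s for s in scan_pam_sites(genome, flank_up=0, flank_down=0)
             if s.strand == "+"]
    assert len(sites) == 1
    assert sites[0].pam == "TTGAAT"
    assert sites[0].spacer == spacer


def test_scan_rejects_non_R_at_position4():
    spacer = "A" * 21
    genome = spacer + "AAGCAT"  # position 4 = C violates R
    assert all(s.pam != "AAGCAT" for s in scan_pam_sites(genome, flank_up=0, flank_down=0))


def test_scan_rejects_bad_spacer_len():
    with pytest.raises(ValueError):
        scan_pam_sites("ACGT" * 20, spacer_len=20)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(DNA)
def test_scan_reverse_complement_mirror(genome):
    """Scanning a sequence and its reverse complement gives mirror site sets."""
    fwd = scan_pam_sites(genome, flank_up=2, flank_down=2)
    rev = scan_pam_sites(reverse_complement(genome), flank_up=2, flank_down=2)
    L = len(genome)
    fwd_keys = sorted((s.spacer, s.pam, s.upstream_flank, s.downstream_flank,
                       L - s.spacer_end, L - s.spacer_start,
                       "-" if s.strand == "+" else "+") for s in fwd)
    rev_keys = sorted((s.spacer, s.pam, s.upstream_flank, s.downstream_flank,
                       s.spacer_start, s.spacer_end, s.strand) for s in rev)
    assert fwd_keys == rev_keys


def test_nngrrn_density_on_uniform_dna():
    """Expected NNGRRN density is 1/16 per strand, 1/8 over both strands."""
    genome = simulate.simulate_genome(1_000_000, 0.5, seed=2)
    sites = scan_pam_sites(genome, flank_up=0, flank_down=0)
    density = len(sites) / len(genome)
    assert abs(density - 0.125) / 0.125 < 0.05


def brute_force_hamming(query, genome, max_mm):
    total = 0
    for seq in (genome, reverse_complement(genome)):
        for p in range(len(seq) - len(query) + 1):
            if sum(a != b for a, b in zip(query, seq[p:p + len(query)])) <= max_mm:
                total += 1
    return total


def test_hamming_exact_single_locus():
    rng = np.random.default_rng(5)
    genome = "".join(rng.choice(list("ACGT"), 400))
    query = genome[100:121]
    n = hamming_matches(query, genome, 0)
    assert n == brute_force_hamming(query, genome, 0) >= 1


def test_hamming_threshold_boundary():
    genome = "A" * 50
    query = "A" * 17 + "CCCC"  # 4 mismatches to every locus
    assert hamming_matches(query, genome, 3) == 0
    assert hamming_matches(query, genome, 4) > 0


def test_hamming_matches_brute_force_random():
    rng = np.random.default_rng(9)
    genome = "".join(rng.choice(list("ACGT"), 3000))
    for _ in range(40):
        start = rng.integers(0, 2979)
        query = list(genome[start:start + 21])
        for pos in rng.choice(21, size=rng.integers(0, 4), replace=False):
            query[pos] = "ACGT"[rng.integers(4)]
        query = "".join(query)
        for mm in (0, 2, 3):
            assert hamming_matches(query, genome, mm) == \
                brute_force_hamming(query, genome, mm)


def test_hamming_rejects_ambiguous_query():
    with pytest.raises(ValueError):
        hamming_matches("ACGTN", "ACGTACGT", 0)


@pytest.fixture
def curation_pool():
    genome = simulate.simulate_genome(20_000, 0.5, seed=21)
    sites = scan_pam_sites(genome, flank_up=4, flank_down=8)[:100]
    assert len(sites) == 100
    counts = pd.DataFrame(
        {"control:1": 100, "control:2": 100,
         "experimental:1": 50, "experimental:2": 50},
        index=pd.Index([s.sgrna_id for s in sites], name="sgrna_id"),
    )
    return genome, sites, counts


def test_curation_removes_planted_violations(curation_pool):
    """100 sgRNAs with 10 planted violations -> exactly 90 survive."""
    genome, sites, counts = curation_pool
    low = [s.sgrna_id for s in sites[:5]]
    counts.loc[low, "control:1"] = 20  # boundary: "20 or fewer" removed
    offtarget = "TTTT".join(s.spacer for s in sites[5:10]) + "A" * 50
    kept, log = curate_sites(sites, counts, ["control:1", "control:2"],
                             offtarget_genome=offtarget)
    assert len(kept) == 90
    assert sorted(log["rule"].value_counts().to_dict().items()) == [
        ("low_control_count", 5), ("offtarget_exact_match", 5)]


def test_curation_count_boundary_inclusive(curation_pool):
    genome, sites, counts = curation_pool
    counts.loc[sites[0].sgrna_id, ["control:1", "control:2"]] = [21, 25]
    counts.loc[sites[1].sgrna_id, ["control:1", "control:2"]] = [20, 400]
    kept, log = curate_sites(sites, counts, ["control:1", "control:2"])
    kept_ids = {s.sgrna_id for s in kept}
    assert sites[0].sgrna_id in kept_ids
    assert sites[1].sgrna_id not in kept_ids


def test_curation_idempotent(curation_pool):
    genome, sites, counts = curation_pool
    counts.iloc[:7, 0] = 3
    kept1, _ = curate_sites(sites, counts, ["control:1", "control:2"])
    kept2, log2 = curate_sites(kept1, counts.loc[[s.sgrna_id for s in kept1]],
                               ["control:1", "control:2"])
    assert [s.sgrna_id for s in kept1] == [s.sgrna_id for s in kept2]
    assert log2.empty


def test_curation_depletion_near_match_filter(curation_pool):
    """An sgRNA with a second <=3-mismatch PAM-adjacent locus is removed."""
    genome, sites, counts = curation_pool
    victim = sites[0]
    decoy = list(victim.spacer)
    decoy[0] = {"A": "C", "C": "A", "G": "T", "T": "G"}[decoy[0]]
    host = genome + "".join(decoy) + victim.pam + "AAAA"
    kept, log = curate_sites(sites, counts, ["control:1", "control:2"],
                             host_genome=host, mode="depletion")
    assert victim.sgrna_id not in {s.sgrna_id for s in kept}
    assert set(log["rule"]) == {"host_near_match"}


def test_curation_orphan_counts_error(curation_pool):
    genome, sites, counts = curation_pool
    counts.loc["ghost"] = 100
    with pytest.raises(ValueError, match="ghost"):
        curate_sites(sites, counts, ["control:1", "control:2"])
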