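"""Seed-and-extend assembly: filter fidelity, extension, failure modes."""

import numpy as np
import pytest

from igrescue.assembly import (
    AssemblyError,
    PoolRead,
    extend_contig,
    filter_vdj_reads,
    find_seeds,
    polish_contig,
    reconstruct_chain,
)
from igrescue.simulate import SeqRead, simulate_repertoire
from igrescue.alignment import revcomp

from conftest import single_clone_readset
from dp_oracle import oracle_filter_decision


def _pool(seqs):
    return [PoolRead(f"p{i}", s, "V", 1.0, "+") for i, s in enumerate(seqs)]


def _tile(seq, start, end, read_len, step):
    """Reads tiling [start, end) left to right."""
    out = []
    at = start
    while at < end:
        out.append(seq[at : min(at + read_len, end)])
        at += step
    return [s for s in out if len(s) >= 30]


# ---------------------------------------------------------------------------
# VDJ filter


def test_exact_germline_read_is_retained(germline):
    v = germline.alleles("V", "IGH")[0]
    reads = [SeqRead("a", v.nt_sequence[50:170])]
    pool = filter_vdj_reads(reads, germline)
    assert len(pool) == 1 and pool[0].seq == reads[0].seq


def test_quarter_mismatched_read_is_discarded(germline):
    v = germline.alleles("V", "IGH")[0]
    rng = np.random.default_rng(50)
    seq = list(v.nt_sequence[50:170])
    for i in rng.choice(len(seq), size=30, replace=False):  # 25% mismatches
        seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
    pool = filter_vdj_reads([SeqRead("a", "".join(seq))], germline)
    assert pool == []


def test_minus_strand_reads_are_flipped_to_coding(germline):
    v = germline.alleles("V", "IGH")[0]
    frag = v.nt_sequence[50:170]
    pool = filter_vdj_reads([SeqRead("a", revcomp(frag))], germline)
    assert pool[0].seq == frag and pool[0].strand == "-"


def test_filter_decisions_match_dp_oracle_near_threshold(germline):
    """Reads engineered around 80% identity: filter membership equals the
    brute-force DP decision read-by-read."""
    rng = np.random.default_rng(51)
    v_alleles = germline.alleles("V")
    segments = v_alleles + germline.alleles("J")
    reads = []
    for i in range(120):
        src = v_alleles[int(rng.integers(0, len(v_alleles)))]
        ln = int(rng.integers(60, 140))
        at = int(rng.integers(0, len(src.nt_sequence) - ln))
        seq = list(src.nt_sequence[at : at + ln])
        n_mut = int(rng.integers(int(0.12 * ln), int(0.30 * ln)))
        for p in rng.choice(ln, size=n_mut, replace=False):
            seq[p] = "ACGT"[int(rng.integers(0, 4))]
        s = "".join(seq)
        if rng.random() < 0.5:
            s = revcomp(s)
        reads.append(SeqRead(f"r{i}", s))
    pool_ids = {r.read_id for r in filter_vdj_reads(reads, germline)}
    for read in reads:
        expected = oracle_filter_decision(read.seq, segments)
        assert (read.read_id in pool_ids) == expected, read.read_id


def test_read_fraction_mode_uses_aligned_share_of_read(germline):
    v = germline.alleles("V", "IGH")[0]
    # 40 nt of V + 80 nt of junk: identity ~1 over the aligned part but
    # only 1/3 of the read aligns
    rng = np.random.default_rng(52)
    junk = "".join("ACGT"[i] for i in rng.integers(0, 4, size=80))
    read = SeqRead("a", v.nt_sequence[100:140] + junk)
    assert filter_vdj_reads([read], germline, mode="identity")
    assert not filter_vdj_reads([read], germline, mode="read_fraction")


# ---------------------------------------------------------------------------
# Seeding


def test_seeds_found_at_junction_coverage(germline):
    clone, reads = single_clone_readset(germline, seed=60, coverage=30)
    pool = filter_vdj_reads(reads, germline)
    seeds = find_seeds(pool, clone.junction_nt)
    assert seeds and seeds[0].exactness == "exact"
    # sorted by longest 5' flank
    flanks = [s.offset for s in seeds if s.exactness == "exact"]
    assert flanks == sorted(flanks, reverse=True)


def test_absent_junction_raises_no_seed_reads(germline):
    _, reads = single_clone_readset(germline, seed=61)
    pool = filter_vdj_reads(reads, germline)
    with pytest.raises(AssemblyError) as err:
        find_seeds(pool, "TGT" + "ACGATT" * 5 + "TGG")
    assert err.value.reason == "no_seed_reads"


def test_empty_pool_raises_no_vdj_reads(germline):
    with pytest.raises(AssemblyError) as err:
        find_seeds([], "TGTACGTGG")
    assert err.value.reason == "no_vdj_reads"


def test_seed_with_mutated_anchor_cys_is_excluded(germline):
    clone, _ = single_clone_readset(germline, seed=62)
    junction = clone.junction_nt
    t = clone.full_transcript_nt
    js = clone.junction_interval[0]
    read_ok = t[js - 30 : js + len(junction) + 20]
    broken = t[js - 30 : js] + "GCT" + t[js + 3 : js + len(junction) + 20]
    pool = _pool([read_ok, broken])
    seeds = find_seeds(pool, junction)
    assert {s.read_id for s in seeds} == {"p0"}
    # a seed whose junction matches but whose upstream YY motif is lost
    no_y = t[js - 30 : js - 6] + "GCAGCA" + t[js : js + len(junction) + 20]
    with pytest.raises(AssemblyError):
        find_seeds(_pool([no_y]), junction)


# ---------------------------------------------------------------------------
# Extension


def test_noiseless_tiling_recovers_sequence_and_reaches_v_start(germline):
    clone, reads = single_clone_readset(germline, seed=63, coverage=20)
    pool = filter_vdj_reads(reads, germline)
    chain = reconstruct_chain(pool, clone.junction_nt, germline,
                              locus="IGH", prefiltered=True)
    truth = clone.full_transcript_nt[
        clone.v_interval[0] : clone.junction_interval[1]
    ]
    assert chain.termination_reason == "v_start_reached"
    assert chain.contig_nt[: chain.junction_interval[1]] == truth
    assert chain.coverage.min() >= 1
    assert (chain.agreement[chain.coverage >= 2] >= 0.5).all()


def test_coverage_gap_stops_extension_at_gap_edge(germline):
    clone, _ = single_clone_readset(germline, seed=64)
    t = clone.full_transcript_nt
    js, je = clone.junction_interval
    gap_lo, gap_hi = js - 120, js - 80  # 40-nt hole upstream of the junction
    left = _tile(t, 0, gap_lo, 90, 25)
    # two staggered tilings so every position down to the gap edge has
    # coverage >= 2 (the vote minimum)
    right = _tile(t, gap_hi, je + 30, 90, 25) + _tile(t, gap_hi, je + 30, 90, 40)
    pool = _pool(right + left)
    seeds = find_seeds(pool, clone.junction_nt)
    seed_read = next(r for r in pool if r.read_id == seeds[0].read_id)
    res = extend_contig(seed_read.seq, pool, "5prime")
    assert res.termination == "no_overlap"
    # the contig 5' end sits exactly at the downstream edge of the gap
    assert res.contig == t[gap_hi : gap_hi + len(res.contig)]
    assert t.index(res.contig) == gap_hi


def test_equal_abundance_divergence_stops_as_ambiguous_branch(germline):
    clone, _ = single_clone_readset(germline, seed=65)
    t = clone.full_transcript_nt
    js, je = clone.junction_interval
    div = js - 100  # divergence point, upstream of the junction
    variant = t[:div] + ("A" if t[div] != "A" else "G") + t[div + 1 :]
    pool_a = _tile(t, div - 80, je + 20, 80, 20)
    pool_b = _tile(variant, div - 80, je + 20, 80, 20)
    pool = _pool(pool_a + pool_b)
    seeds = find_seeds(pool, clone.junction_nt)
    seed_read = next(r for r in pool if r.read_id == seeds[0].read_id)
    res = extend_contig(seed_read.seq, pool, "5prime")
    assert res.termination == "ambiguous_branch"
    # everything right of the divergence point was assembled; the
    # divergent column itself was not
    assert res.contig == t[div + 1 : div + 1 + len(res.contig)]


def test_enlarging_pool_never_shortens_contig(germline):
    clone, reads = single_clone_readset(germline, seed=66, coverage=12)
    pool = filter_vdj_reads(reads, germline)
    _, extra_reads = single_clone_readset(germline, seed=66, coverage=24)
    pool_big = filter_vdj_reads(extra_reads, germline)
    chain_small = reconstruct_chain(pool, clone.junction_nt, germline,
                                    locus="IGH", prefiltered=True)
    chain_big = reconstruct_chain(pool + pool_big, clone.junction_nt, germline,
                                  locus="IGH", prefiltered=True)
    assert len(chain_big.contig_nt) >= len(chain_small.contig_nt)


def test_reconstruction_is_deterministic(germline, noisy_scenario):
    clones, reads = noisy_scenario
    pool = filter_vdj_reads(reads[:600], germline, prescreen=True)
    a = reconstruct_chain(pool, clones[0].junction_nt, germline,
                          locus="IGH", prefiltered=True)
    b = reconstruct_chain(pool, clones[0].junction_nt, germline,
                          locus="IGH", prefiltered=True)
    assert a.contig_nt == b.contig_nt
    assert np.array_equal(a.coverage, b.coverage)
    assert a.termination_reason == b.termination_reason


def test_contig_equals_truth_alignment_consensus_oracle(germline):
    """On noiseless single-clone input the contig must equal the
    consensus obtained by placing every read at its true offset."""
    clone, reads = single_clone_readset(germline, seed=67, coverage=20)
    pool = filter_vdj_reads(reads, germline)
    chain = reconstruct_chain(pool, clone.junction_nt, germline,
                              locus="IGH", prefiltered=True)
    t = clone.full_transcript_nt
    start = t.index(chain.contig_nt[:40])
    oracle = t[start : start + len(chain.contig_nt)]
    assert chain.contig_nt == oracle


def test_polish_reports_coverage_and_agreement(germline):
    clone, reads = single_clone_readset(germline, seed=68, coverage=15)
    pool = filter_vdj_reads(reads, germline)
    contig = clone.full_transcript_nt[
        clone.v_interval[0] : clone.junction_interval[1]
    ]
    polished, cov, agree, mapped = polish_contig(contig, pool)
    assert polished == contig
    assert cov.min() >= 1
    assert (agree == 1.0).all()
    assert mapped
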