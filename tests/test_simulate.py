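"""Synthetic repertoire / FFPE read generator: truth, determinism, statistics."""

import numpy as np
import pytest

from igrescue.germline import translate
from igrescue.simulate import (
    FragmentModel,
    SimulationError,
    fragment_and_damage,
    load_primers,
    make_igseq_reads,
    make_rnaseq_reads,
    simulate_repertoire,
)
from igrescue.alignment import revcomp


def test_zero_shm_rate_reproduces_germline_exactly(germline):
    clones = simulate_repertoire(germline, 5, 0.6, shm_rate=0.0, seed=1)
    for c in clones:
        v = germline[c.v_allele].nt_sequence
        j = germline[c.j_allele].nt_sequence
        t = c.full_transcript_nt
        assert t[c.v_interval[0] : c.v_interval[1]] == v
        assert t[c.j_interval[0] : c.j_interval[1]] == j
        assert c.shm_events == []


def test_single_clone_requires_full_dominance(germline):
    clones = simulate_repertoire(germline, 1, 1.0, seed=1)
    assert len(clones) == 1 and clones[0].frequency == 1.0
    with pytest.raises(SimulationError):
        simulate_repertoire(germline, 1, 0.9, seed=1)
    with pytest.raises(SimulationError):
        simulate_repertoire(germline, 5, 1.0, seed=1)


def test_background_frequencies_follow_harmonic_power_law(germline):
    clones = simulate_repertoire(
        germline, 51, 0.6, seed=2, power_exponent=1.0
    )
    bg = np.array([c.frequency for c in clones[1:]])
    h50 = np.sum(1.0 / np.arange(1, 51))
    expected = 0.4 / (np.arange(1, 51) * h50)
    np.testing.assert_allclose(bg, expected, rtol=1e-12)
    assert sum(c.frequency for c in clones) == pytest.approx(1.0, abs=1e-9)


def test_transcript_assembles_from_parts_with_exact_shm_events(germline):
    clones = simulate_repertoire(germline, 3, 0.8, shm_rate=0.03, seed=3)
    for c in clones:
        germ = (
            "?" * c.utr_len  # UTR is random, not germline-encoded
            + germline[c.v_allele].nt_sequence
            + "?" * (c.j_interval[0] - c.v_interval[1])
            + germline[c.j_allele].nt_sequence
            + germline[c.c_allele].nt_sequence
        )
        diffs = [
            i
            for i, (g, o) in enumerate(zip(germ, c.full_transcript_nt))
            if g not in ("?", o)
        ]
        assert diffs == sorted(p for p, _, _ in c.shm_events)
        for pos, ref, alt in c.shm_events:
            assert germ[pos] == ref and c.full_transcript_nt[pos] == alt


def test_planted_nonsilent_shms_change_amino_acids(germline):
    clones = simulate_repertoire(
        germline, 1, 1.0, seed=4, dominant_nonsilent_shm=12
    )
    c = clones[0]
    assert len(c.shm_events) == 12
    v0 = c.v_interval[0]
    germ_v = germline[c.v_allele].nt_sequence
    for pos, ref, alt in c.shm_events:
        cs = pos - (pos - v0) % 3
        germ_codon = list(c.full_transcript_nt[cs : cs + 3])
        germ_codon[pos - cs] = ref
        assert translate("".join(germ_codon)) != translate(
            c.full_transcript_nt[cs : cs + 3]
        )
        assert germ_v[pos - v0] == ref


def test_zero_damage_fragments_are_exact_substrings(germline):
    clones = simulate_repertoire(germline, 1, 1.0, seed=5)
    model = FragmentModel(damage_rate=0.0)
    frags, truth = fragment_and_damage(clones, model, 200, seed=6)
    t = clones[0].full_transcript_nt
    for f in frags:
        assert t[f.start : f.start + len(f.seq)] == f.seq
        assert truth.origin[f.frag_id] == (clones[0].clone_id, f.start, "+")


def test_degenerate_length_distribution_clips_at_transcript(germline):
    clones = simulate_repertoire(germline, 1, 1.0, seed=5)
    model = FragmentModel(meanlog=float(np.log(120.0)), sdlog=1e-9,
                          min_len=60, max_len=200, damage_rate=0.0)
    frags, _ = fragment_and_damage(clones, model, 100, seed=7)
    assert all(len(f.seq) == 120 for f in frags)


def test_dv200_matches_closed_form_for_symmetric_truncation(germline):
    """Median-200 log-normal truncated symmetrically in log space keeps
    P(len > 200) = 0.5, so DV200 of 10,000 fragments is 50% +/- 2%."""
    clones = simulate_repertoire(germline, 1, 1.0, seed=5)
    # transcript must not clip lengths: widen with a long constant region
    model = FragmentModel(meanlog=float(np.log(200.0)), sdlog=0.6,
                          min_len=80, max_len=500, damage_rate=0.0)
    rng = np.random.default_rng(8)
    lengths = model.sample_lengths(10000, rng)
    dv200 = np.mean(lengths > 200)
    assert abs(dv200 - 0.5) < 0.02


def test_damage_is_c_to_t_only(germline):
    clones = simulate_repertoire(germline, 1, 1.0, seed=5)
    model = FragmentModel(damage_rate=0.5)
    frags, _ = fragment_and_damage(clones, model, 50, seed=9)
    t = clones[0].full_transcript_nt
    for f in frags:
        for orig, got in zip(t[f.start : f.start + len(f.seq)], f.seq):
            if orig != got:
                assert (orig, got) == ("C", "T")


def test_igseq_amplicon_ends_at_constant_region_primer(germline):
    """A kappa clone's amplicon runs from the TSO tail to the embedded
    constant-region primer site."""
    from igrescue.simulate import TSO_TAIL, _amplicon

    clones = simulate_repertoire(germline, 1, 1.0, seed=10, locus="IGK")
    amp = _amplicon(clones[0], load_primers())
    assert amp.startswith(TSO_TAIL)
    assert amp.endswith("CACACAACAGAGGCAG")
    assert clones[0].junction_nt in amp


def test_igseq_zero_error_reads_are_amplicon_substrings(germline):
    from igrescue.simulate import _amplicon

    clones = simulate_repertoire(germline, 2, 0.7, seed=11)
    r1s, r2s, truth = make_igseq_reads(clones, n_reads=50, error_rate=0.0, seed=12)
    amps = {c.clone_id: _amplicon(c, load_primers()) for c in clones}
    for r1, r2 in zip(r1s, r2s):
        amp = amps[truth.origin[r1.read_id][0]]
        assert r1.seq in amp
        assert revcomp(r2.seq) in amp


def test_igseq_read_counts_track_clone_frequencies(germline):
    clones = simulate_repertoire(germline, 2, 0.6, seed=13)
    _, _, truth = make_igseq_reads(clones, n_reads=1000, error_rate=0.0, seed=14)
    n_dom = sum(
        1 for cid, _, _ in truth.origin.values() if cid == clones[0].clone_id
    )
    n_dom //= 2  # origin holds both mates
    # 99.9% binomial interval around 600
    assert abs(n_dom - 600) < 3.29 * np.sqrt(1000 * 0.6 * 0.4)


def test_rnaseq_truncates_short_fragments_and_orients_mates(germline):
    clones = simulate_repertoire(germline, 1, 1.0, seed=5)
    model = FragmentModel(meanlog=float(np.log(80.0)), sdlog=1e-9,
                          min_len=60, max_len=200, damage_rate=0.0)
    frags, _ = fragment_and_damage(clones, model, 30, seed=15)
    r1s, r2s, _ = make_rnaseq_reads(frags, read_len=150, paired=True,
                                    error_rate=0.0, seed=16)
    for f, r1, r2 in zip(frags, r1s, r2s):
        assert len(r1.seq) == 80 and len(r2.seq) == 80  # truncated, not padded
        # inward orientation: R2 is the reverse complement end of the insert
        assert r2.seq == revcomp(r1.seq)


def test_generators_are_bit_reproducible(germline):
    a = simulate_repertoire(germline, 10, 0.6, seed=17)
    b = simulate_repertoire(germline, 10, 0.6, seed=17)
    assert [c.full_transcript_nt for c in a] == [c.full_transcript_nt for c in b]
    r1a, r2a, ta = make_igseq_reads(a, n_reads=100, seed=18)
    r1b, r2b, tb = make_igseq_reads(b, n_reads=100, seed=18)
    assert [r.seq for r in r1a + r2a] == [r.seq for r in r1b + r2b]
    assert ta.origin == tb.origin


def test_every_read_is_traceable_exactly_once(germline):
    clones = simulate_repertoire(germline, 3, 0.5, seed=19)
    r1s, r2s, truth = make_igseq_reads(clones, n_reads=80, seed=20)
    ids = [r.read_id for r in r1s + r2s]
    assert len(ids) == len(set(ids))
    assert set(ids) == set(truth.origin)


def test_empirical_clone_shares_converge_to_frequencies(germline):
    clones = simulate_repertoire(germline, 5, 0.6, seed=23)
    _, _, truth = make_igseq_reads(clones, n_reads=4000, seed=24)
    counts = {}
    for cid, _, _ in truth.origin.values():
        counts[cid] = counts.get(cid, 0) + 1
    for c in clones:
        share = counts.get(c.clone_id, 0) / (2 * 4000)
        assert share == pytest.approx(c.frequency, abs=0.03)
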