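"""Germline annotation: alleles, CDR projection, SHM calls, isotype."""

import numpy as np
import pytest

from igrescue.annotate import (
    AnnotationError,
    annotate_cdrs,
    annotate_chain,
    assign_germline_alleles,
    call_isotype,
    call_shm,
    alignment_report,
)
from igrescue.assembly import AssembledChain, PoolRead, filter_vdj_reads, reconstruct_chain
from igrescue.simulate import simulate_repertoire

from conftest import single_clone_readset


def _chain_from_contig(contig, junction):
    at = contig.find(junction)
    assert at >= 0
    return AssembledChain(
        target_junction=junction,
        contig_nt=contig,
        coverage=np.full(len(contig), 100),
        agreement=np.ones(len(contig)),
        reading_frame=at % 3,
        junction_interval=(at, at + len(junction)),
        v_start_reached=True,
        termination_reason="v_start_reached",
    )


def _assembled(germline, seed, n_shm, **kw):
    clone, reads = single_clone_readset(germline, seed=seed, n_shm=n_shm, **kw)
    pool = filter_vdj_reads(reads, germline)
    chain = reconstruct_chain(pool, clone.junction_nt, germline,
                              locus="IGH", prefiltered=True)
    return clone, pool, chain


@pytest.mark.parametrize("k", [0, 5, 15])
def test_noiseless_round_trip_recovers_alleles_shms_and_isotype(germline, k):
    clone, pool, chain = _assembled(germline, seed=80 + k, n_shm=k)
    ann = annotate_chain(chain, germline, locus="IGH", pool=pool)
    assert ann.v_allele == clone.v_allele
    assert ann.j_allele == clone.j_allele
    assert ann.isotype == "IgG"
    assert ann.shm_count_aa == k
    assert ann.shm_count_aa <= ann.shm_count_nt
    truth = sorted({(p - clone.v_interval[0]) // 3 + 1
                    for p, _, _ in clone.shm_events})
    assert sorted(r.position for r in ann.shm_list) == truth
    for rec in ann.shm_list:
        assert rec.germline_aa != rec.observed_aa
        assert rec.region != "CDR3"  # junction positions are never SHM
    assert ann.productive


def test_allele_assignment_survives_many_shms(germline):
    clone, _, chain = _assembled(germline, seed=90, n_shm=25)
    v, j, v_id, j_id = assign_germline_alleles(chain, germline, "IGH")
    assert (v, j) == (clone.v_allele, clone.j_allele)
    assert v_id < 1.0  # mutated relative to germline


def test_short_contig_is_insufficient_v_context(germline):
    clone, _, chain = _assembled(germline, seed=91, n_shm=0)
    junction = chain.target_junction
    js = chain.junction_interval[0]
    short = _chain_from_contig(chain.contig_nt[js - 50 :], junction)
    with pytest.raises(AnnotationError) as err:
        assign_germline_alleles(short, germline, "IGH")
    assert err.value.reason == "insufficient_v_context"


def test_cdr_boundaries_project_from_scheme(germline):
    clone, _, chain = _assembled(germline, seed=92, n_shm=0)
    cdrs = annotate_cdrs(chain, clone.v_allele, germline)
    scheme = germline.cdr_scheme.for_allele(clone.v_allele)
    # ungapped noiseless contig: boundaries map 1:1
    assert cdrs["CDR1"] == scheme["CDR1"]
    assert cdrs["CDR2"] == scheme["CDR2"]
    js, je = chain.junction_interval
    assert cdrs["CDR3"] == (js + 3, je - 3)


def test_cdr_boundaries_shift_under_upstream_deletion(germline):
    """A 3-nt deletion upstream of CDR1 shifts projected boundaries by 3."""
    clone, _, chain = _assembled(germline, seed=93, n_shm=0)
    scheme = germline.cdr_scheme.for_allele(clone.v_allele)
    cut = scheme["CDR1"][0] - 30
    contig = chain.contig_nt[:cut] + chain.contig_nt[cut + 3 :]
    deleted = _chain_from_contig(contig, chain.target_junction)
    cdrs = annotate_cdrs(deleted, clone.v_allele, germline)
    assert cdrs["CDR1"] == (scheme["CDR1"][0] - 3, scheme["CDR1"][1] - 3)
    assert cdrs["CDR2"] == (scheme["CDR2"][0] - 3, scheme["CDR2"][1] - 3)


def test_silent_changes_are_reported_separately(germline):
    clone, _, chain = _assembled(germline, seed=94, n_shm=0)
    # plant a silent third-position change: find a codon where a swap is silent
    from igrescue.germline import translate

    js = chain.junction_interval[0]
    contig = list(chain.contig_nt)
    planted = None
    for cs in range(60, js - 12, 3):
        codon = "".join(contig[cs : cs + 3])
        for alt in "ACGT":
            if alt != codon[2] and translate(codon[:2] + alt) == translate(codon):
                planted = cs + 2
                contig[planted] = alt
                break
        if planted:
            break
    assert planted is not None
    mutated = _chain_from_contig("".join(contig), chain.target_junction)
    shm, silent, _ = call_shm(mutated, clone.v_allele, clone.j_allele, germline)
    assert [p for p, _, _ in silent] == [planted]
    assert shm == []


def test_low_confidence_positions_are_uncallable_not_mutations(germline):
    clone, _, chain = _assembled(germline, seed=95, n_shm=5)
    pos = sorted((p - clone.v_interval[0]) for p, _, _ in clone.shm_events)[0]
    chain.agreement[pos] = 0.5  # below the 0.7 confidence floor
    shm, _, uncallable = call_shm(chain, clone.v_allele, clone.j_allele, germline)
    assert pos in uncallable
    assert all(
        rec.position != (pos - chain.reading_frame) // 3 + 1 for rec in shm
    )


def test_isotype_unknown_when_contig_stops_before_constant(germline):
    clone, _, chain = _assembled(germline, seed=96, n_shm=0)
    js, je = chain.junction_interval
    trimmed = _chain_from_contig(chain.contig_nt[: je + 6], chain.target_junction)
    iso, support = call_isotype(germline, chain=trimmed)
    assert iso == "unknown" and support == 0.0


def test_pool_majority_isotype_with_support_fraction(germline):
    clone, _, chain = _assembled(germline, seed=97, n_shm=0)
    junction = chain.target_junction
    igg = germline["IGHG1*01"].nt_sequence
    igm = germline["IGHM*01"].nt_sequence
    ctx = chain.contig_nt[chain.junction_interval[0] - 30 :
                          chain.junction_interval[1]]
    pool = [
        PoolRead(f"g{i}", ctx + igg[:70], "IGHG1*01", 1.0, "+") for i in range(9)
    ] + [
        PoolRead("m0", ctx + igm[:70], "IGHM*01", 1.0, "+")
    ]
    js, je = chain.junction_interval
    headless = _chain_from_contig(chain.contig_nt[: je], junction)
    iso, support = call_isotype(germline, chain=headless, pool=pool,
                                target_junction=junction)
    assert iso == "IgG"
    assert support == pytest.approx(0.9)


def test_annotation_invariant_to_downstream_padding(germline):
    clone, pool, chain = _assembled(germline, seed=98, n_shm=7)
    ann = annotate_chain(chain, germline, locus="IGH")
    padded = _chain_from_contig(
        chain.contig_nt + germline[clone.c_allele].nt_sequence[60:120],
        chain.target_junction,
    )
    ann2 = annotate_chain(padded, germline, locus="IGH")
    assert ann2.v_allele == ann.v_allele and ann2.j_allele == ann.j_allele
    assert [r.position for r in ann2.shm_list] == [
        r.position for r in ann.shm_list
    ]


def test_alignment_report_marks_mutations(germline):
    clone, pool, chain = _assembled(germline, seed=99, n_shm=4)
    ann = annotate_chain(chain, germline, locus="IGH", pool=pool)
    report = alignment_report(chain, ann, germline)
    assert report.count("*") >= 3 * 4  # each mutated codon marked
    assert "IgG" in report
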