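"""Affinity-maturation annotation of an assembled chain.

Compares a reconstructed variable region against its germline: best
V/J allele assignment, CDR1/CDR2 boundaries projected from annotated
germline positions (CDR3 comes from the junction itself), nucleotide-
and amino-acid-level somatic hypermutation (SHM) calls with the
junction excluded (it is template-free), and isotype determination
from the constant-region sequence downstream of J — the evidence for
class switch and antigen-driven maturation.

SHM positions failing the assembler's per-position confidence
(agreement >= 0.7 at coverage >= min_coverage) are reported as
"uncallable" rather than as mutations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .alignment import LocalAlignment, smith_waterman
from .assembly import AssembledChain, PoolRead
from .germline import GermlineSet, translate

SHM_MIN_AGREEMENT = 0.7
SHM_MIN_COVERAGE = 2
ISOTYPE_IDENTITY_FLOOR = 0.80
ISOTYPE_WINDOW = 60

_ISOTYPE_BY_PREFIX = [
    ("IGHG", "IgG"), ("IGHM", "IgM"), ("IGHA", "IgA"), ("IGHE", "IgE"),
    ("IGHD", "IgD"), ("IGKC", "IgK"), ("IGLC", "IgL"),
]


class AnnotationError(RuntimeError):
    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def isotype_of(c_allele: str) -> str:
    for prefix, iso in _ISOTYPE_BY_PREFIX:
        if c_allele.startswith(prefix):
            return iso
    return "unknown"


@dataclass(frozen=True)
class SHMRecord:
    position: int  # 1-based codon index on the assembled variable region
    germline_aa: str
    observed_aa: str
    germline_codon: str
    observed_codon: str
    region: str


@dataclass
class ChainAnnotation:
    v_allele: str
    j_allele: str
    v_identity: float
    j_identity: float
    cdr_boundaries: dict[str, tuple[int, int]]  # contig nt intervals
    shm_list: list[SHMRecord]
    silent_nt: list[tuple[int, str, str]]  # (contig pos, germline, observed)
    shm_count_nt: int
    shm_count_aa: int
    uncallable_positions: list[int]
    isotype: str
    isotype_support: float
    productive: bool

    def to_dict(self) -> dict:
        return {
            "v_allele": self.v_allele,
            "j_allele": self.j_allele,
            "v_identity": self.v_identity,
            "j_identity": self.j_identity,
            "cdr_boundaries": {k: list(v) for k, v in self.cdr_boundaries.items()},
            "shm": [
                {
                    "codon": r.position,
                    "germline_aa": r.germline_aa,
                    "observed_aa": r.observed_aa,
                    "germline_codon": r.germline_codon,
                    "observed_codon": r.observed_codon,
                    "region": r.region,
                }
                for r in self.shm_list
            ],
            "silent_nt": [list(x) for x in self.silent_nt],
            "shm_count_nt": self.shm_count_nt,
            "shm_count_aa": self.shm_count_aa,
            "uncallable_positions": self.uncallable_positions,
            "isotype": self.isotype,
            "isotype_support": self.isotype_support,
            "productive": self.productive,
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _best_segment(query: str, segments) -> tuple[str, LocalAlignment] | None:
    best = None
    for seg in segments:
        aln = smith_waterman(query, seg.nt_sequence)
        if aln is None:
            continue
        if (
            best is None
            or (aln.score, aln.identity) > (best[1].score, best[1].identity)
            or (
                (aln.score, aln.identity) == (best[1].score, best[1].identity)
                and seg.allele_id < best[0]
            )
        ):
            best = (seg.allele_id, aln)
    return best


def assign_germline_alleles(
    chain: AssembledChain,
    germline: GermlineSet,
    locus: str | None = None,
) -> tuple[str, str, float, float]:
    """Best V allele 5' of the junction, best J allele 3' of it.

    Raises ``insufficient_v_context`` when fewer than 60 nt of contig
    lie upstream of the junction.
    """
    j_start, j_end = chain.junction_interval
    if j_start < 60:
        raise AnnotationError("insufficient_v_context")
    v = _best_segment(chain.contig_nt[:j_start], germline.alleles("V", locus))
    j = _best_segment(chain.contig_nt[j_start:], germline.alleles("J", locus))
    if v is None or j is None:
        raise AnnotationError("insufficient_v_context")
    return v[0], j[0], v[1].identity, j[1].identity


def annotate_cdrs(
    chain: AssembledChain,
    v_allele: str,
    germline: GermlineSet,
) -> dict[str, tuple[int, int]]:
    """CDR boundaries on the contig.

    CDR1/CDR2 are projected through the contig-to-germline alignment
    from the allele's annotated positions (supplied by the reference's
    CDR scheme table); CDR3 is the junction minus its anchor codons.
    """
    scheme = germline.cdr_scheme.for_allele(v_allele)
    seg = germline[v_allele]
    j_start, j_end = chain.junction_interval
    aln = smith_waterman(chain.contig_nt[:j_start], seg.nt_sequence)
    if aln is None:
        raise AnnotationError("insufficient_v_context")
    out: dict[str, tuple[int, int]] = {}
    for name in ("CDR1", "CDR2"):
        g0, g1 = scheme[name]
        q0 = aln.project_to_query(g0)
        q1 = aln.project_to_query(g1)
        if q0 is None or q1 is None:
            raise AnnotationError(f"cdr_projection_failed:{name}")
        out[name] = (q0, q1)
    out["CDR3"] = (j_start + 3, j_end - 3)
    return out


def _region_of(pos: int, cdrs: dict[str, tuple[int, int]], junction: tuple[int, int]) -> str:
    if cdrs["CDR1"][0] <= pos < cdrs["CDR1"][1]:
        return "CDR1"
    if cdrs["CDR2"][0] <= pos < cdrs["CDR2"][1]:
        return "CDR2"
    if junction[0] <= pos < junction[1]:
        return "CDR3"
    if pos < cdrs["CDR1"][0]:
        return "FR1"
    if pos < cdrs["CDR2"][0]:
        return "FR2"
    if pos < junction[0]:
        return "FR3"
    return "FR4"


def call_shm(
    chain: AssembledChain,
    v_allele: str,
    j_allele: str,
    germline: GermlineSet,
    min_agreement: float = SHM_MIN_AGREEMENT,
    min_coverage: int = SHM_MIN_COVERAGE,
) -> tuple[list[SHMRecord], list[tuple[int, str, str]], list[int]]:
    """Position-wise germline comparison over V and J, junction excluded.

    Returns (aa-changing records, silent nt changes, uncallable
    positions).  A contig position is compared only when the assembler
    supports it (agreement >= ``min_agreement`` at coverage >=
    ``min_coverage``); differences elsewhere are uncallable.
    """
    j_start, j_end = chain.junction_interval
    contig = chain.contig_nt
    diffs: dict[int, tuple[str, str]] = {}  # contig pos -> (germline, observed)
    uncallable: list[int] = []

    for allele, query, base in (
        (v_allele, contig[:j_start], 0),
        (j_allele, contig[j_end:], j_end),
    ):
        seg = germline[allele]
        aln = smith_waterman(query, seg.nt_sequence)
        if aln is None:
            continue
        for qi, tj in aln.pairs:
            if qi < 0 or tj < 0:
                continue
            pos = base + qi
            if j_start <= pos < j_end:
                continue
            g, o = seg.nt_sequence[tj], contig[pos]
            if g == o:
                continue
            if (
                chain.coverage[pos] < min_coverage
                or chain.agreement[pos] < min_agreement
            ):
                uncallable.append(pos)
                continue
            diffs[pos] = (g, o)

    try:
        cdrs = annotate_cdrs(chain, v_allele, germline)
    except Exception:  # scheme may be absent; regions fall back to FR labels
        cdrs = {"CDR1": (-1, -1), "CDR2": (-1, -1)}

    frame = chain.reading_frame
    records: list[SHMRecord] = []
    silent: list[tuple[int, str, str]] = []
    by_codon: dict[int, list[int]] = {}
    for pos in diffs:
        if pos < frame:
            continue
        by_codon.setdefault((pos - frame) // 3, []).append(pos)
    for codon_idx in sorted(by_codon):
        c0 = frame + 3 * codon_idx
        obs = contig[c0 : c0 + 3]
        if len(obs) < 3:
            continue
        germ = list(obs)
        for pos in by_codon[codon_idx]:
            germ[pos - c0] = diffs[pos][0]
        germ_codon = "".join(germ)
        g_aa, o_aa = translate(germ_codon), translate(obs)
        if g_aa == o_aa:
            for pos in by_codon[codon_idx]:
                silent.append((pos, diffs[pos][0], diffs[pos][1]))
        else:
            records.append(
                SHMRecord(
                    position=codon_idx + 1,
                    germline_aa=g_aa,
                    observed_aa=o_aa,
                    germline_codon=germ_codon,
                    observed_codon=obs,
                    region=_region_of(c0, cdrs, chain.junction_interval),
                )
            )
    return records, silent, sorted(uncallable)


def call_isotype(
    germline: GermlineSet,
    chain: AssembledChain | None = None,
    pool: list[PoolRead] | None = None,
    target_junction: str | None = None,
    identity_floor: float = ISOTYPE_IDENTITY_FLOOR,
    window: int = ISOTYPE_WINDOW,
) -> tuple[str, float]:
    """Isotype from constant-region evidence; (isotype, support fraction).

    Contig route: best C allele over the contig's 3' tail against each
    allele's leading ``window`` nt.  Pool route (used when the contig
    stops before the constant region): every pool read carrying the
    target junction votes with its own best C assignment.
    """
    c_segments = germline.alleles("C")
    if chain is not None:
        j_end = chain.junction_interval[1]
        tail = chain.contig_nt[j_end:]
        best = None
        for seg in c_segments:
            aln = smith_waterman(tail, seg.nt_sequence[:window])
            if aln is None:
                continue
            key = (aln.score, aln.identity)
            if best is None or key > best[0] or (
                key == best[0] and seg.allele_id < best[1]
            ):
                best = (key, seg.allele_id, aln)
        if (
            best is not None
            and best[2].identity >= identity_floor
            and best[2].query_span >= 30
        ):
            return isotype_of(best[1]), 1.0
    if pool is not None and target_junction is not None:
        votes: dict[str, int] = {}
        for read in pool:
            at = read.seq.find(target_junction)
            if at < 0:
                continue
            tail = read.seq[at + len(target_junction) :]
            best = None
            for seg in c_segments:
                aln = smith_waterman(tail, seg.nt_sequence[:window])
                if aln is None:
                    continue
                key = (aln.score, aln.identity)
                if best is None or key > best[0] or (
                    key == best[0] and seg.allele_id < best[1]
                ):
                    best = (key, seg.allele_id, aln)
            if best and best[2].identity >= identity_floor and best[2].query_span >= 20:
                iso = isotype_of(best[1])
                votes[iso] = votes.get(iso, 0) + 1
        if votes:
            total = sum(votes.values())
            iso = max(sorted(votes), key=lambda k: votes[k])
            return iso, votes[iso] / total
    return "unknown", 0.0


def annotate_chain(
    chain: AssembledChain,
    germline: GermlineSet,
    locus: str | None = None,
    pool: list[PoolRead] | None = None,
) -> ChainAnnotation:
    """Full annotation: alleles, CDRs, SHM, isotype, productiveness."""
    v_allele, j_allele, v_id, j_id = assign_germline_alleles(chain, germline, locus)
    cdrs = annotate_cdrs(chain, v_allele, germline)
    shm, silent, uncallable = call_shm(chain, v_allele, j_allele, germline)
    isotype, support = call_isotype(
        germline, chain=chain, pool=pool, target_junction=chain.target_junction
    )
    j_start, j_end = chain.junction_interval
    junction = chain.contig_nt[j_start:j_end]
    aa = translate(junction)
    # productivity concerns the variable region: in-frame junction and a
    # stop-free open reading frame from the contig start through the
    # junction (the constant region has its own frame)
    productive = (
        len(junction) % 3 == 0
        and "*" not in translate(chain.contig_nt[chain.reading_frame : j_end])
    )
    nt_count = len(silent) + sum(
        sum(1 for a, b in zip(r.germline_codon, r.observed_codon) if a != b)
        for r in shm
    )
    return ChainAnnotation(
        v_allele=v_allele,
        j_allele=j_allele,
        v_identity=v_id,
        j_identity=j_id,
        cdr_boundaries=cdrs,
        shm_list=shm,
        silent_nt=silent,
        shm_count_nt=nt_count,
        shm_count_aa=len(shm),
        uncallable_positions=uncallable,
        isotype=isotype,
        isotype_support=support,
        productive=productive,
    )


def alignment_report(
    chain: AssembledChain,
    annotation: ChainAnnotation,
    germline: GermlineSet,
    width: int = 60,
) -> str:
    """Human-readable germline-vs-contig alignment with a CDR ruler.

    Mutated (SHM) codons and the CDR3 are marked — the text analogue of
    the usual red-letter maturation figure.
    """
    contig = chain.contig_nt
    frame = chain.reading_frame
    n = len(contig)
    ruler = [" "] * n
    for name, (a, b) in annotation.cdr_boundaries.items():
        for i in range(max(a, 0), min(b, n)):
            ruler[i] = name[-1]
    marks = [" "] * n
    for rec in annotation.shm_list:
        c0 = frame + 3 * (rec.position - 1)
        for i in range(c0, min(c0 + 3, n)):
            marks[i] = "*"
    germ_line = list(contig)
    for rec in annotation.shm_list:
        c0 = frame + 3 * (rec.position - 1)
        for k, b in enumerate(rec.germline_codon):
            if c0 + k < n:
                germ_line[c0 + k] = b.lower() if b != contig[c0 + k] else b
    lines = [
        f"# V={annotation.v_allele} J={annotation.j_allele} "
        f"isotype={annotation.isotype} "
        f"SHM(aa)={annotation.shm_count_aa} SHM(nt)={annotation.shm_count_nt}",
    ]
    for at in range(0, n, width):
        lines.append(f"cdr    {''.join(ruler[at:at + width])}")
        lines.append(f"germ   {''.join(germ_line[at:at + width])}")
        lines.append(f"contig {contig[at:at + width]}  [{at + 1}-{min(at + width, n)}]")
        lines.append(f"shm    {''.join(marks[at:at + width])}")
        lines.append("")
    return "\n".join(lines)
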