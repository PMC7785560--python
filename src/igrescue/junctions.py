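"""CDR3/junction extraction from Ig-seq reads and clonotype aggregation.

Each read is locally aligned to every V allele (both strands; a fast
edit-distance prescreen narrows the candidate alleles before the exact
affine-gap DP), then to the J alleles on the V strand.  Germline anchor
positions — the conserved V-region Cys and J-region Trp/Phe — are
projected through the alignments onto the read; the junction is the
anchor-inclusive span between them and must still translate to
C...W/F.  Reads sharing (locus, V call, J call, junction) form a
clonotype; a frequency-ratio collapse absorbs sequencing-error
satellites into their parent clonotypes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .alignment import LocalAlignment, revcomp, smith_waterman
from .germline import GermlineSegment, GermlineSet, translate
from .simulate import SeqRead

#: Ig-seq read acceptance: best V alignment must reach this identity
#: over at least MIN_ALIGNED_NT aligned read bases (distinct from the
#: 80% whole-transcriptome VDJ filter of the assembler).
MIN_V_IDENTITY = 0.85
MIN_ALIGNED_NT = 30
#: score floor below which a best local alignment is treated as no hit
#: (random 150-nt DNA essentially never reaches it; a genuine 30-nt
#: segment context always does)
MIN_ALIGN_SCORE = 40
PRESCREEN_K = 12
PRESCREEN_MAX_CANDIDATES = 4


@dataclass(frozen=True)
class SegmentAlignment:
    """Best local alignment of a read against one germline segment."""

    read_id: str
    allele_id: str
    score: int
    identity: float
    read_interval: tuple[int, int]  # on the oriented (coding-strand) read
    segment_interval: tuple[int, int]
    strand: str  # '+' if the read itself is coding-strand
    alignment: LocalAlignment


@dataclass
class Clonotype:
    locus: str
    v_call: str
    j_call: str
    junction_nt: str
    junction_aa: str
    count: int
    frequency: float = 0.0
    productive: bool = True

    @property
    def cdr3_nt(self) -> str:
        return self.junction_nt[3:-3]

    @property
    def cdr3_aa(self) -> str:
        return self.junction_aa[1:-1] if len(self.junction_aa) >= 2 else ""

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.locus, self.v_call, self.j_call, self.junction_nt)


def _kmer_index(
    germline: GermlineSet, mode: str, locus: str | None, k: int = PRESCREEN_K
) -> dict[str, list[GermlineSegment]]:
    """k-mer → segments lookup, cached on the germline set."""
    cache = getattr(germline, "_kmer_cache", None)
    if cache is None:
        cache = {}
        germline._kmer_cache = cache  # type: ignore[attr-defined]
    key = (mode, locus, k)
    if key not in cache:
        index: dict[str, list[GermlineSegment]] = {}
        for seg in germline.alleles(mode, locus):
            s = seg.nt_sequence
            seen = set()
            for i in range(len(s) - k + 1):
                km = s[i : i + k]
                if km not in seen:
                    index.setdefault(km, []).append(seg)
                    seen.add(km)
        cache[key] = index
    return cache[key]


def _prescreen(
    read: str,
    germline: GermlineSet,
    mode: str,
    locus: str | None,
    k: int = PRESCREEN_K,
) -> list[tuple[GermlineSegment, str]]:
    """Candidate (allele, strand) pairs sharing at least one k-mer with
    the read, most-shared first.  Substitution-dominated reads with a
    >= ~20 nt overlap to a segment essentially always retain an intact
    k-mer, so the prescreen loses only hopeless candidates."""
    index = _kmer_index(germline, mode, locus, k)
    counts: dict[tuple[str, str], int] = {}
    by_key: dict[tuple[str, str], GermlineSegment] = {}
    for strand, seq in (("+", read), ("-", revcomp(read))):
        for i in range(len(seq) - k + 1):
            for seg in index.get(seq[i : i + k], ()):
                key = (seg.allele_id, strand)
                counts[key] = counts.get(key, 0) + 1
                by_key[key] = seg
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        (by_key[key], key[1])
        for key, _n in ranked[:PRESCREEN_MAX_CANDIDATES]
    ]


def align_read_to_germline(
    read: SeqRead,
    germline: GermlineSet,
    mode: str,
    locus: str | None = None,
    strand: str | None = None,
    prescreen: bool = True,
    min_score: int = MIN_ALIGN_SCORE,
) -> SegmentAlignment | None:
    """Best local alignment of a read to the V or J alleles.

    Both strands are tried unless ``strand`` pins one.  Best is by
    score, ties by identity, then lexicographic allele id, then '+'
    strand.  Returns None when no allele reaches ``min_score``.
    """
    segments = germline.alleles(mode, locus)
    if not segments:
        return None
    if prescreen:
        candidates = [
            (seg, st)
            for seg, st in _prescreen(read.seq, germline, mode, locus)
            if strand is None or st == strand
        ]
        if not candidates:
            return None  # no shared k-mer with any allele: hopeless read
    else:
        candidates = [
            (seg, st)
            for seg in segments
            for st in ("+", "-")
            if strand is None or st == strand
        ]

    best: SegmentAlignment | None = None
    for seg, st in candidates:
        q = read.seq if st == "+" else revcomp(read.seq)
        aln = smith_waterman(q, seg.nt_sequence)
        if aln is None:
            continue
        cand = SegmentAlignment(
            read_id=read.read_id,
            allele_id=seg.allele_id,
            score=aln.score,
            identity=aln.identity,
            read_interval=(aln.query_start, aln.query_end),
            segment_interval=(aln.target_start, aln.target_end),
            strand=st,
            alignment=aln,
        )
        if best is None or (
            cand.score,
            cand.identity,
            # invert orderings that prefer "smaller"
        ) > (best.score, best.identity) or (
            (cand.score, cand.identity) == (best.score, best.identity)
            and (cand.allele_id, cand.strand) < (best.allele_id, best.strand)
        ):
            best = cand
    if best is not None and best.score < min_score:
        return None
    return best


@dataclass
class JunctionRecord:
    locus: str
    v_call: str
    j_call: str
    junction_nt: str
    junction_aa: str
    productive: bool


def call_junction(
    read: SeqRead,
    v_aln: SegmentAlignment,
    j_aln: SegmentAlignment,
    germline: GermlineSet,
) -> JunctionRecord | str:
    """Extract the anchor-inclusive junction from one read.

    Returns a :class:`JunctionRecord`, or a rejection-reason string:
    ``vj_incoherent`` (strand/order conflict), ``anchor_uncovered``
    (an anchor codon falls off the read) or ``anchor_lost`` (anchor no
    longer translates to C / W / F).
    """
    if v_aln.strand != j_aln.strand:
        return "vj_incoherent"
    v_seg = germline[v_aln.allele_id]
    j_seg = germline[j_aln.allele_id]
    assert v_seg.anchor_pos is not None and j_seg.anchor_pos is not None
    seq = read.seq if v_aln.strand == "+" else revcomp(read.seq)

    v_anchor = v_aln.alignment.project_to_query(v_seg.anchor_pos)
    j_anchor = j_aln.alignment.project_to_query(j_seg.anchor_pos)
    if (
        v_anchor is None
        or j_anchor is None
        or v_anchor < 0
        or j_anchor + 3 > len(seq)
    ):
        return "anchor_uncovered"
    if j_anchor <= v_anchor:
        return "vj_incoherent"
    junction = seq[v_anchor : j_anchor + 3]
    aa = translate(junction)
    first = translate(junction[:3])
    last = translate(junction[-3:]) if len(junction) % 3 == 0 else ""
    want_last = "W" if v_seg.locus == "IGH" else "F"
    if first != "C" or (len(junction) % 3 == 0 and last != want_last):
        return "anchor_lost"
    productive = len(junction) % 3 == 0 and "*" not in aa
    return JunctionRecord(
        locus=v_seg.locus,
        v_call=v_aln.allele_id,
        j_call=j_aln.allele_id,
        junction_nt=junction,
        junction_aa=aa,
        productive=productive,
    )


@dataclass
class ClonotypeTable:
    clonotypes: list[Clonotype]
    qc: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._normalize()

    def _normalize(self) -> None:
        self.clonotypes.sort(key=lambda c: (-c.count, c.junction_nt, c.v_call, c.j_call))
        prod_total = sum(c.count for c in self.clonotypes if c.productive)
        for c in self.clonotypes:
            c.frequency = c.count / prod_total if (c.productive and prod_total) else 0.0

    def view(self, chain_view: str) -> "ClonotypeTable":
        """Per-chain table: 'H' (IGH), 'IGK', 'IGL' or merged 'L'."""
        loci = {
            "H": {"IGH"}, "IGH": {"IGH"}, "IGK": {"IGK"}, "IGL": {"IGL"},
            "L": {"IGK", "IGL"},
        }[chain_view]
        rows = [replace(c) for c in self.clonotypes if c.locus in loci]
        return ClonotypeTable(rows, dict(self.qc))

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clonotypes)

    def write_airr(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                ["locus", "v_call", "j_call", "junction", "junction_aa",
                 "cdr3", "cdr3_aa", "consensus_count", "frequency", "productive"]
            )
            for c in self.clonotypes:
                w.writerow(
                    [c.locus, c.v_call, c.j_call, c.junction_nt, c.junction_aa,
                     c.cdr3_nt, c.cdr3_aa, c.count, f"{c.frequency:.10g}",
                     "T" if c.productive else "F"]
                )

    def write_qc(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.qc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_airr(path: str | Path) -> ClonotypeTable:
    rows = []
    with open(path, newline="") as fh:
        for r in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                Clonotype(
                    locus=r["locus"],
                    v_call=r["v_call"],
                    j_call=r["j_call"],
                    junction_nt=r["junction"],
                    junction_aa=r["junction_aa"],
                    count=int(r["consensus_count"]),
                    productive=r["productive"] == "T",
                )
            )
    return ClonotypeTable(rows)


def build_clonotype_table(
    reads: list[SeqRead],
    germline: GermlineSet,
    min_v_identity: float = MIN_V_IDENTITY,
    min_aligned_nt: int = MIN_ALIGNED_NT,
) -> ClonotypeTable:
    """Attempt junction extraction on every read; aggregate clonotypes.

    The QC tally conserves reads exactly: accepted plus every rejection
    category sums to the input read count.  Out-of-frame or
    stop-containing junctions are kept in the table flagged
    non-productive but excluded from frequency normalization.
    """
    import warnings

    qc = {
        "input_reads": len(reads), "accepted": 0, "no_v_hit": 0, "no_j_hit": 0,
        "low_v_identity": 0, "vj_incoherent": 0, "anchor_uncovered": 0,
        "anchor_lost": 0,
    }
    if not reads:
        warnings.warn("empty read input: returning empty clonotype table")
        return ClonotypeTable([], qc)
    counts: dict[tuple, list] = {}
    for read in reads:
        v_aln = align_read_to_germline(read, germline, "V")
        if v_aln is None:
            qc["no_v_hit"] += 1
            continue
        if (
            v_aln.identity < min_v_identity
            or v_aln.read_interval[1] - v_aln.read_interval[0] < min_aligned_nt
        ):
            qc["low_v_identity"] += 1
            continue
        locus = germline[v_aln.allele_id].locus
        j_aln = align_read_to_germline(
            read, germline, "J", locus=locus, strand=v_aln.strand
        )
        if j_aln is None:
            qc["no_j_hit"] += 1
            continue
        rec = call_junction(read, v_aln, j_aln, germline)
        if isinstance(rec, str):
            qc[rec] += 1
            continue
        qc["accepted"] += 1
        key = (rec.locus, rec.v_call, rec.j_call, rec.junction_nt)
        slot = counts.setdefault(key, [rec, 0])
        slot[1] += 1
    clonotypes = [
        Clonotype(
            locus=rec.locus, v_call=rec.v_call, j_call=rec.j_call,
            junction_nt=rec.junction_nt, junction_aa=rec.junction_aa,
            count=n, productive=rec.productive,
        )
        for rec, n in counts.values()
    ]
    return ClonotypeTable(clonotypes, qc)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def error_correct_clonotypes(
    table: ClonotypeTable,
    ratio_threshold: float = 20.0,
    max_mismatches: int = 2,
) -> ClonotypeTable:
    """Frequency-ratio collapse of sequencing-error satellite clonotypes.

    A clonotype is merged (counts added) into another clonotype of the
    same locus/V/J and junction length when the junctions differ by at
    most ``max_mismatches`` substitutions and the parent is at least
    ``ratio_threshold`` times more abundant.  Children are processed in
    ascending count order and the procedure iterates to a fixed point;
    the total read count is conserved and the table never grows.
    """
    clonotypes = [replace(c) for c in table.clonotypes]
    changed = True
    while changed:
        changed = False
        groups: dict[tuple, list[Clonotype]] = {}
        for c in clonotypes:
            groups.setdefault(
                (c.locus, c.v_call, c.j_call, len(c.junction_nt)), []
            ).append(c)
        merged: set[int] = set()
        for group in groups.values():
            group.sort(key=lambda c: (c.count, c.junction_nt))
            for child in group:
                if id(child) in merged:
                    continue
                parents = [
                    p
                    for p in group
                    if id(p) not in merged
                    and p is not child
                    and p.count >= ratio_threshold * child.count
                    and _hamming(p.junction_nt, child.junction_nt) <= max_mismatches
                ]
                if not parents:
                    continue
                parent = max(parents, key=lambda p: (p.count, p.junction_nt))
                parent.count += child.count
                merged.add(id(child))
                changed = True
        if merged:
            clonotypes = [c for c in clonotypes if id(c) not in merged]
    return ClonotypeTable(clonotypes, dict(table.qc))
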