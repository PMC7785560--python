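"""CDR3-seeded reconstruction of full-length antibody chains.

This is the pipeline's central computation: starting from a junction
(CDR3 with its anchors) called on the Ig-seq library, reads of the
whole-transcriptome library that carry that junction seed a contig,
which is then grown greedily from the 3' end of the V segment to its
5' start by overlapping reads, each extension column decided by a
weighted majority vote.  Ambiguous branches, coverage gaps and reaching
the projected germline V start are distinct, recorded outcomes.

Reads enter the pool only if their best local alignment against any
V or J allele reaches 80% identity (the VDJ filter); pool reads are
strand-normalized to the coding strand.

Coordinates are 0-based, half-open; the junction interval is tracked
through every extension and trim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from .alignment import revcomp, smith_waterman
from .germline import GermlineSet, translate
from .junctions import align_read_to_germline
from .simulate import SeqRead

DEFAULT_MIN_OVERLAP = 20
DEFAULT_MIN_OVERLAP_IDENTITY = 0.95
DEFAULT_MIN_COVERAGE = 2
DEFAULT_BRANCH_RATIO = 0.8
DEFAULT_MAX_ITERATIONS = 10_000
DEFAULT_C_CAP = 60  # nt of constant region kept past the J segment
POLISH_MIN_IDENTITY = 0.90
PROJECTION_MIN_IDENTITY = 0.85
PROJECTION_MIN_SPAN = 40
PROJECTION_MAX_START_OFFSET = 3  # alignment must reach the segment start


class AssemblyError(RuntimeError):
    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class PoolRead:
    """A VDJ-filtered read, strand-normalized to the coding strand."""

    read_id: str
    seq: str
    best_allele: str
    best_identity: float
    strand: str  # strand of the original read relative to coding


@dataclass(frozen=True)
class SeedMatch:
    read_id: str
    strand: str
    offset: int  # junction occurrence on the (normalized) read
    exactness: str  # "exact" or "k-mismatch"
    read_len: int = 0


@dataclass
class AssembledChain:
    target_junction: str
    contig_nt: str
    coverage: np.ndarray
    agreement: np.ndarray
    reading_frame: int
    junction_interval: tuple[int, int]
    v_start_reached: bool
    termination_reason: str  # 5' (V-ward) phase outcome
    termination_reason_3prime: str = ""
    supporting_reads: list[str] = field(default_factory=list)
    protein: str = ""

    @property
    def v_region_nt(self) -> str:
        return self.contig_nt[: self.junction_interval[0]]

    def write_report(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "target_junction": self.target_junction,
                    "contig_length": len(self.contig_nt),
                    "junction_interval": list(self.junction_interval),
                    "v_start_reached": self.v_start_reached,
                    "termination_reason": self.termination_reason,
                    "termination_reason_3prime": self.termination_reason_3prime,
                    "n_supporting_reads": len(self.supporting_reads),
                    "mean_coverage": float(self.coverage.mean()),
                },
                fh,
                indent=2,
            )
            fh.write("\n")

    def write_fasta(self, path: str | Path, name: str = "contig") -> None:
        with open(path, "w") as fh:
            fh.write(f">{name}\n{self.contig_nt}\n")

    def write_coverage(self, path: str | Path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["contig_pos", "base", "coverage", "agreement"])
            for i, b in enumerate(self.contig_nt):
                w.writerow(
                    [i, b, int(self.coverage[i]), f"{self.agreement[i]:.4g}"]
                )


# ---------------------------------------------------------------------------
# VDJ filter


def filter_vdj_reads(
    reads: list[SeqRead],
    germline: GermlineSet,
    min_identity: float = 0.80,
    min_aligned_nt: int = 30,
    mode: str = "identity",
    prescreen: bool = False,
) -> list[PoolRead]:
    """Keep reads whose best V/J alignment passes the 80% filter.

    ``mode='identity'`` (default) applies ``min_identity`` to the
    alignment identity over the locally aligned region;
    ``mode='read_fraction'`` instead requires that fraction of the read
    to be aligned.  Retained reads are flipped onto the coding strand.
    The default is the exact all-allele scan, so filter decisions are a
    pure function of the DP; ``prescreen=True`` trades that guarantee
    for speed on large read sets.
    """
    pool: list[PoolRead] = []
    for read in reads:
        best = None
        for seg_class in ("V", "J"):
            aln = align_read_to_germline(
                read, germline, seg_class, prescreen=prescreen, min_score=1
            )
            if aln is None:
                continue
            if best is None or (aln.score, aln.identity) > (
                best.score,
                best.identity,
            ) or (
                (aln.score, aln.identity) == (best.score, best.identity)
                and aln.allele_id < best.allele_id
            ):
                best = aln
        if best is None:
            continue
        span = best.read_interval[1] - best.read_interval[0]
        if span < min_aligned_nt:
            continue
        measure = best.identity if mode == "identity" else span / len(read.seq)
        if measure < min_identity:
            continue
        seq = read.seq if best.strand == "+" else revcomp(read.seq)
        pool.append(
            PoolRead(read.read_id, seq, best.allele_id, best.identity, best.strand)
        )
    return pool


# ---------------------------------------------------------------------------
# Seeding


def _occurrences(seq: str, pattern: str, max_mismatches: int) -> list[tuple[int, int]]:
    """All (offset, n_mismatches) occurrences of pattern within seq."""
    n, m = len(seq), len(pattern)
    if m == 0 or n < m:
        return []
    if max_mismatches == 0:
        out, at = [], seq.find(pattern)
        while at != -1:
            out.append((at, 0))
            at = seq.find(pattern, at + 1)
        return out
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    out = []
    for off in range(n - m + 1):
        mm = int(np.count_nonzero(s[off : off + m] != p))
        if mm <= max_mismatches:
            out.append((off, mm))
    return out


def _seed_motif_ok(seq: str, offset: int, junction_len: int) -> bool:
    """Anchor Cys intact and any fully-present upstream codons are Tyr.

    The FR3 end upstream of the junction carries the conserved
    Tyr-Tyr-Cys run; a seed read whose anchor codon no longer encodes C
    (or whose in-frame upstream codons lost their Y) is rejected.
    """
    if translate(seq[offset : offset + 3]) != "C":
        return False
    for k in (1, 2):
        start = offset - 3 * k
        if start >= 0 and translate(seq[start : start + 3]) != "Y":
            return False
    return True


def find_seeds(
    pool: list[PoolRead],
    target_junction_nt: str,
    max_mismatches: int = 0,
) -> list[SeedMatch]:
    """Pool reads carrying the target junction (with its upstream motif).

    Sorted exact-first, then by 5' flank length (longest first), then
    read id.  Raises :class:`AssemblyError` ``no_seed_reads`` when the
    junction occurs nowhere in the pool.
    """
    if not pool:
        raise AssemblyError("no_vdj_reads")
    seeds = []
    for read in pool:
        for offset, mm in _occurrences(read.seq, target_junction_nt, max_mismatches):
            if not _seed_motif_ok(read.seq, offset, len(target_junction_nt)):
                continue
            seeds.append(
                SeedMatch(
                    read_id=read.read_id,
                    strand=read.strand,
                    offset=offset,
                    exactness="exact" if mm == 0 else "k-mismatch",
                    read_len=len(read.seq),
                )
            )
    seeds.sort(
        key=lambda s: (s.exactness != "exact", -s.offset, s.read_id)
    )
    if not seeds:
        raise AssemblyError("no_seed_reads")
    return seeds


# ---------------------------------------------------------------------------
# Greedy overlap extension


def _pad_matrix(seqs: list[str], align: str) -> tuple[np.ndarray, np.ndarray]:
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    width = int(lens.max()) if len(seqs) else 0
    mat = np.zeros((len(seqs), width), dtype=np.uint8)
    for i, s in enumerate(seqs):
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        if align == "right":
            mat[i, width - len(s) :] = arr
        else:
            mat[i, : len(s)] = arr
    return mat, lens


def _collect_overlaps(
    mat: np.ndarray,
    lens: np.ndarray,
    contig: str,
    direction: str,
    min_overlap: int,
    min_identity: float,
) -> list[tuple[int, int]]:
    """(read index, overlap length) pairs; each read at its longest
    qualifying overlap with the contig end."""
    width = mat.shape[1]
    carr = np.frombuffer(contig.encode(), dtype=np.uint8)
    hi = int(min(width, len(contig)))
    assigned = np.zeros(mat.shape[0], dtype=bool)
    out: list[tuple[int, int]] = []
    for o in range(hi, min_overlap - 1, -1):
        cand = (~assigned) & (lens >= o)
        if not cand.any():
            continue
        if direction == "5prime":
            mism = np.count_nonzero(mat[cand, width - o :] != carr[:o], axis=1)
        else:
            mism = np.count_nonzero(mat[cand, :o] != carr[len(contig) - o :], axis=1)
        ok = mism <= (1.0 - min_identity) * o
        idx = np.flatnonzero(cand)[ok]
        for i in idx:
            out.append((int(i), o))
        assigned[idx] = True
    return out


def _project_segment_start(
    contig: str, segments, direction: str, window: int = 260
) -> int | None:
    """Contig coordinate where the best-matching segment's position 0 lands.

    For the 5' phase the segments are V alleles and the window is the
    contig head; for the 3' phase they are C alleles and the window is
    the tail.  Returns None unless a segment aligns confidently *and*
    the alignment itself reaches (within a couple of trimmed terminal
    mismatches) the segment's first base — extrapolating the start from
    a distant alignment is unreliable and a weak random hit must never
    trigger a boundary stop.
    """
    if direction == "5prime":
        query, base = contig[:window], 0
    else:
        base = max(0, len(contig) - window)
        query = contig[base:]
    best, best_key = None, None
    for seg in segments:
        aln = smith_waterman(query, seg.nt_sequence)
        if aln is None:
            continue
        key = (aln.score, aln.identity, seg.allele_id)
        if best is None or (key[0], key[1]) > (best_key[0], best_key[1]) or (
            (key[0], key[1]) == (best_key[0], best_key[1]) and key[2] < best_key[2]
        ):
            best, best_key = aln, key
    if (
        best is None
        or best.identity < PROJECTION_MIN_IDENTITY
        or best.query_span < PROJECTION_MIN_SPAN
        or best.target_start > PROJECTION_MAX_START_OFFSET
    ):
        return None
    return base + best.query_start - best.target_start


@dataclass
class _ExtensionResult:
    contig: str
    added: int  # net columns added on the extension side (after any trim)
    trimmed: int  # columns trimmed off the extension side
    termination: str
    used_reads: list[str]


def extend_contig(
    contig: str,
    pool: list[PoolRead],
    direction: str = "5prime",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_overlap_identity: float = DEFAULT_MIN_OVERLAP_IDENTITY,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    branch_ratio: float = DEFAULT_BRANCH_RATIO,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    boundary_segments=None,
    boundary_cap: int = 0,
) -> _ExtensionResult:
    """Grow the contig in one direction by greedy overlap consensus.

    Each round gathers pool reads overlapping the contig end by at
    least ``min_overlap`` nt at ``min_overlap_identity`` (Hamming, the
    error model being substitution-only) and appends one voted column
    at a time.  Stops on: the projected boundary segment start
    (``v_start_reached`` with V alleles / ``c_cap_reached`` with C
    alleles, trimming any overshoot), no qualifying overlap or vote
    coverage below ``min_coverage`` (``no_overlap``), a tie or a
    runner-up base with support >= ``branch_ratio`` x the winner
    (``ambiguous_branch``), or ``max_iterations`` columns.
    """
    if direction not in ("5prime", "3prime"):
        raise ValueError("direction must be '5prime' or '3prime'")
    seqs = [r.seq for r in pool]
    mat, lens = _pad_matrix(seqs, "right" if direction == "5prime" else "left")
    used: set[int] = set()
    iterations = 0
    termination = None

    def boundary_hit(cur: str):
        """(reached, trimmed_contig, trim_amount) under the boundary rule."""
        if boundary_segments is None:
            return False, cur, 0
        q = _project_segment_start(cur, boundary_segments, direction)
        if q is None:
            return False, cur, 0
        if direction == "5prime":
            if q >= 0:
                return True, cur[q:], q
            return False, cur, 0
        cap_end = q + boundary_cap
        if 0 <= cap_end <= len(cur):
            return True, cur[:cap_end], len(cur) - cap_end
        return False, cur, 0

    trimmed_total = 0
    start_len = len(contig)
    boundary_every = 20  # columns between boundary-projection checks
    since_boundary_check = 0
    while termination is None:
        # (a) boundary check, amortized: overshoot is trimmed on detection
        if boundary_segments is not None and since_boundary_check >= boundary_every:
            since_boundary_check = 0
            reached, contig2, trim = boundary_hit(contig)
            if reached:
                contig = contig2
                trimmed_total += trim
                termination = (
                    "v_start_reached" if direction == "5prime" else "c_cap_reached"
                )
                break
        overlaps = _collect_overlaps(
            mat, lens, contig, direction, min_overlap, min_overlap_identity
        )
        # leading-column vote over the bases overlapping reads contribute
        votes: dict[int, int] = {}
        for i, o in overlaps:
            used.add(i)
            if lens[i] - o < 1:
                continue
            if direction == "5prime":
                b = int(mat[i, mat.shape[1] - o - 1])
            else:
                b = int(mat[i, o])
            votes[b] = votes.get(b, 0) + 1
        cov = sum(votes.values())
        if cov < min_coverage:
            termination = "no_overlap"
            break
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        winner, w = ranked[0]
        if len(ranked) > 1 and (ranked[1][1] == w or ranked[1][1] >= branch_ratio * w):
            termination = "ambiguous_branch"
            break
        ch = chr(winner)
        contig = ch + contig if direction == "5prime" else contig + ch
        iterations += 1
        since_boundary_check += 1
        if iterations >= max_iterations:
            termination = "max_iterations"
            break
    # final boundary check: the stop may coincide with (or overshoot) the
    # projected segment start
    if boundary_segments is not None and termination in (
        "no_overlap", "ambiguous_branch", "max_iterations",
    ):
        reached, contig2, trim = boundary_hit(contig)
        if reached:
            contig = contig2
            trimmed_total += trim
            termination = (
                "v_start_reached" if direction == "5prime" else "c_cap_reached"
            )
    added = len(contig) - start_len
    return _ExtensionResult(
        contig=contig,
        added=added,
        trimmed=trimmed_total,
        termination=termination,
        used_reads=[pool[i].read_id for i in sorted(used)],
    )


# ---------------------------------------------------------------------------
# Polish + full reconstruction


def _cigar_walk(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def polish_contig(
    contig: str,
    pool: list[PoolRead],
    min_identity: float = POLISH_MIN_IDENTITY,
) -> tuple[str, np.ndarray, np.ndarray, list[str]]:
    """One round of re-mapping all pool reads and majority-voting.

    Returns the polished contig with per-position coverage and
    agreement (fraction of covering reads matching the consensus base).
    Positions no read covers keep the input base with coverage counted
    as the contig's own evidence (1).
    """
    n = len(contig)
    counts = np.zeros((n, 4), dtype=np.int64)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mapped: list[str] = []
    for read in pool:
        if len(read.seq) > n:
            continue
        res = edlib.align(read.seq, contig, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        if 1.0 - res["editDistance"] / len(read.seq) < min_identity:
            continue
        t = res["locations"][0][0]
        q = 0
        for ln, op in _cigar_walk(res["cigar"]):
            if op in ("=", "X", "M"):
                for k in range(ln):
                    b = read.seq[q + k]
                    if b in base_idx:
                        counts[t + k, base_idx[b]] += 1
                q += ln
                t += ln
            elif op == "I":
                q += ln
            elif op == "D":
                t += ln
        mapped.append(read.read_id)
    order = "ACGT"
    out = []
    coverage = np.zeros(n, dtype=np.int64)
    agreement = np.zeros(n, dtype=float)
    for i in range(n):
        cov = int(counts[i].sum())
        if cov == 0:
            out.append(contig[i])
            coverage[i] = 1
            agreement[i] = 1.0
            continue
        top = int(counts[i].argmax())
        out.append(order[top])
        coverage[i] = cov
        agreement[i] = counts[i, top] / cov
    return "".join(out), coverage, agreement, mapped


def reconstruct_chain(
    reads: list[SeqRead] | list[PoolRead],
    target_junction: str,
    germline: GermlineSet,
    locus: str | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_overlap_identity: float = DEFAULT_MIN_OVERLAP_IDENTITY,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    branch_ratio: float = DEFAULT_BRANCH_RATIO,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    seed_max_mismatches: int = 0,
    c_cap: int = DEFAULT_C_CAP,
    filter_min_identity: float = 0.80,
    filter_mode: str = "identity",
    prefiltered: bool = False,
) -> AssembledChain:
    """Full reconstruction: filter -> seed -> extend 5' then 3' -> polish.

    Raises :class:`AssemblyError` with reason ``no_vdj_reads`` or
    ``no_seed_reads`` when the pool or the seed set is empty; all other
    outcomes (including partial contigs) are returned with their
    termination reasons.
    """
    if prefiltered:
        pool = list(reads)  # type: ignore[arg-type]
    else:
        pool = filter_vdj_reads(
            reads, germline, min_identity=filter_min_identity, mode=filter_mode
        )
    if not pool:
        raise AssemblyError("no_vdj_reads")
    seeds = find_seeds(pool, target_junction, seed_max_mismatches)
    by_id = {r.read_id: r for r in pool}
    seed = seeds[0]
    contig = by_id[seed.read_id].seq
    junction_start = seed.offset
    junction_len = len(target_junction)

    v_segments = germline.alleles("V", locus)
    c_segments = germline.alleles("C", locus)
    res5 = extend_contig(
        contig, pool, "5prime",
        min_overlap, min_overlap_identity, min_coverage, branch_ratio,
        max_iterations, boundary_segments=v_segments,
    )
    junction_start += res5.added
    contig = res5.contig
    res3 = extend_contig(
        contig, pool, "3prime",
        min_overlap, min_overlap_identity, min_coverage, branch_ratio,
        max_iterations, boundary_segments=c_segments or None, boundary_cap=c_cap,
    )
    contig = res3.contig

    polished, coverage, agreement, mapped = polish_contig(
        contig, pool
    )
    frame = junction_start % 3
    protein = translate(polished[frame:])
    supporting = sorted(set(res5.used_reads) | set(res3.used_reads) | set(mapped))
    return AssembledChain(
        target_junction=target_junction,
        contig_nt=polished,
        coverage=coverage,
        agreement=agreement,
        reading_frame=frame,
        junction_interval=(junction_start, junction_start + junction_len),
        v_start_reached=res5.termination == "v_start_reached",
        termination_reason=res5.termination,
        termination_reason_3prime=res3.termination,
        supporting_reads=supporting,
        protein=protein,
    )
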