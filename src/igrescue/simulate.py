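"""Synthetic repertoire, FFPE fragmentation and read simulation.

Emulates the data regime the pipeline is built for: an antibody
repertoire dominated by one strongly expanded, class-switched and
heavily hypermutated IgG clone, expressed in archival (FFPE) tissue
whose RNA is fragmented to mostly sub-200-nt pieces (the DV200≈50%
regime) and carries a low residual C→T deamination artifact.

Two library types are produced:

* **Ig-seq** — constant-region-primed amplicons with a template-switch
  (TSO) tail, read paired-end so that the downstream mate crosses the
  V(D)J junction;
* **RNA-seq** — reads from randomly fragmented whole transcripts.

Every read is traceable to its source clone through a
:class:`SimTruth` sidecar, so pipeline output can be scored exactly.
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import revcomp
from .germline import (
    STOP_FREE_CODONS,
    GermlineSegment,
    GermlineSet,
    translate,
)

TSO_TAIL = "AAGCAGTGGTATCAACGCAGAGTACATGGG"
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_UTR_LEN = 60


class SimulationError(ValueError):
    pass


def load_primers(path: str | Path | None = None, pool: str = "rt") -> dict[str, str]:
    """Load a primer pool (name → sequence) from a TSV (default: bundled set)."""
    if path is None:
        ref = importlib.resources.files("igrescue") / "_data" / "primers.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    out = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        if row["pool"] == pool:
            out[row["name"]] = row["sequence"]
    return out


@dataclass
class Clone:
    """One chain-level B-cell clone with its recombined, mutated transcript."""

    clone_id: str
    locus: str
    v_allele: str
    j_allele: str
    c_allele: str
    junction_nt: str
    shm_events: list[tuple[int, str, str]]
    frequency: float
    full_transcript_nt: str
    # transcript geometry (0-based, half-open)
    utr_len: int = DEFAULT_UTR_LEN
    v_interval: tuple[int, int] = (0, 0)
    junction_interval: tuple[int, int] = (0, 0)
    j_interval: tuple[int, int] = (0, 0)
    c_interval: tuple[int, int] = (0, 0)

    @property
    def variable_region_nt(self) -> str:
        """V start (leader included) through the junction end."""
        return self.full_transcript_nt[
            self.v_interval[0] : self.junction_interval[1]
        ]


@dataclass
class SeqRead:
    read_id: str
    seq: str
    qual: str = ""

    def __post_init__(self) -> None:
        if not self.qual:
            self.qual = "I" * len(self.seq)


@dataclass
class Fragment:
    frag_id: str
    clone_id: str
    start: int  # offset on the clone transcript
    seq: str  # sense strand, damage applied


@dataclass
class SimTruth:
    """Ground truth emitted beside every synthetic dataset."""

    clones: list[Clone]
    origin: dict[str, tuple[str, int, str]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def clone(self, clone_id: str) -> Clone:
        for c in self.clones:
            if c.clone_id == clone_id:
                return c
        raise KeyError(clone_id)

    def write(self, out_dir: str | Path, prefix: str = "truth") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"{prefix}_clones.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                ["clone_id", "locus", "v_allele", "j_allele", "c_allele",
                 "frequency", "junction_nt", "n_shm", "full_transcript_nt"]
            )
            for c in self.clones:
                w.writerow(
                    [c.clone_id, c.locus, c.v_allele, c.j_allele, c.c_allele,
                     f"{c.frequency:.10g}", c.junction_nt, len(c.shm_events),
                     c.full_transcript_nt]
                )
        with open(out / f"{prefix}_origin.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["read_id", "clone_id", "offset", "strand"])
            for rid, (cid, off, strand) in self.origin.items():
                w.writerow([rid, cid, off, strand])
        with open(out / f"{prefix}_params.json", "w") as fh:
            json.dump(self.params, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


@dataclass
class FragmentModel:
    """FFPE fragment-length and damage model.

    Lengths are log-normal, truncated to ``[min_len, max_len]`` by
    redraw; defaults put the median at 200 nt so roughly half the
    fragments exceed 200 nt (DV200 ≈ 50%).  ``damage_rate`` is the
    per-base probability of the deamination artifact (C→T on the sense
    strand, seen as G→A on the antisense strand).
    """

    meanlog: float = float(np.log(200.0))
    sdlog: float = 0.6
    min_len: int = 40
    max_len: int = 500
    damage_rate: float = 0.002
    three_prime_bias: float = 0.0  # probability a fragment is forced into the 3' window

    def __post_init__(self) -> None:
        if not 0 <= self.damage_rate <= 1 or not 0 <= self.three_prime_bias <= 1:
            raise SimulationError("rates must lie in [0, 1]")
        if self.min_len < 20 or self.max_len < self.min_len:
            raise SimulationError("fragment length bounds invalid")

    def sample_lengths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n, dtype=np.int64)
        need = np.arange(n)
        while need.size:
            draw = np.rint(rng.lognormal(self.meanlog, self.sdlog, need.size))
            ok = (draw >= self.min_len) & (draw <= self.max_len)
            out[need[ok]] = draw[ok].astype(np.int64)
            need = need[~ok]
        return out


# ---------------------------------------------------------------------------
# Repertoire construction


def _apply_substitution_errors(
    seq: str, error_rate: float, rng: np.random.Generator
) -> str:
    if error_rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.where(rng.random(arr.size) < error_rate)[0]
    for i in hit:
        alts = BASES[BASES != arr[i]]
        arr[i] = alts[rng.integers(0, len(alts))]
    return arr.tobytes().decode()


def _shm_allowed_positions(
    v: GermlineSegment, j: GermlineSegment, utr_len: int, ins_len: int
) -> list[int]:
    """Transcript positions eligible for SHM.

    The junction (V anchor .. J anchor) is excluded — it is clone-
    specific already — as are the conserved FR3 Tyr-Tyr codons before
    the V anchor and the WG / FGxG codons after the J anchor, which are
    structurally constrained in real repertoires and are the guideposts
    the seed search relies on.
    """
    assert v.anchor_pos is not None and j.anchor_pos is not None
    v_off = utr_len
    j_off = utr_len + len(v.nt_sequence) + ins_len
    allowed = list(range(v_off, v_off + v.anchor_pos - 6))
    guard = 3 if v.locus == "IGH" else 9  # G of WG / G-x-G of FGxG
    allowed.extend(
        range(j_off + j.anchor_pos + 3 + guard, j_off + len(j.nt_sequence))
    )
    return allowed


def _has_inframe_stop(transcript: str, orf_start: int, c_start: int) -> bool:
    coding = transcript[orf_start:c_start]
    return "*" in translate(coding)


def make_clone(
    germline: GermlineSet,
    locus: str,
    v_allele: str,
    j_allele: str,
    c_allele: str,
    clone_id: str,
    frequency: float,
    rng: np.random.Generator,
    insert_codons: int = 8,
    shm_rate: float = 0.0,
    n_nonsilent_shm: int | None = None,
    utr_len: int = DEFAULT_UTR_LEN,
) -> Clone:
    """Build one clone: recombine V + junction insert + J + C, apply SHM.

    ``n_nonsilent_shm`` plants exactly that many single-nucleotide,
    amino-acid-changing mutations at distinct codons of the mature V
    region (overrides ``shm_rate``); otherwise SHM positions are drawn
    per-base at ``shm_rate`` over the eligible V+J positions.
    """
    v, j, c = germline[v_allele], germline[j_allele], germline[c_allele]
    assert v.anchor_pos is not None and j.anchor_pos is not None
    idx = rng.integers(0, len(STOP_FREE_CODONS), size=insert_codons)
    insert = "".join(STOP_FREE_CODONS[i] for i in idx)
    utr = "".join("ACGT"[i] for i in rng.integers(0, 4, size=utr_len))
    ins_len = len(insert)
    germ_transcript = utr + v.nt_sequence + insert + j.nt_sequence + c.nt_sequence
    v_start = utr_len
    v_end = utr_len + len(v.nt_sequence)
    j_start = v_end + ins_len
    j_end = j_start + len(j.nt_sequence)
    c_start = j_end
    junction_start = utr_len + v.anchor_pos
    junction_end = j_start + j.anchor_pos + 3

    arr = list(germ_transcript)
    events: list[tuple[int, str, str]] = []
    if n_nonsilent_shm is not None:
        mature_start = v_start + 45  # past the leader
        codon_starts = np.arange(mature_start, v_start + v.anchor_pos - 9, 3)
        if n_nonsilent_shm > codon_starts.size:
            raise SimulationError("too many SHMs requested for V length")
        chosen = rng.choice(codon_starts, size=n_nonsilent_shm, replace=False)
        for cs in sorted(int(x) for x in chosen):
            codon = "".join(arr[cs : cs + 3])
            aa = translate(codon)
            placed = False
            for off in rng.permutation(3):
                for b in rng.permutation(4):
                    alt = "ACGT"[b]
                    if alt == codon[off]:
                        continue
                    new = codon[:off] + alt + codon[off + 1 :]
                    new_aa = translate(new)
                    if new_aa != aa and new_aa != "*":
                        events.append((cs + off, codon[off], alt))
                        arr[cs + off] = alt
                        placed = True
                        break
                if placed:
                    break
            if not placed:  # pragma: no cover - every codon has a nonsilent alt
                raise SimulationError(f"no nonsilent substitution at codon {cs}")
    elif shm_rate > 0:
        for pos in _shm_allowed_positions(v, j, utr_len, ins_len):
            if rng.random() >= shm_rate:
                continue
            ref = arr[pos]
            for b in rng.permutation(4):
                alt = "ACGT"[b]
                if alt == ref:
                    continue
                arr[pos] = alt
                if not _has_inframe_stop("".join(arr), v_start, c_start):
                    events.append((pos, ref, alt))
                    break
                arr[pos] = ref

    transcript = "".join(arr)
    return Clone(
        clone_id=clone_id,
        locus=locus,
        v_allele=v_allele,
        j_allele=j_allele,
        c_allele=c_allele,
        junction_nt=transcript[junction_start:junction_end],
        shm_events=events,
        frequency=frequency,
        full_transcript_nt=transcript,
        utr_len=utr_len,
        v_interval=(v_start, v_end),
        junction_interval=(junction_start, junction_end),
        j_interval=(j_start, j_end),
        c_interval=(c_start, len(transcript)),
    )


def simulate_repertoire(
    germline: GermlineSet,
    n_clones: int,
    dominance: float,
    shm_rate: float = 0.02,
    junction_len_range: tuple[int, int] = (24, 48),
    seed: int = 0,
    locus: str = "IGH",
    power_exponent: float = 1.0,
    dominant_nonsilent_shm: int | None = None,
) -> list[Clone]:
    """Simulate a chain-level repertoire with one dominant clone.

    Clone 1 takes frequency ``dominance``; the remaining mass is split
    over the background clones by a discrete power law (frequency of
    rank *r* proportional to ``r**-power_exponent``).  The dominant
    heavy clone is class-switched (IgG constant region); junction
    insert lengths are drawn so the junction stays in frame within
    ``junction_len_range`` (nt, anchor-inclusive).
    """
    if not 0 < dominance <= 1:
        raise SimulationError("dominance must lie in (0, 1]")
    if n_clones < 1:
        raise SimulationError("n_clones must be >= 1")
    if n_clones == 1 and dominance < 1:
        raise SimulationError(
            "n_clones=1 requires dominance=1 (no background to carry the rest)"
        )
    if n_clones > 1 and dominance == 1:
        raise SimulationError("dominance=1 leaves no mass for background clones")
    lo, hi = junction_len_range
    lo_c, hi_c = max(0, (lo - 18 + 2) // 3), (hi - 18) // 3
    if hi_c < lo_c:
        raise SimulationError(f"junction_len_range {junction_len_range} too narrow")

    rng = np.random.default_rng(seed)
    freqs = [dominance]
    if n_clones > 1:
        ranks = np.arange(1, n_clones, dtype=float)
        w = ranks ** (-power_exponent)
        freqs.extend((1.0 - dominance) * w / w.sum())

    v_ids = [s.allele_id for s in germline.alleles("V", locus)]
    j_ids = [s.allele_id for s in germline.alleles("J", locus)]
    c_ids = [s.allele_id for s in germline.alleles("C", locus)]
    igg = [c for c in c_ids if c.startswith("IGHG")]

    clones: list[Clone] = []
    seen_junctions: set[str] = set()
    for r, freq in enumerate(freqs, start=1):
        if locus == "IGH":
            c_allele = (igg[0] if igg else c_ids[0]) if r == 1 else (
                c_ids[rng.integers(0, len(c_ids))]
            )
        else:
            c_allele = c_ids[rng.integers(0, len(c_ids))]
        for _attempt in range(50):
            clone = make_clone(
                germline,
                locus,
                v_ids[int(rng.integers(0, len(v_ids)))],
                j_ids[int(rng.integers(0, len(j_ids)))],
                c_allele,
                clone_id=f"{locus}_clone{r:03d}",
                frequency=float(freq),
                rng=rng,
                insert_codons=int(rng.integers(lo_c, hi_c + 1)),
                shm_rate=shm_rate if dominant_nonsilent_shm is None or r > 1 else 0.0,
                n_nonsilent_shm=dominant_nonsilent_shm if r == 1 else None,
            )
            if clone.junction_nt not in seen_junctions:
                break
        seen_junctions.add(clone.junction_nt)
        clones.append(clone)
    total = sum(c.frequency for c in clones)
    assert abs(total - 1.0) < 1e-9
    return clones


# ---------------------------------------------------------------------------
# Fragmentation / damage (FFPE model)


def _damage(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    cs = np.where(arr == ord("C"))[0]
    hit = cs[rng.random(cs.size) < rate]
    arr[hit] = ord("T")
    return arr.tobytes().decode()


def fragment_and_damage(
    clones: list[Clone],
    model: FragmentModel,
    n_fragments: int,
    seed: int = 0,
) -> tuple[list[Fragment], SimTruth]:
    """Fragment clone transcripts and apply the deamination artifact.

    Fragments are drawn from clones proportional to clone frequency;
    each fragment's length comes from the model's truncated log-normal
    (clipped at the transcript if the transcript is shorter).  The
    empirical DV200 (fraction of fragments > 200 nt) is reported in the
    truth parameters.
    """
    if n_fragments < 1:
        raise SimulationError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = np.array([c.frequency for c in clones])
    picks = rng.choice(len(clones), size=n_fragments, p=freqs / freqs.sum())
    lengths = model.sample_lengths(n_fragments, rng)
    frags: list[Fragment] = []
    truth = SimTruth(clones=clones)
    for i, (ci, ln) in enumerate(zip(picks, lengths)):
        clone = clones[ci]
        t = clone.full_transcript_nt
        ln = int(min(ln, len(t)))
        if model.three_prime_bias and rng.random() < model.three_prime_bias:
            lo = max(0, len(t) - ln - int(rng.integers(0, max(1, ln // 2))))
            start = int(min(lo, len(t) - ln))
        else:
            start = int(rng.integers(0, len(t) - ln + 1))
        seq = _damage(t[start : start + ln], model.damage_rate, rng)
        fid = f"frag{i:07d}"
        frags.append(Fragment(fid, clone.clone_id, start, seq))
        truth.origin[fid] = (clone.clone_id, start, "+")
    dv200 = float(np.mean([len(f.seq) > 200 for f in frags]))
    truth.params = {
        "n_fragments": n_fragments,
        "seed": seed,
        "dv200": dv200,
        "damage_rate": model.damage_rate,
        "meanlog": model.meanlog,
        "sdlog": model.sdlog,
        "min_len": model.min_len,
        "max_len": model.max_len,
    }
    return frags, truth


# ---------------------------------------------------------------------------
# Read generation


def _amplicon(clone: Clone, primers: dict[str, str]) -> str | None:
    """Constant-region-primed, template-switched amplicon (sense strand).

    The RT primer anneals inside the constant region; the cDNA spans
    from the primer site to the transcript 5' end where the TSO tail is
    appended.  Returns None when no primer of the pool matches the
    clone's constant region.
    """
    c_start, _ = clone.c_interval
    c_seq = clone.full_transcript_nt[c_start:]
    for _name, pseq in sorted(primers.items()):
        at = c_seq.find(pseq)
        if at >= 0:
            end = c_start + at + len(pseq)
            return TSO_TAIL + clone.full_transcript_nt[:end]
    return None


def make_igseq_reads(
    clones: list[Clone],
    primers: dict[str, str] | None = None,
    n_reads: int = 10000,
    read_len: int = 150,
    error_rate: float = 0.005,
    seed: int = 0,
) -> tuple[list[SeqRead], list[SeqRead], SimTruth]:
    """Paired-end Ig-seq reads: R1 from the TSO end, R2 from the primer end.

    ``n_reads`` counts read *pairs*, sampled over clones proportional to
    frequency; substitution errors are i.i.d. at ``error_rate``.  Clones
    whose constant region contains no primer site are skipped with a
    warning recorded in the truth parameters.
    """
    import warnings

    if primers is None:
        primers = load_primers()
    rng = np.random.default_rng(seed)
    amplicons, usable, skipped = {}, [], []
    for clone in clones:
        amp = _amplicon(clone, primers)
        if amp is None:
            skipped.append(clone.clone_id)
            warnings.warn(
                f"clone {clone.clone_id}: no primer site in constant region; skipped"
            )
        else:
            amplicons[clone.clone_id] = amp
            usable.append(clone)
    if not usable:
        raise SimulationError("no clone has a primer binding site")
    freqs = np.array([c.frequency for c in usable])
    picks = rng.choice(len(usable), size=n_reads, p=freqs / freqs.sum())
    r1s, r2s = [], []
    truth = SimTruth(clones=clones)
    for i, ci in enumerate(picks):
        clone = usable[ci]
        amp = amplicons[clone.clone_id]
        base = f"ig{i:06d}"
        r1 = _apply_substitution_errors(amp[:read_len], error_rate, rng)
        r2 = _apply_substitution_errors(
            revcomp(amp)[:read_len], error_rate, rng
        )
        r1s.append(SeqRead(f"{base}/1", r1))
        r2s.append(SeqRead(f"{base}/2", r2))
        truth.origin[f"{base}/1"] = (clone.clone_id, 0, "+")
        truth.origin[f"{base}/2"] = (clone.clone_id, len(amp) - len(r2), "-")
    truth.params = {
        "n_reads": n_reads,
        "read_len": read_len,
        "error_rate": error_rate,
        "seed": seed,
        "skipped_clones": skipped,
    }
    return r1s, r2s, truth


def make_rnaseq_reads(
    fragments: list[Fragment],
    read_len: int = 150,
    paired: bool = True,
    error_rate: float = 0.005,
    seed: int = 0,
    truth_clones: list[Clone] | None = None,
) -> tuple[list[SeqRead], list[SeqRead] | None, SimTruth]:
    """Whole-transcriptome reads from fragments, both strands emitted.

    Paired mode reads the two fragment ends inward (insert size = the
    fragment length); single mode emits one read from the 5' end of a
    uniformly chosen strand.  Reads are truncated, never padded, when a
    fragment is shorter than ``read_len``.
    """
    rng = np.random.default_rng(seed)
    r1s: list[SeqRead] = []
    r2s: list[SeqRead] = []
    truth = SimTruth(clones=truth_clones or [])
    for i, frag in enumerate(fragments):
        strand = "+" if rng.random() < 0.5 else "-"
        fwd = frag.seq if strand == "+" else revcomp(frag.seq)
        base = f"rna{i:07d}"
        r1 = _apply_substitution_errors(fwd[:read_len], error_rate, rng)
        r1s.append(SeqRead(f"{base}/1" if paired else base, r1))
        truth.origin[f"{base}/1" if paired else base] = (
            frag.clone_id, frag.start, strand,
        )
        if paired:
            r2 = _apply_substitution_errors(
                revcomp(fwd)[:read_len], error_rate, rng
            )
            r2s.append(SeqRead(f"{base}/2", r2))
            truth.origin[f"{base}/2"] = (frag.clone_id, frag.start, strand)
    truth.params = {
        "read_len": read_len,
        "paired": paired,
        "error_rate": error_rate,
        "seed": seed,
    }
    return r1s, (r2s if paired else None), truth
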