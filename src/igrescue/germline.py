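"""Germline V/J/C segment references with junction-anchor annotations.

The downstream stages key on two structural guideposts of antibody
variable regions: the 2nd conserved cysteine at the 3' end of the V
segment (IMGT position 104) and the conserved tryptophan (heavy) or
phenylalanine (light) of the J segment (IMGT 118).  The *junction* is
the anchor-inclusive span C..W/F; *CDR3* excludes both anchor codons.
Each reference segment therefore carries, besides its sequence, the
0-based nucleotide index of its anchor codon and the reading frame of
codon 1.

References are loaded from a plain FASTA plus a TSV sidecar
(``allele_id, locus, class, frame, anchor_pos, motif``).  A seeded toy
generator emits a complete, invariant-satisfying reference set (with a
CDR-boundary scheme table) so the whole pipeline runs without any
database download.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

LOCI = ("IGH", "IGK", "IGL")
SEGMENT_CLASSES = ("V", "J", "C")

STOP_FREE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


class GermlineError(ValueError):
    pass


def translate(nt: str) -> str:
    """Translate a nucleotide string (trailing partial codon dropped)."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


@dataclass(frozen=True)
class GermlineSegment:
    """One reference allele of a V, J or C gene segment."""

    allele_id: str
    locus: str
    segment_class: str
    nt_sequence: str
    reading_frame: int = 0
    anchor_pos: int | None = None
    anchor_motif_aa: str = ""

    def validate(self) -> None:
        if self.locus not in LOCI:
            raise GermlineError(f"{self.allele_id}: unknown locus {self.locus!r}")
        if self.segment_class not in SEGMENT_CLASSES:
            raise GermlineError(
                f"{self.allele_id}: unknown segment class {self.segment_class!r}"
            )
        if not self.nt_sequence or set(self.nt_sequence) - set("ACGT"):
            raise GermlineError(
                f"{self.allele_id}: sequence must be non-empty uppercase ACGT"
            )
        if self.reading_frame not in (0, 1, 2):
            raise GermlineError(f"{self.allele_id}: reading_frame must be 0-2")
        if self.segment_class == "C":
            return
        if self.anchor_pos is None:
            raise GermlineError(f"{self.allele_id}: V/J segment needs anchor_pos")
        if not 0 <= self.anchor_pos <= len(self.nt_sequence) - 3:
            raise GermlineError(f"{self.allele_id}: anchor_pos out of bounds")
        if (self.anchor_pos - self.reading_frame) % 3 != 0:
            raise GermlineError(
                f"{self.allele_id}: anchor_pos not on a codon boundary "
                f"in the declared frame"
            )
        aa = translate(self.anchor_codon)
        if self.segment_class == "V":
            if aa != "C":
                raise GermlineError(
                    f"{self.allele_id}: V anchor codon translates to {aa}, not C"
                )
        else:
            if self.locus == "IGH":
                if aa != "W":
                    raise GermlineError(
                        f"{self.allele_id}: heavy J anchor translates to {aa}, not W"
                    )
                nxt = translate(
                    self.nt_sequence[self.anchor_pos + 3 : self.anchor_pos + 6]
                )
                if nxt != "G":
                    raise GermlineError(
                        f"{self.allele_id}: heavy J anchor not followed by G (WG)"
                    )
            else:
                if aa != "F":
                    raise GermlineError(
                        f"{self.allele_id}: light J anchor translates to {aa}, not F"
                    )
                run = translate(
                    self.nt_sequence[self.anchor_pos : self.anchor_pos + 12]
                )
                if len(run) < 4 or run[1] != "G" or run[3] != "G":
                    raise GermlineError(
                        f"{self.allele_id}: light J anchor does not begin an "
                        f"F-G-x-G run (got {run!r})"
                    )

    @property
    def anchor_codon(self) -> str:
        assert self.anchor_pos is not None
        return self.nt_sequence[self.anchor_pos : self.anchor_pos + 3]


@dataclass
class CdrScheme:
    """Per-allele CDR1/CDR2 nucleotide intervals on the germline V allele."""

    intervals: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def for_allele(self, allele_id: str) -> dict[str, tuple[int, int]]:
        if allele_id not in self.intervals:
            raise GermlineError(f"no CDR scheme for allele {allele_id}")
        return self.intervals[allele_id]


@dataclass
class GermlineSet:
    """A validated collection of germline segments with a locus/class index."""

    segments: list[GermlineSegment]
    cdr_scheme: CdrScheme = field(default_factory=CdrScheme)

    def __post_init__(self) -> None:
        ids = [s.allele_id for s in self.segments]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GermlineError(f"duplicate allele ids: {dup}")
        self.index: dict[str, dict[str, list[GermlineSegment]]] = {}
        self._by_id: dict[str, GermlineSegment] = {}
        for seg in self.segments:
            self.index.setdefault(seg.locus, {}).setdefault(
                seg.segment_class, []
            ).append(seg)
            self._by_id[seg.allele_id] = seg
        for locus, classes in self.index.items():
            if "V" not in classes or "J" not in classes:
                raise GermlineError(
                    f"locus {locus} must have at least one V and one J segment"
                )

    def __getitem__(self, allele_id: str) -> GermlineSegment:
        return self._by_id[allele_id]

    def __contains__(self, allele_id: str) -> bool:
        return allele_id in self._by_id

    def alleles(self, segment_class: str, locus: str | None = None):
        out = []
        for loc, classes in sorted(self.index.items()):
            if locus is not None and loc != locus:
                continue
            out.extend(classes.get(segment_class, []))
        return out

    @property
    def loci(self) -> list[str]:
        return sorted(self.index)


# ---------------------------------------------------------------------------
# I/O


def load_germline(
    fasta_path: str | Path,
    annotation_path: str | Path,
    scheme_path: str | Path | None = None,
) -> GermlineSet:
    """Load a germline set from FASTA + annotation TSV (+ optional CDR scheme).

    Every FASTA record must have an annotation row; records whose anchor
    fails its structural invariant raise :class:`GermlineError` naming
    the record.
    """
    from Bio import SeqIO

    ann: dict[str, dict[str, str]] = {}
    with open(annotation_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            ann[row["allele_id"]] = row
    segments = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in ann:
            raise GermlineError(f"no annotation for FASTA record {rec.id!r}")
        row = ann[rec.id]
        anchor = row.get("anchor_pos", "")
        seg = GermlineSegment(
            allele_id=rec.id,
            locus=row["locus"],
            segment_class=row["class"],
            nt_sequence=str(rec.seq).upper(),
            reading_frame=int(row["frame"]),
            anchor_pos=int(anchor) if anchor not in ("", "-1", ".") else None,
            anchor_motif_aa=row.get("motif", ""),
        )
        seg.validate()
        segments.append(seg)
    scheme = CdrScheme()
    if scheme_path is not None:
        with open(scheme_path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                scheme.intervals[row["allele_id"]] = {
                    "CDR1": (int(row["cdr1_start"]), int(row["cdr1_end"])),
                    "CDR2": (int(row["cdr2_start"]), int(row["cdr2_end"])),
                }
    return GermlineSet(segments, scheme)


def write_germline(
    gset: GermlineSet, fasta_path: str | Path, annotation_path: str | Path,
    scheme_path: str | Path | None = None,
) -> None:
    with open(fasta_path, "w") as fa:
        for seg in gset.segments:
            fa.write(f">{seg.allele_id}\n{seg.nt_sequence}\n")
    with open(annotation_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["allele_id", "locus", "class", "frame", "anchor_pos", "motif"])
        for seg in gset.segments:
            w.writerow(
                [
                    seg.allele_id,
                    seg.locus,
                    seg.segment_class,
                    seg.reading_frame,
                    seg.anchor_pos if seg.anchor_pos is not None else "",
                    seg.anchor_motif_aa,
                ]
            )
    if scheme_path is not None:
        with open(scheme_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                ["allele_id", "cdr1_start", "cdr1_end", "cdr2_start", "cdr2_end"]
            )
            for allele_id in sorted(gset.cdr_scheme.intervals):
                iv = gset.cdr_scheme.intervals[allele_id]
                w.writerow(
                    [allele_id, *iv["CDR1"], *iv["CDR2"]]
                )


# ---------------------------------------------------------------------------
# Toy reference generator

# primer binding sites embedded in the toy constant regions, one per
# isotype class; sequences follow the constant-region-primed library
# design (RT primer pool)
TOY_C_PRIMER_SITES = {
    "IGHG1*01": "AGAGGTGCTCTTGGAGC",
    "IGHM*01": "GGGAATTCTCACAGGAG",
    "IGKC*01": "CACACAACAGAGGCAG",
    "IGLC1*01": "CACCAGTGTGGCCTTG",
}

# toy V layout (nt, all multiples of 3): leader | FR1 | CDR1 | FR2 | CDR2 | FR3
TOY_V_LAYOUT = {"leader": 45, "FR1": 75, "CDR1": 24, "FR2": 51, "CDR2": 24, "FR3": 81}
TOY_C_PRIMER_OFFSET = 25


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(STOP_FREE_CODONS), size=n_codons)
    return "".join(STOP_FREE_CODONS[i] for i in idx)


def _toy_v(rng: np.random.Generator, v_len: int) -> tuple[str, dict]:
    if v_len % 3 or v_len < sum(TOY_V_LAYOUT.values()):
        raise GermlineError(
            f"toy V length must be a multiple of 3 and >= "
            f"{sum(TOY_V_LAYOUT.values())} nt, got {v_len}"
        )
    extra = v_len - sum(TOY_V_LAYOUT.values())  # absorbed into FR3
    body = _random_orf(rng, v_len // 3 - 3)
    # FR3 ends in the conserved Tyr-Tyr-Cys motif; anchor = the Cys codon
    seq = body + "TATTAC" + "TGT"
    lay = dict(TOY_V_LAYOUT)
    lay["FR3"] += extra
    cdr1_start = lay["leader"] + lay["FR1"]
    cdr2_start = cdr1_start + lay["CDR1"] + lay["FR2"]
    meta = {
        "anchor_pos": v_len - 3,
        "cdr1": (cdr1_start, cdr1_start + lay["CDR1"]),
        "cdr2": (cdr2_start, cdr2_start + lay["CDR2"]),
        "leader_len": lay["leader"],
    }
    return seq, meta


def _toy_j(rng: np.random.Generator, locus: str, j_len: int) -> tuple[str, int]:
    tail_len, fr4_len = 12, j_len - 15
    if j_len % 3 or fr4_len < 9:
        raise GermlineError(
            f"toy J length must be a multiple of 3 and >= 24 nt, got {j_len}"
        )
    tail = _random_orf(rng, tail_len // 3)
    if locus == "IGH":
        # W anchor followed by G (the conserved "WG")
        fr4 = "GGC" + _random_orf(rng, fr4_len // 3 - 1)
        return tail + "TGG" + fr4, tail_len
    # light chains: anchor F begins an F-G-x-G run
    fr4 = "GGC" + _random_orf(rng, 1) + "GGC" + _random_orf(rng, fr4_len // 3 - 3)
    return tail + "TTC" + fr4, tail_len


def _toy_c(rng: np.random.Generator, allele_id: str, c_len: int) -> str:
    site = TOY_C_PRIMER_SITES.get(allele_id, "")
    if c_len < TOY_C_PRIMER_OFFSET + len(site) + 20:
        raise GermlineError(f"toy C length {c_len} too short for primer site")
    n = c_len - len(site)
    body = _random_orf(rng, -(-n // 3))[:n]
    return body[:TOY_C_PRIMER_OFFSET] + site + body[TOY_C_PRIMER_OFFSET:]


DEFAULT_LOCUS_SPEC = {
    "IGH": {"n_v": 4, "n_j": 2, "c_alleles": ["IGHG1*01", "IGHM*01"]},
    "IGK": {"n_v": 3, "n_j": 2, "c_alleles": ["IGKC*01"]},
    "IGL": {"n_v": 2, "n_j": 2, "c_alleles": ["IGLC1*01"]},
}

TOY_V_NAMES = {
    "IGH": ["IGHV3-9*01", "IGHV1-2*01", "IGHV4-34*01", "IGHV5-51*01",
            "IGHV3-23*01", "IGHV2-5*01"],
    "IGK": ["IGKV1-6*01", "IGKV3-20*01", "IGKV2-28*01", "IGKV1-39*01"],
    "IGL": ["IGLV1-44*01", "IGLV2-14*01", "IGLV3-21*01"],
}


def make_toy_germline(
    locus_spec: dict | None = None,
    seed: int = 0,
    v_len: int = 300,
    j_len: int = 45,
    c_len: int = 160,
    out_dir: str | Path | None = None,
) -> GermlineSet:
    """Generate a deterministic, invariant-satisfying toy germline set.

    Anchors and conserved motifs (YYC, WG, FGxG) are planted by
    construction; V alleles carry a 45-nt leader so that "V start"
    means the start of the annotated germline segment.  When
    ``out_dir`` is given the FASTA/annotation/scheme files are written
    there and round-trip through :func:`load_germline`.
    """
    spec = locus_spec or DEFAULT_LOCUS_SPEC
    rng = np.random.default_rng(seed)
    segments: list[GermlineSegment] = []
    scheme = CdrScheme()
    for locus in sorted(spec):
        cfg = spec[locus]
        v_names = TOY_V_NAMES.get(locus, [])
        for k in range(cfg["n_v"]):
            name = v_names[k] if k < len(v_names) else f"{locus}V9-{k}*01"
            seq, meta = _toy_v(rng, cfg.get("v_len", v_len))
            segments.append(
                GermlineSegment(name, locus, "V", seq, 0, meta["anchor_pos"], "YYC")
            )
            scheme.intervals[name] = {"CDR1": meta["cdr1"], "CDR2": meta["cdr2"]}
        for k in range(cfg["n_j"]):
            seq, anchor = _toy_j(rng, locus, cfg.get("j_len", j_len))
            motif = "WG" if locus == "IGH" else "FGxG"
            segments.append(
                GermlineSegment(f"{locus}J{k + 1}*01", locus, "J", seq, 0, anchor, motif)
            )
        for allele_id in cfg["c_alleles"]:
            segments.append(
                GermlineSegment(
                    allele_id, locus, "C", _toy_c(rng, allele_id, cfg.get("c_len", c_len))
                )
            )
    for seg in segments:
        seg.validate()
    gset = GermlineSet(segments, scheme)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_germline(
            gset,
            out / "germline.fasta",
            out / "germline_annotation.tsv",
            out / "cdr_scheme.tsv",
        )
    return gset


def leader_length(segment: GermlineSegment) -> int:
    """Leader length of a toy V allele (fixed layout)."""
    return TOY_V_LAYOUT["leader"]
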