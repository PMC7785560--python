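"""FASTQ/FASTA plumbing shared by the CLI and tests."""

from __future__ import annotations

import gzip
from pathlib import Path

from Bio import SeqIO

from .simulate import SeqRead


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> list[SeqRead]:
    with _open(path) as fh:
        return [
            SeqRead(rec.id, str(rec.seq).upper(),
                    "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]))
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads: list[SeqRead], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
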