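"""Core sequence containers and plain-text I/O.

The pipeline works on named nucleotide sequences with an explicit topology
(linear or circular) and simple feature tables. FASTA goes through
Biopython; GFF3 feature lines are (de)serialized by a deliberately small
9-column reader/writer because every annotation this pipeline touches is a
flat CDS/tRNA line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "Feature",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "revcomp",
]

_COMP = str.maketrans("ACGTacgtNnRYSWKMryswkm", "TGCAtgcaNnYRSWMKyrswmk")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware for the common codes)."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence.

    Attributes
    ----------
    id : str
        Sequence name (FASTA header word).
    seq : str
        Uppercase nucleotide sequence.
    circular : bool
        Topology flag; circular sequences wrap for windowed statistics and
        read simulation.
    sample : str or None
        Source-sample label, when the record came from a specific sample.
    """

    id: str
    seq: str
    circular: bool = False
    sample: str | None = None

    def __len__(self) -> int:
        return len(self.seq)

    def rotated(self, offset: int) -> "GenomeRecord":
        """Rotate a circular record so position ``offset`` becomes 0."""
        if not self.circular:
            raise ValueError("only circular records can be rotated")
        off = offset % len(self.seq)
        return replace(self, seq=self.seq[off:] + self.seq[:off])


@dataclass(frozen=True)
class Feature:
    """A flat genome annotation (0-based, half-open internally)."""

    start: int
    end: int
    type: str  # e.g. "CDS", "tRNA"
    strand: int = 1  # +1 / -1
    id: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty feature interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, circular_flag: bool = True) -> list[GenomeRecord]:
    """Read FASTA records; ``topology=circular`` in the description sets topology."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circ = circular_flag and "topology=circular" in rec.description
        out.append(GenomeRecord(id=rec.id, seq=str(rec.seq).upper(), circular=circ))
    return out


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write 60-column-wrapped FASTA; circular records carry ``topology=circular``."""
    seqrecs = []
    for r in records:
        desc = "topology=circular" if r.circular else ""
        seqrecs.append(SeqRecord(Seq(r.seq), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# GFF3 (1-based inclusive on disk, 0-based half-open in memory)


def _fmt_attrs(feat: Feature) -> str:
    parts = []
    if feat.id:
        parts.append(f"ID={feat.id}")
    for k, v in feat.attributes.items():
        parts.append(f"{k}={v}")
    return ";".join(parts) if parts else "."


def write_gff3(features: Iterable[Feature], seqid: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda f: (f.start, f.end)):
            strand = "+" if f.strand >= 0 else "-"
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "phagehost",
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        strand,
                        ".",
                        _fmt_attrs(f),
                    ]
                )
                + "\n"
            )


def _parse_attrs(text: str) -> dict:
    attrs: dict = {}
    if text and text != ".":
        for part in text.rstrip(";").split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: str | Path, seqid: str | None = None) -> list[Feature]:
    """Read flat GFF3 feature lines into 0-based half-open Features."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            if seqid is not None and cols[0] != seqid:
                continue
            attrs = _parse_attrs(cols[8])
            feats.append(
                Feature(
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    type=cols[2],
                    strand=-1 if cols[6] == "-" else 1,
                    id=attrs.pop("ID", ""),
                    attributes=attrs,
                )
            )
    return feats


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, seq, qual) from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        yield rec.id, str(rec.seq), qual
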