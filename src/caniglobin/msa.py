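"""Light multiple-sequence-alignment container and plain-text I/O.

Sequences are stored as uppercase strings of equal length. FASTA round-trips
go through Biopython; segment annotations use BED conventions (0-based,
half-open). All alignment coordinates in this package are 0-based half-open;
1-based inclusive coordinates appear only in human-readable reports.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = frozenset("-.")


class Alignment:
    """An ordered set of equal-length named sequences."""

    def __init__(self, names: Sequence[str], seqs: Sequence[str]):
        if len(names) != len(seqs):
            raise ValueError("names and seqs must have equal length")
        if len(set(names)) != len(names):
            raise ValueError("duplicate sequence names")
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self.names = list(names)
        self.seqs = [s.upper() for s in seqs]
        self._index = {n: i for i, n in enumerate(self.names)}

    # -- basic protocol -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.names)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def __getitem__(self, name: str) -> str:
        return self.seqs[self._index[name]]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.names, self.seqs))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.names == other.names
            and self.seqs == other.seqs
        )

    # -- views --------------------------------------------------------------
    def column(self, i: int) -> str:
        return "".join(s[i] for s in self.seqs)

    def matrix(self) -> np.ndarray:
        """Alignment as a (n_seqs, length) array of single characters."""
        return np.array([list(s) for s in self.seqs], dtype="U1")

    def subset(self, names: Iterable[str]) -> "Alignment":
        names = list(names)
        missing = [n for n in names if n not in self._index]
        if missing:
            raise KeyError(f"sequences not in alignment: {missing}")
        return Alignment(names, [self[n] for n in names])

    def slice(self, start: int, end: int) -> "Alignment":
        if not (0 <= start <= end <= self.length):
            raise ValueError(f"slice [{start}, {end}) outside alignment")
        return Alignment(self.names, [s[start:end] for s in self.seqs])

    def drop_gap_columns(self) -> "Alignment":
        """Complete gap deletion: remove every column containing any gap."""
        keep = [
            i
            for i in range(self.length)
            if not any(s[i] in GAP_CHARS for s in self.seqs)
        ]
        return Alignment(self.names, ["".join(s[i] for i in keep) for s in self.seqs])

    def ungapped(self, name: str) -> str:
        return "".join(c for c in self[name] if c not in GAP_CHARS)

    def ungapped_position(self, name: str, column: int) -> int | None:
        """0-based residue index of `column` in the ungapped sequence.

        Returns None when the sequence has a gap at that column.
        """
        s = self[name]
        if s[column] in GAP_CHARS:
            return None
        return sum(1 for c in s[:column] if c not in GAP_CHARS)

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=n, description="") for n, s in zip(self.names, self.seqs)
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_fasta_string(self) -> str:
        buf = io.StringIO()
        SeqIO.write(
            [SeqRecord(Seq(s), id=n, description="") for n, s in self],
            buf,
            "fasta",
        )
        return buf.getvalue()


@dataclass(frozen=True)
class Segment:
    """A labelled, 0-based half-open interval of alignment columns."""

    label: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.label}: [{self.start}, {self.end})")


@dataclass
class SegmentAnnotation:
    """Ordered, non-overlapping labelled intervals over an alignment.

    The canonical gene-structure labels are 5'UTR500, exon1, intron1, exon2,
    intron2, exon3, 3'UTR500, but any unique labels are accepted.
    """

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self):
        labels = [s.label for s in self.segments]
        if len(set(labels)) != len(labels):
            raise ValueError("segment labels must be unique")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start < a.end:
                raise ValueError(f"segments {a.label} and {b.label} overlap or are unsorted")

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    @classmethod
    def from_bed(cls, path) -> "SegmentAnnotation":
        segs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"BED line needs chrom/start/end/name: {line!r}")
                segs.append(Segment(fields[3], int(fields[1]), int(fields[2])))
        segs.sort(key=lambda s: s.start)
        return cls(segs)

    def to_bed(self, path, chrom: str = "alignment") -> None:
        with open(path, "w") as fh:
            for s in self.segments:
                fh.write(f"{chrom}\t{s.start}\t{s.end}\t{s.label}\n")


GENE_STRUCTURE_LABELS = (
    "5'UTR500",
    "exon1",
    "intron1",
    "exon2",
    "intron2",
    "exon3",
    "3'UTR500",
)


def gene_structure_annotation(lengths: Sequence[int]) -> SegmentAnnotation:
    """Tile the seven canonical gene-structure segments with given lengths."""
    if len(lengths) != len(GENE_STRUCTURE_LABELS):
        raise ValueError(f"need {len(GENE_STRUCTURE_LABELS)} lengths")
    segs, pos = [], 0
    for label, ln in zip(GENE_STRUCTURE_LABELS, lengths):
        segs.append(Segment(label, pos, pos + ln))
        pos += ln
    return SegmentAnnotation(segs)
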