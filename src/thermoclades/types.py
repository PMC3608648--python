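"""Core containers shared across the pipeline.

Coordinates are 0-based half-open on the forward strand of the contig,
regardless of the strand a feature is encoded on.  GFF3 I/O (``io``) converts
to and from the 1-based inclusive interchange convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from Bio.Seq import Seq

FORWARD = "+"
REVERSE = "-"
STRANDS = (FORWARD, REVERSE)


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str  # uppercase ACGTN

    def __len__(self) -> int:
        return len(self.seq)


class ContigSet:
    """Ordered, id-keyed collection of contigs."""

    def __init__(self, contigs: list[Contig]):
        self._contigs: dict[str, Contig] = {}
        for c in contigs:
            if c.id in self._contigs:
                raise ValueError(f"duplicate contig id: {c.id}")
            self._contigs[c.id] = c

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    def __getitem__(self, contig_id: str) -> Contig:
        return self._contigs[contig_id]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._contigs

    @property
    def ids(self) -> list[str]:
        return list(self._contigs)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self)

    def gc_content(self) -> float:
        gc = sum(c.seq.count("G") + c.seq.count("C") for c in self)
        return gc / self.total_length


@dataclass(frozen=True)
class CdsFeature:
    """Single-exon coding interval.  ``start``/``end`` are contig coordinates
    (0-based half-open); for ``-`` strand features the coding sequence is the
    reverse complement of the interval."""

    id: str
    contig: str
    start: int
    end: int
    strand: str
    anomaly_id: str | None = None  # link into an anomaly ledger, if corrupted

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r} for CDS {self.id}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start},{self.end}) for CDS {self.id}")

    def __len__(self) -> int:
        return self.end - self.start

    def coding_sequence(self, contigs: ContigSet) -> str:
        nt = contigs[self.contig].seq[self.start : self.end]
        if self.strand == REVERSE:
            nt = str(Seq(nt).reverse_complement())
        return nt


class CdsSet:
    """Id-keyed collection of CDS features."""

    def __init__(self, features: list[CdsFeature]):
        self._features: dict[str, CdsFeature] = {}
        for f in features:
            if f.id in self._features:
                raise ValueError(f"duplicate CDS id: {f.id}")
            self._features[f.id] = f

    def __iter__(self) -> Iterator[CdsFeature]:
        return iter(self._features.values())

    def __len__(self) -> int:
        return len(self._features)

    def __getitem__(self, cds_id: str) -> CdsFeature:
        return self._features[cds_id]

    def __contains__(self, cds_id: str) -> bool:
        return cds_id in self._features

    @property
    def ids(self) -> list[str]:
        return list(self._features)


@dataclass(frozen=True)
class Read:
    id: str
    seq: str


class ReadSet:
    def __init__(self, reads: list[Read]):
        self.reads = list(reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


MISSING_GENE = "missing_gene"
TRUNCATED_GENE = "truncated_gene"
ANOMALY_CATEGORIES = (MISSING_GENE, TRUNCATED_GENE)


@dataclass(frozen=True)
class AnomalyRecord:
    """One ledgered annotation irregularity (the stand-in for an external
    annotation-QC report): the *true* interval that was dropped or clipped."""

    anomaly_id: str
    category: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.category not in ANOMALY_CATEGORIES:
            raise ValueError(f"unknown anomaly category {self.category!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class ObservedPeptide:
    """An experimentally observed peptide with its LC retention time."""

    id: str
    sequence: str
    retention_time: float
    is_outlier: bool | None = None  # ground-truth flag when simulated


@dataclass
class GenomeStatistics:
    total_length: int
    gc_percent: float
    n_contigs: int


def genome_statistics(contigs: ContigSet) -> GenomeStatistics:
    """Headline assembly statistics: total bases, G+C %, contig count."""
    return GenomeStatistics(
        total_length=contigs.total_length,
        gc_percent=100.0 * contigs.gc_content(),
        n_contigs=len(contigs),
    )
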