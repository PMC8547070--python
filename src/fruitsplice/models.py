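"""Core domain objects shared across the pipeline.

Coordinates are 0-based, half-open everywhere inside the package; GTF and
junction-table I/O convert at the boundary.  An *intron* is the gap between
two consecutive exons of one transcript, and a *junction* is an intron tagged
with its chromosome and strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

EVENT_TYPES = ("IR", "ES", "A3SS", "A5SS")

#: junction key: (chrom, intron_start, intron_end, strand), 0-based half-open
Junction = tuple[str, int, int, str]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript as an ordered exon chain on a chromosome strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    stage: str | None = None
    class_code: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s >= e:
                raise ValueError(f"empty exon ({s},{e}) in {self.transcript_id}")
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"exons of {self.transcript_id} overlap or are unsorted"
                )
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def junctions(self) -> tuple[Junction, ...]:
        return tuple((self.chrom, s, e, self.strand) for s, e in self.introns)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_single_exon(self) -> bool:
        return len(self.exons) == 1

    @property
    def intron_chain_key(self) -> tuple:
        """Grouping key: identical for transcripts with the same splicing."""
        if self.is_single_exon:
            return (self.chrom, self.strand, "mono", self.exons[0])
        return (self.chrom, self.strand, "multi", self.introns)

    def with_class_code(self, code: str) -> "TranscriptModel":
        return replace(self, class_code=code)


@dataclass(frozen=True)
class ASEvent:
    """One local alternative-splicing event.

    ``coords`` holds the type-specific junction boundaries as ordered
    (start, end) pairs: the retained intron for IR; the two flanking
    (inclusion) introns for ES; the two alternative introns, sorted, for
    A5SS/A3SS.  ``inclusion_transcripts`` follow the conventions: IR =
    intron retained, ES = exon included, A5SS/A3SS = longer-exon form.
    """

    event_id: str
    etype: str
    gene_id: str
    chrom: str
    strand: str
    coords: tuple[tuple[int, int], ...]
    inclusion_transcripts: frozenset[str]
    exclusion_transcripts: frozenset[str]

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"unknown AS type {self.etype!r}")
        if not self.inclusion_transcripts or not self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: empty inclusion/exclusion set")
        if self.inclusion_transcripts & self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: inclusion/exclusion overlap")
        flat = [c for pair in self.coords for c in pair]
        if any(s >= e for s, e in self.coords):
            raise ValueError(f"{self.event_id}: degenerate coordinate pair")
        if flat != sorted(flat) and tuple(sorted(self.coords)) != self.coords:
            raise ValueError(f"{self.event_id}: coords not ordered")

    @property
    def member_transcripts(self) -> frozenset[str]:
        return self.inclusion_transcripts | self.exclusion_transcripts


def event_id_string(
    gene_id: str,
    etype: str,
    chrom: str,
    strand: str,
    coords: Iterable[tuple[int, int]],
) -> str:
    """Canonical event id, ioe-style, with 1-based inclusive coordinates."""
    parts = ":".join(f"{s + 1}-{e}" for s, e in coords)
    return f"{gene_id};{etype}:{chrom}:{parts}:{strand}"


def make_event(
    etype: str,
    gene_id: str,
    chrom: str,
    strand: str,
    coords: tuple[tuple[int, int], ...],
    inclusion: Iterable[str],
    exclusion: Iterable[str],
) -> ASEvent:
    return ASEvent(
        event_id=event_id_string(gene_id, etype, chrom, strand, coords),
        etype=etype,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        coords=tuple(tuple(p) for p in coords),
        inclusion_transcripts=frozenset(inclusion),
        exclusion_transcripts=frozenset(exclusion),
    )


def group_by_gene(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, list[TranscriptModel]]:
    genes: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, []).append(t)
    return genes
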