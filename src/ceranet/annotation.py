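"""Stranded gene models with exon structure.

Coordinates are 0-based half-open throughout the package; GTF I/O converts
from the 1-based inclusive convention at the boundary (see :mod:`ceranet.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence, Tuple

Interval = Tuple[int, int]

BIOTYPES = ("mRNA", "lncRNA", "miRNA")


class AnnotationError(ValueError):
    """Malformed gene model (exon structure, strand, coordinates)."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One stranded gene locus.

    Parameters
    ----------
    gene_id : str
        Unique feature identifier.
    chrom : str
        Chromosome / contig name.
    strand : str
        ``"+"`` or ``"-"``.
    start, end : int
        Gene span, 0-based half-open, ``end > start``.
    exons : tuple of (int, int)
        Sorted, non-overlapping exon intervals contained in the span.
    biotype : str
        One of ``mRNA``, ``lncRNA``, ``miRNA``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: Tuple[Interval, ...]
    biotype: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.end <= self.start:
            raise AnnotationError(f"{self.gene_id}: end must exceed start")
        if self.biotype not in BIOTYPES:
            raise AnnotationError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: gene must have >=1 exon")
        prev_end = None
        for (s, e) in self.exons:
            if e <= s:
                raise AnnotationError(f"{self.gene_id}: empty exon [{s},{e})")
            if s < self.start or e > self.end:
                raise AnnotationError(f"{self.gene_id}: exon [{s},{e}) outside span")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    def introns(self) -> List[Interval]:
        """Gaps between consecutive exons, in genomic order."""
        out: List[Interval] = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    def shifted(self, offset: int) -> "GeneAnnotation":
        """Return a copy with all coordinates shifted by ``offset``."""
        return GeneAnnotation(
            self.gene_id,
            self.chrom,
            self.strand,
            self.start + offset,
            self.end + offset,
            tuple((s + offset, e + offset) for s, e in self.exons),
            self.biotype,
        )


@dataclass
class AnnotationSet:
    """Mapping of gene_id -> :class:`GeneAnnotation` with biotype views."""

    genes: Dict[str, GeneAnnotation] = field(default_factory=dict)

    def add(self, gene: GeneAnnotation) -> None:
        if gene.gene_id in self.genes:
            raise AnnotationError(f"duplicate gene_id {gene.gene_id!r}")
        self.genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneAnnotation]:
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneAnnotation:
        return self.genes[gene_id]

    def get(self, gene_id: str):
        return self.genes.get(gene_id)

    def by_biotype(self, biotype: str) -> List[GeneAnnotation]:
        return [g for g in self.genes.values() if g.biotype == biotype]

    def ids(self, biotype: str | None = None) -> List[str]:
        if biotype is None:
            return list(self.genes)
        return [g.gene_id for g in self.genes.values() if g.biotype == biotype]
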