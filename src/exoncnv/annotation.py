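"""Gene-level annotation of CNV calls.

Joins copy-number calls to gene models: which genes a call overlaps, how
many exons of each gene are affected, whether the event is confined to a
single exon of a single gene, and the genomic size of the event.

Coordinate convention: 1-based, fully inclusive intervals throughout the
public API (matching how clinical arrays report minimal intervals).  A
gene "overlaps" a call when the call interval intersects the gene's
genomic span — the hull from the first exon start to the last exon end,
introns included — because intronic deletions can disrupt a gene and are
counted by clinical convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GeneRecord",
    "GeneIndex",
    "AnnotatedCnv",
    "DiseaseStatus",
    "cnv_size",
    "format_size",
    "overlap_genes",
    "gene_disease_status",
]

#: OMIM-style inheritance modes understood by the disease-status logic.
INHERITANCE_MODES = frozenset({"AD", "AR", "XL"})


@dataclass(frozen=True)
class GeneRecord:
    """A gene model plus the disease metadata used downstream.

    Parameters
    ----------
    symbol : str
        Gene symbol (unique within a gene set).
    chrom : str
        Chromosome name, e.g. ``"chr8"``.
    strand : str
        ``"+"`` or ``"-"``; kept for reporting only.
    exons : tuple of (int, int)
        1-based inclusive exon intervals, sorted, non-overlapping.
    omim_mode : frozenset of str
        Subset of {"AD", "AR", "XL"}; empty = not an OMIM disease gene.
    sfari : bool
        Listed in the SFARI autism gene database (evidence, not OMIM status).
    dosage_sensitive : bool
        Known dosage-sensitive / haploinsufficient disease gene.
    hi_score : float or None
        Haploinsufficiency rank percentile; low rank (0-10%) predicts
        haploinsufficiency.
    pli : float or None
        Probability of loss-of-function intolerance, in [0, 1].
    """

    symbol: str
    chrom: str
    strand: str = "+"
    exons: tuple = ()
    omim_mode: frozenset = frozenset()
    sfari: bool = False
    dosage_sensitive: bool = False
    hi_score: Optional[float] = None
    pli: Optional[float] = None

    def __post_init__(self):
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "omim_mode", frozenset(self.omim_mode))
        if not self.omim_mode <= INHERITANCE_MODES:
            raise ValueError(
                f"{self.symbol}: unknown inheritance mode(s) "
                f"{sorted(self.omim_mode - INHERITANCE_MODES)}"
            )
        prev_end = None
        for s, e in exons:
            if e < s:
                raise ValueError(f"{self.symbol}: exon end {e} < start {s}")
            if s < 1:
                raise ValueError(f"{self.symbol}: exon start {s} < 1")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.symbol}: exons overlap or are unsorted")
            prev_end = e
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValueError(f"{self.symbol}: pli {self.pli} outside [0, 1]")

    @property
    def span(self) -> tuple:
        """Genomic hull (first exon start, last exon end), 1-based inclusive."""
        if not self.exons:
            raise ValueError(f"{self.symbol}: gene model has no exons")
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def cnv_size(start: int, end: int) -> int:
    """Size in bp of a 1-based inclusive interval: ``end - start + 1``."""
    if end < start:
        raise ValueError(f"interval end {end} < start {start}")
    return int(end) - int(start) + 1


def format_size(size_bp: int) -> str:
    """Render a size the way clinical CNV tables print it.

    Below 1 Mb: nearest kb ("87 kb"); at or above 1 Mb: one decimal in
    Mb ("1.1 Mb").
    """
    if size_bp < 0:
        raise ValueError("negative size")
    if size_bp >= 1_000_000:
        return f"{size_bp / 1e6:.1f} Mb"
    return f"{round(size_bp / 1e3):d} kb"


class GeneIndex:
    """Interval index over gene spans, one tree per chromosome."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self._trees: dict = {}
        self.genes = list(genes)
        for g in self.genes:
            s, e = g.span
            # intervaltree is half-open; store [s, e + 1) for inclusive ends
            self._trees.setdefault(g.chrom, IntervalTree()).addi(s, e + 1, g)

    def query(self, chrom: str, start: int, end: int) -> list:
        """Genes whose span intersects [start, end] (1-based inclusive).

        Result is sorted by (span start, symbol) and therefore independent
        of construction order.
        """
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        return sorted(hits, key=lambda g: (g.span[0], g.symbol))


@dataclass
class AnnotatedCnv:
    """A CNV call joined to the gene models it overlaps.

    ``genes`` holds ``(GeneRecord, exons_affected)`` pairs in genomic
    order.  An exon is "affected" if the call interval intersects it at
    all (partial overlap counts).
    """

    call: object  # calling.CnvCall
    genes: list = field(default_factory=list)

    @property
    def gene_count(self) -> int:
        return len(self.genes)

    @property
    def single_gene(self) -> bool:
        return self.gene_count == 1

    @property
    def single_exon(self) -> bool:
        return self.single_gene and self.genes[0][1] == 1

    @property
    def size_bp(self) -> int:
        return cnv_size(self.call.start, self.call.end)

    @property
    def gene_symbols(self) -> list:
        return [g.symbol for g, _ in self.genes]

    def is_intragenic(self, gene: GeneRecord) -> bool:
        """True if the call lies entirely within the gene's span."""
        s, e = gene.span
        return s <= self.call.start and self.call.end <= e


def _intersects(a_start, a_end, b_start, b_end) -> bool:
    return a_start <= b_end and b_start <= a_end


def overlap_genes(call, index: GeneIndex) -> AnnotatedCnv:
    """Annotate one call against a gene index.

    A gene is overlapped iff the call intersects its span (exon hull);
    ``exons_affected`` counts exons intersecting the call interval.
    """
    hits = index.query(call.chrom, call.start, call.end)
    genes = []
    for g in hits:
        n_aff = sum(
            1 for (es, ee) in g.exons if _intersects(call.start, call.end, es, ee)
        )
        genes.append((g, n_aff))
    return AnnotatedCnv(call=call, genes=genes)


class DiseaseStatus(NamedTuple):
    status: str  # "known_disease" | "candidate_or_novel"
    provenance: str  # "omim" | "no_compatible_mode" | "unlisted"


#: inheritance modes compatible with each copy-number context
_COMPATIBLE = {
    "autosomal_het": frozenset({"AD", "AR"}),
    "x_male_hemizygous": frozenset({"XL", "AR"}),
}


def gene_disease_status(gene: Optional[GeneRecord], context: str) -> DiseaseStatus:
    """Classify a gene as known-disease vs candidate/novel for a CNV context.

    ``context`` is ``"autosomal_het"`` (heterozygous autosomal event) or
    ``"x_male_hemizygous"`` (chrX event in a male).  A gene is a known
    disease gene when its OMIM inheritance mode is compatible with the
    context: AD for heterozygous autosomal events, XL for hemizygous
    male-X events.  AR genes count as known in either context but are
    interpreted downstream as a potential recessive carrier state.
    SFARI listing is supporting evidence only, never OMIM status.
    """
    if context not in _COMPATIBLE:
        raise ValueError(f"unknown context {context!r}")
    if gene is None:
        return DiseaseStatus("candidate_or_novel", "unlisted")
    if not gene.omim_mode:
        return DiseaseStatus("candidate_or_novel", "no_omim")
    if gene.omim_mode & _COMPATIBLE[context]:
        return DiseaseStatus("known_disease", "omim")
    return DiseaseStatus("candidate_or_novel", "no_compatible_mode")
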