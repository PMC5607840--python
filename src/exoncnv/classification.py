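"""Clinical classification of annotated CNVs.

Mirrors the reporting practice of clinical exon-targeted aCGH: small
gene-less CNVs, CNVs inside segmental duplications and CNVs matching
benign polymorphic regions (a DGV-like track) are excluded before
interpretation; the remainder is classified as pathogenic, likely
benign, loss/gain in a non-disease region, or of uncertain clinical
significance (VUS).

Rule precedence is fixed: exclusions -> pathogenic -> likely benign ->
non-disease region -> VUS.  CNVs overlapping a configured
disease-associated region (known microdeletion/microduplication
syndromes, incomplete-penetrance loci) escape the polymorphic exclusion
and classify pathogenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .annotation import AnnotatedCnv, GeneRecord

__all__ = [
    "ClassificationConfig",
    "CnvCategory",
    "Tracks",
    "DgvEntry",
    "classify_cnv",
    "reciprocal_overlap",
]

CATEGORY_VALUES = (
    "excluded_polymorphic",
    "excluded_segdup",
    "excluded_small_no_gene",
    "pathogenic",
    "likely_benign",
    "non_disease_region",
    "vus",
)


@dataclass(frozen=True)
class ClassificationConfig:
    """Size floors/ceilings and overlap fractions of the rule set."""

    no_gene_report_floor: int = 500_000       # bp; smaller gene-less CNVs are not reported
    benign_size_ceiling: int = 1_000_000      # bp
    dup_pathogenic_floor: int = 2_000_000     # bp; larger gene-containing dups are pathogenic
    dup_dosage_floor: int = 1_000_000         # bp; larger dups with dosage-sensitive genes
    dgv_reciprocal_overlap: float = 0.7
    segdup_overlap: float = 0.5
    rare_frequency_ceiling: float = 0.01      # internal-cohort frequency for "rare"

    def __post_init__(self):
        for v in (self.no_gene_report_floor, self.benign_size_ceiling,
                  self.dup_pathogenic_floor, self.dup_dosage_floor):
            if v <= 0:
                raise ValueError("size thresholds must be positive")
        for f in (self.dgv_reciprocal_overlap, self.segdup_overlap):
            if not (0.0 < f <= 1.0):
                raise ValueError("overlap fractions must be in (0, 1]")


@dataclass(frozen=True)
class DgvEntry:
    """One benign polymorphic-region entry; type 'loss', 'gain' or 'both'."""

    chrom: str
    start: int
    end: int
    type: str = "both"

    def matches_type(self, cnv_type: str) -> bool:
        return self.type == "both" or self.type == cnv_type


@dataclass
class Tracks:
    """Annotation tracks the classifier consults.

    Empty lists mean "no overlaps anywhere"; ``None`` means the track is
    missing and classification refuses to run.  ``disease_regions`` are
    (chrom, start, end, label) tuples.
    """

    dgv: Optional[List[DgvEntry]] = field(default_factory=list)
    segdup: Optional[List[Tuple[str, int, int]]] = field(default_factory=list)
    disease_regions: Optional[List[Tuple[str, int, int, str]]] = field(default_factory=list)

    def require_complete(self):
        for name in ("dgv", "segdup", "disease_regions"):
            if getattr(self, name) is None:
                raise ValueError(f"missing track: {name}")


@dataclass(frozen=True)
class CnvCategory:
    value: str
    rationale: str

    def __post_init__(self):
        if self.value not in CATEGORY_VALUES:
            raise ValueError(f"unknown category {self.value!r}")


def _intersection(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)) for 1-based inclusive intervals."""
    inter = _intersection(a[0], a[1], b[0], b[1])
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0] + 1), inter / (b[1] - b[0] + 1))


def _segdup_fraction(call, segdup: Sequence[Tuple[str, int, int]]) -> float:
    """Fraction of the call covered by the (merged) segdup track."""
    ivs = sorted(
        (max(s, call.start), min(e, call.end))
        for c, s, e in segdup
        if c == call.chrom and _intersection(call.start, call.end, s, e) > 0
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s + 1
    return covered / (call.end - call.start + 1)


def _disease_region_hits(call, regions) -> List[str]:
    return [
        label
        for c, s, e, label in regions
        if c == call.chrom and _intersection(call.start, call.end, s, e) > 0
    ]


def _is_disease_implicated(gene: GeneRecord) -> bool:
    # SFARI listing is supporting evidence, not established disease status
    return bool(gene.omim_mode) or gene.dosage_sensitive


def classify_cnv(
    cnv: AnnotatedCnv,
    tracks: Tracks,
    cfg: ClassificationConfig = ClassificationConfig(),
    inherited_multiple_times: bool = False,
    cohort_frequency: float = 0.0,
) -> CnvCategory:
    """Assign exactly one clinical category to an annotated CNV.

    ``inherited_multiple_times`` flags events seen repeatedly as
    inherited in the cohort database; ``cohort_frequency`` is the
    internal cohort frequency used for the "rare" determination.
    """
    tracks.require_complete()
    call = cnv.call
    size = cnv.size_bp
    genes = [g for g, _ in cnv.genes]

    dgv_hits = [
        d for d in tracks.dgv
        if d.chrom == call.chrom and d.matches_type(call.type)
        and _intersection(call.start, call.end, d.start, d.end) > 0
    ]
    dgv_recip = [
        d for d in dgv_hits
        if reciprocal_overlap((call.start, call.end), (d.start, d.end))
        >= cfg.dgv_reciprocal_overlap
    ]
    disease_hits = _disease_region_hits(call, tracks.disease_regions)

    # (a) benign polymorphic region, unless in a reportable disease region
    if dgv_recip and not disease_hits:
        return CnvCategory("excluded_polymorphic", "dgv_reciprocal_match")

    # (b) mostly inside segmental duplications: probes unreliable
    if _segdup_fraction(call, tracks.segdup) >= cfg.segdup_overlap:
        return CnvCategory("excluded_segdup", "segdup_fraction")

    # (c) small and gene-less: below reporting floor
    if size < cfg.no_gene_report_floor and cnv.gene_count == 0:
        return CnvCategory("excluded_small_no_gene", "lt_floor_no_gene")

    # (d) pathogenic
    if disease_hits:
        return CnvCategory("pathogenic", f"disease_region:{disease_hits[0]}")
    dosage_ad = [g for g in genes if g.dosage_sensitive and "AD" in g.omim_mode]
    if call.type == "loss" and dosage_ad:
        return CnvCategory("pathogenic", "deletion_dosage_sensitive_ad")
    if call.type == "gain":
        if any(cnv.is_intragenic(g) for g in dosage_ad):
            return CnvCategory("pathogenic", "intragenic_dup_dosage_sensitive_ad")
        if size > cfg.dup_pathogenic_floor and cnv.gene_count > 0:
            return CnvCategory("pathogenic", "large_dup_with_genes")
        if size > cfg.dup_dosage_floor and any(g.dosage_sensitive for g in genes):
            return CnvCategory("pathogenic", "dup_gt1mb_dosage_sensitive")

    # (e) likely benign
    if size < cfg.benign_size_ceiling:
        if cnv.gene_count == 0:
            return CnvCategory("likely_benign", "no_genes")
        if inherited_multiple_times and dgv_hits:
            return CnvCategory("likely_benign", "dgv_inherited_multiple_times")

    # (f) rare, small, no disease-implicated gene
    rare = (not dgv_recip) and cohort_frequency < cfg.rare_frequency_ceiling
    if (
        size < cfg.benign_size_ceiling
        and rare
        and cnv.gene_count > 0
        and not any(_is_disease_implicated(g) for g in genes)
    ):
        return CnvCategory("non_disease_region", "rare_no_disease_gene")

    # (g) uncertain significance; flag deletions of AR-only genes as a
    # potential recessive carrier state
    implicated = [g for g in genes if _is_disease_implicated(g)]
    if (
        call.type == "loss"
        and implicated
        and all(g.omim_mode == frozenset({"AR"}) for g in implicated)
    ):
        return CnvCategory("vus", "recessive_carrier_state")
    return CnvCategory("vus", "genes_without_evidence")
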