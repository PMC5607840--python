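"""Trio inheritance determination and the cohort filtering cascade.

After classification, surviving CNVs are partitioned by gene content
(single gene / 2-5 genes / more) and inheritance (de novo autosomal,
X-linked hemizygous deletion in males, inherited), candidate genes are
extracted from the de novo and male-X buckets, and the cohort call
database can be queried for additional overlapping deletions up to a
size ceiling.

De novo status requires both parents tested and negative; paternity is
assumed, not molecularly confirmed, and the emitted inheritance calls
carry a ``paternity_confirmed = False`` caveat implicitly (the status
value alone never encodes confirmed paternity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .annotation import AnnotatedCnv, GeneRecord, gene_disease_status
from .calling import CnvCall
from .classification import reciprocal_overlap
from .synthetic import Pedigree, validate_pedigree

__all__ = [
    "InheritanceCall",
    "CascadeCounts",
    "determine_inheritance",
    "run_cascade",
    "extract_candidate_genes",
    "query_overlapping_deletions",
    "BUCKETS",
]

INHERITED_STATUSES = ("maternal", "paternal", "inherited_unknown_parent")

BUCKETS = (
    "single_de_novo",
    "single_x_male",
    "single_inherited",
    "single_other",
    "multi_de_novo",
    "multi_x_male",
    "multi_inherited",
    "multi_other",
    "gt5_parked",
    "no_gene_other",
)


@dataclass(frozen=True)
class InheritanceCall:
    """Inheritance status of one child CNV plus the evidence level."""

    status: str  # de_novo | maternal | paternal | inherited_unknown_parent | unknown
    evidence: str  # both_parents_tested | one_parent_tested | none_tested

    def __post_init__(self):
        if self.status == "de_novo" and self.evidence != "both_parents_tested":
            raise ValueError("de_novo requires both parents tested")


def _matches(child: CnvCall, parent_calls: Sequence[CnvCall], min_ro: float) -> bool:
    return any(
        pc.type == child.type
        and pc.chrom == child.chrom
        and reciprocal_overlap((child.start, child.end), (pc.start, pc.end)) >= min_ro
        for pc in parent_calls
    )


def determine_inheritance(
    child_call,
    parent_calls: Dict[str, Optional[Sequence[CnvCall]]],
    pedigree: Dict[str, Pedigree],
    min_reciprocal_overlap: float = 0.5,
) -> InheritanceCall:
    """Determine the inheritance status of one child call.

    ``parent_calls`` maps parent sample ids to their call lists; a
    parent absent from the mapping (or mapped to None) is untested.  A
    call is inherited from a parent iff that parent has a same-type call
    on the same chromosome with reciprocal overlap at least
    ``min_reciprocal_overlap``; de novo requires both parents tested and
    neither matching.  With only one parent tested and negative the
    status is ``unknown`` (the untested parent cannot be excluded); with
    both parents matching it is ``inherited_unknown_parent``.
    """
    call = child_call.call if isinstance(child_call, AnnotatedCnv) else child_call
    ped = pedigree.get(call.sample_id)
    if ped is None:
        raise ValueError(f"sample {call.sample_id} absent from pedigree")

    def tested(pid):
        return pid is not None and parent_calls.get(pid) is not None

    mo_tested, fa_tested = tested(ped.mother_id), tested(ped.father_id)
    mo_hit = mo_tested and _matches(call, parent_calls[ped.mother_id], min_reciprocal_overlap)
    fa_hit = fa_tested and _matches(call, parent_calls[ped.father_id], min_reciprocal_overlap)

    if mo_tested and fa_tested:
        evidence = "both_parents_tested"
    elif mo_tested or fa_tested:
        evidence = "one_parent_tested"
    else:
        evidence = "none_tested"

    if mo_hit and fa_hit:
        return InheritanceCall("inherited_unknown_parent", evidence)
    if mo_hit:
        return InheritanceCall("maternal", evidence)
    if fa_hit:
        return InheritanceCall("paternal", evidence)
    if evidence == "both_parents_tested":
        return InheritanceCall("de_novo", evidence)
    return InheritanceCall("unknown", evidence)


@dataclass
class CascadeCounts:
    """Cohort-level counts emitted by the cascade.

    Headline fields (de novo losses/gains, X-linked-male, inherited)
    count the single-gene tier, mirroring how such cohorts are usually
    summarized; ``bucket_counts`` carries every routed bucket.
    """

    n_patients: int = 0
    n_cnvs: int = 0
    n_single_gene: int = 0
    n_multi_2_5: int = 0
    n_gt5: int = 0
    n_no_gene: int = 0
    n_de_novo_autosomal_losses: int = 0
    n_de_novo_autosomal_gains: int = 0
    n_x_male: int = 0
    n_inherited_losses: int = 0
    n_inherited_gains: int = 0
    n_single_exon: int = 0
    bucket_counts: Dict[str, int] = field(default_factory=dict)

    @property
    def n_de_novo_autosomal(self) -> int:
        return self.n_de_novo_autosomal_losses + self.n_de_novo_autosomal_gains

    @property
    def n_inherited(self) -> int:
        return self.n_inherited_losses + self.n_inherited_gains


def _route_tier(
    cnv: AnnotatedCnv, inh: InheritanceCall, sex: Optional[str], tier: str
) -> str:
    call = cnv.call
    if call.chrom == "chrX":
        if sex is None:
            warnings.warn(
                f"{call.sample_id}: chrX call but sex unknown; routed to other",
                stacklevel=3,
            )
            return f"{tier}_other"
        if sex == "male" and call.type == "loss":
            return f"{tier}_x_male"
        return f"{tier}_other"
    if inh.status == "de_novo":
        return f"{tier}_de_novo"
    if inh.status in INHERITED_STATUSES:
        return f"{tier}_inherited"
    return f"{tier}_other"


def run_cascade(
    annotated_calls: Sequence[AnnotatedCnv],
    pedigree: Sequence[Pedigree],
    min_reciprocal_overlap: float = 0.5,
    max_genes: int = 5,
    sexes: Optional[Dict[str, str]] = None,
) -> Tuple[CascadeCounts, Dict[str, List[Tuple[AnnotatedCnv, InheritanceCall]]]]:
    """Route every proband CNV into exactly one cascade bucket.

    ``annotated_calls`` holds calls for the whole cohort, parents
    included; parents' own calls serve only as the reference for
    inheritance determination.  Probands are the pedigree samples with a
    recorded parent.  Returns ``(counts, routed)`` where routed maps
    bucket name to ``(annotated call, inheritance)`` pairs; the routed
    lists partition the proband calls (conservation).
    """
    by_id = validate_pedigree(pedigree)
    sexes = sexes or {p.sample_id: p.sex for p in pedigree}
    calls_by_sample: Dict[str, List[CnvCall]] = {p.sample_id: [] for p in pedigree}
    for ac in annotated_calls:
        sid = ac.call.sample_id
        if sid not in calls_by_sample:
            raise ValueError(f"sample {sid} absent from pedigree")
        calls_by_sample[sid].append(ac.call)

    probands = {p.sample_id for p in pedigree if p.mother_id or p.father_id}
    routed: Dict[str, List[Tuple[AnnotatedCnv, InheritanceCall]]] = {b: [] for b in BUCKETS}
    counts = CascadeCounts()
    patients = set()

    for ac in annotated_calls:
        sid = ac.call.sample_id
        if sid not in probands:
            continue
        counts.n_cnvs += 1
        patients.add(sid)
        inh = determine_inheritance(ac, calls_by_sample, by_id, min_reciprocal_overlap)
        sex = sexes.get(sid)
        if ac.gene_count == 0:
            bucket = "no_gene_other"
            counts.n_no_gene += 1
        elif ac.gene_count == 1:
            bucket = _route_tier(ac, inh, sex, "single")
            counts.n_single_gene += 1
        elif ac.gene_count <= max_genes:
            bucket = _route_tier(ac, inh, sex, "multi")
            counts.n_multi_2_5 += 1
        else:
            bucket = "gt5_parked"
            counts.n_gt5 += 1
        routed[bucket].append((ac, inh))
        if ac.single_exon:
            counts.n_single_exon += 1
        if bucket == "single_de_novo":
            if ac.call.type == "loss":
                counts.n_de_novo_autosomal_losses += 1
            else:
                counts.n_de_novo_autosomal_gains += 1
        elif bucket == "single_x_male":
            counts.n_x_male += 1
        elif bucket == "single_inherited":
            if ac.call.type == "loss":
                counts.n_inherited_losses += 1
            else:
                counts.n_inherited_gains += 1

    counts.n_patients = len(patients)
    counts.bucket_counts = {b: len(v) for b, v in routed.items()}
    return counts, routed


CANDIDATE_BUCKETS = {
    "single_de_novo": ("single_de_novo", "autosomal_het"),
    "single_x_male": ("single_x_male", "x_male_hemizygous"),
    "multi_de_novo": ("multi_de_novo", "autosomal_het"),
    "multi_x_male": ("multi_x_male", "x_male_hemizygous"),
}


def extract_candidate_genes(
    routed: Dict[str, List[Tuple[AnnotatedCnv, InheritanceCall]]],
) -> pd.DataFrame:
    """One evidence row per (candidate gene, CNV) in the de novo and
    male-X buckets of both tiers.

    Known disease genes (OMIM mode compatible with the CNV context) are
    not emitted; in mixed-content multi-gene CNVs only the
    candidate/novel genes yield rows.
    """
    rows = []
    for bucket, (tier, context) in CANDIDATE_BUCKETS.items():
        for ac, inh in routed.get(bucket, []):
            for gene, _n_ex in ac.genes:
                status = gene_disease_status(gene, context)
                if status.status != "candidate_or_novel":
                    continue
                rows.append(
                    (gene.symbol, tier, ac.call.id, ac.call.type, inh.status, ac.size_bp)
                )
    return pd.DataFrame(
        rows, columns=["gene", "tier", "cnv_id", "type", "inheritance", "size_bp"]
    )


def query_overlapping_deletions(
    gene: GeneRecord,
    call_database: Sequence[CnvCall],
    max_size: int = 5_000_000,
) -> List[CnvCall]:
    """Deletions of size <= max_size overlapping the gene span, any
    inheritance, in genomic order."""
    gs, ge = gene.span
    hits = [
        c
        for c in call_database
        if c.type == "loss"
        and c.chrom == gene.chrom
        and c.size_bp <= max_size
        and c.start <= ge
        and gs <= c.end
    ]
    return sorted(hits, key=lambda c: (c.start, c.end, str(c.sample_id)))
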