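"""Synthetic exon-targeted array cohorts with a known CNV truth set.

The real study population behind this pipeline is a clinical aCGH
database that is not publicly available, so every downstream stage is
exercised against simulated data with known ground truth.  Three
generators live here:

* :func:`design_array` — an exon-targeted probe design over a toy
  genome: several probes per exon of each targeted gene (>90% of exons
  with at least three probes, mean > 4.2 probes/exon), intronic probes
  every 10 kb within targeted genes, and a genome backbone at 30 kb
  resolution that skips segmental duplications.
* :func:`simulate_cohort` — per-sample log2-ratio profiles for a set of
  trios, with heterozygous / hemizygous / mosaic CNVs implanted at known
  coordinates.  A fraction f of cells carrying a one-copy loss gives an
  expected ratio log2((2 - f)/2); a one-copy gain gives log2((2 + f)/2);
  a hemizygous male-X loss removes the only copy and is clipped to a
  configurable floor (arrays never report -inf).  I.i.d. Gaussian noise
  is added on top.
* :func:`simulate_wes_variants` — exome variant tables whose coverage,
  variant-allele-fraction and population-frequency columns deliberately
  straddle every boundary of the downstream loss-of-function filter.

All generators are deterministic for a fixed seed.  Coordinates are
1-based inclusive everywhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneRecord

__all__ = [
    "TOY_CHROM_LENGTHS",
    "ArrayDesignParams",
    "Pedigree",
    "TruthCnv",
    "WesSimParams",
    "toy_gene_models",
    "design_array",
    "simulate_cohort",
    "expected_log2",
    "simulate_wes_variants",
    "wes_boundary_fixture",
    "make_trio_pedigree",
    "make_validation_cohort",
    "ValidationCohort",
    "expand_truth_with_carriers",
]

#: Toy genome used by the bundled simulations: three autosomes plus X.
TOY_CHROM_LENGTHS: Dict[str, int] = {
    "chr1": 10_000_000,
    "chr2": 8_000_000,
    "chr3": 6_000_000,
    "chrX": 8_000_000,
}

PROBE_COLUMNS = ["probe_id", "chrom", "pos", "probe_class"]


@dataclass(frozen=True)
class ArrayDesignParams:
    """Exon-targeted array design parameters.

    Defaults reproduce the design density of clinical exon-targeted
    arrays: at least three interrogating oligos on >=90% of targeted
    exons, a cohort-mean above 4.2 probes per exon, intronic probes
    every 10 kb and a 30 kb genome backbone.
    """

    probes_per_exon_min: int = 3
    probes_per_exon_mean: float = 4.2
    intronic_spacing: int = 10_000
    backbone_spacing: int = 30_000
    exon_coverage_fraction: float = 0.90
    seed: int = 0

    def __post_init__(self):
        if self.intronic_spacing <= 0 or self.backbone_spacing <= 0:
            raise ValueError("spacings must be positive")
        if not (0.0 < self.exon_coverage_fraction <= 1.0):
            raise ValueError("exon_coverage_fraction must be in (0, 1]")
        if self.probes_per_exon_mean < self.probes_per_exon_min:
            raise ValueError("probes_per_exon_mean < probes_per_exon_min")
        if self.probes_per_exon_min < 1:
            raise ValueError("probes_per_exon_min must be >= 1")


@dataclass(frozen=True)
class Pedigree:
    """One sample of a trio cohort. Absent parent = untested/unknown."""

    sample_id: str
    sex: str  # "male" | "female"
    mother_id: Optional[str] = None
    father_id: Optional[str] = None

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.sample_id}: sex must be male/female")
        if self.sample_id in (self.mother_id, self.father_id):
            raise ValueError(f"{self.sample_id} is its own parent")


DOSAGES = ("heterozygous", "homozygous", "hemizygous")
ORIGINS = ("de_novo", "maternal", "paternal")


@dataclass(frozen=True)
class TruthCnv:
    """An implanted CNV: the ground truth for parameter-recovery tests."""

    sample_id: str
    chrom: str
    start: int
    end: int
    type: str  # "loss" | "gain"
    allele_dosage: str = "heterozygous"
    mosaic_fraction: float = 1.0
    origin: str = "de_novo"

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("truth CNV end < start")
        if self.type not in ("loss", "gain"):
            raise ValueError(f"bad CNV type {self.type!r}")
        if self.allele_dosage not in DOSAGES:
            raise ValueError(f"bad allele dosage {self.allele_dosage!r}")
        if not (0.0 < self.mosaic_fraction <= 1.0):
            raise ValueError("mosaic_fraction must be in (0, 1]")
        if self.origin not in ORIGINS:
            raise ValueError(f"bad origin {self.origin!r}")


def validate_pedigree(pedigree: Sequence[Pedigree]) -> Dict[str, Pedigree]:
    """Index a pedigree by sample and reject ancestry cycles."""
    by_id = {}
    for p in pedigree:
        if p.sample_id in by_id:
            raise ValueError(f"duplicate sample {p.sample_id}")
        by_id[p.sample_id] = p
    for p in pedigree:
        seen = {p.sample_id}
        frontier = [p.mother_id, p.father_id]
        while frontier:
            a = frontier.pop()
            if a is None or a not in by_id:
                continue
            if a in seen and a == p.sample_id:
                raise ValueError(f"{p.sample_id} is its own ancestor")
            if a in seen:
                continue
            seen.add(a)
            anc = by_id[a]
            if p.sample_id in (anc.mother_id, anc.father_id):
                raise ValueError(f"{p.sample_id} is its own ancestor")
            frontier.extend([anc.mother_id, anc.father_id])
    return by_id


# ---------------------------------------------------------------------------
# toy genome / gene models
# ---------------------------------------------------------------------------

def toy_gene_models(
    seed: int = 2017,
    genes_per_chrom: int = 15,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> List[GeneRecord]:
    """Fabricate deterministic multi-exon gene models on the toy genome.

    Genes have 2-18 exons of 80-320 bp separated by 2-8 kb introns and
    are spaced roughly evenly along each chromosome.  Disease metadata
    (OMIM mode, SFARI flag, dosage sensitivity, HI percentile, pLI) is
    drawn once, deterministically in ``seed``.
    """
    chrom_lengths = chrom_lengths or TOY_CHROM_LENGTHS
    rng = np.random.default_rng(seed)
    genes: List[GeneRecord] = []
    idx = 0
    for chrom, length in chrom_lengths.items():
        slot = length // (genes_per_chrom + 1)
        for k in range(genes_per_chrom):
            idx += 1
            anchor = slot * (k + 1) + int(rng.integers(0, slot // 4))
            n_exons = int(rng.integers(2, 19))
            exons = []
            pos = anchor
            for _ in range(n_exons):
                ex_len = int(rng.integers(80, 321))
                exons.append((pos, pos + ex_len - 1))
                pos += ex_len + int(rng.integers(2_000, 8_001))
            if chrom == "chrX":
                omim = frozenset({"XL"}) if rng.random() < 0.35 else frozenset()
            else:
                r = rng.random()
                if r < 0.20:
                    omim = frozenset({"AD"})
                elif r < 0.40:
                    omim = frozenset({"AR"})
                else:
                    omim = frozenset()
            dosage_sensitive = bool("AD" in omim and rng.random() < 0.5)
            genes.append(
                GeneRecord(
                    symbol=f"GENE{idx:03d}",
                    chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=tuple(exons),
                    omim_mode=omim,
                    sfari=bool(rng.random() < 0.1),
                    dosage_sensitive=dosage_sensitive,
                    hi_score=float(np.round(rng.uniform(0, 100), 2)),
                    pli=float(np.round(rng.beta(0.3, 0.3), 3)),
                )
            )
    return genes


# ---------------------------------------------------------------------------
# array design
# ---------------------------------------------------------------------------

def _exon_probe_positions(start: int, end: int, n: int) -> List[int]:
    """Evenly spaced probe positions within an exon, endpoints included."""
    length = end - start + 1
    n = min(n, length)
    if n == 1:
        return [(start + end) // 2]
    raw = np.linspace(start, end, n)
    return sorted(set(int(round(x)) for x in raw))


def design_array(
    gene_models: Sequence[GeneRecord],
    params: ArrayDesignParams = ArrayDesignParams(),
    chrom_lengths: Optional[Dict[str, int]] = None,
    segdups: Optional[Sequence[Tuple[str, int, int]]] = None,
) -> pd.DataFrame:
    """Lay out an exon-targeted probe design.

    Exonic probes are allocated per exon proportionally to exon length
    (at least ``probes_per_exon_min``), with a small seeded fraction of
    exons (up to ``1 - exon_coverage_fraction``) under-covered to mimic
    designs where some exons resist probe placement; probes are then
    topped up on the longest exons until the design-wide mean reaches
    ``probes_per_exon_mean``.  Intronic probes tile targeted gene spans
    at ``intronic_spacing``; backbone probes tile the rest of the genome
    at ``backbone_spacing``, skipping ``segdups`` intervals if given.

    Returns a DataFrame ``probe_id chrom pos probe_class``, sorted by
    (chromosome, position), strictly increasing positions per
    chromosome.
    """
    chrom_lengths = chrom_lengths or TOY_CHROM_LENGTHS
    rng = np.random.default_rng(params.seed)
    for g in gene_models:
        if not g.exons:
            raise ValueError(f"{g.symbol}: gene model has no exons")
        if g.chrom not in chrom_lengths:
            raise ValueError(f"chromosome {g.chrom} absent from length table")
        for s, e in g.exons:
            if e - s + 1 < 1:
                raise ValueError(f"{g.symbol}: exon shorter than 1 bp")

    # --- exonic probe allocation ------------------------------------------
    exon_list = [(g, s, e) for g in gene_models for (s, e) in g.exons]
    n_exons = len(exon_list)
    alloc = np.array(
        [max(params.probes_per_exon_min, math.ceil((e - s + 1) / 55)) for _, s, e in exon_list],
        dtype=int,
    )
    if n_exons:
        n_drop = int((1.0 - params.exon_coverage_fraction) * n_exons)
        if n_drop > 0:
            dropped = rng.choice(n_exons, size=n_drop, replace=False)
            alloc[dropped] = 1
        else:
            dropped = np.array([], dtype=int)
        drop_mask = np.zeros(n_exons, dtype=bool)
        drop_mask[dropped] = True
        lengths = np.array([e - s + 1 for _, s, e in exon_list])
        # top up the best-covered-capacity exons until the mean is met
        while alloc.mean() < params.probes_per_exon_mean:
            cap = np.where(~drop_mask & (alloc < lengths), lengths / (alloc + 1), -1.0)
            j = int(np.argmax(cap))
            if cap[j] < 0:
                break
            alloc[j] += 1

    records: List[Tuple[str, int, int]] = []  # (chrom, pos, class-priority)
    CLASS = {0: "exonic", 1: "intronic", 2: "backbone"}
    for (g, s, e), n in zip(exon_list, alloc):
        for pos in _exon_probe_positions(s, e, int(n)):
            records.append((g.chrom, pos, 0))

    # --- intronic probes within targeted gene spans -----------------------
    exon_by_gene = {g.symbol: g.exons for g in gene_models}
    for g in gene_models:
        gs, ge = g.span
        pos = gs + params.intronic_spacing
        while pos < ge:
            if not any(s <= pos <= e for s, e in exon_by_gene[g.symbol]):
                records.append((g.chrom, pos, 1))
            pos += params.intronic_spacing

    # --- genome backbone ---------------------------------------------------
    spans_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for g in gene_models:
        spans_by_chrom.setdefault(g.chrom, []).append(g.span)
    segdup_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for c, s, e in segdups or []:
        segdup_by_chrom.setdefault(c, []).append((s, e))
    for chrom, length in chrom_lengths.items():
        spans = spans_by_chrom.get(chrom, [])
        sds = segdup_by_chrom.get(chrom, [])
        for pos in range(params.backbone_spacing, length + 1, params.backbone_spacing):
            if any(s <= pos <= e for s, e in spans):
                continue
            if any(s <= pos <= e for s, e in sds):
                continue
            records.append((chrom, pos, 2))

    chrom_order = {c: i for i, c in enumerate(chrom_lengths)}
    records.sort(key=lambda r: (chrom_order[r[0]], r[1], r[2]))
    # de-duplicate colliding positions, keeping the highest-priority class
    rows = []
    last = None
    for chrom, pos, prio in records:
        if last == (chrom, pos):
            continue
        last = (chrom, pos)
        rows.append((chrom, pos, CLASS[prio]))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "probe_class"])
    df.insert(0, "probe_id", [f"P{i:06d}" for i in range(len(df))])
    return df


def probes_per_exon(design: pd.DataFrame, gene_models: Sequence[GeneRecord]) -> pd.DataFrame:
    """Count exonic probes per (gene, exon) of a design; used for QC."""
    rows = []
    for g in gene_models:
        sub = design[(design["chrom"] == g.chrom) & (design["probe_class"] == "exonic")]
        pos = sub["pos"].to_numpy()
        for i, (s, e) in enumerate(g.exons):
            rows.append((g.symbol, i + 1, int(((pos >= s) & (pos <= e)).sum())))
    return pd.DataFrame(rows, columns=["symbol", "exon", "n_probes"])


# ---------------------------------------------------------------------------
# cohort signal simulation
# ---------------------------------------------------------------------------

def expected_log2(
    cnv_type: str,
    allele_dosage: str,
    mosaic_fraction: float,
    hemizygous_floor: float = -3.0,
) -> float:
    """Closed-form expected log2 ratio inside a CNV.

    Heterozygous events change one of two copies in a fraction f of
    cells: loss (2 - f)/2, gain (2 + f)/2.  Homozygous events change
    both copies: loss (2 - 2f)/2, gain (2 + 2f)/2.  Hemizygous events
    sit on a single-copy background (male chrX): loss (1 - f)/1, gain
    (1 + f)/1.  Ratios of zero or below, and any value under the floor,
    are clipped to ``hemizygous_floor``.
    """
    f = mosaic_fraction
    delta = f if cnv_type == "gain" else -f
    if allele_dosage == "heterozygous":
        ratio = (2.0 + delta) / 2.0
    elif allele_dosage == "homozygous":
        ratio = (2.0 + 2.0 * delta) / 2.0
    elif allele_dosage == "hemizygous":
        ratio = 1.0 + delta
    else:
        raise ValueError(f"bad allele dosage {allele_dosage!r}")
    if ratio <= 0.0:
        return hemizygous_floor
    return max(math.log2(ratio), hemizygous_floor)


def _parent_event(t: TruthCnv, parent: Pedigree) -> TruthCnv:
    """Constitutional copy of an inherited event in its carrier parent."""
    dosage = "heterozygous"
    if t.chrom in ("chrX", "chrY") and parent.sex == "male":
        dosage = "hemizygous"
    return TruthCnv(
        sample_id=parent.sample_id,
        chrom=t.chrom,
        start=t.start,
        end=t.end,
        type=t.type,
        allele_dosage=dosage,
        mosaic_fraction=1.0,
        origin="de_novo",  # placeholder; carrier copies carry no origin semantics
    )


def expand_truth_with_carriers(
    truth: Sequence[TruthCnv], pedigree: Sequence[Pedigree]
) -> List[Tuple[str, TruthCnv]]:
    """All (carrier sample, event) pairs implied by a truth set.

    Each truth CNV is carried by its own sample; maternally/paternally
    inherited events are additionally carried constitutionally by the
    respective parent.
    """
    by_id = validate_pedigree(pedigree)
    pairs: List[Tuple[str, TruthCnv]] = []
    for t in truth:
        pairs.append((t.sample_id, t))
        if t.origin in ("maternal", "paternal"):
            ped = by_id[t.sample_id]
            pid = ped.mother_id if t.origin == "maternal" else ped.father_id
            if pid is None:
                raise ValueError(
                    f"{t.sample_id}: {t.origin} event but that parent is absent from pedigree"
                )
            pairs.append((pid, _parent_event(t, by_id[pid])))
    return pairs


def simulate_cohort(
    design: pd.DataFrame,
    pedigree: Sequence[Pedigree],
    truth: Sequence[TruthCnv],
    noise_sd: float = 0.15,
    seed: int = 0,
    hemizygous_floor: float = -3.0,
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate per-sample log2 profiles over a probe design.

    Returns ``(profiles, truth_table)`` where ``profiles`` maps every
    pedigree sample to a probe table with a ``log2`` column and
    ``truth_table`` is a 1-based BED-like frame
    ``chrom start end sample type dosage mosaic_fraction origin n_probes
    flag`` (flag "undetectable" marks events overlapping zero probes;
    these also emit a warning).  Inherited events are implanted in the
    carrier parent constitutionally.  Deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    by_id = validate_pedigree(pedigree)
    for t in truth:
        if t.sample_id not in by_id:
            raise ValueError(f"truth CNV sample {t.sample_id} not in pedigree")
        if t.allele_dosage == "hemizygous":
            if t.chrom not in ("chrX", "chrY") or by_id[t.sample_id].sex != "male":
                raise ValueError(
                    f"{t.sample_id}: hemizygous event must be on chrX/chrY of a male"
                )

    chroms = design["chrom"].to_numpy()
    pos = design["pos"].to_numpy()
    chrom_slices: Dict[str, slice] = {}
    start_i = 0
    for i in range(1, len(design) + 1):
        if i == len(design) or chroms[i] != chroms[start_i]:
            chrom_slices[chroms[start_i]] = slice(start_i, i)
            start_i = i

    events = expand_truth_with_carriers(truth, pedigree)
    events_by_sample: Dict[str, List[TruthCnv]] = {}
    for sid, ev in events:
        events_by_sample.setdefault(sid, []).append(ev)

    rng = np.random.default_rng(seed)
    profiles: Dict[str, pd.DataFrame] = {}
    probe_counts: Dict[Tuple, int] = {}
    for ped in pedigree:
        log2 = np.zeros(len(design))
        for ev in events_by_sample.get(ped.sample_id, []):
            sl = chrom_slices.get(ev.chrom)
            if sl is None:
                n_hit = 0
            else:
                p = pos[sl]
                lo = int(np.searchsorted(p, ev.start, side="left"))
                hi = int(np.searchsorted(p, ev.end, side="right"))
                n_hit = hi - lo
                if n_hit:
                    log2[sl.start + lo : sl.start + hi] = expected_log2(
                        ev.type, ev.allele_dosage, ev.mosaic_fraction, hemizygous_floor
                    )
            key = (ev.sample_id, ev.chrom, ev.start, ev.end, ev.type)
            probe_counts[key] = n_hit
        if noise_sd > 0:
            log2 = log2 + rng.normal(0.0, noise_sd, size=len(design))
        prof = design.copy()
        prof["log2"] = log2
        profiles[ped.sample_id] = prof

    rows = []
    for t in truth:
        n_hit = probe_counts.get((t.sample_id, t.chrom, t.start, t.end, t.type), 0)
        flag = "ok" if n_hit > 0 else "undetectable"
        if flag == "undetectable":
            warnings.warn(
                f"truth CNV {t.sample_id} {t.chrom}:{t.start}-{t.end} overlaps no probes",
                stacklevel=2,
            )
        rows.append(
            (t.chrom, t.start, t.end, t.sample_id, t.type, t.allele_dosage,
             t.mosaic_fraction, t.origin, n_hit, flag)
        )
    truth_table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "sample", "type", "dosage",
                 "mosaic_fraction", "origin", "n_probes", "flag"],
    )
    return profiles, truth_table


# ---------------------------------------------------------------------------
# WES variant simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WesSimParams:
    """Rates and spectra for the WES variant simulator.

    ``maf_log10_range`` spans both sides of the 1e-3 and 1e-4 filter
    cutoffs; ``zero_maf_fraction`` of variants are absent from all
    population databases (MAF columns 0).
    """

    lof_rate: float = 0.01        # per (sample, gene) probability of a LOF variant
    missense_rate: float = 0.03   # per (sample, gene) probability of a missense variant
    mean_coverage: float = 60.0   # Poisson mean of total read depth
    maf_log10_range: Tuple[float, float] = (-6.0, -2.0)
    zero_maf_fraction: float = 0.5
    include_boundary_set: bool = True

    def __post_init__(self):
        for r in (self.lof_rate, self.missense_rate, self.zero_maf_fraction):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")


LOF_CLASSES = ("stop_gain", "frameshift", "splicing")

WES_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt", "functional_class",
    "total_reads", "alt_reads", "maf_esp", "maf_1kg", "maf_local", "maf_exac",
]


def wes_boundary_fixture(gene: GeneRecord) -> pd.DataFrame:
    """Deterministic variants straddling every LOF-filter boundary.

    Coverage 19/20/21, VAF 0.19/0.20/0.21 (on 100 reads), common-database
    MAFs 9e-4 / 1e-3 / 1.1e-3, ExAC MAFs 9e-5 / 1e-4 / 1.1e-4, plus a
    perfectly supported missense variant.
    """
    gs, _ = gene.span
    rows = []

    def row(i, cls, total, alt, esp=0.0, kg=0.0, local=0.0, exac=0.0):
        rows.append(("boundary", gene.symbol, gene.chrom, gs + i, "A", "T",
                     cls, total, alt, esp, kg, local, exac))

    i = 0
    for cov in (19, 20, 21):
        row(i, "stop_gain", cov, cov // 2); i += 1
    for alt in (19, 20, 21):
        row(i, "frameshift", 100, alt); i += 1
    for maf in (9e-4, 1e-3, 1.1e-3):
        row(i, "splicing", 100, 50, esp=maf); i += 1
        row(i, "splicing", 100, 50, kg=maf); i += 1
        row(i, "splicing", 100, 50, local=maf); i += 1
    for maf in (9e-5, 1e-4, 1.1e-4):
        row(i, "stop_gain", 100, 50, exac=maf); i += 1
    row(i, "missense", 100, 50)
    return pd.DataFrame(rows, columns=WES_COLUMNS)


def simulate_wes_variants(
    genes: Sequence[GeneRecord],
    n_samples: int,
    params: WesSimParams = WesSimParams(),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a WES variant table over a gene set.

    Variant sites are drawn per (sample, gene) with the configured LOF
    and missense rates; read depth is Poisson, alt reads binomial at
    heterozygous expectation 0.5, and population MAFs are log-uniform
    over ``maf_log10_range`` (or zero for the unobserved fraction).
    When ``include_boundary_set`` is on, the deterministic boundary
    fixture for the first gene is appended so the downstream filter is
    exercised at every cutoff.  Empty gene list yields an empty table.
    """
    rng = np.random.default_rng(seed)
    rows = []
    lo, hi = params.maf_log10_range
    for si in range(n_samples):
        sid = f"WES{si:04d}"
        for g in genes:
            for cls_pool, rate in ((LOF_CLASSES, params.lof_rate), (("missense",), params.missense_rate)):
                if rng.random() >= rate:
                    continue
                cls = cls_pool[int(rng.integers(len(cls_pool)))]
                gs, ge = g.span
                total = max(1, int(rng.poisson(params.mean_coverage)))
                alt = int(rng.binomial(total, 0.5))
                if rng.random() < params.zero_maf_fraction:
                    mafs = (0.0, 0.0, 0.0, 0.0)
                else:
                    mafs = tuple(10.0 ** rng.uniform(lo, hi) for _ in range(4))
                rows.append((sid, g.symbol, g.chrom, int(rng.integers(gs, ge + 1)),
                             "A", "T", cls, total, alt, *mafs))
    df = pd.DataFrame(rows, columns=WES_COLUMNS)
    if params.include_boundary_set and len(genes):
        df = pd.concat([df, wes_boundary_fixture(genes[0])], ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# validation cohort (the benchmark the recovery tests run on)
# ---------------------------------------------------------------------------

@dataclass
class ValidationCohort:
    """A fully materialized synthetic trio cohort with known truth."""

    gene_models: List[GeneRecord]
    design: pd.DataFrame
    pedigree: List[Pedigree]
    truth: List[TruthCnv]
    truth_table: pd.DataFrame
    profiles: Dict[str, pd.DataFrame]
    noise_sd: float
    seed: int


def make_trio_pedigree(n_trios: int) -> List[Pedigree]:
    """n_trios independent trios; child sexes alternate male/female."""
    ped: List[Pedigree] = []
    for i in range(n_trios):
        mo, fa, ch = f"T{i:03d}-MO", f"T{i:03d}-FA", f"T{i:03d}-CH"
        ped.append(Pedigree(mo, "female"))
        ped.append(Pedigree(fa, "male"))
        ped.append(Pedigree(ch, "male" if i % 2 == 0 else "female",
                            mother_id=mo, father_id=fa))
    return ped


#: Fixed instrument seed: the array design is a fixed platform; only the
#: cohort (event placement, noise) varies with the user seed.
_DESIGN_SEED = 2017

#: Mosaic events are implanted at fractions whose expected in-CNV signal
#: clears the caller threshold by more than one probe-noise SD (0.15) in
#: log2 space; below f ~ 0.68 a heterozygous-loss mosaic is undetectable
#: by a -0.6 threshold caller by construction.
_MOSAIC_F_RANGE = (0.85, 1.0)
_MOSAIC_MIN_PROBES = 20


def make_validation_cohort(
    seed: int,
    n_trios: int = 30,
    n_cnvs: int = 50,
    noise_sd: float = 0.0,
    mosaic_rate: float = 0.12,
    loss_rate: float = 0.75,
    de_novo_rate: float = 0.34,
    min_probes: int = 3,
    max_probes: int = 200,
) -> ValidationCohort:
    """Build the standard parameter-recovery benchmark cohort.

    ``n_cnvs`` events are implanted across the trio children, each
    spanning ``min_probes``-``max_probes`` consecutive design probes
    (log-uniform span), 75% losses, roughly one third de novo and the
    rest split between maternal and paternal origin.  Events on male
    chrX are hemizygous.  A ``mosaic_rate`` fraction of de novo
    autosomal losses is implanted as mosaic with cell fraction in
    [0.85, 1) over at least 20 probes.  Event boundaries coincide with
    the first/last overlapped probe so boundary recovery can be asserted
    exactly.  Events within a child are separated by at least three
    probes so runs never merge.
    """
    gene_models = toy_gene_models(_DESIGN_SEED)
    design = design_array(gene_models, ArrayDesignParams(seed=_DESIGN_SEED))
    pedigree = make_trio_pedigree(n_trios)
    children = [p for p in pedigree if p.mother_id is not None]
    by_id = {p.sample_id: p for p in pedigree}

    chroms = list(TOY_CHROM_LENGTHS)
    pos_by_chrom = {
        c: design.loc[design["chrom"] == c, "pos"].to_numpy() for c in chroms
    }
    n_by_chrom = np.array([len(pos_by_chrom[c]) for c in chroms], dtype=float)
    chrom_w = n_by_chrom / n_by_chrom.sum()

    rng = np.random.default_rng(seed)
    used: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    truth: List[TruthCnv] = []
    attempts = 0
    while len(truth) < n_cnvs and attempts < 100_000:
        attempts += 1
        child = children[int(rng.integers(len(children)))]
        chrom = chroms[int(rng.choice(len(chroms), p=chrom_w))]
        p = pos_by_chrom[chrom]
        cnv_type = "loss" if rng.random() < loss_rate else "gain"
        origin = (
            "de_novo" if rng.random() < de_novo_rate
            else ("maternal" if rng.random() < 0.5 else "paternal")
        )
        dosage = "hemizygous" if (chrom == "chrX" and child.sex == "male") else "heterozygous"
        if dosage == "hemizygous" and origin == "paternal":
            origin = "maternal"  # a boy's X is maternal; fathers contribute Y
        mosaic = (
            origin == "de_novo" and dosage == "heterozygous" and cnv_type == "loss"
            and rng.random() < mosaic_rate
        )
        lo_n = max(min_probes, _MOSAIC_MIN_PROBES) if mosaic else min_probes
        if len(p) <= lo_n:
            continue
        span = int(round(math.exp(rng.uniform(math.log(lo_n), math.log(max_probes)))))
        span = int(np.clip(span, lo_n, min(max_probes, len(p))))
        a = int(rng.integers(0, len(p) - span + 1))
        b = a + span - 1
        key = (child.sample_id, chrom)
        if any(a <= e + min_probes and s - min_probes <= b for s, e in used.get(key, [])):
            continue
        used.setdefault(key, []).append((a, b))
        f = float(rng.uniform(*_MOSAIC_F_RANGE)) if mosaic else 1.0
        truth.append(
            TruthCnv(
                sample_id=child.sample_id,
                chrom=chrom,
                start=int(p[a]),
                end=int(p[b]),
                type=cnv_type,
                allele_dosage=dosage,
                mosaic_fraction=f,
                origin=origin,
            )
        )
    if len(truth) < n_cnvs:
        raise RuntimeError("could not place all truth CNVs without collisions")

    profiles, truth_table = simulate_cohort(
        design, pedigree, truth, noise_sd=noise_sd, seed=seed
    )
    return ValidationCohort(
        gene_models=gene_models,
        design=design,
        pedigree=pedigree,
        truth=truth,
        truth_table=truth_table,
        profiles=profiles,
        noise_sd=noise_sd,
        seed=seed,
    )
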