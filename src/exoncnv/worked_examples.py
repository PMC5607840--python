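"""Published worked examples used to verify the size arithmetic and the
cohort bookkeeping.

``REPORTED_CNVS`` lists hg19 coordinates of clinically reported CNV
deletions involving the candidate disease genes ARGLU1, STK3, MEIS2 and
PTCHD1, together with the size as printed in the corresponding case
tables.  ``REPORTED_COHORT_COUNTS`` holds the printed summary counts of
the reference clinical exon-targeted CMA cohort; they are used for
internal-arithmetic consistency checks only (the underlying call
database is proprietary, so the counts themselves are inputs, never
recomputed).
"""

from __future__ import annotations

from typing import List, NamedTuple


class ReportedCnv(NamedTuple):
    gene: str
    chrom: str
    start: int
    end: int
    printed_value: float  # size as printed
    printed_unit: str     # "kb" | "Mb"


REPORTED_CNVS: List[ReportedCnv] = [
    ReportedCnv("ARGLU1", "chr13", 106_624_717, 107_768_458, 1.1, "Mb"),
    ReportedCnv("ARGLU1", "chr13", 104_114_620, 108_292_078, 4.1, "Mb"),
    ReportedCnv("ARGLU1", "chr13", 106_884_343, 110_711_191, 3.8, "Mb"),
    ReportedCnv("STK3", "chr8", 99_591_666, 99_678_567, 87, "kb"),
    ReportedCnv("STK3", "chr8", 99_883_084, 100_026_306, 143, "kb"),
    ReportedCnv("STK3", "chr8", 99_638_463, 99_719_599, 81, "kb"),
    ReportedCnv("STK3", "chr8", 99_524_409, 99_546_574, 22, "kb"),
    ReportedCnv("MEIS2", "chr15", 37_328_986, 37_332_249, 3.2, "kb"),
    ReportedCnv("MEIS2", "chr15", 35_001_138, 39_899_594, 4.9, "Mb"),
    ReportedCnv("MEIS2", "chr15", 33_894_032, 38_659_166, 4.8, "Mb"),
    ReportedCnv("MEIS2", "chr15", 35_001_138, 38_474_933, 3.47, "Mb"),
    ReportedCnv("MEIS2", "chr15", 36_512_757, 38_052_959, 1.54, "Mb"),
    ReportedCnv("MEIS2", "chr15", 36_790_702, 37_404_359, 0.6, "Mb"),
    ReportedCnv("MEIS2", "chr15", 36_606_006, 37_515_525, 0.9, "Mb"),
    ReportedCnv("PTCHD1", "chrX", 23_269_452, 23_364_920, 95, "kb"),
    ReportedCnv("PTCHD1", "chrX", 23_395_713, 23_487_393, 92, "kb"),
    ReportedCnv("PTCHD1", "chrX", 23_140_737, 23_360_470, 220, "kb"),
]


def matches_printed(size_bp: int, printed_value: float, unit: str) -> bool:
    """True when a bp size agrees with a printed kb/Mb value to the
    printed precision.

    Agreement means within one unit in the last printed digit: clinical
    tables round loosely (a 3,264 bp event may be printed "3.2 kb", a
    4,177,459 bp event "4.1 Mb"), so exact half-up rounding is not a
    property of the source values.
    """
    scale = 1e3 if unit == "kb" else 1e6
    decimals = len(str(printed_value).split(".")[1]) if "." in str(printed_value) else 0
    ulp = 10.0 ** (-decimals)
    return abs(size_bp / scale - printed_value) <= ulp


REPORTED_COHORT_COUNTS = {
    "patients_total": 63_127,
    "patients_single_gene_cnv": 7_200,
    "single_gene_cnvs": 8_094,
    "single_exon_cnvs": 1_857,
    "de_novo_autosomal_losses": 117,
    "de_novo_autosomal_gains": 28,
    "de_novo_autosomal_total": 145,
    "x_linked_male_deletions": 257,
    "inherited_autosomal_losses": 878,
    "inherited_autosomal_gains": 171,
    "inherited_autosomal_total": 1_049,
    "candidate_de_novo_deletions": 37,
    "candidate_de_novo_duplications": 10,
    "candidate_x_linked_male": 100,
    "candidate_single_gene_cnvs_total": 147,
    "single_exon_fraction_printed_pct": 23,
    "single_gene_patient_fraction_printed_pct": 11,
}
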