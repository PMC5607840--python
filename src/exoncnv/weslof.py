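"""Rare loss-of-function variant filtering for WES tables.

A variant passes iff it is a predicted LOF class (stop-gain, frameshift
or splicing), has total coverage of at least 20 reads and a variant
allele fraction of at least 0.2, and is rare: MAF no greater than 0.001
in ESP, 1000 Genomes and the local exome database, and no greater than
0.0001 in ExAC.  The exclusion thresholds are strict ("coverage < 20",
"ratio below 0.2", "MAF > 0.001"), so values exactly at a boundary pass.
Absent MAF fields count as 0 (unobserved, not known common).

Missense variants are never counted as LOF; a separate, clearly
labelled channel applies the same support and rarity rules to missense
variants for manual follow-up of inherited missense alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

__all__ = ["LofFilterConfig", "filter_lof_variants", "select_rare_missense", "LOF_CLASSES"]

LOF_CLASSES = frozenset({"stop_gain", "frameshift", "splicing"})

#: fixed rule order for first-failure attribution in the exclusion tally
RULE_ORDER = ("class", "coverage", "vaf", "maf_common", "maf_exac")

_MAF_COMMON_COLS = ("maf_esp", "maf_1kg", "maf_local")


@dataclass(frozen=True)
class LofFilterConfig:
    min_coverage: int = 20
    min_vaf: float = 0.2
    maf_ceiling_common: float = 0.001   # ESP / 1000 Genomes / local
    maf_ceiling_exac: float = 0.0001

    def __post_init__(self):
        if self.min_coverage < 0 or self.maf_ceiling_common < 0 or self.maf_ceiling_exac < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0.0 <= self.min_vaf <= 1.0):
            raise ValueError("min_vaf must be in [0, 1]")


def _rule_failures(df: pd.DataFrame, cfg: LofFilterConfig, lof_only: bool) -> Dict[str, np.ndarray]:
    total = df["total_reads"].to_numpy(dtype=float)
    alt = df["alt_reads"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(total > 0, alt / np.where(total > 0, total, 1.0), 0.0)
    mafs = {
        col: (df[col].to_numpy(dtype=float) if col in df else np.zeros(len(df)))
        for col in (*_MAF_COMMON_COLS, "maf_exac")
    }
    for col, v in mafs.items():
        mafs[col] = np.nan_to_num(v, nan=0.0)
    cls = df["functional_class"].to_numpy()
    fails = {
        "class": (
            ~np.isin(cls, list(LOF_CLASSES))
            if lof_only
            else ~(cls == "missense")
        ),
        "coverage": total < cfg.min_coverage,
        "vaf": vaf < cfg.min_vaf,
        "maf_common": np.any(
            [mafs[c] > cfg.maf_ceiling_common for c in _MAF_COMMON_COLS], axis=0
        ),
        "maf_exac": mafs["maf_exac"] > cfg.maf_ceiling_exac,
    }
    return fails


def _apply(df: pd.DataFrame, cfg: LofFilterConfig, lof_only: bool) -> Tuple[pd.DataFrame, Dict[str, int]]:
    if len(df) == 0:
        return df.copy(), {r: 0 for r in RULE_ORDER}
    fails = _rule_failures(df, cfg, lof_only)
    any_fail = np.any([fails[r] for r in RULE_ORDER], axis=0)
    # first-failing rule per variant, in fixed rule order
    tally = {r: 0 for r in RULE_ORDER}
    remaining = np.ones(len(df), dtype=bool)
    for r in RULE_ORDER:
        first = remaining & fails[r]
        tally[r] = int(first.sum())
        remaining &= ~first
    passing = df.loc[~any_fail].reset_index(drop=True)
    return passing, tally


def filter_lof_variants(
    variants: pd.DataFrame, cfg: LofFilterConfig = LofFilterConfig()
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Filter a WES table to rare, well-supported LOF variants.

    Returns ``(passing, tally)``: the passing rows (original order) and
    a per-rule exclusion tally attributing each excluded variant to its
    first failing rule in the order class, coverage, VAF, common-MAF,
    ExAC-MAF.  ``len(passing) + sum(tally.values()) == len(variants)``.
    """
    return _apply(variants, cfg, lof_only=True)


def select_rare_missense(
    variants: pd.DataFrame, cfg: LofFilterConfig = LofFilterConfig()
) -> pd.DataFrame:
    """Optional missense channel: rare, well-supported missense variants.

    Applies the same coverage/VAF/MAF rules to missense variants only.
    The result carries a ``channel`` column set to ``"missense"`` and is
    never merged into LOF counts.
    """
    passing, _ = _apply(variants, cfg, lof_only=False)
    passing = passing.copy()
    passing["channel"] = "missense"
    return passing
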