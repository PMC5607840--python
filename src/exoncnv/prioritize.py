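"""Candidate-disease-gene prioritization.

Aggregates, per gene, the lines of evidence the cohort analysis
produces — recurrence of de novo CNVs, recurrent male-X CNVs,
additional overlapping deletions in the call database, LOF variants in
WES cohorts, haploinsufficiency/pLI predictions, and manually curated
literature and phenotype-overlap flags — into an integer evidence tally
and a strong/moderate/weak tier.

The criteria are those such cohort studies state; the integer weights,
tier cutoffs and the LOF-tolerance penalty are this package's own
configuration (no canonical formula exists) and every weight is
adjustable so sensitivity can be explored.  A gene with recurrent de
novo events is never penalized for an unfavourable pLI: de novo
recurrence is direct human-genetic evidence and may reflect mechanisms
other than haploinsufficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

__all__ = ["ScoreWeights", "GeneEvidence", "CandidateRank", "score_candidate", "rank_cohort"]


@dataclass(frozen=True)
class ScoreWeights:
    """Integer weights of the evidence tally and the tier cutoffs."""

    de_novo_recurrent: int = 2     # >= 2 de novo CNVs
    de_novo_single: int = 1        # exactly 1 de novo CNV
    x_male_recurrent: int = 1      # >= 2 male-X CNVs
    overlapping_deletions: int = 1  # >= 1 additional deletion <= 5 Mb in the database
    lof_wes: int = 1               # >= 1 rare LOF variant in WES cohorts
    haploinsufficiency: int = 1    # HI rank 0-10% or pLI >= 0.9
    literature: int = 1
    phenotype_overlap: int = 1
    tolerant_penalty: int = 1      # pLI <= 0.1 with zero de novo CNVs
    strong_min: int = 4
    moderate_min: int = 2


@dataclass(frozen=True)
class GeneEvidence:
    """Assembled per-gene evidence.

    ``hi_supportive`` means the haploinsufficiency rank falls in the top
    0-10% band (low rank = likely haploinsufficient); ``pli_intolerant``
    is pLI >= 0.9 and ``pli_tolerant`` pLI <= 0.1.  Literature and
    phenotype-overlap flags are manual curation inputs.
    """

    symbol: str
    n_de_novo_cnv: int = 0
    n_x_male_cnv: int = 0
    n_overlapping_del_5mb: int = 0
    n_lof_wes: int = 0
    hi_score: Optional[float] = None
    pli: Optional[float] = None
    hi_supportive: bool = False
    pli_intolerant: bool = False
    pli_tolerant: bool = False
    literature_flag: bool = False
    phenotype_overlap_flag: bool = False

    def __post_init__(self):
        for name in ("n_de_novo_cnv", "n_x_male_cnv", "n_overlapping_del_5mb", "n_lof_wes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.symbol}: negative count {name}")
        if self.pli_intolerant and self.pli_tolerant:
            raise ValueError(f"{self.symbol}: pli_intolerant and pli_tolerant both set")

    @classmethod
    def from_scores(
        cls,
        symbol: str,
        hi_score: Optional[float] = None,
        pli: Optional[float] = None,
        hi_supportive_band: float = 10.0,
        **kwargs,
    ) -> "GeneEvidence":
        """Derive the HI/pLI flags from raw scores (HI as a 0-100 rank
        percentile, pLI as a probability)."""
        return cls(
            symbol=symbol,
            hi_score=hi_score,
            pli=pli,
            hi_supportive=(hi_score is not None and hi_score <= hi_supportive_band),
            pli_intolerant=(pli is not None and pli >= 0.9),
            pli_tolerant=(pli is not None and pli <= 0.1),
            **kwargs,
        )


@dataclass
class CandidateRank:
    symbol: str
    score: int
    tier: str  # strong | moderate | weak
    criteria_met: List[str]
    contributions: Dict[str, int]
    n_de_novo_cnv: int = 0


def score_candidate(e: GeneEvidence, weights: ScoreWeights = ScoreWeights()) -> CandidateRank:
    """Tally one gene's evidence into a score, tier and audited breakdown.

    The score is the sum of the logged per-criterion contributions, so
    ``rank.score == sum(rank.contributions.values())`` always holds.
    """
    contrib: Dict[str, int] = {}
    if e.n_de_novo_cnv >= 2:
        contrib["de_novo_recurrent"] = weights.de_novo_recurrent
    elif e.n_de_novo_cnv == 1:
        contrib["de_novo_single"] = weights.de_novo_single
    if e.n_x_male_cnv >= 2:
        contrib["x_male_recurrent"] = weights.x_male_recurrent
    if e.n_overlapping_del_5mb >= 1:
        contrib["overlapping_deletions"] = weights.overlapping_deletions
    if e.n_lof_wes >= 1:
        contrib["lof_wes"] = weights.lof_wes
    if e.hi_supportive or e.pli_intolerant:
        contrib["haploinsufficiency"] = weights.haploinsufficiency
    if e.literature_flag:
        contrib["literature"] = weights.literature
    if e.phenotype_overlap_flag:
        contrib["phenotype_overlap"] = weights.phenotype_overlap
    if e.pli_tolerant and e.n_de_novo_cnv == 0:
        contrib["lof_tolerant_penalty"] = -weights.tolerant_penalty
    score = sum(contrib.values())
    if score >= weights.strong_min:
        tier = "strong"
    elif score >= weights.moderate_min:
        tier = "moderate"
    else:
        tier = "weak"
    return CandidateRank(
        symbol=e.symbol,
        score=score,
        tier=tier,
        criteria_met=sorted(k for k, v in contrib.items() if v > 0),
        contributions=contrib,
        n_de_novo_cnv=e.n_de_novo_cnv,
    )


def rank_cohort(
    evidence: Sequence[GeneEvidence], weights: ScoreWeights = ScoreWeights()
) -> pd.DataFrame:
    """Score and rank a cohort's genes.

    Deterministic stable sort by (score desc, n_de_novo_cnv desc,
    symbol asc).  Duplicate symbols are an error.
    """
    symbols = [e.symbol for e in evidence]
    if len(set(symbols)) != len(symbols):
        dupes = sorted({s for s in symbols if symbols.count(s) > 1})
        raise ValueError(f"duplicate gene symbols: {dupes}")
    ranks = [score_candidate(e, weights) for e in evidence]
    ranks.sort(key=lambda r: (-r.score, -r.n_de_novo_cnv, r.symbol))
    return pd.DataFrame(
        {
            "symbol": [r.symbol for r in ranks],
            "score": [r.score for r in ranks],
            "tier": [r.tier for r in ranks],
            "criteria_met": [",".join(r.criteria_met) for r in ranks],
            "n_de_novo_cnv": [r.n_de_novo_cnv for r in ranks],
        }
    )
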