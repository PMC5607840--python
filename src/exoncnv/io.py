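"""Flat-file I/O for every pipeline artifact.

All formats are plain tab-delimited text with headers, 1-based inclusive
coordinates:

* probe tables     ``probe_id chrom pos class [log2]``
* truth sets       ``chrom start end sample type dosage mosaic_fraction origin``
* pedigrees        ``sample sex mother father``  ("." = absent)
* gene exons       ``symbol chrom strand exon_start exon_end``
* gene metadata    ``symbol omim_mode sfari dosage_sensitive hi_score pli``
* calls            ``chrom start end sample type n_probes mean_log2 mosaic_fraction_est``
* BED-like tracks  ``chrom start end [type|label]``
"""

from __future__ import annotations

import json
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .annotation import GeneRecord
from .calling import CnvCall
from .classification import DgvEntry
from .synthetic import Pedigree, TruthCnv

_MISSING = "."


def write_probe_table(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"probe_class": "class"})
    out.to_csv(path, sep="\t", index=False)


def read_probe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"class": "probe_class"})


def write_truth_table(truth_df: pd.DataFrame, path) -> None:
    truth_df.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> List[TruthCnv]:
    df = pd.read_csv(path, sep="\t")
    return [
        TruthCnv(
            sample_id=r["sample"], chrom=r["chrom"], start=int(r["start"]),
            end=int(r["end"]), type=r["type"], allele_dosage=r["dosage"],
            mosaic_fraction=float(r["mosaic_fraction"]), origin=r["origin"],
        )
        for _, r in df.iterrows()
    ]


def write_pedigree(pedigree: Sequence[Pedigree], path) -> None:
    rows = [
        (p.sample_id, p.sex, p.mother_id or _MISSING, p.father_id or _MISSING)
        for p in pedigree
    ]
    pd.DataFrame(rows, columns=["sample", "sex", "mother", "father"]).to_csv(
        path, sep="\t", index=False
    )


def read_pedigree(path) -> List[Pedigree]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        out.append(
            Pedigree(
                sample_id=r["sample"],
                sex=r["sex"],
                mother_id=None if r["mother"] in (_MISSING, "0") else r["mother"],
                father_id=None if r["father"] in (_MISSING, "0") else r["father"],
            )
        )
    return out


def write_gene_models(genes: Sequence[GeneRecord], exon_path, metadata_path) -> None:
    ex_rows, md_rows = [], []
    for g in genes:
        for s, e in g.exons:
            ex_rows.append((g.symbol, g.chrom, g.strand, s, e))
        md_rows.append(
            (g.symbol, ",".join(sorted(g.omim_mode)) or _MISSING, int(g.sfari),
             int(g.dosage_sensitive),
             _MISSING if g.hi_score is None else g.hi_score,
             _MISSING if g.pli is None else g.pli)
        )
    pd.DataFrame(
        ex_rows, columns=["symbol", "chrom", "strand", "exon_start", "exon_end"]
    ).to_csv(exon_path, sep="\t", index=False)
    pd.DataFrame(
        md_rows,
        columns=["symbol", "omim_mode", "sfari", "dosage_sensitive", "hi_score", "pli"],
    ).to_csv(metadata_path, sep="\t", index=False)


def read_gene_models(exon_path, metadata_path=None) -> List[GeneRecord]:
    ex = pd.read_csv(exon_path, sep="\t")
    md = {}
    if metadata_path is not None:
        for _, r in pd.read_csv(metadata_path, sep="\t", dtype=str).iterrows():
            md[r["symbol"]] = r
    genes = []
    for (symbol, chrom, strand), grp in ex.groupby(["symbol", "chrom", "strand"], sort=False):
        exons = tuple(
            sorted((int(s), int(e)) for s, e in zip(grp["exon_start"], grp["exon_end"]))
        )
        r = md.get(symbol)
        kwargs = {}
        if r is not None:
            mode = r["omim_mode"]
            kwargs = dict(
                omim_mode=frozenset() if mode in (_MISSING, "", None) else frozenset(mode.split(",")),
                sfari=bool(int(r["sfari"])),
                dosage_sensitive=bool(int(r["dosage_sensitive"])),
                hi_score=None if r["hi_score"] == _MISSING else float(r["hi_score"]),
                pli=None if r["pli"] == _MISSING else float(r["pli"]),
            )
        genes.append(GeneRecord(symbol=symbol, chrom=chrom, strand=strand, exons=exons, **kwargs))
    return genes


def write_calls(calls: Sequence[CnvCall], path) -> None:
    rows = [
        (c.chrom, c.start, c.end, c.sample_id or _MISSING, c.type, c.n_probes,
         c.mean_log2, _MISSING if c.mosaic_fraction_est is None else c.mosaic_fraction_est)
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "sample", "type", "n_probes",
                 "mean_log2", "mosaic_fraction_est"],
    ).to_csv(path, sep="\t", index=False)


def read_calls(path) -> List[CnvCall]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        est = r["mosaic_fraction_est"]
        out.append(
            CnvCall(
                sample_id=None if r["sample"] == _MISSING else r["sample"],
                chrom=r["chrom"], start=int(r["start"]), end=int(r["end"]),
                type=r["type"], n_probes=int(r["n_probes"]),
                mean_log2=float(r["mean_log2"]),
                mosaic_fraction_est=None if est in (_MISSING,) or pd.isna(est) else float(est),
            )
        )
    return out


def read_dgv_track(path) -> List[DgvEntry]:
    df = pd.read_csv(path, sep="\t")
    return [
        DgvEntry(r["chrom"], int(r["start"]), int(r["end"]), r.get("type", "both"))
        for _, r in df.iterrows()
    ]


def read_bed_track(path, with_label: bool = False):
    df = pd.read_csv(path, sep="\t")
    if with_label:
        return [
            (r["chrom"], int(r["start"]), int(r["end"]), str(r.get("label", "")))
            for _, r in df.iterrows()
        ]
    return [(r["chrom"], int(r["start"]), int(r["end"])) for _, r in df.iterrows()]


def write_cascade_summary(counts, path) -> None:
    payload = {
        "n_patients": counts.n_patients,
        "n_cnvs": counts.n_cnvs,
        "n_single_gene": counts.n_single_gene,
        "n_multi_2_5": counts.n_multi_2_5,
        "n_gt5": counts.n_gt5,
        "n_no_gene": counts.n_no_gene,
        "n_de_novo_autosomal": counts.n_de_novo_autosomal,
        "n_de_novo_autosomal_losses": counts.n_de_novo_autosomal_losses,
        "n_de_novo_autosomal_gains": counts.n_de_novo_autosomal_gains,
        "n_x_male": counts.n_x_male,
        "n_inherited": counts.n_inherited,
        "n_inherited_losses": counts.n_inherited_losses,
        "n_inherited_gains": counts.n_inherited_gains,
        "n_single_exon": counts.n_single_exon,
        "bucket_counts": counts.bucket_counts,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
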