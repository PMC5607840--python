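import numpy as np
import pandas as pd
import pytest

from exoncnv import (
    ArrayDesignParams,
    GeneRecord,
    Pedigree,
    TruthCnv,
    design_array,
    toy_gene_models,
)


@pytest.fixture(scope="session")
def gene_models():
    return toy_gene_models(seed=2017)


@pytest.fixture(scope="session")
def design(gene_models):
    return design_array(gene_models, ArrayDesignParams(seed=2017))


@pytest.fixture
def trio():
    return [
        Pedigree("MO", "female"),
        Pedigree("FA", "male"),
        Pedigree("CH", "male", mother_id="MO", father_id="FA"),
    ]


@pytest.fixture
def five_exon_gene():
    # 5 exons of 100 bp, 1 kb apart, span 1000-5499
    exons = tuple((1000 + i * 1100, 1099 + i * 1100) for i in range(5))
    return GeneRecord(symbol="G5", chrom="chr1", exons=exons)


def probe_frame(log2_values, chrom="chr1", spacing=100, start=1000):
    """Minimal sorted probe table from a list of log2 ratios."""
    n = len(log2_values)
    return pd.DataFrame(
        {
            "probe_id": [f"P{i:04d}" for i in range(n)],
            "chrom": [chrom] * n,
            "pos": [start + i * spacing for i in range(n)],
            "probe_class": ["exonic"] * n,
            "log2": list(map(float, log2_values)),
        }
    )


@pytest.fixture
def make_probes():
    return probe_frame
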