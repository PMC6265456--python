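import numpy as np
import pandas as pd
import pytest

from exodecomp.simulate import GeneratorConfig, generate_dataset
from exodecomp.types import GeneModel


@pytest.fixture(scope="session")
def small_dataset():
    """A compact full dataset shared by read-only tests."""
    cfg = GeneratorConfig(seed=7, n_genes=150, n_enhancers=12)
    return generate_dataset(cfg)


@pytest.fixture
def toy_design():
    """Minimal two-condition design: 3 RNAseq replicates per cell."""
    rows = []
    for state in ("ESC", "EBd3"):
        for condition in ("control", "RRP40_KD"):
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "sample_id": f"RNAseq_{state}_{condition}_r{rep}",
                        "assay": "RNAseq",
                        "state": state,
                        "condition": condition,
                        "replicate": rep,
                        "batch": "b1",
                        "library_factor": 1.0,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def make_gene(gene_id="G1", chrom="chr1", strand="+", start=1000,
              exons=((1000, 1200), (1500, 1800)), biotype="protein_coding"):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        start=start, end=exons[-1][1], exons=tuple(exons), biotype=biotype,
    )
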