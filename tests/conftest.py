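import numpy as np
import pandas as pd
import pytest

from cofitval.data_io import FitnessTable, GeneRecord, GenomeAnnotation


@pytest.fixture
def tiny_annotation() -> GenomeAnnotation:
    """Six genes, two scaffolds: a 2-gene (+) operon candidate, a lone (-)
    gene far downstream, and three genes on a second scaffold."""
    genes = [
        GeneRecord("g1", "sc1", 100, 1000, "+"),
        GeneRecord("g2", "sc1", 1100, 2000, "+"),
        GeneRecord("g3", "sc1", 80_000, 81_000, "-"),
        GeneRecord("g4", "sc2", 200, 900, "+"),
        GeneRecord("g5", "sc2", 1000, 1600, "-"),
        GeneRecord("g6", "sc2", 60_000, 61_000, "+"),
    ]
    return GenomeAnnotation("tiny", genes)


def _table_from_rows(rows: dict[str, np.ndarray], genome_id="tiny") -> FitnessTable:
    df = pd.DataFrame(rows).T
    df.columns = [f"exp{j + 1:03d}" for j in range(df.shape[1])]
    return FitnessTable(genome_id, df, df * 2.0)


@pytest.fixture
def table_from_rows():
    return _table_from_rows


@pytest.fixture
def tiny_table(tiny_annotation) -> FitnessTable:
    rng = np.random.default_rng(1)
    rows = {g.locus_id: rng.standard_normal(30) for g in tiny_annotation.genes}
    return _table_from_rows(rows)
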