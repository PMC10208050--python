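import numpy as np
import pandas as pd
import pytest

from cernet.expression import ExpressionMatrix
from cernet.synthetic import SynthConfig


@pytest.fixture
def small_config() -> SynthConfig:
    """A fast study configuration used across tests."""
    return SynthConfig(
        n_genes=300,
        frac_lncrna=0.1,
        probes_per_gene=2,
        n_samples_per_group=10,
        n_de_mrna=30,
        n_de_lncrna=8,
        n_mirnas=30,
        n_hub_lncrnas=3,
        hub_degree=8,
        bg_interaction_prob=0.02,
        db_overlap_frac=0.3,
        n_gene_sets=20,
        set_size_range=(10, 20),
        n_enriched_sets=2,
        seed=11,
    )


def make_matrix(values, samples=None, groups=None, scale="log2", level="gene", index=None):
    """Convenience constructor for small hand-built expression matrices."""
    arr = np.asarray(values, dtype=float)
    samples = samples or [f"S{i}" for i in range(arr.shape[1])]
    if groups is None:
        half = arr.shape[1] // 2
        groups = {s: ("day0" if i < half else "day8") for i, s in enumerate(samples)}
    index = index if index is not None else [f"g{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=index, columns=samples)
    return ExpressionMatrix(values=df, sample_groups=groups, scale=scale, level=level)


@pytest.fixture
def annot_13_genes() -> pd.DataFrame:
    """Annotation for 13 genes (9 mRNA + 4 lncRNA), one probe each."""
    rows = []
    for i in range(9):
        rows.append((f"p_m{i}", f"M{i}", "mRNA", "1q21", 100, 200))
    for i in range(4):
        rows.append((f"p_l{i}", f"L{i}", "lncRNA", "2p11", 100, 200))
    return pd.DataFrame(
        rows, columns=["probe_id", "gene_symbol", "biotype", "chromosome_band", "start", "end"]
    ).set_index("probe_id")
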