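import numpy as np
import pandas as pd
import pytest

import phregulon as pr


def make_matrix(values, gene_ids=None, sample_ids=None, spike_ids=(), scale="raw"):
    """Build an ExpressionMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    flags = pd.Series(df.index.isin(set(spike_ids)), index=df.index)
    return pr.ExpressionMatrix(values=df, spike_flags=flags, scale=scale)


def make_meta(samples):
    """samples: list of (sample, strain, pH, replicate)."""
    df = pd.DataFrame(samples, columns=["sample", "strain", "pH", "replicate"]).set_index("sample")
    return pr.SampleMetadata(table=df)


def full_design(replicates=3, strains=("wt", "dpacC")):
    rows = []
    for strain in strains:
        for ph in (4, 8):
            for r in range(1, replicates + 1):
                rows.append((f"{strain}_pH{ph}_r{r}", strain, ph, r))
    return make_meta(rows)


@pytest.fixture(scope="session")
def small_experiment():
    """A 400-gene synthetic experiment with default study conditions."""
    cfg = pr.SyntheticConfig(
        n_genes=400,
        archetype_sizes={"ph_up": 10, "ph_down": 10, "pacc_up": 10, "pacc_down": 10,
                         "acid_up": 5, "acid_down": 5, "gating_up": 5, "gating_down": 5},
        seed=7,
    )
    return pr.generate_expression_experiment(cfg)


@pytest.fixture(scope="session")
def small_model(small_experiment):
    matrix, meta, spikes, truth = small_experiment
    norm, _ = pr.normalize_expression(matrix, spikes)
    return pr.with_prior(pr.fit_condition_means(norm, meta))
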