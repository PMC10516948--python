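import numpy as np
import pandas as pd
import pytest

from cameta.expression import CountMatrix
from cameta.pangenome import GeneCall
from cameta.synthetic import SimulationConfig, generate_pangenome


def make_call(gene_id, genome_id="G1", aa="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", **kw):
    defaults = dict(contig=genome_id, start=0, end=3 * len(aa), strand="+", aa_sequence=aa)
    defaults.update(kw)
    return GeneCall(gene_id=gene_id, genome_id=genome_id, **defaults)


@pytest.fixture(scope="session")
def small_pangenome_data():
    """Synthetic 3-genome pangenome with sequences, gene calls and truth."""
    cfg = SimulationConfig(
        n_genomes=3, n_core_clusters=15, n_accessory_clusters=15, rng_seed=101
    )
    genomes, calls, truth = generate_pangenome(cfg)
    return cfg, genomes, calls, truth


@pytest.fixture()
def two_group_counts():
    """NB counts for 3 BC vs 3 WAF samples with no true signal."""
    rng = np.random.default_rng(7)
    n_genes = 400
    m = 50 * np.exp(rng.normal(0, 1, n_genes))
    mean = m[:, None] * np.ones(6)[None, :]
    y = rng.negative_binomial(10, 10 / (10 + mean))
    cols = ["BC_r1", "BC_r2", "BC_r3", "WAF_r1", "WAF_r2", "WAF_r3"]
    idx = [f"g{i:04d}" for i in range(n_genes)]
    counts = CountMatrix(
        counts=pd.DataFrame(y, index=idx, columns=cols),
        gene_lengths=pd.Series(900, index=idx),
    )
    samples = pd.DataFrame(
        {
            "sample_id": cols,
            "treatment": ["BC"] * 3 + ["WAF"] * 3,
            "time_days": 0.0,
            "replicate": ["r1", "r2", "r3"] * 2,
        }
    )
    return counts, samples
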