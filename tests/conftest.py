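import numpy as np
import pytest

from eqtlkit.io_formats import MISSING, VariantTable
from eqtlkit.synthetic_data import SimulationConfig, simulate_genotypes


def make_table(calls, pos=None, chrom=None, sample_ids=None, ref=None, alt=None):
    """Small VariantTable from a (samples x snps) list of codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return VariantTable(
        snp_id=np.array([f"s{j}" for j in range(m)], dtype=object),
        chrom=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, m + 1) * 100),
        ref=np.array(ref if ref is not None else ["A"] * m, dtype=object),
        alt=np.array(alt if alt is not None else ["T"] * m, dtype=object),
        calls=calls,
        sample_ids=sample_ids or [f"ind{i}" for i in range(n)],
    )


@pytest.fixture(scope="session")
def small_panel():
    """A modest simulated genotype panel + annotation shared across tests."""
    cfg = SimulationConfig(
        seed=11, n_samples=120, n_snps=2000, n_genes=40, n_local_eqtl=10,
        n_distant_eqtl=4,
    )
    table, ann = simulate_genotypes(cfg)
    return cfg, table, ann
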