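import numpy as np
import pandas as pd
import pytest

from admixscan import AncestryMatrix, PopulationSample, SimConfig


@pytest.fixture
def small_cfg():
    return SimConfig(n_loci=2000, n_chrom=2, seed=11)


@pytest.fixture
def small_matrix(small_cfg):
    from admixscan import simulate_ancestry_frequencies

    mat, truth = simulate_ancestry_frequencies(small_cfg)
    return mat, truth


@pytest.fixture
def pop_metadata(small_cfg):
    return [
        PopulationSample(pid, "maize", e)
        for pid, e in zip(small_cfg.pop_ids, small_cfg.elevations_km)
    ]


def toy_matrix(values, chrom="chr1", start=100, step=100):
    """AncestryMatrix from a plain loci x pops array (1 cM/Mbp positions)."""
    values = np.asarray(values, float)
    L, P = values.shape
    pos = start + step * np.arange(L)
    loci = pd.DataFrame(
        {"chrom": chrom, "pos_bp": pos, "pos_cM": pos / 1e6}
    )
    freqs = pd.DataFrame(values, columns=[f"pop{i:02d}" for i in range(P)])
    return AncestryMatrix(loci=loci, freqs=freqs).validate()
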