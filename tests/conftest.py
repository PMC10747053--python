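import numpy as np
import pandas as pd
import pytest

from sojapop.genotypes import GenotypeMatrix
from sojapop.sim import SimConfig, simulate


def make_gm(dosage, chrom="Gs01", positions=None, chrom_length=None, samples=None):
    """Build a GenotypeMatrix from a raw dosage array (rows = samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    positions = list(positions) if positions is not None else list(range(1, m + 1))
    sites = pd.DataFrame({
        "chrom": [chrom] * m, "pos": positions,
        "ref": ["A"] * m, "alt": ["T"] * m,
    })
    samples = samples or [f"S{i}" for i in range(n)]
    lengths = {chrom: chrom_length or max(positions)}
    return GenotypeMatrix(samples, sites, dosage, lengths)


@pytest.fixture(scope="session")
def small_sim():
    """A 60-sample, 3-group panel with planted sweeps and adaptive loci."""
    cfg = SimConfig(seed=5, n_snps=4000, n_chrom=2, chrom_length=5_000_000,
                    locations_per_group=4, samples_per_location=5)
    return simulate(cfg)


@pytest.fixture(scope="session")
def group_samples(small_sim):
    return {g: list(sub["sample"])
            for g, sub in small_sim.metadata.groupby("group")}
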