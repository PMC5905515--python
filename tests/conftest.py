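import numpy as np
import pytest

from feralsweep.datatypes import VariantTable


def make_vt(dosages, pos=None, chrom="chr1", samples=None) -> VariantTable:
    """Small VariantTable from a (sites x samples) dosage list."""
    d = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = d.shape
    if pos is None:
        pos = np.arange(n_sites) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    chroms = np.array([chrom] * n_sites, dtype=object)
    return VariantTable(chroms, np.asarray(pos), np.array(["A"] * n_sites, dtype=object),
                        np.array(["G"] * n_sites, dtype=object), d, samples)


@pytest.fixture
def two_pop_cohort():
    """Balding-Nichols cohort with moderate differentiation, reused across
    modules (seeded, 2 pops x 50 diploids, 2000 sites)."""
    from feralsweep.simulate import SimConfig, simulate_genotypes

    cfg = SimConfig(seed=42, pop_names=("A", "B"), groups={}, samples_per_pop=50,
                    chrom_lengths={"chr1": 1_000_000}, n_sites=2000, F=0.1)
    vt, pmap = simulate_genotypes(cfg)
    return vt, pmap, cfg
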