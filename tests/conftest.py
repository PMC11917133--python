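import numpy as np
import pytest

from divscan.io import PopulationMap, VariantTable


def make_vt(genotypes, chrom=None, pos=None, samples=None, info=None):
    """Quick VariantTable from a (sites x samples) genotype array."""
    g = np.asarray(genotypes, dtype=np.int8)
    S, N = g.shape
    chrom = np.array(["chr1"] * S, dtype=object) if chrom is None else np.asarray(chrom, dtype=object)
    pos = np.arange(1, S + 1) if pos is None else np.asarray(pos)
    samples = [f"s{j}" for j in range(N)] if samples is None else samples
    ref = np.array(["A"] * S, dtype=object)
    alt = np.array(["T"] * S, dtype=object)
    return VariantTable(chrom, pos, ref, alt, g, samples, info)


def make_pm(vt, groups):
    """PopulationMap assigning vt's samples to labels by group sizes.

    ``groups`` maps label -> count, consumed in order over vt.samples.
    """
    it = iter(vt.samples)
    return PopulationMap({s: lab for lab, n in groups.items() for s in
                          [next(it) for _ in range(n)]})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
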