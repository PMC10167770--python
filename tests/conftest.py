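import numpy as np
import pandas as pd
import pytest

from hybridgp import GenotypeMatrix, SimConfig, simulate_study


def make_genotypes(codes, lines=None, markers=None, chrom=None):
    """Small GenotypeMatrix builder for hand-written examples."""
    codes = np.asarray(codes, dtype=float)
    n, m = codes.shape
    lines = lines or [f"L{i + 1}" for i in range(n)]
    markers = markers or [f"M{j + 1}" for j in range(m)]
    chrom = chrom or ["1"] * m
    marker_map = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(m) * 100 + 100,
         "ref": "A", "alt": "T"},
        index=pd.Index(markers, name="marker"),
    )
    return GenotypeMatrix(lines=lines, markers=markers, codes=codes,
                          marker_map=marker_map)


@pytest.fixture(scope="session")
def desk_study():
    """Small complete synthetic study shared across read-only tests."""
    return simulate_study(SimConfig(n_markers=400, n_qtl=80, seed=11))


@pytest.fixture(scope="session")
def reference_study():
    """Study-shaped design (204 hybrids, 3 testers, 44 shared pollinators)."""
    return simulate_study(
        SimConfig.reference_design(n_markers=500, n_qtl=100, seed=7)
    )
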