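import numpy as np
import pytest
from hypothesis import settings

from autozyg import GenotypeMatrix, MarkerMap, SimConfig, simulate_balding_nichols

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_map(bps, chrom="1", cm=None):
    bps = np.asarray(bps, dtype=np.int64)
    if np.ndim(chrom) == 0:
        chroms = np.full(len(bps), str(chrom), dtype=object)
    else:
        chroms = np.asarray(chrom, dtype=object)
    ids = np.array([f"m{c}_{b}" for c, b in zip(chroms, bps)], dtype=object)
    cm = bps * 1e-6 if cm is None else np.asarray(cm, dtype=float)
    return MarkerMap(chroms, ids, cm, bps)


def make_genotypes(codes, bps=None, chrom="1", populations=None, cm=None):
    codes = np.asarray(codes, dtype=np.int8)
    if bps is None:
        bps = (np.arange(codes.shape[1]) + 1) * 100_000
    markers = make_map(bps, chrom, cm)
    samples = np.array([f"s{i+1}" for i in range(codes.shape[0])], dtype=object)
    pops = (np.full(codes.shape[0], "P1", dtype=object) if populations is None
            else np.asarray(populations, dtype=object))
    return GenotypeMatrix(samples, pops, codes, markers)


@pytest.fixture(scope="session")
def bn_two_pops():
    """Two Balding-Nichols populations at F = 0.1, clean genotypes."""
    cfg = SimConfig(seed=101, populations={"A": 50, "B": 50},
                    divergence_f={"A": 0.1, "B": 0.1},
                    genotyping_error=0.0, missingness=0.0)
    g, truth = simulate_balding_nichols(cfg)
    return g, truth
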