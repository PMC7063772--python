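import numpy as np
import pytest

from codonfold.dlfe import DLFEResult, position_wilcoxon
from codonfold.sequence_io import CodingSequence, GenomeDataset
from codonfold.synthetic_data import SimulationConfig, generate_genome

GRID = np.arange(0, 301, 10)


@pytest.fixture(scope="session")
def small_genome() -> GenomeDataset:
    cfg = SimulationConfig(n_cds=20, cds_length=300, target_gc=0.5, seed=11)
    return generate_genome(cfg, "SP_small", seed=11)


def make_designed_result(target_means, n_cds=30, n_rand=20, noise_sd=0.1,
                         seed=0, species_id="designed", anchor="start"):
    """DLFEResult whose d_i(p, n) are drawn around designed position means.

    Lets rule logic be tested against profiles with known shape without
    running the folding pipeline.
    """
    rng = np.random.default_rng(seed)
    target = np.asarray(target_means, dtype=float)
    assert len(target) == len(GRID)
    diffs = {}
    for p in range(n_cds):
        d = target[None, :] + rng.normal(0, noise_sd, (n_rand, len(GRID)))
        diffs[f"g{p}"] = (GRID.copy(), d)
    stacked = np.concatenate([d for _, d in diffs.values()], axis=0)
    mean_dlfe = np.mean([d.mean(axis=0) for _, d in diffs.values()], axis=0)
    p_values = np.array([position_wilcoxon(stacked[:, j])
                         for j in range(len(GRID))])
    return DLFEResult(species_id, anchor, GRID.copy(), mean_dlfe,
                      np.full(len(GRID), n_cds), p_values, diffs)


@pytest.fixture
def designed_result_factory():
    return make_designed_result
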