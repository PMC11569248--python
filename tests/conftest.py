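import numpy as np
import pytest

from epitype.model import EpitypeModel, ModelConfig
from epitype.regions import DataConfig
from epitype.tracks import BinnedTrack, GenomeIndex


@pytest.fixture
def toy_genome() -> GenomeIndex:
    return GenomeIndex(("chr1", "chr2"), (2048, 1000))


@pytest.fixture
def tiny_dcfg() -> DataConfig:
    # smallest geometry that exercises every constraint: 64-bp bins,
    # 512-bp predictive window inside a 1024-bp input, wider local window
    return DataConfig(
        window_len=512, input_len=1024, local_atac_len=1280, bin=64,
        shift_max=64,
    )


@pytest.fixture
def tiny_mcfg(tiny_dcfg) -> ModelConfig:
    return ModelConfig(
        data=tiny_dcfg, n_marks=2, n_marker_genes=2, backbone_channels=8,
        trunk_channels=8, local_embed_dim=4, global_embed_dim=4,
        hidden_dim=16, combined_channels=8, seed=0,
    )


@pytest.fixture
def tiny_model(tiny_mcfg) -> EpitypeModel:
    return EpitypeModel(tiny_mcfg)


@pytest.fixture
def toy_dcfg() -> DataConfig:
    return DataConfig()  # 4096/2048/128 desk-scale profile


@pytest.fixture
def toy_mcfg(toy_dcfg) -> ModelConfig:
    return ModelConfig(data=toy_dcfg, n_marks=3, n_marker_genes=8, seed=0)


def random_track(genome: GenomeIndex, bin_size: int, rng, **kw) -> BinnedTrack:
    values = {
        c: np.abs(rng.normal(size=genome.n_bins(c, bin_size)))
        for c in genome.names
    }
    return BinnedTrack(genome, bin_size, values, **kw)
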