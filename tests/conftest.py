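import numpy as np
import pytest

from tfkscope import AnalysisParams, SynthConfig, analyze_synthetic


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig(seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def noise0_run(default_config):
    """One noiseless synthetic sample analyzed end to end (shared: the
    render + analysis is the expensive part of the suite)."""
    truth, img, analysis = analyze_synthetic(default_config)
    return truth, img, analysis


@pytest.fixture(scope="session")
def dense_overlap_config() -> SynthConfig:
    """Dense, overlap-allowed tissue for region-recovery tests: real
    follicles are packed with B cells, which the sparse counting-oriented
    default does not emulate."""
    return SynthConfig(
        seed=3, noise_sd=0.0, image_shape=(512, 512), n_follicles=2,
        follicle_radius_px=90, follicle_radius_sd=5, gc_fraction=0.65,
        cell_counts={"B": 250, "GC-B": 200, "T_FH": 15, "T_FK": 5,
                     "Treg": 8, "other": 10},
        planted_contact_pairs=0, allow_overlap=True,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def small_image(channels: dict[str, np.ndarray], **kwargs):
    from tfkscope import MultiChannelImage
    return MultiChannelImage(channels=channels, **kwargs)
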