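import numpy as np
import pytest

from zfstage import embryosim, plateio, stagenet


@pytest.fixture(scope="session")
def tiny_plate(tmp_path_factory):
    """4 wells x 10 frames at 28.5 degC, 64x96 px; shared read-only."""
    out = tmp_path_factory.mktemp("plate28")
    spec = embryosim.SimPlateSpec(
        n_wells=4, temperature=28.5, t_start=3.0, interval=1.0, n_frames=10,
        image_height=64, image_width=96, seed=42,
    )
    manifest = embryosim.simulate_plate(spec, out)
    return spec, out, manifest


@pytest.fixture(scope="session")
def tiny_manifest(tiny_plate):
    _, out, _ = tiny_plate
    return plateio.load_manifest(out / "manifest.csv")


@pytest.fixture
def micro_config():
    """Smallest config that still exercises every layer type."""
    return stagenet.StageModelConfig(
        input_height=16, input_width=24, crop_width=16,
        n_conv_units=2, filters_per_unit=(2, 3), dense_width=4,
        dropout_rate=0.0, learning_rate=1e-2, epochs=3, batch_size=8, seed=0,
    )


@pytest.fixture
def no_augmentation():
    return stagenet.AugmentationConfig(
        p_hist_equalise=0.0, p_saturation=0.0, noise_sigma=0.0,
        p_flip_h=0.0, p_flip_v=0.0, max_x_translation=0.0, max_zoom=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
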