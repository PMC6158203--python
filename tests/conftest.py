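import numpy as np
import pytest

from jawstrain import jawmodel, synthgen


@pytest.fixture(scope="session")
def wt_volume():
    return synthgen.build_parametric_jaw(synthgen.shape_preset("wt"))


@pytest.fixture(scope="session")
def mutant_volume():
    return synthgen.build_parametric_jaw(synthgen.shape_preset("mutant"))


@pytest.fixture(scope="session")
def bimodal_stack(wt_volume):
    """The standard noisy bimodal rendering used by segmentation tests."""
    noise = synthgen.NoiseModel(background_mean=30, foreground_mean=200, sd=10, seed=7)
    return synthgen.render_stack(wt_volume, noise)


@pytest.fixture(scope="session")
def factorial_default():
    """One full 2x2 factorial (both steps) on the default presets."""
    return jawmodel.run_factorial()


def cube_volume(n: int, label: int = 1, pad: int = 1, voxel_size: float = 1.0):
    """Solid n^3 cube of a single label, padded with background."""
    from jawstrain.volume import LabelVolume

    g = np.zeros((n + 2 * pad,) * 3, dtype=np.uint8)
    g[pad : pad + n, pad : pad + n, pad : pad + n] = label
    return LabelVolume(g, voxel_size=voxel_size)
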