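import numpy as np
import pytest

from mslesion.calibration import ReflectanceCube, calibrate
from mslesion.dataset import LabeledDataset
from mslesion.phantom import CLASS_NAMES, SimulationConfig, simulate_dataset


def make_random_cubes(counts: dict[str, int], side: int = 8, bands: int = 3,
                      seed: int = 0) -> LabeledDataset:
    """Random-valued labeled cubes for protocol tests that don't need optics."""
    rng = np.random.default_rng(seed)
    wavelengths = tuple(400.0 + 50.0 * i for i in range(bands))
    cubes = []
    for label, n in counts.items():
        for i in range(n):
            cubes.append(ReflectanceCube(
                values=rng.random((side, side, bands)),
                wavelengths_nm=wavelengths, label=label,
                provenance={"index": i}))
    return LabeledDataset(cubes, tuple(counts))


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(
        frame_shape=(32, 32), sensor_noise_sd=0.0, dark_noise_sd=0.0,
        class_counts={"nevus": 2, "melanoma": 2, "bcc": 2}, seed=11)


@pytest.fixture(scope="session")
def noiseless_captures(noiseless_config):
    return simulate_dataset(noiseless_config)


@pytest.fixture(scope="session")
def small_phantom_dataset():
    """Calibrated 24x24 cubes, 12 per class, fully separable classes."""
    config = SimulationConfig(
        frame_shape=(24, 24), separability_mode="all_bands",
        class_counts={c: 12 for c in CLASS_NAMES}, seed=5)
    captures = simulate_dataset(config)
    data = LabeledDataset([calibrate(c) for c in captures])
    return config, captures, data
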