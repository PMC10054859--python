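import numpy as np
import pytest

import seagrassrs as sg


@pytest.fixture(scope="session")
def default_config() -> sg.SceneConfig:
    return sg.SceneConfig(seed=11)


@pytest.fixture(scope="session")
def noiseless_config() -> sg.SceneConfig:
    return sg.SceneConfig(seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def scene_truth(default_config):
    """A default rendered scene with its truth maps."""
    return sg.simulate_scene(default_config)


@pytest.fixture(scope="session")
def noiseless_scene_truth(noiseless_config):
    return sg.simulate_scene(noiseless_config)


@pytest.fixture(scope="session")
def rois(scene_truth, default_config):
    _, truth = scene_truth
    return sg.make_rois(truth, default_config)


@pytest.fixture(scope="session")
def trained_model(scene_truth, rois):
    """A small but accurate classifier fitted on the default scene's ROIs."""
    scene, _ = scene_truth
    ts = sg.extract_training(scene, rois)
    balanced = sg.balance_classes(ts, n_per_class=2000, seed=3)
    train, test = sg.split_train_test(balanced, seed=3)
    model = sg.train_classifier(train, sg.NetworkConfig(epochs=30, seed=3))
    return model, train, test


def corrected_green(config: sg.SceneConfig):
    """Run simulate -> DOS and return (corrected scene, truth, depth grid)."""
    scene, truth = sg.simulate_scene(config)
    offsets = sg.find_dark_offset(scene, truth.water_mask)
    corrected = sg.dos_correct(scene, offsets)
    depth = sg.tide_adjust(truth.dem, config.tide_height)
    return corrected, truth, depth


def bay_mean_lai_recovery(base_seed: int, lai_mean: float,
                          n_scenes: int = 8) -> float:
    """Relative error of the retrieved bay-mean LAI over replicate scenes.

    Each scene runs the full chain (simulate -> DOS -> R_b -> LAI) with the
    pipeline's optically-deep exclusion (tide-adjusted depth <= 2.5 m), and
    the retrieved mean over scenes is compared to the truth mean over the
    same retained pixels.
    """
    retrieved, truth_means = [], []
    for k in range(n_scenes):
        cfg = sg.SceneConfig(seed=base_seed + k, lai_mean=lai_mean)
        corrected, truth, depth = corrected_green(cfg)
        retained = (truth.class_grid == sg.SEAGRASS) & (depth <= 2.5)
        rb, _ = sg.retrieve_rb(corrected.band("green"), depth, cfg.optics)
        lai = sg.invert_lai(rb, cfg.lai_coeffs, valid=retained)
        retrieved.append(lai.mean)
        truth_means.append(truth.lai_grid[retained].mean())
    truth_mean = float(np.mean(truth_means))
    return abs(float(np.mean(retrieved)) - truth_mean) / truth_mean
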