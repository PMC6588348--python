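import numpy as np
import pytest

import calchip as cc


@pytest.fixture(scope="session")
def small_config() -> cc.SimConfig:
    """A desk-scale experiment: 4 x 20 kb chromosomes, 50 bp reads."""
    return cc.SimConfig(
        seed=11,
        n_chromosomes=4,
        chromosome_length=20_000,
        read_length=50,
        fragment_min=60,
        fragment_max=120,
        reads_per_sample=20_000,
        pericentric_half_width=2_000,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Genomes, anchors and landscapes for the small configuration."""
    experimental, calibration, anchors = cc.make_genomes(small_config)
    landscape = cc.build_landscape(
        experimental,
        anchors,
        small_config.arm_baseline,
        small_config.pericentric_amplitude,
        small_config.pericentric_half_width,
    )
    calib_landscape = cc.uniform_landscape(calibration, 1.0)
    return experimental, calibration, anchors, landscape, calib_landscape


@pytest.fixture(scope="session")
def small_indexes(small_world):
    experimental, calibration, *_ = small_world
    return cc.build_index(calibration), cc.build_index(experimental)


def make_track(label, chroms):
    """CalibratedTrack from {name: list-of-values}."""
    return cc.CalibratedTrack(label, {n: np.asarray(v, dtype=float) for n, v in chroms.items()})
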