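import numpy as np
import pytest

from bonemet import simulate as sim
from bonemet import variants as vr
from bonemet.morphometrics import BinaryMask


@pytest.fixture(scope="session")
def table1_records():
    return vr.read_variant_table(vr.table1_path())


@pytest.fixture(scope="session")
def disc_mask():
    """Rasterized disc of radius 50 centred in a 128x128 frame."""
    truth = sim.SpheroidTruth(base_radius=50)
    return BinaryMask(sim.rasterize_spheroid(truth, (128, 128)))


@pytest.fixture(scope="session")
def ellipse_mask():
    """Axis-aligned 2:1 rasterized ellipse, semi-axes (60, 30)."""
    truth = sim.SpheroidTruth(base_radius=30, axis_ratio=2.0)
    return BinaryMask(sim.rasterize_spheroid(truth, (160, 160)))


@pytest.fixture(scope="session")
def planted_expression():
    """2000-gene matrix with 20 planted axis genes at 3x the noise SD."""
    return sim.gen_expression(
        n_genes=2000,
        n_reps_per_group=3,
        axis_effects=[3.0] * 10 + [-3.0] * 10,
        noise_sd=1.0,
        seed=5,
    )
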