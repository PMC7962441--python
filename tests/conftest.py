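import hypothesis
import numpy as np
import pytest

from fracptt.bioheat import MaterialProps, PhantomGeometry, solve
from fracptt.optics import BeamSpec

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def table1_material():
    return MaterialProps()


@pytest.fixture(scope="session")
def phantom_runs(table1_material):
    """The study-condition phantom simulations (quarter-symmetry, dx=0.1 mm, 15 s).

    Arms span the two self-inconsistent power readings of the exposure (nominal
    1 W/cm^2 over the 8-mm spot = 0.503 W, vs the literal 1 W) and both
    flat-beam shapes (top-hat per the printed source equation, Gaussian per
    the methods text).  Built once per session; each 3-D run takes ~0.5 min.
    """
    geo = PhantomGeometry(dx_mm=0.1, symmetry="quarter3d")
    arms = {
        ("flat_tophat", "literal"): BeamSpec(
            mode="flat", irradiance_W_cm2=1.0, total_power_W=1.0, flat_profile="tophat"
        ),
        ("flat_gauss", "literal"): BeamSpec(
            mode="flat", irradiance_W_cm2=1.0, total_power_W=1.0, flat_profile="gaussian"
        ),
        ("mla", "literal"): BeamSpec(mode="mla", irradiance_W_cm2=1.0, total_power_W=1.0),
        ("flat_tophat", "nominal"): BeamSpec(
            mode="flat", irradiance_W_cm2=1.0, flat_profile="tophat"
        ),
        ("mla", "nominal"): BeamSpec(mode="mla", irradiance_W_cm2=1.0),
    }
    return {
        key: solve(spec, geo, table1_material, duration_s=15.0) for key, spec in arms.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
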