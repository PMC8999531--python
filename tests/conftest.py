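import numpy as np
import pytest

import implantbar as ib


@pytest.fixture(scope="session")
def v1():
    """Wide-trapezoid reference study (implants at +/-21 and +/-12 mm)."""
    return ib.reference_config(1)


@pytest.fixture(scope="session")
def v2():
    """Narrow-trapezoid reference study (implants at +/-16 and +/-6 mm)."""
    return ib.reference_config(2)


def solve_tooth(cfg, tooth, **kwargs):
    """Run the full pipeline for one tooth of a study configuration."""
    load = next(ld for ld in cfg.load_cases() if ld.tooth == tooth)
    return ib.analyze(cfg.implant_array(), cfg.bone_bed(), load, cfg.limits(), **kwargs)


@pytest.fixture(scope="session")
def v2_tooth6(v2):
    return solve_tooth(v2, 6)


@pytest.fixture(scope="session")
def v2_tooth7(v2):
    return solve_tooth(v2, 7)


@pytest.fixture
def rng():
    return np.random.default_rng(20220324)
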