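import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from eciaf.anthro import apply_exclusions, compute_zscores_frame, flag_implausible_frame
from eciaf.classify import classify_frame
from eciaf.reference import default_reference
from eciaf.simulate import RegionConfig, SimConfig, generate_survey


@pytest.fixture(scope="session")
def reference():
    return default_reference()


def small_config(seed=11, n_regions=4, n_psu=6, pool=24, **kwargs):
    defaults = dict(
        households_per_psu=10,
        children_per_household=1.0,
        icc=0.05,
        corr_haz_whz=0.2,
        sd_haz=1.0,
        sd_whz=1.0,
    )
    defaults.update(kwargs)
    regions = tuple(
        RegionConfig(f"R{i}", -1.2 - 0.2 * i, -0.4 - 0.1 * i, n_psu, pool)
        for i in range(n_regions)
    )
    return SimConfig(seed=seed, regions=regions, **defaults)


@pytest.fixture(scope="session")
def small_survey(reference):
    """One generated survey (~240 children) with its ground truth."""
    return generate_survey(small_config(), reference)


@pytest.fixture(scope="session")
def classified_survey(small_survey, reference):
    records, _ = small_survey
    scored = flag_implausible_frame(compute_zscores_frame(records, reference))
    included, _ = apply_exclusions(scored)
    return classify_frame(included)
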