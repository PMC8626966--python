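import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from readbait import (
    MembershipModel,
    PowerLawFit,
    SimulationConfig,
    make_planted_locus,
    make_screen_fixture,
)

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

# the published parameter set: exponent 0.594, C 92,637.295, support
# [1, 6932] (the overlong-median cutoff), retention threshold 0.3
PUBLISHED_ALPHA = 0.594
PUBLISHED_C = 92_637.295
PUBLISHED_XMAX = 6932


@pytest.fixture(scope="session")
def published_fit() -> PowerLawFit:
    return PowerLawFit(
        alpha=PUBLISHED_ALPHA,
        C=PUBLISHED_C,
        x_min=1.0,
        x_max=float(PUBLISHED_XMAX),
        r2=0.83,
        adjusted_r2=0.821,
        slope_pvalue=1e-4,
        n_bins_used=70,
        bin_width=100,
        median_cutoff=float(PUBLISHED_XMAX),
    )


@pytest.fixture(scope="session")
def published_model(published_fit) -> MembershipModel:
    return MembershipModel(published_fit, mode="truncated", threshold=0.3)


@pytest.fixture(scope="session")
def locus(tmp_path_factory):
    """Planted-transcript locus at the study geometry (seed fixed)."""
    cfg = SimulationConfig(seed=7)
    return make_planted_locus(cfg, tmp_path_factory.mktemp("locus"))


@pytest.fixture(scope="session")
def screen_fixture(tmp_path_factory):
    """100 reads with the planted truth table {10,5,2,40,20,3,20}."""
    cfg = SimulationConfig(
        seed=11,
        category_counts={
            "unpaired": 10,
            "contaminant": 5,
            "low_quality": 2,
            "annotated": 40,
            "low_score": 20,
            "new_annotated": 3,
            "candidate": 20,
        },
    )
    return make_screen_fixture(cfg, tmp_path_factory.mktemp("screen"))


@pytest.fixture()
def small_config() -> SimulationConfig:
    return dataclasses.replace(SimulationConfig(seed=5), fragment_count=20)
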