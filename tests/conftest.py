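import math

import pytest
from hypothesis import HealthCheck, settings

from telometa.simulate import CohortSpec, PanelSpec, TrueEffects, generate_consortium, generate_replicates

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_panel() -> PanelSpec:
    """Six metabolites in two blocks, no missingness by default."""
    a = ["Met", "Tyr", "Gly"]
    b = ["lysoPC a C17:0", "lysoPC a C18:0", "lysoPC a C18:1"]
    return PanelSpec(
        metabolite_names=a + b,
        blocks={"AA": a, "lysoPC": b},
        rho_block={"AA": 0.3, "lysoPC": 0.5},
        log_mean={**{m: math.log(120.0) for m in a}, **{m: math.log(25.0) for m in b}},
        log_sd=0.3,
        lod={**{m: 1.0 for m in a}, **{m: 0.05 for m in b}},
        missing_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_specs() -> list[CohortSpec]:
    """Three small cohorts: unrelated, sib-clustered, and one without BMI."""
    return [
        CohortSpec("ALPHA", 250, 52.0, 1.85, 0.33, 55.0, 12.0, 27.0, 4.5),
        CohortSpec("BETA", 200, 45.0, 2.50, 0.45, 50.0, 13.0, 26.0, 4.0,
                   family_size_dist={1: 0.3, 2: 0.4, 3: 0.3}, family_icc=0.35),
        CohortSpec("GAMMA", 150, 100.0, 3.50, 0.60, 30.0, 10.0, None, None,
                   family_size_dist={1: 0.4, 2: 0.6}, family_icc=0.35),
    ]


@pytest.fixture(scope="session")
def planted_effects() -> TrueEffects:
    return TrueEffects(planted_r={"lysoPC a C17:0": 0.1, "Met": -0.1})


@pytest.fixture(scope="session")
def small_consortium(small_specs, tiny_panel, planted_effects):
    return generate_consortium(small_specs, tiny_panel, planted_effects, seed=7)


@pytest.fixture(scope="session")
def tiny_replicates(tiny_panel):
    return generate_replicates(tiny_panel, n_replicates=20, seed=11)
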