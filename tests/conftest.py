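import numpy as np
import pytest

from rvatlas.synthetic import CohortGenerator, GeneratorConfig, generate_mesh


@pytest.fixture(scope="session")
def desk_mesh():
    """Shared ~1000-vertex half-ellipsoid stand-in for the RV wall."""
    return generate_mesh(1000)


@pytest.fixture(scope="session")
def desk_generator(desk_mesh):
    """Cohort generator at the default study conditions (n=300, planted patch)."""
    cfg = GeneratorConfig(n_subjects=300, n_vertices=1000, seed=0)
    return CohortGenerator(cfg, mesh=desk_mesh)


@pytest.fixture(scope="session")
def desk_cohort(desk_generator):
    return desk_generator.generate(seed=0)


@pytest.fixture(scope="session")
def null_generator():
    """Small null-effect generator (no excursion–RVEF coupling)."""
    cfg = GeneratorConfig(n_subjects=100, n_vertices=200, effect_size=0.0, seed=0)
    return CohortGenerator(cfg)


@pytest.fixture()
def tiny_covariates():
    """Deterministic 12-subject covariate table for fixture regressions."""
    import pandas as pd

    rng = np.random.default_rng(1234)
    return pd.DataFrame(
        {
            "age": rng.uniform(20, 70, 12),
            "sex": rng.integers(0, 2, 12),
            "race": pd.Categorical(
                ["Caucasian"] * 8 + ["Asian"] * 3 + ["African"],
                categories=[
                    "African", "Afro-Caribbean", "Asian", "Caucasian", "Chinese", "Other"
                ],
            ),
            "bsa": rng.normal(1.8, 0.15, 12),
        }
    )
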