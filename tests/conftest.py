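import numpy as np
import pytest

from sozloc import evaluate as ev
from sozloc import pipeline as pl
from sozloc import synthetic as syn


@pytest.fixture(scope="session")
def tiny_config() -> syn.SyntheticConfig:
    return syn.SyntheticConfig(seed=21, n_patients=3, ics_per_patient=20)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config) -> syn.SyntheticCohort:
    return syn.generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_precomputed(tiny_config) -> pl.PrecomputedCohort:
    return pl.precompute(tiny_config, pl.PipelineConfig(seed=21))


@pytest.fixture(scope="session")
def template() -> np.ndarray:
    return syn.slice_template()


@pytest.fixture(scope="session")
def study() -> dict:
    """The full parameter-recovery study (10 patients x 100 ICs, textbook
    separation, fixed seed): hybrid LOOCV, CNN-only baseline, knowledge
    ablation.  Computed once per session; several acceptance tests read
    from it."""
    return ev.parameter_recovery_study(seed=1)
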