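import numpy as np
import pytest

import mplung as m
from mplung.pipeline import PipelineConfig, analyze_series

# Reduced phantom geometry for unit tests: the full acquisition geometry is
# exercised in the acceptance suite.
SMALL = dict(n_slices=4, grid=(48, 48), n_frames=120)


@pytest.fixture(scope="session")
def healthy_phantom():
    cfg = m.PhantomConfig(**SMALL, seed=11)
    series, mask, truth = m.generate_phantom_series(cfg)
    return cfg, series, mask, truth


@pytest.fixture(scope="session")
def defect_phantom():
    cfg = m.PhantomConfig(**SMALL, defect_side="left", defect_fraction=0.2,
                          seed=12)
    series, mask, truth = m.generate_phantom_series(cfg)
    return cfg, series, mask, truth


@pytest.fixture(scope="session")
def analyzed_defect(defect_phantom):
    _, series, mask, truth = defect_phantom
    metrics, maps, masks = analyze_series(series, mask, PipelineConfig(),
                                          hernia_side="left")
    return metrics, maps, masks, mask, truth


@pytest.fixture(scope="session")
def cohort_table():
    return m.generate_cohort_table(m.CohortSimConfig(seed=21))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
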