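import warnings

import numpy as np
import pytest

from petclust.autoencoder import TrainConfig
from petclust.phantom import CohortSpec, PhantomSpec, generate_phantom
from petclust.pipeline import PipelineConfig, run_pipeline

# small-sample Cox fits in pipeline runs legitimately warn about separation
warnings.filterwarnings("ignore", category=UserWarning, module="lifelines")


@pytest.fixture(scope="session")
def default_phantom():
    """One mid-burden phantom shared by read-only tests."""
    return generate_phantom(PhantomSpec(lesion_volume_cm3=30.0, lesion_suv=5.0, seed=3))


def _tiered_cohort_spec() -> CohortSpec:
    """Three planted strata: two low-burden tiers that differ only in
    diffuse marrow uptake (image-visible, hazard-irrelevant) and one
    high-burden tier with much higher hazard."""
    return CohortSpec(
        n_subjects=60,
        burden_levels=(10.0, 12.0, 300.0),
        burden_level_probs=(0.4, 0.4, 0.2),
        burden_level_suvs=(5.0, 5.0, 6.0),
        burden_level_bg_suvs=(0.7, 1.5, 1.1),
    )


@pytest.fixture(scope="session")
def e2e_runs(tmp_path_factory):
    """Two identical full pipeline runs on a 60-subject tiered cohort.

    Shared session-wide: the pair serves both the rerun-reproducibility
    check and the survival-structure checks on the first run.  Training is
    shortened to 40 epochs to keep the suite fast; the loss curve has long
    flattened by then on these phantoms.
    """
    cfg = PipelineConfig(
        cohort=_tiered_cohort_spec(),
        train=TrainConfig(epochs=40),
        seed=1,
    )
    out1 = tmp_path_factory.mktemp("run1")
    out2 = tmp_path_factory.mktemp("run2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = run_pipeline(cfg, output_dir=out1)
        r2 = run_pipeline(cfg, output_dir=out2)
    return r1, r2


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
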