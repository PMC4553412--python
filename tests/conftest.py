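import numpy as np
import pytest

import tremornet as tn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def panel_of(data, tr=2.0):
    """Wrap raw matrices into a RoiTimeSeriesPanel (plain helper)."""
    data = [np.asarray(d, float) for d in data]
    return tn.RoiTimeSeriesPanel(
        subject_ids=tuple(f"s{i}" for i in range(len(data))),
        data=tuple(data),
        node_ids=tuple(f"n{j}" for j in range(data[0].shape[1])),
        tr_seconds=tr,
    )


@pytest.fixture
def make_panel():
    return panel_of


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny but fully structured cohort shared by unit tests."""
    cfg = tn.CohortConfig(
        n_group_a=5,
        n_group_b=6,
        n_nodes=24,
        n_modules=4,
        n_timepoints=96,
        seed=42,
    )
    return tn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_run():
    """One reduced-ensemble pipeline run at the full study design.

    36 subjects, 264 nodes, 180 timepoints (175 after discard) at TR = 2 s,
    planted intra-module coupling gap, noiseless clinical scores so the
    planted regression is exactly recoverable.  Shared session-wide because
    it is the expensive end-to-end fixture.
    """
    cfg = tn.RunConfig.reduced(seed=7, cohort=tn.CohortConfig(clinical_noise_sd=0.0))
    return tn.run_pipeline(cfg)
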