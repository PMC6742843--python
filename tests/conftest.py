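import numpy as np
import pandas as pd
import pytest

from roinet import CohortSpec, ConfoundSet, RoiTimeSeries
from roinet.atlas import synthetic_labels
from roinet.cohort import default_planted_effects
from roinet.containers import MOTION_COLUMNS


@pytest.fixture
def small_spec() -> CohortSpec:
    """A fast desk-scale cohort: 3 per group, 60 volumes, 12 ROIs."""
    labels, seeds = synthetic_labels(12, 3)
    return CohortSpec(
        n_per_group=3,
        n_timepoints=60,
        roi_labels=labels,
        blocks=[labels[:4], labels[4:8], labels[8:]],
        planted_effects=default_planted_effects(labels, seeds, n_effects=2),
        master_seed=11,
    )


@pytest.fixture
def clean_spec() -> CohortSpec:
    """Two ROIs, no nuisance contamination, no autocorrelation."""
    return CohortSpec(
        n_per_group=2,
        n_timepoints=10_000,
        roi_labels=["a", "b"],
        blocks=[["a", "b"]],
        r_within=0.5,
        ar_coef=0.0,
        drift_slope=0.0,
        sinusoid_amplitude=0.0,
        motion_noise_scale=0.0,
        master_seed=3,
    )


def make_timeseries(values: np.ndarray, tr: float = 3.2) -> RoiTimeSeries:
    n = values.shape[1]
    cols = [f"r{i}" for i in range(n)]
    return RoiTimeSeries(pd.DataFrame(values, columns=cols), tr=tr)


def make_confounds(
    t_len: int,
    motion: np.ndarray | None = None,
    components: np.ndarray | None = None,
) -> ConfoundSet:
    if motion is None:
        motion = np.zeros((t_len, 6))
    if components is None:
        components = np.zeros((t_len, 0))
    comp_cols = [f"comp_{i + 1:02d}" for i in range(components.shape[1])]
    return ConfoundSet(
        motion=pd.DataFrame(motion, columns=list(MOTION_COLUMNS)),
        nuisance_components=pd.DataFrame(components, columns=comp_cols),
    )
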