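"""In-memory containers shared across the pipeline stages.

The interchange layer is deliberately plain: time series and confounds are
pandas DataFrames (rows = volumes, columns = named series), connectivity
matrices are numpy arrays with an ordered ROI-label list attached. No
imaging formats appear anywhere — the pipeline's domain of validity starts
at extracted ROI time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass
class RoiTimeSeries:
    """One subject's T x N ROI signal table.

    Parameters
    ----------
    data : DataFrame with one column per ROI (label order is meaningful)
        and one row per acquired volume.
    tr : repetition time in seconds (sampling interval of the rows).
    subject_id : optional identifier carried through the pipeline.
    """

    data: pd.DataFrame
    tr: float
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if self.data.shape[1] == 0:
            raise ValueError("time series has no ROI columns")

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[0])

    @property
    def roi_labels(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_values(self, values: np.ndarray) -> "RoiTimeSeries":
        """Return a copy holding ``values`` with the same labels/TR."""
        df = pd.DataFrame(values, columns=self.data.columns)
        return RoiTimeSeries(df, tr=self.tr, subject_id=self.subject_id)


@dataclass
class ConfoundSet:
    """Nuisance regressors for one subject.

    motion : T x 6 table (3 translations in mm, 3 rotations in rad) in
        ``MOTION_COLUMNS`` order.
    nuisance_components : T x K table of aCompCor-style component series
        (stand-ins for the first principal components of white-matter and
        CSF signals).
    outlier_flags : optional boolean vector of scrubbed volumes, filled in
        by the outlier detector.
    nuisance_loadings : optional K x N ground-truth injection loadings;
        present only on simulated data, used to validate denoising.
    """

    motion: pd.DataFrame
    nuisance_components: pd.DataFrame
    outlier_flags: np.ndarray | None = None
    nuisance_loadings: np.ndarray | None = None

    def __post_init__(self) -> None:
        if tuple(self.motion.columns) != MOTION_COLUMNS:
            raise ValueError(
                f"motion table must have columns {MOTION_COLUMNS}, "
                f"got {tuple(self.motion.columns)}"
            )
        if len(self.motion) != len(self.nuisance_components):
            raise ValueError("motion and nuisance tables differ in length")

    @property
    def n_timepoints(self) -> int:
        return int(len(self.motion))


@dataclass
class ConnectivityMatrix:
    """N x N ROI-ROI connectivity values.

    kind="FUN" holds Pearson correlations (symmetric); kind="EFF" holds
    bivariate regression slopes, oriented rows = seed/predictor,
    columns = target. After :func:`roinet.connectivity.fisher_z` the values
    are on the arctanh (Fisher z) scale and ``is_z`` is True. The diagonal
    is masked to NaN and never enters downstream thresholding or inference.
    """

    values: np.ndarray
    kind: str
    roi_labels: list[str]
    is_z: bool = False
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("FUN", "EFF"):
            raise ValueError(f"kind must be 'FUN' or 'EFF', got {self.kind!r}")
        n = len(self.roi_labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} ROI labels"
            )

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def index_of(self, label: str) -> int:
        return self.roi_labels.index(label)


@dataclass
class SubjectGraph:
    """Binary undirected graph: symmetric 0/1 adjacency, zero diagonal."""

    adjacency: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = len(self.roi_labels)
        if a.shape != (n, n):
            raise ValueError("adjacency shape does not match labels")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return len(self.roi_labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


#: Column order of per-node metric tables.
METRIC_COLUMNS = (
    "degree",
    "cost",
    "betweenness",
    "avg_path_length",
    "global_efficiency",
    "local_efficiency",
    "clustering",
)


@dataclass
class Cohort:
    """A simulated or loaded study cohort."""

    subjects: list[RoiTimeSeries]
    confounds: list[ConfoundSet]
    groups: list[str]
    tr: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.subjects) == len(self.confounds) == len(self.groups)):
            raise ValueError("subjects, confounds and groups must align")
        if not self.roi_labels and self.subjects:
            self.roi_labels = self.subjects[0].roi_labels

    def __len__(self) -> int:
        return len(self.subjects)
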