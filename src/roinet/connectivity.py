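"""ROI-ROI connectivity: bivariate correlation (FUN) and bivariate
regression (EFF), with the Fisher z-transform.

FUN entry (i, j) is the Pearson correlation of ROI i and j — symmetric,
scale-invariant, read as synchrony. EFF entry (i, j) is the least-squares
slope of regressing target j's series on seed i's series (with intercept),
b(i->j) = cov(i, j) / var(i) — asymmetric in general, read as directed
influence strength. Series are deliberately NOT variance-normalised before
EFF: normalising would collapse the slope onto the correlation and erase
the asymmetry the regression model carries.

Both matrices are mapped through arctanh (Fisher z). Regression slopes can
exceed 1 in magnitude, where arctanh is undefined, so values are clipped
into [-(1 - 1e-6), 1 - 1e-6] first; every clip is logged and counted on the
returned matrix.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .containers import ConnectivityMatrix, RoiTimeSeries

logger = logging.getLogger(__name__)

DEFAULT_CLIP = 1.0 - 1e-6


def _check_series(ts: RoiTimeSeries) -> np.ndarray:
    x = ts.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for connectivity")
    return x


def _constant_columns(x: np.ndarray) -> np.ndarray:
    return x.std(axis=0) == 0


def functional_connectivity(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson-correlation matrix (kind=FUN, correlation scale).

    Constant ROIs yield undefined entries: their row/column is set to NaN
    with a warning, and they are excluded downstream.
    """
    x = _check_series(ts)
    const = _constant_columns(x)
    if const.any():
        warnings.warn(
            f"constant ROI series: {[ts.roi_labels[i] for i in np.flatnonzero(const)]}"
            "; correlations set to NaN",
            stacklevel=2,
        )
        x = x.copy()
        x[:, const] = np.nan  # propagates NaN through corrcoef
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, np.nan)
    return ConnectivityMatrix(r, kind="FUN", roi_labels=ts.roi_labels)


def effective_connectivity(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Bivariate regression-slope matrix (kind=EFF, slope scale).

    Entry (i, j) = cov(i, j) / var(i): row i is the seed/predictor,
    column j the target. Zero-variance seeds yield an undefined (NaN) row.
    """
    x = _check_series(ts)
    const = _constant_columns(x)
    if const.any():
        warnings.warn(
            f"zero-variance seed ROIs: "
            f"{[ts.roi_labels[i] for i in np.flatnonzero(const)]}; "
            "their rows set to NaN",
            stacklevel=2,
        )
    cov = np.cov(x, rowvar=False)
    var = np.diag(cov).copy()
    var[const] = np.nan
    b = cov / var[:, None]
    np.fill_diagonal(b, np.nan)
    return ConnectivityMatrix(b, kind="EFF", roi_labels=ts.roi_labels)


def fisher_z(matrix: ConnectivityMatrix, clip: float = DEFAULT_CLIP) -> ConnectivityMatrix:
    """Fisher z-transform: z = arctanh(v) after clipping v into [-clip, clip].

    Monotone and sign-preserving with z(0) = 0. Applied to both correlation
    and slope matrices; the number of clipped entries is recorded on the
    result and logged when nonzero.
    """
    if matrix.is_z:
        raise ValueError("matrix is already Fisher z-transformed")
    if not 0 < clip < 1:
        raise ValueError("clip must lie in (0, 1)")
    v = matrix.values
    off = ~np.eye(matrix.n_rois, dtype=bool)
    finite = np.isfinite(v) & off
    n_clipped = int((np.abs(v[finite]) > clip).sum())
    if n_clipped:
        logger.info(
            "fisher_z clipped %d %s entries exceeding |%g|",
            n_clipped,
            matrix.kind,
            clip,
        )
    z = np.arctanh(np.clip(v, -clip, clip))
    z[~finite] = np.nan
    return ConnectivityMatrix(
        z,
        kind=matrix.kind,
        roi_labels=list(matrix.roi_labels),
        is_z=True,
        n_clipped=n_clipped,
    )
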