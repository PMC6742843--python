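"""Temporal denoising of ROI time series.

The stage order is fixed and part of the contract:

1. outlier-volume detection (motion framewise displacement + global-signal
   change), yielding scrub flags;
2. nuisance regression against intercept, the 6 motion parameters, their
   first derivatives, the aCompCor-style component series, and one
   indicator column per flagged volume (scrubbing by regression keeps the
   series length intact, which keeps the spectral step well defined);
3. linear detrending followed by an ideal (rectangular) frequency-domain
   band-pass over 0.008-0.09 Hz.

The filter is a projection, hence linear and idempotent; the regression
residuals are orthogonal to every retained design column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr

from .containers import ConfoundSet, RoiTimeSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DenoiseConfig:
    """Denoising parameters.

    band : retained frequency interval in Hz (inclusive at both edges).
    fd_threshold : framewise-displacement scrub threshold in mm; together
        with ``global_z_threshold`` these mirror common "intermediate"
        artifact-detection settings.
    rotation_radius : lever arm (mm) converting rotation increments to
        displacement at the head surface.
    """

    band: tuple[float, float] = (0.008, 0.09)
    fd_threshold: float = 0.9
    global_z_threshold: float = 5.0
    rotation_radius: float = 50.0
    include_motion_derivatives: bool = True
    n_nuisance_components: int = 10

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 <= low < high:
            raise ValueError(f"band must satisfy 0 <= low < high, got {self.band}")
        for name in ("fd_threshold", "global_z_threshold", "rotation_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def validate_for_tr(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if self.band[1] >= nyquist:
            raise ValueError(
                f"band upper edge {self.band[1]} Hz is at/above the Nyquist "
                f"frequency {nyquist:.4g} Hz for TR={tr}s"
            )


def framewise_displacement(motion: np.ndarray, rotation_radius: float = 50.0) -> np.ndarray:
    """Per-volume head-motion summary in mm.

    FD(0) = 0 and
    FD(t) = sum |d translation| + radius * sum |d rotation|,
    the small-angle approximation placing rotations on a sphere of the given
    radius. Columns must be (trans x/y/z in mm, rot x/y/z in rad).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be T x 6, got shape {motion.shape}")
    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + rotation_radius * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def detect_outliers(
    ts: RoiTimeSeries, motion: np.ndarray, cfg: DenoiseConfig
) -> np.ndarray:
    """Flag volumes with FD above threshold or extreme global-signal change.

    The global criterion z-scores the first difference of the mean-over-ROIs
    signal and flags |z| above ``cfg.global_z_threshold``.
    """
    motion = np.asarray(motion, dtype=float)
    if len(motion) != ts.n_timepoints:
        raise ValueError("motion and time series differ in length")
    fd = framewise_displacement(motion, cfg.rotation_radius)
    flags = fd > cfg.fd_threshold

    global_signal = ts.values.mean(axis=1)
    change = np.concatenate([[0.0], np.diff(global_signal)])
    sd = change.std()
    if sd > 0:
        z = (change - change.mean()) / sd
        flags = flags | (np.abs(z) > cfg.global_z_threshold)
    n = int(flags.sum())
    if n:
        logger.info("flagged %d outlier volumes", n)
    return flags


def build_design_matrix(
    confounds: ConfoundSet, flags: np.ndarray, cfg: DenoiseConfig
) -> tuple[np.ndarray, list[str]]:
    """Assemble the nuisance design: intercept, motion, motion derivatives,
    nuisance components, and one indicator per flagged volume."""
    motion = confounds.motion.to_numpy(dtype=float)
    t_len = len(motion)
    cols: list[np.ndarray] = [np.ones(t_len)]
    names: list[str] = ["intercept"]
    for i, name in enumerate(confounds.motion.columns):
        cols.append(motion[:, i])
        names.append(str(name))
    if cfg.include_motion_derivatives:
        dm = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
        for i, name in enumerate(confounds.motion.columns):
            cols.append(dm[:, i])
            names.append(f"d_{name}")
    comps = confounds.nuisance_components.to_numpy(dtype=float)
    k = min(cfg.n_nuisance_components, comps.shape[1])
    for i in range(k):
        cols.append(comps[:, i])
        names.append(str(confounds.nuisance_components.columns[i]))
    for t in np.flatnonzero(flags):
        ind = np.zeros(t_len)
        ind[t] = 1.0
        cols.append(ind)
        names.append(f"scrub_{t}")
    return np.column_stack(cols), names


def regress_confounds(
    ts: RoiTimeSeries,
    confounds: ConfoundSet,
    cfg: DenoiseConfig,
    flags: np.ndarray | None = None,
) -> tuple[RoiTimeSeries, dict]:
    """Replace every ROI series by its least-squares residual against the
    nuisance design.

    Rank-deficient designs are handled by dropping dependent columns (with
    a warning naming them); a design with as many columns as timepoints is
    a hard error. Returns the residual series and a small report.
    """
    if flags is None:
        flags = (
            confounds.outlier_flags
            if confounds.outlier_flags is not None
            else np.zeros(ts.n_timepoints, dtype=bool)
        )
    design, names = build_design_matrix(confounds, flags, cfg)
    t_len = ts.n_timepoints
    if design.shape[0] != t_len:
        raise ValueError("confound length does not match the time series")
    dropped: list[str] = []
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # pivoted QR: keep the first `rank` pivot columns, drop the rest
        _, _, piv = qr(design, mode="economic", pivoting=True)
        keep = np.sort(piv[:rank])
        dropped = [names[i] for i in range(design.shape[1]) if i not in set(keep)]
        warnings.warn(
            f"nuisance design rank-deficient; dropping columns {dropped}",
            stacklevel=2,
        )
        design = design[:, keep]
        names = [names[i] for i in keep]
    if t_len <= design.shape[1]:
        raise ValueError(
            f"design has {design.shape[1]} columns but only {t_len} "
            "timepoints; cannot regress"
        )
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    resid = ts.values - design @ beta
    report = {
        "n_outliers": int(np.asarray(flags).sum()),
        "design_columns": names,
        "dropped_columns": dropped,
    }
    return ts.with_values(resid), report


def bandpass_filter(ts: RoiTimeSeries, cfg: DenoiseConfig) -> RoiTimeSeries:
    """Ideal FFT band-pass: a frequency bin f is retained iff
    low <= f <= high (inclusive band edges); everything else, including the
    DC and Nyquist bins outside the band, is zeroed. A spectral projection,
    hence linear and idempotent; output length equals input length.
    """
    cfg.validate_for_tr(ts.tr)
    x = ts.values
    t_len = x.shape[0]
    freqs = np.fft.rfftfreq(t_len, d=ts.tr)
    low, high = cfg.band
    keep = (freqs >= low) & (freqs <= high)
    spec = np.fft.rfft(x, axis=0)
    spec[~keep] = 0.0
    filtered = np.fft.irfft(spec, n=t_len, axis=0)
    return ts.with_values(filtered)


def bandpass_detrend(ts: RoiTimeSeries, cfg: DenoiseConfig) -> RoiTimeSeries:
    """Least-squares linear detrend per ROI, then :func:`bandpass_filter`."""
    cfg.validate_for_tr(ts.tr)
    x = ts.values
    t_len = x.shape[0]
    t = np.arange(t_len, dtype=float)
    design = np.column_stack([np.ones(t_len), t])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return bandpass_filter(ts.with_values(x - design @ beta), cfg)


def denoise_subject(
    ts: RoiTimeSeries, confounds: ConfoundSet, cfg: DenoiseConfig | None = None
) -> tuple[RoiTimeSeries, dict]:
    """Full denoising for one subject: detect -> regress -> filter.

    Returns the cleaned series plus a JSON-serialisable report
    (outlier count, dropped design columns, band used).
    """
    cfg = cfg or DenoiseConfig()
    cfg.validate_for_tr(ts.tr)
    flags = detect_outliers(ts, confounds.motion.to_numpy(), cfg)
    confounds.outlier_flags = flags
    resid, report = regress_confounds(ts, confounds, cfg, flags)
    cleaned = bandpass_detrend(resid, cfg)
    report["band_hz"] = list(cfg.band)
    return cleaned, report
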