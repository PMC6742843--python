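"""Synthetic two-group cohort generator.

Emulates a resting-state case/control study at the ROI level: per subject a
T x N multivariate time series whose innovations follow a block-structured
covariance (communities of mutually correlated ROIs), temporally coloured
by an AR(1) process, and contaminated with the nuisance structure real BOLD
data carries — linear drift, an out-of-band physiological sinusoid, motion
spikes mirrored into the global signal, and aCompCor-style nuisance
components injected with known per-ROI loadings.

Group differences are planted as correlation deltas on designated
seed-target edges of the patient group's covariance, giving the downstream
inference a known ground truth.

Defaults mirror the emulated study design: 28 subjects per group, 220
volumes at TR = 3.2 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .atlas import synthetic_labels
from .containers import MOTION_COLUMNS, Cohort, ConfoundSet, RoiTimeSeries

logger = logging.getLogger(__name__)

#: AR(1) burn-in discarded so the series starts near stationarity.
_BURN_IN = 100

#: PD repair may not perturb any requested correlation by more than this.
PD_REPAIR_CAP = 0.05


@dataclass(frozen=True)
class PlantedEffect:
    """A group-difference planted on one (seed, target) edge.

    ``delta`` is added (signed) to the patient group's correlation on that
    edge; the control group keeps the base block value.
    """

    seed: str
    target: str
    delta: float


@dataclass
class CohortSpec:
    """Full description of a simulated two-group cohort.

    Every run is a pure function of this object, ``master_seed`` included.
    """

    n_per_group: int = 28
    n_timepoints: int = 220
    tr: float = 3.2
    roi_labels: list[str] = field(default_factory=lambda: synthetic_labels()[0])
    blocks: list[list[str]] | None = None
    r_within: float = 0.5
    r_between: float = 0.05
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    ar_coef: float = 0.3
    roi_sd: np.ndarray | None = None
    drift_slope: float = 0.005  # signal units per volume
    sinusoid_amplitude: float = 0.5
    sinusoid_freq: float = 0.12  # Hz, outside the analysis band
    spike_schedule: list[tuple[int, float]] = field(default_factory=list)
    motion_noise_scale: float = 0.05  # mm (translations); scaled down for rotations
    n_nuisance_components: int = 10
    nuisance_loading_scale: float = 0.3
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_timepoints < 20:
            raise ValueError("n_timepoints must be >= 20")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must lie in [0, 1)")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("roi_labels must be unique")
        for r in (self.r_within, self.r_between):
            if not -1 < r < 1:
                raise ValueError(f"base correlation {r} outside (-1, 1)")
        if self.blocks is None:
            self.blocks = _default_blocks(self.roi_labels)
        flat = [lab for b in self.blocks for lab in b]
        if sorted(flat) != sorted(self.roi_labels):
            raise ValueError("blocks must partition roi_labels")
        labset = set(self.roi_labels)
        for eff in self.planted_effects:
            if eff.seed not in labset or eff.target not in labset:
                raise ValueError(f"planted effect {eff} names an unknown ROI")
            if eff.seed == eff.target:
                raise ValueError("planted effect may not be a self-pair")
        if self.roi_sd is None:
            self.roi_sd = np.ones(len(self.roi_labels))
        else:
            self.roi_sd = np.asarray(self.roi_sd, dtype=float)
            if self.roi_sd.shape != (len(self.roi_labels),):
                raise ValueError("roi_sd length must match roi_labels")
            if np.any(self.roi_sd <= 0):
                raise ValueError("roi_sd must be positive")
        for t, _amp in self.spike_schedule:
            if not 0 <= t < self.n_timepoints:
                raise ValueError(f"spike index {t} outside [0, T)")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roi_sd"] = list(map(float, self.roi_sd))
        d["planted_effects"] = [
            [e.seed, e.target, e.delta] for e in self.planted_effects
        ]
        return d


def _default_blocks(labels: list[str], block_size: int = 10) -> list[list[str]]:
    return [labels[i : i + block_size] for i in range(0, len(labels), block_size)]


def default_planted_effects(
    labels: list[str],
    seeds: list[str],
    n_effects: int = 10,
    delta: float = 0.3,
) -> list[PlantedEffect]:
    """Planted seed-target deltas: seeds cycled, distinct non-seed targets.

    Targets are taken from the back of the label list so they land outside
    the default seed community.
    """
    targets = [lab for lab in labels if lab not in set(seeds)]
    if n_effects > len(targets):
        raise ValueError("not enough non-seed ROIs for the requested effects")
    chosen_targets = targets[-n_effects:]
    return [
        PlantedEffect(seeds[i % len(seeds)], chosen_targets[i], delta)
        for i in range(n_effects)
    ]


def default_study_spec(
    master_seed: int = 0,
    n_replicate_rois: int = 40,
    n_per_group: int = 28,
    n_timepoints: int = 220,
) -> CohortSpec:
    """The study-design default cohort: 28/group, 220 volumes, TR 3.2 s,
    40 ROIs with 8 seeds and ten +0.3 planted seed-target deltas.

    With fewer ROIs the seed and planted-effect counts scale down so the
    construction stays well defined; the two default motion spikes sit at
    roughly a quarter and two thirds of the run.
    """
    n_seeds = min(8, max(1, n_replicate_rois // 5))
    labels, seeds = synthetic_labels(n_replicate_rois, n_seeds)
    n_effects = min(10, n_replicate_rois - n_seeds - 1)
    return CohortSpec(
        n_per_group=n_per_group,
        n_timepoints=n_timepoints,
        roi_labels=labels,
        planted_effects=default_planted_effects(labels, seeds, n_effects=n_effects),
        spike_schedule=[(int(n_timepoints * 0.27), 1.5), (int(n_timepoints * 0.68), 2.0)],
        master_seed=master_seed,
    )


def build_group_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Target innovation covariance for one group.

    The implied correlation matrix follows the block structure
    (``r_within`` inside a community, ``r_between`` across), with the
    planted deltas applied symmetrically for ``group="patient"`` only. If
    the raw construction is not positive definite it is repaired by the
    smallest-eigenvalue shift (then renormalised to unit diagonal); a repair
    that moves any correlation by more than ``PD_REPAIR_CAP`` is an error.
    """
    if group not in ("control", "patient"):
        raise ValueError(f"group must be 'control' or 'patient', got {group!r}")
    n = spec.n_rois
    index = {lab: i for i, lab in enumerate(spec.roi_labels)}
    corr = np.full((n, n), spec.r_between, dtype=float)
    for block in spec.blocks:
        idx = [index[lab] for lab in block]
        corr[np.ix_(idx, idx)] = spec.r_within
    np.fill_diagonal(corr, 1.0)
    if group == "patient":
        for eff in spec.planted_effects:
            i, j = index[eff.seed], index[eff.target]
            corr[i, j] += eff.delta
            corr[j, i] = corr[i, j]
    off = corr[~np.eye(n, dtype=bool)]
    if np.any(np.abs(off) >= 1):
        raise ValueError("requested correlations leave (-1, 1)")

    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin <= 1e-10:
        shift = 1e-8 - eigmin
        logger.warning(
            "correlation matrix not positive definite (min eig %.3g); "
            "applying eigenvalue shift %.3g",
            eigmin,
            shift,
        )
        repaired = (corr + shift * np.eye(n)) / (1.0 + shift)
        distortion = float(np.abs(repaired - corr).max())
        if distortion > PD_REPAIR_CAP:
            raise ValueError(
                f"PD repair would distort correlations by {distortion:.3f} "
                f"(> {PD_REPAIR_CAP}); revise the block structure"
            )
        corr = repaired

    sd = spec.roi_sd
    return corr * np.outer(sd, sd)


def simulate_confounds(spec: CohortSpec, subject_seed: int) -> ConfoundSet:
    """Six motion-parameter series plus K nuisance component series.

    Motion: random-walk-smoothed noise at ``motion_noise_scale`` (mm for
    translations; the rotation scale is divided by 50 so a 50 mm lever arm
    gives comparable displacement), plus the scheduled spikes on trans_x.
    Nuisance components: unit-variance smooth Gaussian series; their
    ground-truth injection loadings (K x N) are drawn here and stored on
    the returned set so denoising can be validated.
    """
    rng = np.random.default_rng(subject_seed)
    t_len = spec.n_timepoints
    scale = spec.motion_noise_scale
    # smooth noise: cumulative sum of small steps, recentred
    steps = rng.standard_normal((t_len, 6)) * scale * 0.2
    motion = np.cumsum(steps, axis=0)
    motion -= motion.mean(axis=0)
    motion[:, 3:] /= 50.0  # radians
    for t, amp in spec.spike_schedule:
        motion[t, 0] += amp
    motion_df = pd.DataFrame(motion, columns=list(MOTION_COLUMNS))

    k = spec.n_nuisance_components
    comps = rng.standard_normal((t_len, k))
    # mild temporal smoothing so components resemble physiological noise
    comps = lfilter([1.0], [1.0, -0.5], comps, axis=0)
    comps = (comps - comps.mean(axis=0)) / comps.std(axis=0)
    comp_df = pd.DataFrame(
        comps, columns=[f"comp_{i + 1:02d}" for i in range(k)]
    )
    loadings = rng.standard_normal((k, spec.n_rois)) * spec.nuisance_loading_scale
    return ConfoundSet(
        motion=motion_df,
        nuisance_components=comp_df,
        nuisance_loadings=loadings,
    )


def simulate_subject(
    cov: np.ndarray,
    spec: CohortSpec,
    subject_seed: int,
    confounds: ConfoundSet | None = None,
    subject_id: str | None = None,
) -> RoiTimeSeries:
    """Simulate one subject's T x N ROI series.

    Innovations are multivariate Gaussian with covariance ``cov``, combined
    as an AR(1) process with ``spec.ar_coef`` (a 100-sample burn-in is
    discarded), then additively contaminated with linear drift, the
    sinusoid, global-signal spikes at the scheduled motion-spike times, and
    — when ``confounds`` carries loadings — the injected nuisance
    components. Same seed, same output, bit for bit.
    """
    cov = np.asarray(cov, dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    rng = np.random.default_rng(subject_seed)
    t_len = spec.n_timepoints
    innov = rng.standard_normal((t_len + _BURN_IN, cov.shape[0])) @ chol.T
    series = lfilter([1.0], [1.0, -spec.ar_coef], innov, axis=0)[_BURN_IN:]

    t = np.arange(t_len, dtype=float)
    drift = spec.drift_slope * t
    sinus = spec.sinusoid_amplitude * np.sin(
        2.0 * np.pi * spec.sinusoid_freq * t * spec.tr
    )
    series = series + (drift + sinus)[:, None]
    for idx, amp in spec.spike_schedule:
        series[idx] += amp * 3.0  # global signal excursion at the spike
    if confounds is not None and confounds.nuisance_loadings is not None:
        series = series + (
            confounds.nuisance_components.to_numpy() @ confounds.nuisance_loadings
        )
    df = pd.DataFrame(series, columns=spec.roi_labels)
    return RoiTimeSeries(df, tr=spec.tr, subject_id=subject_id)


def subject_seeds(spec: CohortSpec) -> list[tuple[int, int]]:
    """Deterministic per-subject (signal, confound) seed pairs.

    Two independent streams per subject, spawned from the master seed, so
    the motion/nuisance draws never overlap the signal innovations.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    children = ss.spawn(4 * spec.n_per_group)
    flat = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    return list(zip(flat[0::2], flat[1::2]))


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate the full two-group cohort (controls first, then patients)."""
    seeds = subject_seeds(spec)
    covs = {
        "control": build_group_covariance(spec, "control"),
        "patient": build_group_covariance(spec, "patient"),
    }
    subjects: list[RoiTimeSeries] = []
    confs: list[ConfoundSet] = []
    groups: list[str] = []
    for i in range(2 * spec.n_per_group):
        group = "control" if i < spec.n_per_group else "patient"
        sid = f"sub-{i + 1:03d}"
        signal_seed, confound_seed = seeds[i]
        conf = simulate_confounds(spec, confound_seed)
        ts = simulate_subject(covs[group], spec, signal_seed, conf, subject_id=sid)
        subjects.append(ts)
        confs.append(conf)
        groups.append(group)
    return Cohort(
        subjects=subjects,
        confounds=confs,
        groups=groups,
        tr=spec.tr,
        roi_labels=list(spec.roi_labels),
    )
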