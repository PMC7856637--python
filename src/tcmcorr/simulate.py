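"""Synthetic overt-speech fMRI runs with ground-truth labels.

Each simulated voxel time series is

    x(t) = baseline * (1 + bold(t) + tcm(t) + drift(t)) + noise

where ``bold`` is the stimulus train convolved with the canonical HRF
(confined to a true-signal mask and scaled so its peak is the configured %
signal change), ``tcm`` is a spiky task-correlated motion artifact — a
biphasic spike in the first frames after each onset, with trial-to-trial
amplitude variation — confined to a fronto-temporal region plus a one-voxel
extracerebral rim, ``drift`` is a slow polynomial, and the noise is white
Gaussian.  The generator also produces plausible 6-parameter rigid-motion
traces with optional stimulus-locked bumps.

The geometry is desk scale: a 20 x 20 x 10 grid of 3 mm voxels with an
ellipsoidal brain.  The true-signal mask has one blob inside the artifact-prone
region (frontal/temporal co-localization of speech and language signal) and one
posterior blob immune to the artifact, so selectivity of denoising can be
scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .hrf import canonical_hrf
from .schedule import StimulusSchedule, make_schedule

__all__ = [
    "GroundTruth",
    "MotionParams",
    "BoldRun",
    "default_masks",
    "default_ground_truth",
    "bold_waveform",
    "tcm_waveform",
    "simulate_run",
    "simulate_motion",
    "simulate_collection",
]

DEFAULT_GRID = (20, 20, 10)
DEFAULT_VOXEL_MM = 3.0
BASELINE = 1000.0  # arbitrary EPI-like intensity scale

# biphasic spike: positive lobe then negative lobe, within the first 3 TRs
TCM_SPIKE_SHAPE = (1.0, -0.5)


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    bold_mask: np.ndarray
    tcm_mask_true: np.ndarray
    bold_amplitude: float  # % signal change at HRF peak
    tcm_amplitudes: np.ndarray  # (n_runs, trials_per_run), % peak amplitude
    tcm_window_trs: int = 3
    noise_sd: float = 5.0  # intensity units
    drift_coeffs: tuple[float, ...] = (0.0, 0.5, -0.3)  # % units, Legendre basis
    seed: int = 0
    baseline: float = BASELINE
    brain_mask: np.ndarray | None = None
    gm_mask: np.ndarray | None = None
    wm_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bold_mask.shape != self.tcm_mask_true.shape:
            raise ValueError("bold_mask and tcm_mask_true shapes differ")


@dataclass(frozen=True)
class MotionParams:
    """Per-frame rigid motion: 3 translations (mm), 3 rotations (deg)."""

    params: np.ndarray  # (n_frames, 6)

    @property
    def displacement(self) -> np.ndarray:
        """Euclidean norm of backward differences (first frame 0), in mm.

        Rotations in degrees are normed numerically as mm (stated convention).
        """
        d = np.zeros(len(self.params))
        if len(self.params) > 1:
            d[1:] = np.linalg.norm(np.diff(self.params, axis=0), axis=1)
        return d


@dataclass
class BoldRun:
    """One run's 4D intensity grid plus acquisition metadata."""

    data: np.ndarray  # (x, y, z, t), retained frames only
    tr_s: float
    voxel_size_mm: float
    run_index: int = 0
    schedule: StimulusSchedule | None = None
    motion: MotionParams | None = None
    ground_truth: GroundTruth | None = None

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    def copy_with(self, data: np.ndarray) -> "BoldRun":
        return BoldRun(
            data=data,
            tr_s=self.tr_s,
            voxel_size_mm=self.voxel_size_mm,
            run_index=self.run_index,
            schedule=self.schedule,
            motion=self.motion,
            ground_truth=self.ground_truth,
        )


def _sphere(grid_shape, center, radius) -> np.ndarray:
    idx = np.indices(grid_shape).astype(float)
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return d2 <= radius**2


def default_masks(grid_shape=DEFAULT_GRID) -> dict[str, np.ndarray]:
    """Ellipsoidal brain with rim, fronto-temporal artifact region, GM/WM shells
    and a two-blob true-signal mask (one blob artifact-prone, one immune)."""
    nx, ny, nz = grid_shape
    idx = np.indices(grid_shape).astype(float)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 0.42 * nx, 0.42 * ny, 0.42 * nz
    brain = ((idx[0] - cx) / ax) ** 2 + ((idx[1] - cy) / ay) ** 2 + ((idx[2] - cz) / az) ** 2 <= 1.0
    rim = binary_dilation(brain) & ~brain  # one-voxel extracerebral shell
    core = ((idx[0] - cx) / (0.6 * ax)) ** 2 + ((idx[1] - cy) / (0.6 * ay)) ** 2 + (
        (idx[2] - cz) / (0.6 * az)
    ) ** 2 <= 1.0
    wm = brain & core
    gm = brain & ~core
    # anterior (high-y) third of the brain: frontal/temporal artifact-prone zone
    tcm_region = brain & (idx[1] >= 0.65 * (ny - 1))
    tcm_mask_true = tcm_region | rim
    prone_blob = _sphere(grid_shape, (cx, 0.78 * (ny - 1), cz), 2.2) & brain & tcm_region
    immune_blob = _sphere(grid_shape, (cx, 0.22 * (ny - 1), cz), 2.2) & brain & ~tcm_mask_true
    return {
        "brain": brain,
        "rim": rim,
        "gm": gm,
        "wm": wm,
        "tcm": tcm_mask_true,
        "bold": prone_blob | immune_blob,
        "bold_prone": prone_blob,
        "bold_immune": immune_blob,
    }


def default_ground_truth(
    schedule: StimulusSchedule | None = None,
    grid_shape=DEFAULT_GRID,
    seed: int = 0,
    bold_amplitude: float = 2.0,
    tcm_amp_range: tuple[float, float] = (2.0, 5.0),
    noise_sd: float = 5.0,
    drift_coeffs: tuple[float, ...] = (0.0, 0.5, -0.3),
) -> GroundTruth:
    """Ground truth at the study's default conditions.

    BOLD amplitude 2% (a typical task response); per-trial artifact peaks drawn
    uniformly from 2-5% so the artifact can dominate weaker true signal and
    vary trial to trial; noise SD 5 intensity units (0.5% of baseline); gentle
    polynomial drift within +-1%.
    """
    schedule = schedule or make_schedule()
    rng = np.random.default_rng(seed)
    masks = default_masks(grid_shape)
    amps = rng.uniform(*tcm_amp_range, size=(schedule.n_runs, schedule.trials_per_run))
    return GroundTruth(
        bold_mask=masks["bold"],
        tcm_mask_true=masks["tcm"],
        bold_amplitude=bold_amplitude,
        tcm_amplitudes=amps,
        noise_sd=noise_sd,
        drift_coeffs=drift_coeffs,
        seed=seed,
        brain_mask=masks["brain"],
        gm_mask=masks["gm"],
        wm_mask=masks["wm"],
    )


def bold_waveform(schedule: StimulusSchedule, run_index: int, amplitude_pct: float) -> np.ndarray:
    """Fractional BOLD time course: stimulus train convolved with the canonical
    HRF, normalized to unit peak and scaled to ``amplitude_pct`` percent."""
    n = schedule.n_frames
    train = np.zeros(n)
    frames = schedule.onset_frames(run_index)
    train[frames[frames < n]] = 1.0
    t = np.arange(n) * schedule.tr_s
    kernel = canonical_hrf(t)
    kernel = kernel / kernel.max()
    return (amplitude_pct / 100.0) * np.convolve(train, kernel)[:n]


def tcm_waveform(
    schedule: StimulusSchedule,
    run_index: int,
    amplitudes_pct: np.ndarray,
    window_trs: int = 3,
) -> np.ndarray:
    """Fractional artifact time course: a biphasic spike after each onset.

    Strictly zero outside the first ``window_trs`` frames after each onset.
    """
    if len(TCM_SPIKE_SHAPE) > window_trs:
        raise ValueError("spike shape longer than the artifact window")
    n = schedule.n_frames
    wave = np.zeros(n)
    for amp, frame in zip(amplitudes_pct, schedule.onset_frames(run_index)):
        for j, w in enumerate(TCM_SPIKE_SHAPE):
            if frame + j < n:
                wave[frame + j] += (amp / 100.0) * w
    return wave


def _drift_waveform(n_frames: int, coeffs: tuple[float, ...]) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n_frames)
    return sum((c / 100.0) * np.polynomial.legendre.Legendre.basis(i)(x)
               for i, c in enumerate(coeffs)) if coeffs else np.zeros(n_frames)


def simulate_run(
    schedule: StimulusSchedule,
    run_index: int,
    ground_truth: GroundTruth,
    grid_shape=DEFAULT_GRID,
    seed: int = 0,
    voxel_size_mm: float = DEFAULT_VOXEL_MM,
    motion_coupling: float = 0.05,
) -> BoldRun:
    """Simulate one run on the given grid.

    The BOLD term lives inside ``bold_mask``, the artifact inside
    ``tcm_mask_true``, drift is global within brain-plus-rim, and white noise
    covers the whole grid.
    """
    gt = ground_truth
    if gt.bold_mask.shape != tuple(grid_shape):
        raise ValueError(
            f"ground-truth masks {gt.bold_mask.shape} do not match grid {tuple(grid_shape)}"
        )
    rng = np.random.default_rng(seed)
    n = schedule.n_frames
    bold = bold_waveform(schedule, run_index, gt.bold_amplitude)
    tcm = tcm_waveform(
        schedule, run_index, gt.tcm_amplitudes[run_index], gt.tcm_window_trs
    )
    drift = _drift_waveform(n, gt.drift_coeffs)

    support = gt.brain_mask if gt.brain_mask is not None else np.ones(grid_shape, bool)
    support = support | gt.tcm_mask_true | gt.bold_mask
    frac = np.zeros((*grid_shape, n))
    frac[support] += drift
    frac[gt.bold_mask] += bold
    frac[gt.tcm_mask_true] += tcm
    data = gt.baseline * (1.0 + frac)
    if gt.noise_sd > 0:
        data = data + rng.normal(0.0, gt.noise_sd, size=data.shape)
    motion = simulate_motion(
        schedule, tcm_coupling=motion_coupling, seed=seed + 1, run_index=run_index
    )
    return BoldRun(
        data=data,
        tr_s=schedule.tr_s,
        voxel_size_mm=voxel_size_mm,
        run_index=run_index,
        schedule=schedule,
        motion=motion,
        ground_truth=gt,
    )


def simulate_motion(
    schedule: StimulusSchedule,
    tcm_coupling: float = 0.05,
    seed: int = 0,
    run_index: int = 0,
    walk_sd: float = 0.01,
) -> MotionParams:
    """Rigid-motion trace: a smooth random walk plus stimulus-locked bumps.

    ``tcm_coupling`` (mm) scales transient bumps in the first 3 frames after
    each onset, mimicking speech-locked head movement.
    """
    if tcm_coupling < 0:
        raise ValueError("tcm_coupling must be non-negative")
    rng = np.random.default_rng(seed)
    n = schedule.n_frames
    steps = rng.normal(0.0, walk_sd, size=(n, 6)) if walk_sd > 0 else np.zeros((n, 6))
    params = np.cumsum(steps, axis=0)
    if tcm_coupling > 0:
        bump = np.array([1.0, 0.6, 0.2])
        for frame in schedule.onset_frames(run_index):
            axis = rng.integers(0, 6)
            for j, b in enumerate(bump):
                if frame + j < n:
                    params[frame + j, axis] += tcm_coupling * b * rng.choice([-1.0, 1.0])
    return MotionParams(params=params)


def simulate_collection(
    n_datasets: int,
    schedule: StimulusSchedule | None = None,
    grid_shape=DEFAULT_GRID,
    seed: int = 0,
    **gt_kwargs,
) -> list[BoldRun]:
    """Independent ground-truth-labeled runs for classifier training.

    Per-dataset seeds are derived deterministically from the master seed; the
    artifact amplitudes vary across datasets through the per-dataset seed.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    schedule = schedule or make_schedule()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_datasets) % (2**31 - 1)
    runs = []
    for i, s in enumerate(child_seeds):
        gt = default_ground_truth(schedule, grid_shape, seed=int(s), **gt_kwargs)
        runs.append(
            simulate_run(schedule, run_index=i % schedule.n_runs, ground_truth=gt,
                         grid_shape=grid_shape, seed=int(s))
        )
    return runs
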