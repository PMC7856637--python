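"""Evaluation metrics for denoising comparisons.

Temporal stability is quantified inside a 5 mm sphere centered at the peak of
the surviving activation map: the coefficient of variation (CoV = SD / mean) of
the ROI-averaged smoothed series per run (then averaged across runs), and the
trial-by-trial Fano factor

    FF = sigma_W^2 / mu_W

computed over a window W of the first 3 TRs (= 5.1 s at TR 1.7 s) after each
stimulus onset — the frames in which speech-locked motion is concentrated.
Per-run FF values are normalized by the run mean and then averaged across runs,
giving one value per trial position.  Spatial specificity is the count of
surviving activation voxels inside gray- and white-matter masks; methods are
compared by paired t-tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import StimulusSchedule
from .deconvolution import ActivationMap

__all__ = [
    "SphereROI",
    "FanoResult",
    "MetricsReport",
    "NoActivationError",
    "peak_sphere",
    "cov",
    "cov_per_run",
    "fano_factor",
    "tissue_counts",
    "compare_methods",
]


class NoActivationError(ValueError):
    """The activation map has no surviving voxels."""


@dataclass(frozen=True)
class SphereROI:
    center: tuple[int, int, int]
    radius_mm: float
    members: np.ndarray  # (n, 3) voxel indices

    def mask(self, grid_shape) -> np.ndarray:
        m = np.zeros(grid_shape, bool)
        m[tuple(self.members.T)] = True
        return m


@dataclass
class FanoResult:
    per_trial_ff: np.ndarray  # (n_runs, trials_per_run), NaN where flagged
    window_n_trs: int
    run_means: np.ndarray  # per-run normalization record
    run_averaged_ff: np.ndarray  # (trials_per_run,)

    @property
    def mean_ff(self) -> float:
        return float(np.nanmean(self.run_averaged_ff))


@dataclass
class MetricsReport:
    method_tag: str
    cov_per_run: np.ndarray
    cov_average: float
    fano: FanoResult | None = None
    gm_voxels: int = 0
    wm_voxels: int = 0

    def to_frame(self, dataset: str = "synthetic") -> pd.DataFrame:
        rows = [
            (dataset, self.method_tag, "cov_average", self.cov_average),
            (dataset, self.method_tag, "gm_voxels", self.gm_voxels),
            (dataset, self.method_tag, "wm_voxels", self.wm_voxels),
        ]
        if self.fano is not None:
            rows.append((dataset, self.method_tag, "fano_mean", self.fano.mean_ff))
        return pd.DataFrame(rows, columns=["dataset", "method", "metric", "value"])


def peak_sphere(
    act_map: ActivationMap,
    radius_mm: float = 5.0,
    voxel_size_mm: float = 3.0,
    restrict_mask: np.ndarray | None = None,
) -> SphereROI:
    """Sphere of ``radius_mm`` centered at the peak-R^2 surviving voxel.

    Ties break to the smallest linear (C-order) index.  ``restrict_mask``
    limits the peak search (e.g. to an artifact-prone region); the sphere
    itself is not restricted.
    """
    surviving = act_map.surviving_mask.copy()
    if restrict_mask is not None:
        surviving = surviving & np.asarray(restrict_mask, bool)
    if not surviving.any():
        raise NoActivationError("no surviving activation voxels to center on")
    masked = np.where(surviving, act_map.r2_map, -np.inf)
    center = np.unravel_index(int(np.argmax(masked)), masked.shape)
    idx = np.indices(masked.shape)
    d2 = sum(((idx[i] - center[i]) * voxel_size_mm) ** 2 for i in range(3))
    members = np.argwhere(d2 <= radius_mm**2)
    return SphereROI(center=tuple(int(c) for c in center), radius_mm=radius_mm, members=members)


def cov(series: np.ndarray, ddof: int = 1) -> float:
    """Coefficient of variation, SD / mean.  Zero-mean series give NaN."""
    x = np.asarray(series, float)
    m = x.mean()
    if abs(m) < 1e-300:
        return float("nan")
    return float(x.std(ddof=ddof) / m)


def cov_per_run(run_series: list[np.ndarray] | np.ndarray) -> tuple[np.ndarray, float]:
    """CoV of the ROI-averaged series per run, plus the cross-run average."""
    vals = np.array([cov(s) for s in run_series])
    return vals, float(np.nanmean(vals))


def fano_factor(
    run_series: list[np.ndarray] | np.ndarray,
    schedule: StimulusSchedule,
    window_n_trs: int = 3,
    normalization: str = "run-mean",
    ddof: int = 0,
) -> FanoResult:
    """Trial-by-trial Fano factor of ROI-averaged series, one series per run.

    For each trial, FF = variance / mean over the ``window_n_trs`` frames
    starting at the first frame at/after the onset (ceil(onset / TR)).  Trials
    with non-positive window mean are flagged (NaN) and excluded from run
    means.  ``normalization``: "run-mean" divides each run's FF values by that
    run's mean FF before averaging across runs; "zscore" centers/scales
    instead; "none" skips it.
    """
    if normalization not in ("run-mean", "zscore", "none"):
        raise ValueError("unknown normalization")
    series = [np.asarray(s, float) for s in run_series]
    if len(series) != len(schedule.onsets_s):
        raise ValueError("one series per scheduled run required")
    n_trials = schedule.trials_per_run
    ff = np.full((len(series), n_trials), np.nan)
    for r, x in enumerate(series):
        for t, onset in enumerate(schedule.onsets_s[r]):
            start = math.ceil(onset / schedule.tr_s - 1e-9)
            win = x[start : start + window_n_trs]
            if len(win) < window_n_trs:
                warnings.warn(f"trial {t} of run {r} window truncated; flagged", stacklevel=2)
                continue
            mu = win.mean()
            if mu <= 0:
                warnings.warn(
                    f"trial {t} of run {r} has non-positive window mean; flagged",
                    stacklevel=2,
                )
                continue
            ff[r, t] = win.var(ddof=ddof) / mu
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN runs
        run_means = np.nanmean(ff, axis=1)
    if normalization == "run-mean":
        safe = np.where(np.abs(run_means) < 1e-300, np.nan, run_means)
        normed = ff / safe[:, None]
    elif normalization == "zscore":
        sd = np.nanstd(ff, axis=1)
        sd = np.where(sd == 0, np.nan, sd)
        normed = (ff - run_means[:, None]) / sd[:, None]
    else:
        normed = ff
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN trial columns
        run_avg = np.nanmean(normed, axis=0)
    return FanoResult(
        per_trial_ff=ff,
        window_n_trs=window_n_trs,
        run_means=run_means,
        run_averaged_ff=run_avg,
    )


def tissue_counts(
    act_map: ActivationMap, gm_mask: np.ndarray, wm_mask: np.ndarray
) -> tuple[int, int]:
    """Surviving activation voxels inside the GM and WM masks."""
    gm = np.asarray(gm_mask, bool)
    wm = np.asarray(wm_mask, bool)
    if (gm & wm).any():
        warnings.warn("GM and WM masks overlap", stacklevel=2)
    s = act_map.surviving_mask
    return int((s & gm).sum()), int((s & wm).sum())


def compare_methods(reports: dict[str, list[MetricsReport]]) -> pd.DataFrame:
    """Paired comparison of metrics across methods.

    ``reports`` maps method tag -> per-dataset reports (same dataset order in
    every method).  Returns one row per (metric, method pair) with means,
    paired t statistic and p value; zero-variance nonzero differences are
    flagged degenerate (p reported as 0).
    """
    tags = list(reports)
    if len(tags) < 2:
        raise ValueError("at least two methods required")
    n = {tag: len(r) for tag, r in reports.items()}
    if len(set(n.values())) != 1:
        raise ValueError(f"unpaired inputs: dataset counts {n}")

    def metric_values(tag: str, metric: str) -> np.ndarray:
        vals = []
        for rep in reports[tag]:
            if metric == "fano_mean":
                vals.append(rep.fano.mean_ff if rep.fano is not None else np.nan)
            else:
                vals.append(getattr(rep, metric))
        return np.asarray(vals, float)

    rows = []
    for metric in ("cov_average", "fano_mean", "gm_voxels", "wm_voxels"):
        for i, a in enumerate(tags):
            for b in tags[i + 1 :]:
                va, vb = metric_values(a, metric), metric_values(b, metric)
                if np.isnan(va).all() or np.isnan(vb).all():
                    continue
                d = va - vb
                degenerate = False
                if np.allclose(d, 0):
                    t, p = 0.0, 1.0
                elif np.isclose(d.std(ddof=1), 0):
                    t, p = np.inf if d.mean() > 0 else -np.inf, 0.0
                    degenerate = True
                else:
                    t, p = stats.ttest_rel(va, vb)
                rows.append(
                    {
                        "metric": metric,
                        "method_a": a,
                        "method_b": b,
                        "mean_a": float(np.nanmean(va)),
                        "mean_b": float(np.nanmean(vb)),
                        "t": float(t),
                        "p": float(p),
                        "n": len(d),
                        "degenerate": degenerate,
                    }
                )
    return pd.DataFrame(rows)
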