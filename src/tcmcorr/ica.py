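"""Spatio-temporal IC classification and removal of task-correlated motion.

A run is decomposed by spatial ICA into spatial-map / time-course pairs.  Each
component is characterised by six pieces of spatio-temporal evidence:

- ``irf_template_corr``: Pearson correlation of the component's stimulus-locked
  impulse response (FIR deconvolution of its time course) with the canonical
  HRF — high for genuine BOLD components.
- ``voxel_match_frac``: within the artifact-prone spatial mask, the fraction of
  task-active voxels whose own FIR impulse response correlates with the
  component's impulse response at r >= 0.7 — the core spatio-temporal match.
- ``psd_task_ratio``: periodogram power at the task frequency (+- one bin)
  relative to broadband median power — spuriously elevated for stimulus-locked
  components.
- ``spatial_overlap``: fraction of the component's suprathreshold |z| mass that
  lies inside the artifact-prone mask.
- ``spikiness``: max |first difference| of the time course over its robust SD —
  large for the rapid, spiky signal changes of speech-locked motion, small for
  the sluggish BOLD response.
- ``early_energy_frac``: fraction of impulse-response energy in the first three
  lags, where speech-locked motion concentrates.

Components are labeled noise either by a conservative hand-emulating rule or by
a regularized linear classifier trained on labeled components from at least ten
datasets, and removed non-aggressively (only the noise components' uniquely
fitted contribution is subtracted, preserving variance shared with retained
components).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .deconvolution import DesignMatrix, IRFEstimate, deconvolve
from .hrf import canonical_hrf
from .schedule import StimulusSchedule
from .simulate import BoldRun

__all__ = [
    "ICDecomposition",
    "ICFeatureVector",
    "ICLabel",
    "TrainedClassifier",
    "RuleConfig",
    "decompose",
    "estimate_n_ics",
    "ic_irf",
    "extract_features",
    "hrf_ic_match",
    "rule_label",
    "train_classifier",
    "apply_classifier",
    "task_regressor",
    "protection_matrix",
    "remove_components",
    "true_ic_labels",
]

FEATURE_NAMES = (
    "irf_template_corr",
    "voxel_match_frac",
    "psd_task_ratio",
    "spatial_overlap",
    "spikiness",
    "early_energy_frac",
)


@dataclass
class ICDecomposition:
    """Spatial ICA of one run: z-scored maps, unit-variance time courses, and
    the raw factors needed to reconstruct the demeaned data."""

    spatial_maps: np.ndarray  # (n_ics, x, y, z), z-scored
    timecourses: np.ndarray  # (n_ics, frames), unit variance
    mixing: np.ndarray  # (frames, n_ics): column k is timecourse k
    maps_raw: np.ndarray  # (n_ics, n_voxels): loadings matching `timecourses`
    mean_image: np.ndarray  # (x, y, z) temporal mean
    frame_offset: np.ndarray  # (frames,) spatial-mean residual per frame
    residual_frac: float  # fraction of demeaned variance not reconstructed
    n_ics: int

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mean_image.shape

    def reconstruct(self) -> np.ndarray:
        """Mean + mixing x maps (x, y, z, t)."""
        xd = self.mixing @ self.maps_raw + self.frame_offset[:, None]
        n_frames = self.mixing.shape[0]
        vol = xd.T.reshape(*self.grid_shape, n_frames)
        return vol + self.mean_image[..., None]


@dataclass(frozen=True)
class ICFeatureVector:
    ic_index: int
    irf_template_corr: float
    voxel_match_frac: float
    psd_task_ratio: float
    spatial_overlap: float
    spikiness: float
    early_energy_frac: float
    match_flag: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


@dataclass(frozen=True)
class ICLabel:
    ic_index: int
    decision: str  # "signal" | "noise"
    score: float  # probability-like in [0, 1] that the IC is noise
    source: str = "rule"  # rule | classifier | manual

    def __post_init__(self) -> None:
        if self.decision not in ("signal", "noise"):
            raise ValueError("decision must be 'signal' or 'noise'")


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds for the hand-emulating rule (all configurable)."""

    r_thresh: float = 0.7
    min_frac: float = 0.05
    tau_psd: float = 2.0
    tau_spike: float = 4.0
    tau_spatial: float = 0.2
    z_thresh: float = 2.0


def estimate_n_ics(xd: np.ndarray, cap: int = 30) -> int:
    """Automatic dimensionality: count of data eigenvalues above the
    Marchenko-Pastur upper edge of the noise bulk (noise variance taken from
    the median eigenvalue), floored at 2 and capped at min(cap, frames // 5).

    ``xd`` is the demeaned (voxels, frames) matrix.
    """
    n_vox, n_frames = xd.shape
    ev = np.linalg.svd(xd, compute_uv=False) ** 2 / n_vox
    q = min(n_frames / n_vox, 1.0)
    sigma2 = np.median(ev) / max(1.0 - q, 1e-6)
    lam_plus = sigma2 * (1.0 + np.sqrt(q)) ** 2
    n = int(np.sum(ev > lam_plus))
    return int(np.clip(n, 2, min(cap, n_frames // 5)))


def decompose(run: BoldRun | np.ndarray, n_ics: int | None = None, seed: int = 0,
              max_retries: int = 3) -> ICDecomposition:
    """Spatial ICA of a run via FastICA, with no variance normalization of the
    data beyond removal of the temporal mean.

    ``n_ics`` defaults to automatic dimensionality estimation (eigenvalues
    above the Marchenko-Pastur noise edge), capped at min(30, frames // 5):
    asking FastICA to split an isotropic noise subspace prevents convergence.
    On non-convergence the decomposition is retried with a new seed up to
    ``max_retries`` times.
    """
    data = run.data if isinstance(run, BoldRun) else np.asarray(run, float)
    *grid, n_frames = data.shape
    mean_image = data.mean(axis=-1)
    xd = (data - mean_image[..., None]).reshape(-1, n_frames)  # (voxels, frames)
    if n_ics is None:
        n_ics = estimate_n_ics(xd)
    if not 2 <= n_ics <= n_frames - 1:
        raise ValueError("n_ics must be in [2, frames-1]")

    last_err: Exception | None = None
    for attempt in range(max_retries + 1):
        ica = FastICA(
            n_components=n_ics,
            whiten="unit-variance",
            max_iter=1000,
            tol=1e-3,
            random_state=seed + attempt,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(xd)  # (voxels, n_ics)
                break
            except ConvergenceWarning as err:  # pragma: no cover - rare
                last_err = err
    else:  # pragma: no cover
        raise RuntimeError(f"ICA failed to converge after {max_retries + 1} attempts") from last_err

    mixing = ica.mixing_  # (frames, n_ics)
    frame_offset = ica.mean_  # per-frame mean across voxels
    # resolve ICA sign indeterminacy: orient each time course to positive skew
    # (both the hemodynamic response and the artifact spike are positive-going)
    tc_centered = mixing - mixing.mean(axis=0, keepdims=True)
    m3 = (tc_centered**3).mean(axis=0)
    flip = np.where(m3 < 0, -1.0, 1.0)
    mixing = mixing * flip
    sources = sources * flip
    sd = mixing.std(axis=0)
    sd[sd == 0] = 1.0
    timecourses = (mixing / sd).T  # (n_ics, frames), unit variance
    maps_raw = (sources * sd).T  # (n_ics, voxels)
    recon = sources @ mixing.T + frame_offset[None, :]  # (voxels, frames)
    resid = xd - recon
    denom = float(np.sum(xd**2))
    residual_frac = float(np.sum(resid**2) / denom) if denom > 0 else 0.0
    zmaps = maps_raw - maps_raw.mean(axis=1, keepdims=True)
    zsd = zmaps.std(axis=1, keepdims=True)
    zsd[zsd == 0] = 1.0
    zmaps = (zmaps / zsd).reshape(n_ics, *grid)
    return ICDecomposition(
        spatial_maps=zmaps,
        timecourses=timecourses,
        mixing=mixing / sd,
        maps_raw=maps_raw,
        mean_image=mean_image,
        frame_offset=frame_offset,
        residual_frac=residual_frac,
        n_ics=n_ics,
    )


def ic_irf(ic_timecourse: np.ndarray, design: DesignMatrix) -> IRFEstimate:
    """Stimulus-locked FIR deconvolution of one component time course."""
    return deconvolve(np.asarray(ic_timecourse, float), design)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def hrf_ic_match(
    voxel_hrfs: np.ndarray,
    ic_irf_coefs: np.ndarray,
    r_thresh: float = 0.7,
    min_frac: float = 0.05,
) -> tuple[float, bool]:
    """Fraction of task-active artifact-mask voxels whose impulse response
    correlates (signed Pearson r) with the component's at ``r_thresh``.

    ``voxel_hrfs`` has shape (n_voxels, n_lags).  With no active voxels the
    fraction is 0 and the flag false (warning logged).
    """
    v = np.atleast_2d(np.asarray(voxel_hrfs, float))
    if v.shape[0] == 0:
        warnings.warn("no active voxels inside the artifact mask", stacklevel=2)
        return 0.0, False
    rs = np.array([_pearson(row, ic_irf_coefs) for row in v])
    frac = float(np.mean(rs >= r_thresh))
    return frac, frac >= min_frac


def _psd_task_ratio(tc: np.ndarray, task_freq: float, fs: float) -> float:
    freqs, pxx = periodogram(tc, fs=fs)
    if np.all(pxx == 0):
        return 0.0
    ibin = int(np.argmin(np.abs(freqs - task_freq)))
    lo, hi = max(ibin - 1, 0), min(ibin + 1, len(freqs) - 1)
    band = pxx[lo : hi + 1].max()
    med = np.median(pxx[1:])  # exclude DC
    return float(band / med) if med > 0 else 0.0


def _spikiness(tc: np.ndarray) -> float:
    d = np.abs(np.diff(tc))
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(tc - np.median(tc)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        return 0.0
    return float(d.max() / robust_sd)


def extract_features(
    decomposition: ICDecomposition,
    schedule: StimulusSchedule,
    design: DesignMatrix,
    voxel_hrfs: np.ndarray,
    active_mask: np.ndarray,
    tcm_mask: np.ndarray,
    rule_config: RuleConfig = RuleConfig(),
    task_freq_hz: float | None = None,
) -> list[ICFeatureVector]:
    """Six-feature evidence vector for every component of a decomposition.

    ``voxel_hrfs`` is the (x, y, z, n_lags) FIR coefficient grid from whole-run
    deconvolution and ``active_mask`` the surviving activation mask used to
    select the artifact-mask voxels entering the spatio-temporal match.
    """
    cfg = rule_config
    task_freq = task_freq_hz if task_freq_hz is not None else schedule.task_freq_hz
    fs = 1.0 / schedule.tr_s
    t_lags = design.lag_times_s
    template = canonical_hrf(t_lags)
    mask_active = np.asarray(tcm_mask, bool) & np.asarray(active_mask, bool)
    hrfs_in_mask = np.asarray(voxel_hrfs, float)[mask_active]

    out: list[ICFeatureVector] = []
    for k in range(decomposition.n_ics):
        tc = decomposition.timecourses[k]
        irf = ic_irf(tc, design)
        coefs = irf.coefficients
        energy = float(np.sum(coefs**2))
        early = float(np.sum(coefs[:3] ** 2) / energy) if energy > 0 else 0.0
        if tc.std() == 0:
            out.append(
                ICFeatureVector(k, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, match_flag=False)
            )
            continue
        frac, flag = hrf_ic_match(hrfs_in_mask, coefs, cfg.r_thresh, cfg.min_frac)
        zmap = np.abs(decomposition.spatial_maps[k])
        supra = zmap >= cfg.z_thresh
        mass = float(zmap[supra].sum())
        overlap = float(zmap[supra & tcm_mask].sum() / mass) if mass > 0 else 0.0
        out.append(
            ICFeatureVector(
                ic_index=k,
                irf_template_corr=_pearson(coefs, template),
                voxel_match_frac=frac,
                psd_task_ratio=_psd_task_ratio(tc, task_freq, fs),
                spatial_overlap=overlap,
                spikiness=_spikiness(tc),
                early_energy_frac=early,
                match_flag=flag,
            )
        )
    return out


def rule_label(features: ICFeatureVector, rule_config: RuleConfig = RuleConfig()) -> ICLabel:
    """Conservative hand-emulating rule: a component is noise only when the
    spatio-temporal voxel match fires AND its time course is task-spiky (power
    or spikiness) AND its map sits in the artifact-prone region.  Ambiguous
    mixtures are retained as signal."""
    cfg = rule_config
    is_noise = (
        features.match_flag
        and (features.psd_task_ratio > cfg.tau_psd or features.spikiness > cfg.tau_spike)
        and features.spatial_overlap > cfg.tau_spatial
    )
    return ICLabel(
        ic_index=features.ic_index,
        decision="noise" if is_noise else "signal",
        score=1.0 if is_noise else 0.0,
        source="rule",
    )


@dataclass
class TrainedClassifier:
    feature_names: tuple[str, ...]
    model: LogisticRegression
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    decision_threshold: float
    training_meta: dict

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.feat_mean) / self.feat_sd
        return self.model.predict_proba(Xs)[:, 1]


def _stack_features(feature_sets: list[list[ICFeatureVector]]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([[f.as_array() for f in fs] for fs in feature_sets if fs])
    groups = np.concatenate(
        [np.full(len(fs), i) for i, fs in enumerate(feature_sets) if fs]
    )
    return X, groups


def _labels_to_binary(labels: list[ICLabel]) -> np.ndarray:
    return np.array([1 if lab.decision == "noise" else 0 for lab in labels])


def _fit_logistic(X: np.ndarray, y: np.ndarray, seed: int) -> tuple[LogisticRegression, np.ndarray, np.ndarray]:
    mean, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    model = LogisticRegression(
        C=1.0, class_weight="balanced", max_iter=2000, random_state=seed
    )
    model.fit((X - mean) / sd, y)
    return model, mean, sd


def train_classifier(
    feature_sets: list[list[ICFeatureVector]],
    label_sets: list[list[ICLabel]],
    seed: int = 0,
    allow_few_datasets: bool = False,
    decision_threshold: float = 0.5,
) -> TrainedClassifier:
    """Train the regularized linear noise classifier on labeled components.

    Requires components from at least 10 datasets (overridable with a warning
    via ``allow_few_datasets``).  Leave-one-dataset-out (LODO) sensitivity and
    specificity for the noise class are reported in ``training_meta``.
    """
    if len(feature_sets) != len(label_sets):
        raise ValueError("feature and label sets must pair one-to-one")
    n_datasets = len(feature_sets)
    if n_datasets < 10:
        if not allow_few_datasets:
            raise ValueError(
                f"{n_datasets} datasets < 10 required for robust training; "
                "pass allow_few_datasets=True to override"
            )
        warnings.warn(f"training on only {n_datasets} datasets", stacklevel=2)
    X, groups = _stack_features(feature_sets)
    y = np.concatenate([_labels_to_binary(labs) for labs in label_sets if labs])
    if len(np.unique(y)) < 2:
        raise ValueError("both signal and noise labels are required for training")

    # leave-one-dataset-out evaluation
    tp = fn = tn = fp = 0
    for g in np.unique(groups):
        tr, te = groups != g, groups == g
        if len(np.unique(y[tr])) < 2:
            continue
        m, mean, sd = _fit_logistic(X[tr], y[tr], seed)
        pred = (m.predict_proba((X[te] - mean) / sd)[:, 1] >= decision_threshold).astype(int)
        tp += int(np.sum((pred == 1) & (y[te] == 1)))
        fn += int(np.sum((pred == 0) & (y[te] == 1)))
        tn += int(np.sum((pred == 0) & (y[te] == 0)))
        fp += int(np.sum((pred == 1) & (y[te] == 0)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    total = tp + fn + tn + fp
    accuracy = (tp + tn) / total if total else np.nan

    model, mean, sd = _fit_logistic(X, y, seed)
    return TrainedClassifier(
        feature_names=FEATURE_NAMES,
        model=model,
        feat_mean=mean,
        feat_sd=sd,
        decision_threshold=decision_threshold,
        training_meta={
            "n_datasets": n_datasets,
            "n_components": int(len(y)),
            "n_noise": int(y.sum()),
            "seed": seed,
            "lodo_sensitivity": sens,
            "lodo_specificity": spec,
            "lodo_accuracy": accuracy,
        },
    )


def apply_classifier(
    model: TrainedClassifier, features: list[ICFeatureVector]
) -> list[ICLabel]:
    """Deterministic noise/signal decisions at the trained threshold."""
    if model.feature_names != FEATURE_NAMES:
        raise ValueError("feature schema does not match the trained model")
    if not features:
        return []
    X = np.vstack([f.as_array() for f in features])
    scores = model.predict_scores(X)
    return [
        ICLabel(
            ic_index=f.ic_index,
            decision="noise" if s >= model.decision_threshold else "signal",
            score=float(s),
            source="classifier",
        )
        for f, s in zip(features, scores)
    ]


def task_regressor(
    schedule: StimulusSchedule,
    run_index: int = 0,
    hrf_params=None,
) -> np.ndarray:
    """Canonical task model for signal protection during removal.

    The stimulus onset train convolved with the canonical HRF, sampled at the
    TR grid and normalized to unit peak.  Passing this as ``protect`` to
    :func:`remove_components` shields canonically shaped task-locked variance
    from removal.
    """
    n = schedule.n_frames
    train = np.zeros(n)
    frames = schedule.onset_frames(run_index)
    train[frames[frames < n]] = 1.0
    t = np.arange(n) * schedule.tr_s
    kernel = canonical_hrf(t, hrf_params)
    peak = kernel.max()
    if peak <= 0:
        raise ValueError("canonical HRF kernel has a non-positive peak")
    return np.convolve(train, kernel / peak)[:n]


def protection_matrix(
    schedule: StimulusSchedule,
    run_index: int = 0,
    poly_order: int = 3,
    hrf_params=None,
) -> np.ndarray:
    """Default protected-signal regressors for :func:`remove_components`.

    Columns: the canonical task model (:func:`task_regressor`) and a Legendre
    drift basis up to ``poly_order``.  Protecting drift alongside the task
    model matters because mixture components carrying both drift and artifact
    would otherwise re-inject artifact into drift-bearing voxels.
    """
    n = schedule.n_frames
    x = np.linspace(-1.0, 1.0, n)
    drift = np.column_stack(
        [np.polynomial.legendre.Legendre.basis(d)(x) for d in range(poly_order + 1)]
    )
    return np.column_stack([task_regressor(schedule, run_index, hrf_params), drift])


def remove_components(
    run: BoldRun | np.ndarray,
    decomposition: ICDecomposition,
    noise_labels: list[ICLabel] | list[int],
    mode: str = "nonaggressive",
    protect: np.ndarray | None = None,
):
    """Remove noise components from a run.

    nonaggressive (default): regress all component time courses against each
    voxel series and subtract only the noise components' fitted contribution —
    the part of each series unique to the noise time courses once the retained
    components are controlled for (the noise block's partialled contribution,
    equal to the projection onto the noise time courses residualized against
    the retained ones).  Variance shared with retained components is preserved
    and per-voxel variance never increases.  aggressive: subtract the full
    projection onto the noise time courses alone.  The voxel means are
    preserved either way.

    ``protect`` (frames x k, or a single series) supplies explicit signal
    regressors to shield from removal — typically the canonical task model and
    a drift basis.  When given, they replace the retained components' time
    courses as the definition of the signal to preserve: noise time courses
    are residualized against the protected regressors before the removal
    projection, so any noise variance shared with the protected model is
    retained.  This guards pure-signal voxels against over-correction when the
    artifact and the hemodynamic response are temporally correlated.  (The
    protected model must not be combined with the data-driven retained time
    courses: whitened components are mutually decorrelated, so a retained
    component plus an exact task regressor can jointly span the artifact
    direction and leave nothing to remove.)
    """
    if mode not in ("nonaggressive", "aggressive"):
        raise ValueError("mode must be 'nonaggressive' or 'aggressive'")
    data = run.data if isinstance(run, BoldRun) else np.asarray(run, float)
    noise_idx = sorted(
        lab.ic_index if isinstance(lab, ICLabel) else int(lab)
        for lab in noise_labels
        if not isinstance(lab, ICLabel) or lab.decision == "noise"
    )
    if not noise_idx:
        cleaned = data.copy()
    else:
        *grid, n_frames = data.shape
        mean_image = data.mean(axis=-1)
        xd = (data - mean_image[..., None]).reshape(-1, n_frames).T  # (frames, voxels)
        T = decomposition.mixing - decomposition.mixing.mean(axis=0, keepdims=True)
        P = None
        if protect is not None:
            P = np.atleast_2d(np.asarray(protect, float))
            P = P.T if P.shape[0] != n_frames else P
            P = P - P.mean(axis=0, keepdims=True)
        Tn = T[:, noise_idx]
        if mode == "nonaggressive":
            if P is not None:
                R = P
            else:
                retained_idx = [k for k in range(T.shape[1]) if k not in noise_idx]
                R = T[:, retained_idx]
            if R.shape[1]:
                coef, *_ = np.linalg.lstsq(R, Tn, rcond=None)
                Tn = Tn - R @ coef
        elif P is not None:
            coef, *_ = np.linalg.lstsq(P, Tn, rcond=None)
            Tn = Tn - P @ coef
        beta, *_ = np.linalg.lstsq(Tn, xd, rcond=None)
        fitted_noise = Tn @ beta
        cleaned = data - fitted_noise.T.reshape(data.shape)
    if isinstance(run, BoldRun):
        return run.copy_with(cleaned)
    return cleaned


def true_ic_labels(
    decomposition: ICDecomposition,
    artifact_timecourse: np.ndarray,
    r_thresh: float = 0.6,
) -> list[ICLabel]:
    """Ground-truth component labels for simulations: a component is noise when
    its time course correlates with the injected artifact waveform at
    |r| >= ``r_thresh``.  The simulation analogue of expert hand labels."""
    out = []
    for k in range(decomposition.n_ics):
        r = abs(_pearson(decomposition.timecourses[k], artifact_timecourse))
        out.append(
            ICLabel(
                ic_index=k,
                decision="noise" if r >= r_thresh else "signal",
                score=r,
                source="manual",
            )
        )
    return out
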