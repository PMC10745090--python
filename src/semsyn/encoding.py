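"""Voxelwise haemodynamic encoding models.

Feature time courses are built by placing (possibly amplitude-modulated)
impulses at word offsets, convolving with the canonical SPM double-gamma
HRF on an oversampled grid, and sampling at scan times.  Each voxel's
preprocessed BOLD series is then regressed on the design with ridge
regression under nested leave-one-run-out cross-validation: the inner loop
selects the penalty per voxel, the outer loop scores a cross-validated
Pearson correlation R on the held-out run.  ΔR is the per-voxel increase
in R when a feature set is appended to the confound-only baseline model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .grids import VoxelGrid, VoxelMap, check_same_grid

__all__ = [
    "HrfSpec", "WordEventSeries", "DesignMatrix", "BoldRun", "RidgeConfig",
    "EncodingResult", "spm_hrf", "make_regressor", "make_design",
    "make_baseline", "preprocess_bold", "ridge_fit", "fit_encoder", "delta_r",
]


@dataclass(frozen=True)
class HrfSpec:
    """Canonical SPM double-gamma HRF parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0
    oversampling: int = 16

    def __post_init__(self):
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion", "undershoot_ratio", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HrfSpec.{name} must be positive")
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")


@dataclass
class WordEventSeries:
    """Timed impulses: event times (word offsets) with per-event amplitudes.

    ``amplitudes`` may be a 1-D vector (one column) or an
    (n_events, n_columns) matrix (one regressor per column).
    """

    times: np.ndarray
    amplitudes: np.ndarray
    run_id: int = 1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("event times must be a 1-D array")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("event times must be sorted within a run")
        if self.amplitudes.shape[0] != self.times.shape[0]:
            raise ValueError("amplitude rows must align with event times")


@dataclass
class DesignMatrix:
    """Scan-sampled regressors for one run."""

    matrix: np.ndarray
    labels: list[str]
    tr: float = 2.0
    run_id: int = 1

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("design matrix shape does not match labels")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("design matrix contains NaN/inf")


@dataclass
class BoldRun:
    """Scans × voxels BOLD matrix for one subject/run."""

    data: np.ndarray
    tr: float = 2.0
    subject: str = "sub-01"
    run_id: int = 1
    grid: VoxelGrid | None = None
    constant_voxels: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BOLD data must be scans × voxels")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]


@dataclass
class RidgeConfig:
    """Nested-CV ridge settings: log-spaced penalty grid, leave-one-run-out."""

    alphas: np.ndarray = field(default_factory=lambda: np.logspace(-3, 5, 10))
    standardize: bool = True

    def __post_init__(self):
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.alphas.size == 0 or np.any(self.alphas <= 0):
            raise ValueError("alpha grid must be nonempty and positive")


@dataclass
class EncodingResult:
    """Cross-validated encoding scores: R per voxel, per-fold detail."""

    r_cv: np.ndarray              # (voxels,) mean over outer folds
    per_fold: np.ndarray          # (folds, voxels)
    alphas: np.ndarray            # (folds, voxels) selected penalties
    label: str = "model"

    @property
    def n_folds(self) -> int:
        return self.per_fold.shape[0]


def spm_hrf(spec: HrfSpec = HrfSpec(), tr: float = 2.0) -> np.ndarray:
    """SPM canonical double-gamma HRF sampled on the oversampled grid.

    Difference of two gamma densities (peak minus ratio-scaled undershoot),
    normalised to unit peak, over [0, duration) at dt = tr / oversampling.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    dt = tr / spec.oversampling
    t = np.arange(0.0, spec.duration, dt)
    peak = stats.gamma.pdf(t, spec.peak_delay / spec.peak_dispersion,
                           scale=spec.peak_dispersion)
    under = stats.gamma.pdf(t, spec.undershoot_delay / spec.undershoot_dispersion,
                            scale=spec.undershoot_dispersion)
    h = peak - spec.undershoot_ratio * under
    return h / h.max()


def _event_series(events: WordEventSeries, spec: HrfSpec, scan_times: np.ndarray,
                  tr: float) -> np.ndarray:
    """Oversampled impulse series (grid × columns) for the events."""
    dt = tr / spec.oversampling
    last_scan = scan_times[-1]
    n_hi = int(round(last_scan / dt)) + 1
    amps = events.amplitudes
    if amps.ndim == 1:
        amps = amps[:, None]
    series = np.zeros((n_hi, amps.shape[1]))
    for t_ev, a in zip(events.times, amps):
        idx = int(round(t_ev / dt))
        if idx >= n_hi:
            if t_ev > last_scan + spec.duration:
                warnings.warn(f"event at {t_ev:.2f}s falls after the last scan "
                              "plus HRF duration and contributes nothing")
            continue
        series[idx] += a
    return series


def make_regressor(events: WordEventSeries, spec: HrfSpec,
                   scan_times: np.ndarray, tr: float = 2.0) -> np.ndarray:
    """One HRF-convolved, scan-sampled regressor column.

    Impulses of the given amplitudes are placed at event times on the
    oversampled grid, convolved with the kernel, and read out at scan
    times.  Linear in the amplitudes by construction.
    """
    cols = make_design(events, spec, scan_times, tr=tr)
    if cols.shape[1] != 1:
        raise ValueError("make_regressor expects a single amplitude column")
    return cols[:, 0]


def make_design(events: WordEventSeries, spec: HrfSpec, scan_times: np.ndarray,
                tr: float = 2.0) -> np.ndarray:
    """HRF-convolve an event series with matrix amplitudes; scans × columns."""
    scan_times = np.asarray(scan_times, dtype=float)
    dt = tr / spec.oversampling
    scan_idx = np.round(scan_times / dt).astype(int)
    if not np.allclose(scan_times, scan_idx * dt, atol=1e-9):
        raise ValueError("scan times must lie on the TR/oversampling grid")
    series = _event_series(events, spec, scan_times, tr)
    kernel = spm_hrf(spec, tr)
    conv = sps.fftconvolve(series, kernel[:, None], axes=0)[:series.shape[0]]
    return conv[scan_idx]


def make_baseline(events: WordEventSeries, audio_rms: tuple[np.ndarray, np.ndarray],
                  log_freq: np.ndarray, spec: HrfSpec, scan_times: np.ndarray,
                  tr: float = 2.0) -> DesignMatrix:
    """Confound-only design: acoustic energy, word rate, log lexical frequency.

    Column 1: HRF-convolved RMS of the audio signal (10 ms sampling);
    column 2: unit impulses at word offsets, convolved;
    column 3: impulses modulated by mean-centred log unigram frequency.
    """
    log_freq = np.asarray(log_freq, dtype=float)
    if log_freq.shape[0] != events.times.shape[0]:
        raise ValueError("log_freq must align with word events")
    if np.any(~np.isfinite(log_freq)):
        bad = int(np.flatnonzero(~np.isfinite(log_freq))[0])
        raise ValueError(f"missing lexical frequency for token index {bad}")
    rms_t, rms_v = audio_rms
    rms_events = WordEventSeries(times=np.asarray(rms_t, dtype=float),
                                 amplitudes=np.asarray(rms_v, dtype=float),
                                 run_id=events.run_id)
    col_rms = make_design(rms_events, spec, scan_times, tr=tr)[:, 0]
    word_amp = np.column_stack([
        np.ones_like(events.times),
        log_freq - log_freq.mean(),
    ])
    word_events = WordEventSeries(times=events.times, amplitudes=word_amp,
                                  run_id=events.run_id)
    cols = make_design(word_events, spec, scan_times, tr=tr)
    matrix = np.column_stack([col_rms, cols])
    return DesignMatrix(matrix=matrix,
                        labels=["acoustic_energy", "word_rate", "log_frequency"],
                        tr=tr, run_id=events.run_id)


def preprocess_bold(raw: BoldRun) -> BoldRun:
    """Linear detrend then z-score each voxel; flag and zero constant voxels."""
    if raw.n_scans < 3:
        raise ValueError("need at least 3 scans to detrend")
    detrended = sps.detrend(raw.data, axis=0, type="linear")
    sd = detrended.std(axis=0)
    constant = sd < 1e-12
    sd_safe = np.where(constant, 1.0, sd)
    out = (detrended - detrended.mean(axis=0)) / sd_safe
    out[:, constant] = 0.0
    return BoldRun(data=out, tr=raw.tr, subject=raw.subject, run_id=raw.run_id,
                   grid=raw.grid, constant_voxels=constant)


# ---------------------------------------------------------------------------
# ridge engine


def ridge_fit(X: np.ndarray, Y: np.ndarray, alpha: float) -> np.ndarray:
    """Ridge weights via SVD: solves (XᵀX + αI) W = XᵀY without intercept."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    shrink = s / (s * s + alpha)
    return Vt.T @ (shrink[:, None] * (U.T @ Y))


def _pearson_columns(pred: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r; zero-variance columns score 0."""
    pc = pred - pred.mean(axis=0)
    yc = y - y.mean(axis=0)
    ps = np.sqrt((pc * pc).sum(axis=0))
    ys = np.sqrt((yc * yc).sum(axis=0))
    denom = ps * ys
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc * yc).sum(axis=0) / denom
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def _standardize_runs(designs: list[np.ndarray]) -> list[np.ndarray]:
    out = []
    for X in designs:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        out.append((X - mu) / sd)
    return out


def fit_encoder(designs: list, bolds: list, cfg: RidgeConfig = None,
                label: str = "model") -> EncodingResult:
    """Nested leave-one-run-out ridge encoding, per-voxel penalty selection.

    For each outer fold (one run held out), the inner loop leaves out each
    training run in turn, scores every alpha on it, and selects — per voxel —
    the alpha with the best mean inner correlation.  The model is refit on
    all training runs at the selected alpha and scored on the held-out run;
    the final R is the mean of per-fold Pearson correlations.
    """
    if cfg is None:
        cfg = RidgeConfig()
    Xs = [d.matrix if isinstance(d, DesignMatrix) else np.asarray(d, dtype=float)
          for d in designs]
    Ys = [b.data if isinstance(b, BoldRun) else np.asarray(b, dtype=float)
          for b in bolds]
    n_runs = len(Xs)
    if n_runs < 3:
        raise ValueError("nested cross-validation needs at least 3 runs")
    if len(Ys) != n_runs:
        raise ValueError("designs and BOLD runs must pair up")
    for X, Y in zip(Xs, Ys):
        if X.shape[0] != Y.shape[0]:
            raise ValueError("design/BOLD scan counts differ within a run")
    if all(np.allclose(X, 0) for X in Xs):
        raise ValueError("design matrix is all zero")
    if cfg.standardize:
        Xs = _standardize_runs(Xs)

    n_vox = Ys[0].shape[1]
    alphas = cfg.alphas
    per_fold = np.empty((n_runs, n_vox))
    chosen = np.empty((n_runs, n_vox))
    boundary_votes = 0

    for outer in range(n_runs):
        train_runs = [r for r in range(n_runs) if r != outer]
        inner_r = np.zeros((alphas.size, n_vox))
        for inner_val in train_runs:
            tr_idx = [r for r in train_runs if r != inner_val]
            X_tr = np.vstack([Xs[r] for r in tr_idx])
            Y_tr = np.vstack([Ys[r] for r in tr_idx])
            U, s, Vt = np.linalg.svd(X_tr, full_matrices=False)
            UtY = U.T @ Y_tr
            XvV = Xs[inner_val] @ Vt.T
            Y_val = Ys[inner_val]
            for ai, a in enumerate(alphas):
                shrink = s / (s * s + a)
                pred = XvV @ (shrink[:, None] * UtY)
                inner_r[ai] += _pearson_columns(pred, Y_val)
        best = np.argmax(inner_r, axis=0)
        boundary_votes += int(np.sum((best == 0) | (best == alphas.size - 1)))
        chosen[outer] = alphas[best]

        X_full = np.vstack([Xs[r] for r in train_runs])
        Y_full = np.vstack([Ys[r] for r in train_runs])
        U, s, Vt = np.linalg.svd(X_full, full_matrices=False)
        UtY = U.T @ Y_full
        XtV = Xs[outer] @ Vt.T
        fold_r = np.empty(n_vox)
        for ai in np.unique(best):
            sel = best == ai
            shrink = s / (s * s + alphas[ai])
            pred = XtV @ (shrink[:, None] * UtY[:, sel])
            fold_r[sel] = _pearson_columns(pred, Ys[outer][:, sel])
        per_fold[outer] = fold_r

    if boundary_votes > 0.9 * n_runs * n_vox:
        warnings.warn("alpha grid exhausted at a boundary for most voxels; "
                      "consider widening the grid")
    return EncodingResult(r_cv=per_fold.mean(axis=0), per_fold=per_fold,
                          alphas=chosen, label=label)


def delta_r(model: EncodingResult, baseline: EncodingResult,
            grid: VoxelGrid | None = None) -> VoxelMap | np.ndarray:
    """Per-voxel increase in cross-validated R over the baseline model."""
    if model.per_fold.shape != baseline.per_fold.shape:
        raise ValueError("encoding results have mismatched folds or voxel grids")
    values = model.r_cv - baseline.r_cv
    if grid is None:
        return values
    return VoxelMap(values=values, grid=grid)
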