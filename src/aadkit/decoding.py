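"""Lag-windowed backward (stimulus-reconstruction) ridge models.

A backward model maps time-lagged multichannel EEG to the attended speech
envelope.  Instead of one decoder over the whole 0-500 ms lag range, a
45-ms window is slid over the lag axis in 15-ms hops (30 ms overlap),
giving 34 window decoders and hence a latency-resolved tracking profile:
the Pearson correlation between the reconstructed and the true envelope,
per lag window, per 60-s trial, for both the attended and the ignored
stream.

Ridge weights solve ``(X'X + lambda * m * I) w = X'y`` where ``m`` is the
mean diagonal of ``X'X`` over the penalized columns, making the
``10^-6 .. 10^+6`` regularization grid meaningful independent of data
scale; the intercept column is never penalized.  One lambda is shared
across all window models and selected by cross-validation on the mean
held-out correlation.

Two model variants:

- subject-independent: all subjects' 60-s trials of a condition are pooled
  and leave-one-trial-out cross-validated (9 trials x n_subjects folds);
- subject-dependent: each subject's 9 trials are 9-fold cross-validated
  on their own, with a per-subject lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .envelope import Envelope

__all__ = [
    "LagWindowDesign",
    "Trial",
    "DecoderModel",
    "TrackingCurve",
    "CrossValidationResult",
    "make_lag_design",
    "lambda_grid",
    "build_design_matrix",
    "train_ridge",
    "reconstruct_and_correlate",
    "partition_segments",
    "cross_validate",
]


@dataclass
class LagWindowDesign:
    """Ordered lag windows on the millisecond hop grid.

    ``windows`` maps each window start (ms) to the working-rate sample
    lags whose latency falls in ``[start, start + width)`` ms.
    """

    window_width: float
    overlap: float
    start_bound: float
    fs: float
    starts_ms: np.ndarray
    lag_sets: list[np.ndarray]

    @property
    def hop(self) -> float:
        return self.window_width - self.overlap

    @property
    def n_windows(self) -> int:
        return self.starts_ms.size

    @property
    def all_lags(self) -> np.ndarray:
        return np.unique(np.concatenate(self.lag_sets))


@dataclass
class Trial:
    """One 60-s aligned bundle of preprocessed EEG and envelope(s)."""

    eeg: np.ndarray  # channels x samples at the working rate
    env_att: Envelope
    env_ign: Envelope | None
    subject: int
    block: str = ""
    condition: str = ""
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.eeg = np.atleast_2d(np.asarray(self.eeg, dtype=float))
        if self.eeg.shape[1] != len(self.env_att):
            raise ValueError("EEG and attended envelope lengths differ")
        if self.env_ign is not None and len(self.env_ign) != self.eeg.shape[1]:
            raise ValueError("EEG and ignored envelope lengths differ")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.env_att.fs


@dataclass
class DecoderModel:
    """Per-window ridge weights (channels*lags + intercept) at one lambda."""

    design: LagWindowDesign
    weights: list[np.ndarray]  # one (n_features + 1,) vector per window
    lam: float
    metadata: dict = field(default_factory=dict)


@dataclass
class TrackingCurve:
    """Per-trial reconstruction correlations over the lag windows."""

    r_att: np.ndarray
    r_ign: np.ndarray | None
    trial: Trial | None = None


@dataclass
class CrossValidationResult:
    curves: list[TrackingCurve]
    lam: float | dict[int, float]
    lambda_table: pd.DataFrame  # columns: lam, mean_r (held-out, attended)
    mode: str


def make_lag_design(
    width: float = 45.0,
    overlap: float = 30.0,
    start_bound: float = 500.0,
    fs: float = 64.0,
) -> LagWindowDesign:
    """Enumerate lag windows: every start on the hop grid strictly below
    ``start_bound`` ms; the defaults give 34 windows over 0-500 ms."""
    if not 0 < overlap < width:
        raise ValueError("need 0 < overlap < width")
    if start_bound <= 0:
        raise ValueError("start_bound must be positive")
    hop = width - overlap
    starts = np.arange(0.0, start_bound, hop)
    sample_ms = 1000.0 / fs
    max_lag = int(np.ceil((start_bound + width) / sample_ms)) + 1
    lags_ms = np.arange(max_lag + 1) * sample_ms
    lag_sets = []
    for s in starts:
        sel = np.flatnonzero((lags_ms >= s) & (lags_ms < s + width))
        lag_sets.append(sel.astype(np.intp))
    return LagWindowDesign(width, overlap, start_bound, fs, starts, lag_sets)


def lambda_grid(low_exp: int = -6, high_exp: int = 6, step_exp: int = 2) -> np.ndarray:
    """Logarithmic regularization grid 10^low .. 10^high (default: 7 values)."""
    if step_exp <= 0 or high_exp < low_exp:
        raise ValueError("need step_exp > 0 and high_exp >= low_exp")
    return 10.0 ** np.arange(low_exp, high_exp + 1, step_exp, dtype=float)


def build_design_matrix(eeg: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Time-lagged feature matrix (samples x channels*|lags|).

    Column ``(c, j)`` at row ``t`` holds ``eeg[c, t + lags[j]]``: in the
    backward model the envelope sample at time ``t`` is reconstructed
    from the EEG that *follows* it, because the neural response lags the
    stimulus (a positive lag is a post-onset latency).  Rows whose lag
    runs off the end of the trial are zero-padded.  Column order is
    channel-major, lag-minor.
    """
    eeg = np.atleast_2d(eeg)
    n_ch, n = eeg.shape
    lags = np.asarray(lags, dtype=np.intp)
    L = lags.size
    if L > 1 and np.all(np.diff(lags) == 1) and lags[0] >= 0:
        # contiguous lag range: one zero-padded sliding-window view + copy
        from numpy.lib.stride_tricks import sliding_window_view

        pad = np.zeros((n_ch, n + int(lags[-1])))
        pad[:, :n] = eeg
        V = sliding_window_view(pad[:, int(lags[0]) :], L, axis=1)[:, :n, :]
        return np.ascontiguousarray(V.transpose(1, 0, 2)).reshape(n, n_ch * L)
    X = np.zeros((n, n_ch * L))
    for j, lag in enumerate(lags):
        if lag < n:
            X[: n - lag, j::L] = eeg[:, lag:].T
    return X


def _add_intercept(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, np.ones((X.shape[0], 1))])


def _ridge_from_gram(G: np.ndarray, b: np.ndarray, lam: float) -> np.ndarray:
    """Solve the penalized normal equations; the last column is the
    unpenalized intercept."""
    p = G.shape[0]
    diag = np.diagonal(G)[:-1]
    m = diag.mean() if p > 1 else 1.0
    A = G.copy()
    idx = np.arange(p - 1)
    A[idx, idx] += lam * m
    try:
        c = cho_factor(A, lower=True, check_finite=False)
        return cho_solve(c, b, check_finite=False)
    except np.linalg.LinAlgError as err:
        if lam == 0:
            raise np.linalg.LinAlgError(
                "normal equations are rank deficient at lambda = 0"
            ) from err
        return np.linalg.lstsq(A, b, rcond=None)[0]


def train_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge weights with unpenalized intercept.

    ``w = (X'X + lam * m * I)^-1 X'y`` with ``m`` the mean diagonal of
    ``X'X`` (scale-invariant regularization).  The returned vector has the
    intercept as its last entry.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    Xi = _add_intercept(X)
    return _ridge_from_gram(Xi.T @ Xi, Xi.T @ y, lam)


def _pearson_cols(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r of each column of A against b (degenerate columns -> 0)."""
    Ac = A - A.mean(axis=0)
    bc = b - b.mean()
    den = np.sqrt((Ac * Ac).sum(axis=0) * (bc @ bc))
    num = Ac.T @ bc
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a @ a) * (b @ b))
    if den == 0:
        return 0.0
    return float(np.clip((a @ b) / den, -1.0, 1.0))


def reconstruct_and_correlate(model: DecoderModel, trial: Trial) -> TrackingCurve:
    """Reconstruct the envelope per lag window and correlate with truth."""
    design = model.design
    r_att = np.empty(design.n_windows)
    r_ign = np.empty(design.n_windows) if trial.env_ign is not None else None
    for w, lags in enumerate(design.lag_sets):
        X = _add_intercept(build_design_matrix(trial.eeg, lags))
        yhat = X @ model.weights[w]
        r_att[w] = _pearson(yhat, trial.env_att.samples)
        if r_ign is not None:
            r_ign[w] = _pearson(yhat, trial.env_ign.samples)
    return TrackingCurve(r_att, r_ign, trial)


def partition_segments(recordings, segment: float = 60.0) -> list[Trial]:
    """Cut preprocessed recordings into non-overlapping fixed-length trials.

    ``recordings`` is an iterable of objects with ``eeg`` (channels x
    samples at the envelope rate or an EEGRecording), ``env_att``,
    ``env_ign`` (optional), ``subject``, ``block``, ``condition``.
    Trailing remainders shorter than ``segment`` are dropped.
    """
    trials: list[Trial] = []
    for rec in recordings:
        eeg = rec.eeg
        data = np.atleast_2d(eeg) if isinstance(eeg, np.ndarray) else eeg.data
        fs = rec.env_att.fs
        n_seg = int(round(segment * fs))
        n = min(data.shape[1], len(rec.env_att))
        env_ign = getattr(rec, "env_ign", None)
        if env_ign is not None:
            n = min(n, len(env_ign))
        for k in range(n // n_seg):
            sl = slice(k * n_seg, (k + 1) * n_seg)
            trials.append(
                Trial(
                    eeg=data[:, sl],
                    env_att=Envelope(rec.env_att.samples[sl], fs, rec.env_att.source_id),
                    env_ign=None
                    if env_ign is None
                    else Envelope(env_ign.samples[sl], fs, env_ign.source_id),
                    subject=getattr(rec, "subject", 0),
                    block=getattr(rec, "block", ""),
                    condition=getattr(rec, "condition", ""),
                    start_time=k * segment,
                )
            )
    return trials


def _normalized_target(env: Envelope) -> np.ndarray:
    y = env.samples.astype(float)
    sd = y.std()
    return y / sd if sd > 0 else y.copy()


def _window_columns(design: LagWindowDesign, n_ch: int) -> list[np.ndarray]:
    """Column indices of each lag window inside the full lagged matrix
    built over ``design.all_lags`` (channel-major, lag-minor layout)."""
    all_lags = design.all_lags
    pos = {lag: i for i, lag in enumerate(all_lags)}
    L = all_lags.size
    col_idx = []
    for lags in design.lag_sets:
        cols = np.concatenate(
            [c * L + np.array([pos[l] for l in lags], dtype=np.intp) for c in range(n_ch)]
        )
        col_idx.append(cols)
    return col_idx


def _trial_window_grams(trial: Trial, design: LagWindowDesign, col_idx):
    """Per-window intercept-augmented Gram matrices and cross-products.

    The full lagged matrix over all unique lags is built once, its Gram
    computed with one symmetric rank-k update, and the per-window Grams
    extracted as submatrices; only those small Grams are kept, so leave-
    one-trial-out training reduces to subtracting them from pooled totals.
    """
    from scipy.linalg import blas

    X_full = build_design_matrix(trial.eeg, design.all_lags)
    y_att = _normalized_target(trial.env_att)
    G_all = blas.dsyrk(1.0, X_full, trans=1, lower=0)
    G_all = G_all + np.triu(G_all, 1).T
    b_all = X_full.T @ y_att
    s_all = X_full.sum(axis=0)
    y_sum = y_att.sum()
    n = X_full.shape[0]
    grams, b_att = [], []
    for cols in col_idx:
        p = cols.size
        G = np.empty((p + 1, p + 1))
        G[:p, :p] = G_all[np.ix_(cols, cols)]
        G[:p, p] = s_all[cols]
        G[p, :p] = s_all[cols]
        G[p, p] = n
        grams.append(G)
        bv = np.empty(p + 1)
        bv[:p] = b_all[cols]
        bv[p] = y_sum
        b_att.append(bv)
    return grams, b_att


def _cv_group(
    trials: list[Trial], design: LagWindowDesign, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Leave-one-trial-out CV of one pooled trial group.

    Returns ``(r_att, r_ign, lam)`` with ``r_att``/``r_ign`` of shape
    (n_trials, n_windows, n_lambdas): held-out correlations of models
    trained on all other trials at each grid lambda.  ``lam`` is the grid
    value maximizing the mean held-out attended correlation (ties go to
    the smaller lambda).
    """
    n_t, n_w, n_l = len(trials), design.n_windows, grid.size
    col_idx = _window_columns(design, trials[0].eeg.shape[0])
    stats = [_trial_window_grams(t, design, col_idx) for t in trials]
    G_tot = [sum(s[0][w] for s in stats) for w in range(n_w)]
    b_tot = [sum(s[1][w] for s in stats) for w in range(n_w)]

    r_att = np.zeros((n_t, n_w, n_l))
    has_ign = all(t.env_ign is not None for t in trials)
    r_ign = np.zeros((n_t, n_w, n_l)) if has_ign else None

    for i, (grams, b_att) in enumerate(stats):
        trial = trials[i]
        X_full = build_design_matrix(trial.eeg, design.all_lags)
        y_att = _normalized_target(trial.env_att)
        y_ign = (
            _normalized_target(trial.env_ign) if trial.env_ign is not None else None
        )
        for w in range(n_w):
            G_train = G_tot[w] - grams[w]
            b_train = b_tot[w] - b_att[w]
            Xw = X_full[:, col_idx[w]]
            W = np.column_stack(
                [_ridge_from_gram(G_train, b_train, lam) for lam in grid]
            )
            yhat = Xw @ W[:-1] + W[-1]  # samples x lambdas
            r_att[i, w] = _pearson_cols(yhat, y_att)
            if r_ign is not None:
                r_ign[i, w] = _pearson_cols(yhat, y_ign)

    mean_r = r_att.mean(axis=(0, 1))
    best = int(np.flatnonzero(mean_r == mean_r.max())[0])  # grid ascending: first = smallest
    return r_att, r_ign, float(grid[best])


def cross_validate(
    trials: list[Trial],
    design: LagWindowDesign,
    grid: np.ndarray | None = None,
    mode: str = "subject_independent",
    k: int = 9,
) -> CrossValidationResult:
    """Cross-validated lambda selection and held-out tracking curves.

    Stage 1 selects the shared lambda maximizing the mean held-out
    attended correlation over all folds and windows; stage 2 reports, for
    every trial, the tracking curve of the model trained on the remaining
    folds at the selected lambda.  Folds are single trials
    (``subject_independent`` pools all subjects; ``subject_dependent``
    runs the scheme within each subject with its own lambda).
    """
    grid = lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    if mode not in ("subject_independent", "subject_dependent"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(trials) < 2:
        raise ValueError("need at least 2 trials (folds) for cross-validation")

    if mode == "subject_independent":
        r_att, r_ign, lam = _cv_group(trials, design, grid)
        j = int(np.flatnonzero(grid == lam)[0])
        curves = [
            TrackingCurve(r_att[i, :, j], None if r_ign is None else r_ign[i, :, j], t)
            for i, t in enumerate(trials)
        ]
        table = pd.DataFrame({"lam": grid, "mean_r": r_att.mean(axis=(0, 1))})
        return CrossValidationResult(curves, lam, table, mode)

    subjects = sorted({t.subject for t in trials})
    curves: list[TrackingCurve | None] = [None] * len(trials)
    lams: dict[int, float] = {}
    tables = []
    for s in subjects:
        idx = [i for i, t in enumerate(trials) if t.subject == s]
        if len(idx) < 2:
            raise ValueError(f"subject {s} has fewer trials than folds")
        sub = [trials[i] for i in idx]
        r_att, r_ign, lam = _cv_group(sub, design, grid)
        j = int(np.flatnonzero(grid == lam)[0])
        lams[s] = lam
        for local, i in enumerate(idx):
            curves[i] = TrackingCurve(
                r_att[local, :, j],
                None if r_ign is None else r_ign[local, :, j],
                trials[i],
            )
        tables.append(
            pd.DataFrame({"subject": s, "lam": grid, "mean_r": r_att.mean(axis=(0, 1))})
        )
    table = pd.concat(tables, ignore_index=True)
    return CrossValidationResult(curves, lams, table, mode)


def train_decoder(
    trials: list[Trial], design: LagWindowDesign, lam: float, metadata: dict | None = None
) -> DecoderModel:
    """Fit one per-window ridge decoder on a pooled trial set."""
    col_idx = _window_columns(design, trials[0].eeg.shape[0])
    stats = [_trial_window_grams(t, design, col_idx) for t in trials]
    weights = []
    for w in range(design.n_windows):
        G = sum(s[0][w] for s in stats)
        b = sum(s[1][w] for s in stats)
        weights.append(_ridge_from_gram(G, b, lam))
    return DecoderModel(design, weights, lam, metadata or {})
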