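"""Cross-validated decoding of kinematics and task variables from
population activity.

Joint angle/velocity time series are decoded with ridge regression from
PCA-reduced, Gaussian-smoothed deconvolved events (rank = 90% of the
included neuron count, 10-fold x 5-repeat trial-level cross-validation,
variance explained per joint on held-out trials).  Target identity is
decoded per 10 ms bin with an L2 logistic classifier; single-trial
projections onto the classifier axis yield threshold-crossing latencies,
and training the classifier in separate 100 ms epochs produces a temporal
generalization matrix.  Reaction time is decoded by classifying pre- vs
post-lift activity and reading out when each held-out trial's projection
crosses threshold.

Trials, never time points, are the unit of cross-validation splitting:
time samples within a trial are strongly correlated, and splitting them
across train and test would leak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .preprocess import gaussian_smooth

#: inverse L2 regularization of the logistic classifiers.  C = 1 matches the
#: conventional default of linear-classifier routines (penalty weight 1/n on
#: the summed loss); with far more ROIs than trials a weaker penalty lets the
#: fit drift to a max-margin direction dominated by single-trial noise, which
#: destroys the projection-trace signal-to-noise the latency analyses rely on.
LOGISTIC_C = 1.0


# ---------------------------------------------------------------------------
# configuration / results
# ---------------------------------------------------------------------------


@dataclass
class RidgeConfig:
    """Settings for joint kinematic decoding."""

    ridge_lambda: float | str = "auto"  # >= 0 or "auto" (GCV on a log grid)
    pca_fraction: float = 0.9  # PCA rank = floor(pca_fraction * n_neurons)
    n_folds: int = 10
    n_repeats: int = 5
    window_ms: tuple = (-100.0, 400.0)
    neural_smoothing_sd_ms: float = 35.0
    lags: str | None = None  # None | "causal" (-100..0) | "acausal" (-100..+100)
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if isinstance(self.ridge_lambda, (int, float)) and self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be nonnegative")
        if self.lags not in (None, "causal", "acausal"):
            raise ValueError("lags must be None, 'causal' or 'acausal'")


@dataclass
class DecodingResult:
    """Per-joint, per-fold variance explained and bagged reconstructions."""

    variance_explained: np.ndarray  # (n_joints, n_folds_total)
    folds: list  # (repeat, fold, test trial indices)
    bagged_predictions: np.ndarray  # (n_trials, n_bins, n_joints)
    ridge_lambdas: np.ndarray

    @property
    def median_ve(self) -> np.ndarray:
        return np.median(self.variance_explained, axis=1)


@dataclass
class ClassifierResult:
    """Binary target decoding along a single population axis."""

    weights: np.ndarray  # (n_folds, n_features)
    projections: np.ndarray  # (n_trials, n_bins), held-out, normalized
    thresholds: dict  # trial type -> threshold on the normalized projection
    crossing_times: np.ndarray  # (n_trials,) s, NaN when undefined
    accuracy_per_bin: np.ndarray  # (n_bins,)
    bin_times_ms: np.ndarray
    targets: np.ndarray
    generalization: np.ndarray | None = None  # (n_epochs, n_bins)
    flags: dict = field(default_factory=dict)

    @property
    def overall_accuracy(self) -> float:
        """Median accuracy over time bins (per-timepoint convention)."""
        return float(np.median(self.accuracy_per_bin))


# ---------------------------------------------------------------------------
# ROI selection
# ---------------------------------------------------------------------------


def select_rois(p_values: np.ndarray, rule: str, n_top: int = 100,
                p_threshold: float = 0.01) -> np.ndarray:
    """Choose ROIs for decoding from their ZETA p-values.

    ``p_values`` is (n_rois, n_tests) over locking-event x target-side
    combinations.  rule='top' sorts ROIs ascending by their minimum p and
    keeps the ``n_top`` smallest (all, with a warning, if fewer exist);
    rule='threshold' keeps every ROI with any p below ``p_threshold``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    pmin = np.nanmin(p, axis=1)
    if rule == "top":
        order = np.argsort(pmin, kind="stable")
        if pmin.size < n_top:
            warnings.warn(f"only {pmin.size} ROIs available (< {n_top}); using all")
            return order
        return np.sort(order[:n_top])
    if rule == "threshold":
        sel = np.flatnonzero(np.any(p < p_threshold, axis=1))
        if sel.size == 0:
            raise ValueError("no ROI passes the modulation threshold")
        return sel
    raise ValueError("rule must be 'top' or 'threshold'")


# ---------------------------------------------------------------------------
# ridge regression
# ---------------------------------------------------------------------------


def _gcv_lambda(u, s, y, grid):
    """Generalized cross-validation score of ridge on SVD factors."""
    n = y.shape[0]
    uty = u.T @ y
    best, best_score = None, np.inf
    for lam in grid:
        shrink = s**2 / (s**2 + lam)
        fitted = u @ (shrink[:, None] * uty)
        rss = np.sum((y - fitted) ** 2)
        df = np.sum(shrink)
        denom = (1.0 - df / n) ** 2
        score = (rss / n) / max(denom, 1e-12)
        if score < best_score:
            best, best_score = lam, score
    return best


def fit_ridge(x: np.ndarray, y: np.ndarray, lam: float | str = "auto",
              n_grid: int = 20):
    """Ridge regression ``min ||Y - XW||^2 + lam ||W||^2``.

    Columns of X and Y are centered on the training data; returns
    (W, x_mean, y_mean, lam).  ``lam='auto'`` selects the penalty by
    generalized (leave-one-out) cross-validation on a ``n_grid``-point
    log grid spanning the squared singular-value range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression inputs")
    if y.ndim == 1:
        y = y[:, None]
    xm, ym = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - xm, y - ym
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    if lam == "auto":
        smax2 = max(s[0] ** 2, 1e-30)
        grid = smax2 * np.logspace(-8.0, 1.0, n_grid)
        lam = _gcv_lambda(u, s, yc, grid)
    lam = float(lam)
    if lam > 0:
        shrink = s / (s**2 + lam)
    else:
        shrink = np.divide(1.0, s, out=np.zeros_like(s), where=s > 1e-12 * max(s[0], 1e-300))
    w = vt.T @ (shrink[:, None] * (u.T @ yc))
    return w, xm, ym, lam


def ridge_predict(x, w, xm, ym):
    return (np.asarray(x) - xm) @ w + ym


# ---------------------------------------------------------------------------
# joint kinematic decoding
# ---------------------------------------------------------------------------


def _lag_augment(neural: np.ndarray, lags: str | None, bin_ms: float) -> np.ndarray:
    """Append time-shifted copies of the neural features within each trial.

    'causal' uses neural activity from -100..0 ms relative to the decoded
    sample; 'acausal' from -100..+100 ms, at 10 ms steps.  Shifted-in
    samples at trial edges are zero.
    """
    if lags is None:
        return neural
    steps = int(round(100.0 / bin_ms))
    shifts = range(-steps, 1) if lags == "causal" else range(-steps, steps + 1)
    parts = []
    for k in shifts:
        shifted = np.roll(neural, -k, axis=1)
        if k < 0:
            shifted[:, :(-k), :] = 0.0
        elif k > 0:
            shifted[:, -k:, :] = 0.0
        parts.append(shifted)
    return np.concatenate(parts, axis=2)


def decode_joint_timeseries(
    neural: np.ndarray,
    kinematics: np.ndarray,
    config: RidgeConfig | None = None,
) -> DecodingResult:
    """Decode joint angle (or velocity) time series from population activity.

    Parameters
    ----------
    neural : (n_trials, n_bins, n_rois)
        Event-locked binned events (unsmoothed; smoothing per config).
    kinematics : (n_trials, n_bins, n_joints)
        Aligned kinematic variables on the same 10 ms grid.

    Variance explained is computed per joint on held-out trials, pooled
    over (trial, time): ``VE = 1 - SSE / SStot`` with SStot about the
    test-set mean.  Bagged per-trial reconstructions average the
    ``n_repeats`` folds in which the trial was held out.
    """
    config = config or RidgeConfig()
    neural = np.asarray(neural, dtype=float)
    kin = np.asarray(kinematics, dtype=float)
    n_tr, n_bins, n_rois = neural.shape
    if kin.shape[:2] != (n_tr, n_bins):
        raise ValueError("neural and kinematic grids must align")
    if n_tr < config.n_folds:
        raise ValueError("fewer trials than folds")
    n_joints = kin.shape[2]

    sm = gaussian_smooth(neural, config.neural_smoothing_sd_ms, axis=1)
    sm = _lag_augment(sm, config.lags, 10.0)
    rank = int(np.floor(config.pca_fraction * n_rois))
    rank = max(1, min(rank, sm.shape[2]))

    rng = np.random.default_rng(config.seed)
    n_total = config.n_folds * config.n_repeats
    ve = np.zeros((n_joints, n_total))
    lams = np.zeros(n_total)
    folds = []
    bagged = np.zeros((n_tr, n_bins, n_joints))
    fold_i = 0
    for rep in range(config.n_repeats):
        kf = KFold(n_splits=config.n_folds, shuffle=True,
                   random_state=int(rng.integers(2**31 - 1)))
        for tr_idx, te_idx in kf.split(np.arange(n_tr)):
            xtr = sm[tr_idx].reshape(-1, sm.shape[2])
            xte = sm[te_idx].reshape(-1, sm.shape[2])
            ytr = kin[tr_idx].reshape(-1, n_joints)
            yte = kin[te_idx].reshape(-1, n_joints)
            # PCA on the training samples only
            mu = xtr.mean(axis=0)
            _, _, vt = np.linalg.svd(xtr - mu, full_matrices=False)
            pcs = vt[:rank].T
            ztr, zte = (xtr - mu) @ pcs, (xte - mu) @ pcs
            w, xm, ym, lam = fit_ridge(ztr, ytr, config.ridge_lambda)
            pred = ridge_predict(zte, w, xm, ym)
            sse = np.sum((yte - pred) ** 2, axis=0)
            sstot = np.sum((yte - yte.mean(axis=0)) ** 2, axis=0)
            ve[:, fold_i] = 1.0 - sse / np.where(sstot > 0, sstot, np.nan)
            lams[fold_i] = lam
            folds.append((rep, fold_i % config.n_folds, te_idx.copy()))
            bagged[te_idx] += pred.reshape(len(te_idx), n_bins, n_joints)
            fold_i += 1
    bagged /= config.n_repeats
    return DecodingResult(variance_explained=ve, folds=folds,
                          bagged_predictions=bagged, ridge_lambdas=lams)


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------


def residualize(y: np.ndarray, z: np.ndarray, intercept: bool = True) -> np.ndarray:
    """Least-squares residuals of ``y`` after regressing out ``z``.

    A rank-deficient regressor matrix falls back to the pseudo-inverse
    with a warning.  Residualization is a projection (idempotent).
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    shape = y.shape
    y2 = y.reshape(-1, shape[-1]) if y.ndim > 2 else y
    z2 = z.reshape(-1, z.shape[-1]) if z.ndim > 2 else z
    if intercept:
        z2 = np.column_stack([np.ones(z2.shape[0]), z2])
    coef, _, rank, _ = np.linalg.lstsq(z2, y2, rcond=None)
    if rank < z2.shape[1]:
        warnings.warn("rank-deficient regressors; using pseudo-inverse")
    return (y2 - z2 @ coef).reshape(shape)


def residualize_condition_means(y: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Subtract the per-target mean trace from trial x time x feature data."""
    y = np.asarray(y, dtype=float).copy()
    targets = np.asarray(targets)
    for side in np.unique(targets):
        m = targets == side
        y[m] -= y[m].mean(axis=0, keepdims=True)
    return y


# ---------------------------------------------------------------------------
# target classification
# ---------------------------------------------------------------------------


def _fit_logistic(x, y, seed=0):
    clf = LogisticRegression(
        C=LOGISTIC_C, solver="lbfgs", max_iter=2000, random_state=seed,
    )
    clf.fit(x, y)
    return clf


def classify_target(
    neural: np.ndarray,
    targets: np.ndarray,
    bin_times_ms: np.ndarray,
    train_mask_ms: tuple | None = (0.0, None),
    n_folds: int = 5,
    smoothing_sd_ms: float = 35.0,
    seed: int = 0,
) -> ClassifierResult:
    """Decode target identity per 10 ms bin with a logistic classifier.

    The classifier is trained on all post-cue time points of the training
    trials (trial-level stratified 80/20 splits) and applied to every time
    point of the held-out trials.  Held-out projections are normalized by
    the 90th-percentile value within each trial type, then thresholded
    (midpoint of the across-trial median trace's extrema, per type) to
    produce single-trial crossing latencies.
    """
    neural = gaussian_smooth(np.asarray(neural, dtype=float), smoothing_sd_ms, axis=1)
    targets = np.asarray(targets)
    labels = np.unique(targets)
    if labels.size != 2:
        raise ValueError("target classification needs exactly two classes")
    y = (targets == labels[1]).astype(int)
    n_tr, n_bins, n_feat = neural.shape
    bin_times_ms = np.asarray(bin_times_ms, dtype=float)

    if train_mask_ms is None:
        train_bins = np.arange(n_bins)
    else:
        lo = -np.inf if train_mask_ms[0] is None else train_mask_ms[0]
        hi = np.inf if train_mask_ms[1] is None else train_mask_ms[1]
        train_bins = np.flatnonzero((bin_times_ms >= lo) & (bin_times_ms <= hi))

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    raw_proj = np.zeros((n_tr, n_bins))
    correct = np.zeros((n_tr, n_bins), dtype=bool)
    weights = []
    for tr_idx, te_idx in skf.split(np.arange(n_tr), y):
        xtr = neural[tr_idx][:, train_bins, :].reshape(-1, n_feat)
        ytr = np.repeat(y[tr_idx], train_bins.size)
        clf = _fit_logistic(xtr, ytr, seed)
        weights.append(np.concatenate([clf.coef_[0], clf.intercept_]))
        xte = neural[te_idx].reshape(-1, n_feat)
        proj = clf.decision_function(xte).reshape(len(te_idx), n_bins)
        raw_proj[te_idx] = proj
        pred = (proj > 0).astype(int)
        correct[te_idx] = pred == y[te_idx, None]
    accuracy = correct.mean(axis=0)

    # sign the projection so each trial's own class is positive, then
    # normalize by the 90th percentile within trial type
    signed = np.where(y[:, None] == 1, raw_proj, -raw_proj)
    proj_norm = np.zeros_like(signed)
    thresholds, crossing = {}, np.full(n_tr, np.nan)
    flags = {}
    for li, lab in enumerate(labels):
        m = y == li
        q = np.percentile(signed[m], 90.0)
        if q <= 0:
            q = max(np.abs(signed[m]).max(), 1e-12)
            flags[str(lab)] = "nonpositive 90th percentile"
        proj_norm[m] = signed[m] / q
        ct, thr, degen = threshold_crossing_time(proj_norm[m], bin_times_ms)
        thresholds[str(lab)] = thr
        crossing[m] = ct
        if degen:
            flags[str(lab)] = "degenerate threshold"
    return ClassifierResult(
        weights=np.array(weights), projections=proj_norm, thresholds=thresholds,
        crossing_times=crossing, accuracy_per_bin=accuracy,
        bin_times_ms=bin_times_ms, targets=targets, flags=flags,
    )


def threshold_crossing_time(
    projections: np.ndarray,
    bin_times_ms: np.ndarray,
    min_sustained: int = 5,
):
    """Per-trial threshold-crossing times from projection traces.

    The threshold is the midpoint of the max and min of the across-trial
    median trace.  A trial's crossing is the leading edge of the first run
    of at least ``min_sustained`` consecutive supra-threshold bins,
    linearly interpolated between the bin below and the first bin above
    threshold; trials never sustaining a crossing are NaN.

    Returns (times_s, threshold, degenerate_flag).
    """
    p = np.atleast_2d(np.asarray(projections, dtype=float))
    t = np.asarray(bin_times_ms, dtype=float) / 1000.0
    med = np.median(p, axis=0)
    hi, lo = med.max(), med.min()
    if hi == lo:
        return np.full(p.shape[0], np.nan), float(hi), True
    thr = (hi + lo) / 2.0
    out = np.full(p.shape[0], np.nan)
    n_bins = p.shape[1]
    for i in range(p.shape[0]):
        above = p[i] > thr
        k = 0
        while k <= n_bins - min_sustained:
            if above[k:k + min_sustained].all():
                if k == 0:
                    out[i] = t[0]
                else:
                    frac = (thr - p[i, k - 1]) / (p[i, k] - p[i, k - 1])
                    out[i] = t[k - 1] + frac * (t[k] - t[k - 1])
                break
            k += 1
    return out, float(thr), False


def time_generalized_accuracy(
    neural: np.ndarray,
    targets: np.ndarray,
    bin_times_ms: np.ndarray,
    epoch_ms: float = 100.0,
    n_folds: int = 5,
    smoothing_sd_ms: float = 35.0,
    seed: int = 0,
) -> np.ndarray:
    """Temporal generalization matrix of target decoding.

    Training epochs are non-overlapping ``epoch_ms`` windows tiling the
    locked window (11 epochs for -100..+1000 ms); each epoch's classifier
    is tested on every 10 ms bin of the held-out trials.  Entry (e, b) is
    the mean held-out accuracy over stratified folds.
    """
    neural = gaussian_smooth(np.asarray(neural, dtype=float), smoothing_sd_ms, axis=1)
    targets = np.asarray(targets)
    labels = np.unique(targets)
    y = (targets == labels[1]).astype(int)
    n_tr, n_bins, n_feat = neural.shape
    bt = np.asarray(bin_times_ms, dtype=float)
    per_epoch = int(round(epoch_ms / 10.0))
    n_epochs = n_bins // per_epoch
    acc = np.zeros((n_epochs, n_bins))
    counts = np.zeros((n_epochs, n_bins))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr_idx, te_idx in skf.split(np.arange(n_tr), y):
        xte = neural[te_idx].reshape(-1, n_feat)
        for e in range(n_epochs):
            bins = np.arange(e * per_epoch, (e + 1) * per_epoch)
            xtr = neural[tr_idx][:, bins, :].reshape(-1, n_feat)
            ytr = np.repeat(y[tr_idx], bins.size)
            clf = _fit_logistic(xtr, ytr, seed)
            pred = clf.predict(xte).reshape(len(te_idx), n_bins)
            acc[e] += (pred == y[te_idx, None]).mean(axis=0)
            counts[e] += 1
    return acc / counts


def decode_reaction_time(
    neural_lift: np.ndarray,
    reaction_times: np.ndarray,
    targets: np.ndarray,
    bin_times_ms: np.ndarray,
    n_folds: int = 5,
    smoothing_sd_ms: float = 10.0,
    seed: int = 0,
):
    """Predict single-trial lift reaction times from population activity.

    A logistic classifier discriminates the pre-lift (-100..0 ms) from the
    post-lift (0..+100 ms) 100 ms bin of each training trial (stratified
    by target).  Held-out trials' lift-locked traces (10 ms bins, smoothed
    with a 10 ms-s.d. Gaussian) are projected onto the classifier axis;
    the projection's threshold crossing (midpoint of the across-trial
    median's extrema) gives a per-trial offset from true lift time, and
    predicted RT = true RT + offset.  Returns (predicted_rt, offsets, r)
    with r the Pearson correlation between predicted and true RT over
    trials with a defined crossing.
    """
    x = np.asarray(neural_lift, dtype=float)  # (trial, bin, roi), lift-locked
    rt = np.asarray(reaction_times, dtype=float)
    targets = np.asarray(targets)
    bt = np.asarray(bin_times_ms, dtype=float)
    n_tr, n_bins, n_feat = x.shape
    pre_bins = np.flatnonzero((bt > -100.0) & (bt < 0.0))
    post_bins = np.flatnonzero((bt > 0.0) & (bt < 100.0))
    pre = x[:, pre_bins, :].sum(axis=1)
    post = x[:, post_bins, :].sum(axis=1)

    sm = gaussian_smooth(x, smoothing_sd_ms, axis=1)
    y = (targets == np.unique(targets)[1]).astype(int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    proj = np.zeros((n_tr, n_bins))
    for tr_idx, te_idx in skf.split(np.arange(n_tr), y):
        xtr = np.vstack([pre[tr_idx], post[tr_idx]])
        ytr = np.concatenate([np.zeros(len(tr_idx)), np.ones(len(tr_idx))]).astype(int)
        clf = _fit_logistic(xtr, ytr, seed)
        proj[te_idx] = clf.decision_function(sm[te_idx].reshape(-1, n_feat)).reshape(
            len(te_idx), n_bins)

    offsets, _thr, degen = threshold_crossing_time(proj, bt)
    ok = np.isfinite(offsets)
    if degen or not ok.any():
        raise ValueError("no defined threshold crossings; RT undefined")
    predicted = rt + offsets
    r = float(np.corrcoef(predicted[ok], rt[ok])[0, 1])
    return predicted, offsets, r
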