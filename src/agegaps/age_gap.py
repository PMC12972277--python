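"""PLS age prediction, age-stratified cross-validation, bias correction,
and age-gap computation.

The model projects a block of predictors (cognitive test scores or
brain-pathology proxies) onto a small number of latent components chosen to
maximize covariance with chronological age (SIMPLS algorithm; for a
univariate response NIPALS gives the same fit).  Out-of-fold predictions
from ten-fold age-stratified cross-validation are bias-corrected for the
regression-to-the-mean artifact — predicted age overestimates the young and
underestimates the old — and the corrected prediction minus chronological
age is the subject's age gap: negative values mean younger than expected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AgeGapResult",
    "BiasCorrection",
    "FoldAssignment",
    "PLSModel",
    "PredictionMetrics",
    "apply_bias_correction",
    "compute_gap",
    "crossval_age_prediction",
    "explained_variance_in_y",
    "fit_bias_correction",
    "fit_pls",
    "pls_predict",
    "prediction_metrics",
    "stratified_age_folds",
    "suggest_components",
]


# ---------------------------------------------------------------------------
# SIMPLS
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted univariate-response SIMPLS regression.

    ``coefficients`` act on centered/scaled predictors; predictions are
    ``y_center + ((X - x_center) / x_scale) @ coefficients``.
    """

    n_components: int
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    x_weights: np.ndarray     # p x A (apply to centered/scaled X for scores)
    x_loadings: np.ndarray    # p x A
    y_loadings: np.ndarray    # A
    coefficients: np.ndarray  # p
    pct_var_y: np.ndarray     # per-component % of response variance

    @property
    def n_predictors(self) -> int:
        return self.x_center.size


def fit_pls(
    X: np.ndarray, y: np.ndarray, n_components: int, scale: bool = True
) -> PLSModel:
    """Fit SIMPLS with a univariate response.

    Predictors are centered (and by default scaled to unit sample SD)
    internally; successive score vectors are mutually orthogonal.

    Raises
    ------
    ValueError
        If ``n_components`` exceeds the achievable rank of the centered
        predictor matrix.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n <= n_components:
        raise ValueError("need n > n_components")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("fit_pls requires complete data (impute upstream)")
    x_center = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(p)
    if np.any(x_scale == 0):
        bad = np.flatnonzero(np.asarray(x_scale) == 0)
        raise ValueError(f"constant predictor columns: {bad.tolist()}")
    X0 = (X - x_center) / x_scale
    y_center = float(y.mean())
    y0 = y - y_center
    rank = np.linalg.matrix_rank(X0)
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds achievable rank {rank}"
        )

    R = np.zeros((p, n_components))   # weights
    P = np.zeros((p, n_components))   # x loadings
    Q = np.zeros(n_components)        # y loadings
    T = np.zeros((n, n_components))   # scores (orthonormal)
    V = np.zeros((p, n_components))   # orthonormal basis of x-loading space
    s = X0.T @ y0
    for a in range(n_components):
        r = s.copy()
        t = X0 @ r
        t -= t.mean()
        normt = np.linalg.norm(t)
        if normt < 1e-12:
            raise ValueError(f"component {a + 1} degenerate (no covariance left)")
        t /= normt
        r /= normt
        p_a = X0.T @ t
        q_a = float(y0 @ t)
        v = p_a.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_a)
        v /= np.linalg.norm(v)
        s -= v * (v @ s)
        R[:, a], P[:, a], Q[a], T[:, a], V[:, a] = r, p_a, q_a, t, v

    coefficients = R @ Q
    ss_y = float(y0 @ y0)
    pct_var_y = 100.0 * Q**2 / ss_y if ss_y > 0 else np.zeros(n_components)
    return PLSModel(
        n_components=n_components,
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        x_weights=R,
        x_loadings=P,
        y_loadings=Q,
        coefficients=coefficients,
        pct_var_y=pct_var_y,
    )


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict ages for new predictor rows."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_predictors:
        raise ValueError(
            f"X has {X.shape[1]} columns; model expects {model.n_predictors}"
        )
    X0 = (X - model.x_center) / model.x_scale
    return model.y_center + X0 @ model.coefficients


def explained_variance_in_y(model: PLSModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-component and cumulative percentage of response variance
    explained by the fitted components."""
    per = model.pct_var_y
    return per, np.cumsum(per)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Age-stratified fold labels: subjects sorted by age are dealt into
    consecutive blocks of K, and fold labels are permuted within each
    block, so every fold spans the entire age range."""

    folds: np.ndarray     # per-subject fold index, 1..K
    n_folds: int
    seed: int
    strategy: str = "age_stratified_block"


def stratified_age_folds(age: np.ndarray, n_folds: int, seed: int) -> FoldAssignment:
    age = np.asarray(age, float)
    n = age.size
    if n < 2 * n_folds:
        raise ValueError("need n >= 2 * n_folds")
    order = np.argsort(age, kind="stable")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    labels = np.arange(1, n_folds + 1)
    for start in range(0, n, n_folds):
        block = order[start : start + n_folds]
        folds[block] = rng.permutation(labels)[: block.size]
    return FoldAssignment(folds=folds, n_folds=n_folds, seed=seed)


def crossval_age_prediction(
    X: np.ndarray,
    age: np.ndarray,
    n_components: int,
    n_folds: int = 10,
    seed: int = 0,
    scale: bool = True,
) -> tuple[np.ndarray, FoldAssignment, dict]:
    """Out-of-fold age predictions from K-fold age-stratified CV.

    Each subject is predicted exactly once, by a model never trained on it.
    Also returns per-fold cumulative %-variance-in-age summaries (training
    folds), mirroring how PLS fit quality is usually reported.
    """
    X = np.asarray(X, float)
    age = np.asarray(age, float)
    assignment = stratified_age_folds(age, n_folds, seed)
    raw = np.full(age.shape, np.nan)
    cum_pct = []
    for k in range(1, n_folds + 1):
        held = assignment.folds == k
        model = fit_pls(X[~held], age[~held], n_components, scale=scale)
        raw[held] = pls_predict(model, X[held])
        cum_pct.append(float(np.cumsum(model.pct_var_y)[-1]))
    info = {
        "cum_pct_var_y_mean": float(np.mean(cum_pct)),
        "cum_pct_var_y_sd": float(np.std(cum_pct, ddof=1)),
        "cum_pct_var_y_by_fold": cum_pct,
    }
    return raw, assignment, info


# ---------------------------------------------------------------------------
# bias correction and gaps
# ---------------------------------------------------------------------------

@dataclass
class BiasCorrection:
    """Linear age-bias model: predicted = alpha * age + beta, least squares
    on pooled out-of-fold predictions."""

    alpha: float
    beta: float
    fit_sample: str = "pooled_cv"
    variant: str = "offset"


def fit_bias_correction(
    raw_predictions: np.ndarray, age: np.ndarray, variant: str = "offset"
) -> BiasCorrection:
    pred = np.asarray(raw_predictions, float)
    age = np.asarray(age, float)
    ac = age - age.mean()
    denom = float(ac @ ac)
    if denom < 1e-12:
        raise ValueError("zero age variance; bias line undefined")
    alpha = float(ac @ (pred - pred.mean())) / denom
    beta = float(pred.mean() - alpha * age.mean())
    return BiasCorrection(alpha=alpha, beta=beta, variant=variant)


def apply_bias_correction(
    raw_predictions: np.ndarray, age: np.ndarray, bc: BiasCorrection
) -> np.ndarray:
    """Correct raw predicted ages.

    ``offset`` (default): ``corrected = raw + (age - (alpha*age + beta))``,
    an additive removal of the fitted bias at each subject's age.
    ``rescale``: ``corrected = (raw - beta) / alpha``.
    """
    pred = np.asarray(raw_predictions, float)
    age = np.asarray(age, float)
    if bc.variant == "offset":
        return pred + (age - (bc.alpha * age + bc.beta))
    if bc.variant == "rescale":
        if abs(bc.alpha) < 1e-8:
            raise ValueError("rescale variant undefined for alpha ~ 0")
        return (pred - bc.beta) / bc.alpha
    raise ValueError(f"unknown variant {bc.variant!r}")


def compute_gap(corrected: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Gap = corrected predicted age - chronological age (years);
    negative = younger than expected."""
    return np.asarray(corrected, float) - np.asarray(age, float)


@dataclass
class AgeGapResult:
    """Per-subject age-gap estimates for one model (cognitive or brain)."""

    raw_predicted_age: np.ndarray
    corrected_predicted_age: np.ndarray
    gap: np.ndarray
    fold: np.ndarray
    bias: BiasCorrection


def estimate_age_gap(
    X: np.ndarray,
    age: np.ndarray,
    n_components: int,
    n_folds: int = 10,
    seed: int = 0,
    variant: str = "offset",
) -> tuple[AgeGapResult, dict]:
    """Full estimation: CV predictions, pooled bias correction, gaps."""
    raw, assignment, info = crossval_age_prediction(
        X, age, n_components, n_folds=n_folds, seed=seed
    )
    bc = fit_bias_correction(raw, age, variant=variant)
    corrected = apply_bias_correction(raw, age, bc)
    gap = compute_gap(corrected, age)
    return (
        AgeGapResult(raw, corrected, gap, assignment.folds, bc),
        info,
    )


# ---------------------------------------------------------------------------
# metrics and component choice
# ---------------------------------------------------------------------------

@dataclass
class PredictionMetrics:
    pearson_r: float
    r_squared: float
    mae: float
    mae_sd: float
    mse: float


def prediction_metrics(predictions: np.ndarray, age: np.ndarray) -> PredictionMetrics:
    """Pearson r, correlation R^2, MAE (with SD of absolute errors), MSE."""
    pred = np.asarray(predictions, float)
    age = np.asarray(age, float)
    if pred.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.std(pred) == 0 or np.std(age) == 0:
        raise ValueError("zero variance; correlation undefined")
    r = float(np.corrcoef(pred, age)[0, 1])
    err = np.abs(pred - age)
    return PredictionMetrics(
        pearson_r=r,
        r_squared=r**2,
        mae=float(err.mean()),
        mae_sd=float(err.std(ddof=1)),
        mse=float(((pred - age) ** 2).mean()),
    )


def suggest_components(
    cv_metric_by_k: dict[int, float] | list[float], threshold: float = 5.0
) -> int:
    """Elbow rule on a cumulative-explained-variance (or similar) curve.

    Returns the component count after which the marginal improvement drops
    below ``threshold`` (same units as the metric).  Advisory only — the
    pipeline configuration may override it.
    """
    if isinstance(cv_metric_by_k, dict):
        ks = sorted(cv_metric_by_k)
        vals = [cv_metric_by_k[k] for k in ks]
    else:
        vals = list(cv_metric_by_k)
        ks = list(range(1, len(vals) + 1))
    if not vals:
        raise ValueError("empty metric curve")
    if len(vals) == 1:
        return ks[0]
    for i in range(1, len(vals)):
        if vals[i] - vals[i - 1] < threshold:
            return ks[i - 1]
    return ks[-1]
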