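"""Preprocessing: eligibility screening, normalizing transforms, direction
and covariate adjustment, outlier fencing, and imputation.

The operations here are pure — input arrays/tables are never mutated — and
every modification a pipeline makes is logged in a :class:`PreprocessReport`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "EligibilityDecision",
    "PreprocessReport",
    "TransformSpec",
    "adjust_for_ticv",
    "apply_transform",
    "fit_boxcox_lambda",
    "fit_transform_spec",
    "fit_zscore",
    "flag_extreme_outliers",
    "impute_cognitive_scores",
    "invert_direction",
    "iterative_impute",
    "normality_statistic",
    "residualize_age_sex",
    "screen_eligibility",
    "select_normalizing_transform",
]

TRANSFORM_KINDS = (
    "identity",
    "log_shift",
    "sqrt_shift",
    "boxcox",
    "rank_inverse_normal",
    "invert",
    "zscore",
)


@dataclass
class TransformSpec:
    """A fitted elementwise transform.

    ``shift`` is added before any power/log; ``lmbda`` is the Box-Cox
    exponent; ``center``/``scale`` parameterize the z-score kind;
    ``normality_stat`` records the goodness score used during selection.
    """

    variable: str
    kind: str
    lmbda: float | None = None
    shift: float = 0.0
    center: float | None = None
    scale: float | None = None
    normality_stat: float | None = None

    def __post_init__(self):
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "zscore" and self.scale is not None and self.scale <= 0:
            raise ValueError("zscore scale must be > 0")


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

@dataclass
class EligibilityDecision:
    """Outcome of cognitive screening; ``include`` iff no rule triggered."""

    include: bool
    reasons: list[str] = field(default_factory=list)


def screen_eligibility(
    z_scores: Mapping[str, float],
    mmse_raw: float,
    domain_map: Mapping[str, str],
) -> EligibilityDecision:
    """Apply the cognitive eligibility rules to one subject.

    A subject is excluded if the raw MMSE is below 26, any screening
    z-score (age/sex/education adjusted) is below -1.5, or the actuarial
    Jak/Bondi criteria hold: (i) at least two tests below -1 within the
    same cognitive domain, or (ii) at least one test below -1 in each of
    three domains.  Missing z-scores are treated as no evidence.
    """
    missing = [t for t in z_scores if t not in domain_map]
    if missing:
        raise ValueError(f"tests without a domain assignment: {missing}")
    reasons: list[str] = []
    if mmse_raw is not None and not np.isnan(mmse_raw) and mmse_raw < 26:
        reasons.append("mmse_below_26")
    observed = {t: z for t, z in z_scores.items() if z is not None and not np.isnan(z)}
    for test in sorted(observed):
        if observed[test] < -1.5:
            reasons.append(f"z_below_minus_1_5:{test}")
    by_domain: dict[str, int] = {}
    for test, z in observed.items():
        if z < -1.0:
            dom = domain_map[test]
            by_domain[dom] = by_domain.get(dom, 0) + 1
    for dom in sorted(by_domain):
        if by_domain[dom] >= 2:
            reasons.append(f"jak_bondi_two_in_domain:{dom}")
    if len(by_domain) >= 3:
        reasons.append("jak_bondi_one_in_each_of_three")
    return EligibilityDecision(include=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def fit_boxcox_lambda(values: np.ndarray, shift: bool = True) -> tuple[float, float]:
    """Profile-likelihood Box-Cox exponent.

    Maximizes the Box-Cox profile log-likelihood on a coarse grid over
    [-5, 5] followed by bounded local refinement.  Returns ``(lambda,
    shift)`` where ``shift`` (``1 - min`` when needed and allowed) makes
    all values strictly positive.
    """
    x = np.asarray(values, float)
    x = x[~np.isnan(x)]
    if x.size < 10:
        raise ValueError(f"need at least 10 values to fit lambda; got {x.size}")
    offset = 0.0
    if x.min() <= 0:
        if not shift:
            raise ValueError("nonpositive values and shifting disabled")
        offset = 1.0 - x.min()
    xs = x + offset
    grid = np.linspace(-5.0, 5.0, 201)
    lls = np.array([stats.boxcox_llf(l, xs) for l in grid])
    best = grid[int(np.argmax(lls))]
    lo, hi = max(best - 0.1, -5.0), min(best + 0.1, 5.0)
    res = optimize.minimize_scalar(
        lambda l: -stats.boxcox_llf(l, xs),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-5},
    )
    return float(res.x), offset


def _boxcox(x: np.ndarray, lmbda: float) -> np.ndarray:
    if abs(lmbda) < 1e-12:
        return np.log(x)
    return (np.power(x, lmbda) - 1.0) / lmbda


def fit_zscore(variable: str, values: np.ndarray, ddof: int = 1) -> TransformSpec:
    """Fit a z-score spec (sample SD by default)."""
    x = np.asarray(values, float)
    x = x[~np.isnan(x)]
    sd = float(np.std(x, ddof=ddof))
    if sd <= 0:
        raise ValueError(f"{variable!r} has zero variance; z-score undefined")
    return TransformSpec(variable, "zscore", center=float(np.mean(x)), scale=sd)


def apply_transform(spec: TransformSpec, values: np.ndarray) -> np.ndarray:
    """Apply a fitted spec elementwise (NaN passes through).

    Raises
    ------
    ValueError
        Naming the offending position when a log/Box-Cox input is not
        strictly positive after the stored shift.
    """
    x = np.asarray(values, float).copy()
    obs = ~np.isnan(x)
    if spec.kind in ("log_shift", "boxcox", "sqrt_shift"):
        shifted = x[obs] + spec.shift
        if spec.kind in ("log_shift", "boxcox") and np.any(shifted <= 0):
            bad = int(np.flatnonzero(obs)[np.argmax(shifted <= 0)])
            raise ValueError(
                f"{spec.variable!r}: value at position {bad} is <= {-spec.shift} "
                f"(nonpositive after shift {spec.shift})"
            )
        if spec.kind == "sqrt_shift" and np.any(shifted < 0):
            bad = int(np.flatnonzero(obs)[np.argmax(shifted < 0)])
            raise ValueError(
                f"{spec.variable!r}: value at position {bad} negative after shift"
            )
    if spec.kind == "identity":
        return x
    if spec.kind == "invert":
        x[obs] = -x[obs]
        return x
    if spec.kind == "zscore":
        if spec.center is None or spec.scale is None:
            raise ValueError("zscore spec not fitted")
        x[obs] = (x[obs] - spec.center) / spec.scale
        return x
    if spec.kind == "log_shift":
        x[obs] = np.log(x[obs] + spec.shift)
        return x
    if spec.kind == "sqrt_shift":
        x[obs] = np.sqrt(x[obs] + spec.shift)
        return x
    if spec.kind == "boxcox":
        if spec.lmbda is None:
            raise ValueError("boxcox spec not fitted")
        x[obs] = _boxcox(x[obs] + spec.shift, spec.lmbda)
        return x
    if spec.kind == "rank_inverse_normal":
        # Blom-style rank-based inverse normal, computed on the given sample
        xo = x[obs]
        ranks = stats.rankdata(xo)
        x[obs] = special.ndtri((ranks - 0.375) / (xo.size + 0.25))
        return x
    raise AssertionError(spec.kind)


def normality_statistic(values: np.ndarray) -> float:
    """Pearson chi-square / df against a fitted normal.

    Equiprobable classes, ``k = ceil(2 n^{2/5})``; the returned ratio is
    the selection criterion — lower is closer to normal.
    """
    x = np.asarray(values, float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 8:
        raise ValueError("too few values for the normality statistic")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return float("inf")
    k = int(np.ceil(2 * n ** 0.4))
    edges = stats.norm.ppf(np.linspace(0, 1, k + 1), loc=np.mean(x), scale=sd)
    counts, _ = np.histogram(x, bins=edges)
    expected = n / k
    chi2 = float(np.sum((counts - expected) ** 2) / expected)
    return chi2 / (k - 1)


def select_normalizing_transform(
    variable: str, values: np.ndarray
) -> tuple[TransformSpec, np.ndarray]:
    """Pick the transform that brings a sample closest to normality.

    Candidates: identity, shifted log, shifted square root, Box-Cox
    (profile-likelihood lambda), rank-based inverse normal; ranked by the
    Pearson chi-square/df statistic of :func:`normality_statistic`.
    Returns the winning fitted spec and the transformed sample.
    """
    x = np.asarray(values, float)
    obs = x[~np.isnan(x)]
    if obs.size < 10:
        raise ValueError(f"{variable!r}: need >= 10 observed values")
    shift = 1.0 - obs.min() if obs.min() <= 0 else 0.0
    candidates = [
        TransformSpec(variable, "identity"),
        TransformSpec(variable, "log_shift", shift=shift),
        TransformSpec(variable, "sqrt_shift", shift=max(shift, 0.0)),
    ]
    lmbda, bc_shift = fit_boxcox_lambda(obs)
    candidates.append(TransformSpec(variable, "boxcox", lmbda=lmbda, shift=bc_shift))
    candidates.append(TransformSpec(variable, "rank_inverse_normal"))
    best_spec, best_vals, best_stat = None, None, np.inf
    for spec in candidates:
        try:
            transformed = apply_transform(spec, x)
            stat = normality_statistic(transformed)
        except ValueError:
            continue
        if stat < best_stat:
            best_spec, best_vals, best_stat = spec, transformed, stat
    assert best_spec is not None
    best_spec.normality_stat = best_stat
    return best_spec, best_vals


def fit_transform_spec(variable: str, values: np.ndarray, kind: str) -> TransformSpec:
    """Fit a spec of a requested kind (Box-Cox lambda, shifts, z-moments)."""
    x = np.asarray(values, float)
    obs = x[~np.isnan(x)]
    if kind == "boxcox":
        lmbda, shift = fit_boxcox_lambda(obs)
        return TransformSpec(variable, "boxcox", lmbda=lmbda, shift=shift)
    if kind in ("log_shift", "sqrt_shift"):
        shift = 1.0 - obs.min() if obs.min() <= 0 else 0.0
        return TransformSpec(variable, kind, shift=shift)
    if kind == "zscore":
        return fit_zscore(variable, obs)
    if kind in ("identity", "invert", "rank_inverse_normal"):
        return TransformSpec(variable, kind)
    raise ValueError(f"unknown transform kind {kind!r}")


def invert_direction(variable: str, values: np.ndarray) -> np.ndarray:
    """Negate values so that higher numbers mean more pathology/impairment
    (applied to e.g. hippocampal volume, gray-matter thickness, and scores
    where high raw values mean good performance)."""
    return apply_transform(TransformSpec(variable, "invert"), values)


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

def adjust_for_ticv(
    volume: np.ndarray, ticv: np.ndarray, method: str = "residual"
) -> np.ndarray:
    """Adjust a regional volume for total intracranial volume.

    ``residual`` (default): residuals of ``volume ~ ticv`` with the sample
    mean re-added (degenerate constant-TICV designs return the input
    unchanged).  ``ratio``: ``volume / ticv``.
    """
    v = np.asarray(volume, float)
    t = np.asarray(ticv, float)
    if np.any(t[~np.isnan(t)] <= 0):
        raise ValueError("ticv must be strictly positive")
    if method == "ratio":
        return v / t
    if method != "residual":
        raise ValueError(f"unknown method {method!r}")
    obs = ~(np.isnan(v) | np.isnan(t))
    tc = t[obs] - t[obs].mean()
    denom = float(tc @ tc)
    out = v.copy()
    if denom < 1e-12 * max(1.0, float(np.abs(t[obs]).max()) ** 2):
        return out  # constant TICV: nothing to remove
    slope = float(tc @ (v[obs] - v[obs].mean())) / denom
    out[obs] = v[obs] - slope * tc
    return out


def residualize_age_sex(
    values: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    alpha: float = 0.05,
) -> tuple[np.ndarray, bool, dict[str, float]]:
    """Remove age/sex effects from a variable when they are significant.

    Fits ``values ~ age + sex``; if the omnibus F-test has p < ``alpha``
    the residuals (grand mean re-added) are returned.  Otherwise age-only
    and sex-only models are tested and the variable is residualized on any
    individually significant predictor; failing that it is returned
    unchanged.  Returns ``(values', used_residuals, p_values)``.
    """
    import statsmodels.api as sm

    y = np.asarray(values, float)
    a = np.asarray(age, float)
    s = np.asarray(sex, float)
    if np.isnan(a).any() or np.isnan(s).any():
        raise ValueError("age/sex must be complete")
    obs = ~np.isnan(y)
    pvals: dict[str, float] = {}
    degenerate = np.unique(s).size < 2
    if degenerate:
        warnings.warn("single-sex sample: falling back to age-only model")

    def _fit(cols: list[np.ndarray]):
        X = sm.add_constant(np.column_stack(cols))
        return sm.OLS(y[obs], X[obs]).fit()

    def _residuals(fit, cols):
        X = sm.add_constant(np.column_stack(cols))
        out = y.copy()
        out[obs] = y[obs] - fit.predict(X[obs]) + y[obs].mean()
        return out

    if degenerate:
        fit = _fit([a])
        pvals["age_only"] = float(fit.f_pvalue)
        if fit.f_pvalue < alpha:
            return _residuals(fit, [a]), True, pvals
        return y.copy(), False, pvals

    joint = _fit([a, s])
    pvals["omnibus"] = float(joint.f_pvalue)
    if joint.f_pvalue < alpha:
        return _residuals(joint, [a, s]), True, pvals
    fit_age = _fit([a])
    fit_sex = _fit([s])
    pvals["age_only"] = float(fit_age.f_pvalue)
    pvals["sex_only"] = float(fit_sex.f_pvalue)
    use = []
    if pvals["age_only"] < alpha:
        use.append(a)
    if pvals["sex_only"] < alpha:
        use.append(s)
    if use:
        fit = _fit(use)
        return _residuals(fit, use), True, pvals
    return y.copy(), False, pvals


# ---------------------------------------------------------------------------
# outliers and imputation
# ---------------------------------------------------------------------------

def flag_extreme_outliers(values: np.ndarray) -> np.ndarray:
    """Indices of extreme outliers by the 3-IQR fence rule.

    Flags values strictly below ``Q1 - 3*IQR`` or strictly above
    ``Q3 + 3*IQR``; quartiles use linear interpolation between order
    statistics.  NaNs are never flagged.
    """
    x = np.asarray(values, float)
    obs = ~np.isnan(x)
    if obs.sum() < 4:
        raise ValueError("need at least 4 observed values")
    q1, q3 = np.percentile(x[obs], [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    flagged = (x < lo) | (x > hi)
    flagged &= obs
    return np.flatnonzero(flagged)


def impute_cognitive_scores(
    z_matrix: np.ndarray | pd.DataFrame, max_missing: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing z-scores with each subject's own mean over observed
    tests; subjects missing more than ``max_missing`` scores are excluded.

    Returns ``(filled, included)`` where ``filled`` has the input shape
    (excluded rows keep their NaNs) and ``included`` is a boolean row mask.
    """
    Z = np.asarray(z_matrix, float).copy()
    if Z.ndim != 2:
        raise ValueError("expected a subjects x tests matrix")
    n_missing = np.isnan(Z).sum(axis=1)
    included = n_missing <= max_missing
    included &= n_missing < Z.shape[1]   # all-missing rows can never be imputed
    for i in np.flatnonzero(included & (n_missing > 0)):
        row = Z[i]
        row[np.isnan(row)] = np.nanmean(row)
    return Z, included


def iterative_impute(
    table: pd.DataFrame,
    seed: int = 0,
    max_iter: int = 25,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Chained linear-regression imputation of a numeric table.

    Missing cells are initialized with column means; the variables are then
    cycled (in a seed-determined order), each regressed on all others by
    least squares and its missing cells refilled, until the largest change
    in an imputed value (in column-SD units) stalls below ``tol`` or
    ``max_iter`` sweeps elapse.  Deterministic given ``seed``; the input
    frame is not modified.
    """
    df = table.copy()
    cols = list(df.columns)
    X = df.to_numpy(float)
    mask = np.isnan(X)
    if mask.all(axis=0).any():
        bad = [c for c, m in zip(cols, mask.all(axis=0)) if m]
        raise ValueError(f"fully-missing columns cannot be imputed: {bad}")
    frac = mask.mean(axis=0)
    if (frac >= 0.5).any():
        heavy = [c for c, f in zip(cols, frac) if f >= 0.5]
        warnings.warn(f"variables missing >= 50%: {heavy}; imputation unstable")
    col_means = np.nanmean(X, axis=0)
    col_sds = np.nanstd(X, axis=0, ddof=1)
    col_sds[col_sds == 0] = 1.0
    X[mask] = np.take(col_means, np.nonzero(mask)[1])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cols))
    targets = [j for j in order if mask[:, j].any()]
    for _ in range(max_iter):
        delta = 0.0
        for j in targets:
            others = [k for k in range(len(cols)) if k != j]
            A = np.column_stack([np.ones(X.shape[0]), X[:, others]])
            rows_obs = ~mask[:, j]
            beta, *_ = np.linalg.lstsq(A[rows_obs], X[rows_obs, j], rcond=None)
            pred = A[mask[:, j]] @ beta
            delta = max(delta, float(np.max(np.abs(pred - X[mask[:, j], j])) / col_sds[j]))
            X[mask[:, j], j] = pred
        if delta < tol:
            break
    return pd.DataFrame(X, columns=cols, index=df.index)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class PreprocessReport:
    """Ledger of everything a preprocessing pass did to a table."""

    transforms: dict[str, list[TransformSpec]] = field(default_factory=dict)
    outlier_subjects: list[tuple[str, str]] = field(default_factory=list)
    residualized_vars: dict[str, dict] = field(default_factory=dict)
    imputation_log: list[dict] = field(default_factory=list)
    excluded_subjects: list[tuple[str, str]] = field(default_factory=list)

    def log_transform(self, variable: str, spec: TransformSpec) -> None:
        self.transforms.setdefault(variable, []).append(spec)

    def to_jsonable(self) -> dict:
        return {
            "transforms": {
                v: [
                    {
                        "kind": s.kind,
                        "lambda": s.lmbda,
                        "shift": s.shift,
                        "center": s.center,
                        "scale": s.scale,
                        "normality_stat": s.normality_stat,
                    }
                    for s in specs
                ]
                for v, specs in self.transforms.items()
            },
            "outlier_subjects": [list(t) for t in self.outlier_subjects],
            "residualized_vars": self.residualized_vars,
            "imputation_log": self.imputation_log,
            "excluded_subjects": [list(t) for t in self.excluded_subjects],
        }
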