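"""Association testing and quasi-Bayesian causal mediation.

Linear models go through statsmodels OLS.  The mediation estimator follows
the simulation approach for linear, no-interaction mediator/outcome models:
fit ``M ~ T + covariates`` and ``Y ~ M + T + covariates`` by OLS, draw both
coefficient vectors from multivariate normals centered at the estimates
with the estimated coefficient covariance, and per draw compute the average
causal mediation effect ``ACME = a * b`` (treatment coefficient in the
mediator model times mediator coefficient in the outcome model), the
average direct effect ``ADE`` (treatment coefficient in the outcome model)
and their sum, the total effect.  Point estimates are means of the draws
(median for the proportion mediated); intervals are percentile intervals of
the draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MediationResult",
    "OLSResult",
    "TTestResult",
    "fit_ols",
    "mediate_quasibayes",
    "pearson_corr",
    "proportion_mediated",
    "ttest_onesided_pooled",
]


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

@dataclass
class OLSResult:
    """Per-term estimates with t-based 95% CIs and two-sided p-values."""

    terms: list[str]
    coefficients: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    n: int
    residual_df: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Estimates": self.coefficients,
                "CI_low": self.ci_low,
                "CI_high": self.ci_high,
                "p": self.p_values,
            }
        )


def fit_ols(y: np.ndarray, design: pd.DataFrame, add_intercept: bool = True) -> OLSResult:
    """Least-squares fit of ``y`` on the named design columns.

    Raises
    ------
    ValueError
        Naming the aliased terms when the design is collinear.
    """
    y = np.asarray(y, float)
    X = design.astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by testing rank contribution
        aliased = []
        keep: list[str] = []
        for col in X.columns:
            trial = X[keep + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(keep):
                aliased.append(col)
            else:
                keep.append(col)
        raise ValueError(f"collinear design; aliased terms: {aliased}")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return OLSResult(
        terms=list(X.columns),
        coefficients={t: float(fit.params[t]) for t in X.columns},
        ci_low={t: float(ci.loc[t, 0]) for t in X.columns},
        ci_high={t: float(ci.loc[t, 1]) for t in X.columns},
        p_values={t: float(fit.pvalues[t]) for t in X.columns},
        r_squared=float(fit.rsquared),
        n=int(fit.nobs),
        residual_df=int(fit.df_resid),
    )


# ---------------------------------------------------------------------------
# t-test and correlation
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    df: int
    p_one_sided: float
    cohens_d: float
    group_means: tuple[float, float]
    direction: str = "a_greater"


def ttest_onesided_pooled(group_a: np.ndarray, group_b: np.ndarray) -> TTestResult:
    """Two-sample pooled-variance t-test, one-sided for mean(a) > mean(b),
    with Cohen's d from the pooled SD."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    t = float((a.mean() - b.mean()) / se)
    p = float(stats.t.sf(t, df))
    d = float((a.mean() - b.mean()) / np.sqrt(sp2))
    return TTestResult(
        t=t, df=df, p_one_sided=p, cohens_d=d,
        group_means=(float(a.mean()), float(b.mean())),
    )


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-approximation p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    """Quasi-Bayesian mediation summary.

    ``acme + ade = total`` holds exactly within every draw; point
    estimates are draw means (median for the proportion).  ``mc_p`` is the
    two-sided sign-based Monte-Carlo p-value ``2 * min(Pr(>0), Pr(<0))``.
    """

    acme: float
    ade: float
    total_effect: float
    prop_mediated: float
    ci: dict[str, tuple[float, float]]
    mc_p: dict[str, float]
    n_draws: int
    seed: int
    treat_value: float = 1.0
    control_value: float = 0.0
    draws: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def _draw_coefs(fit, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    cov = np.asarray(fit.cov_params())
    # guard: the coefficient covariance must be usable for sampling
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular coefficient covariance") from exc
    z = rng.standard_normal((n_draws, cov.shape[0]))
    return np.asarray(fit.params)[None, :] + z @ chol.T


def mediate_quasibayes(
    treatment: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_draws: int = 10000,
    seed: int = 0,
    treat_value: float = 1.0,
    control_value: float = 0.0,
) -> MediationResult:
    """Causal mediation for linear no-interaction models.

    Fits ``mediator ~ treatment + covariates`` and ``outcome ~ mediator +
    treatment + covariates`` by OLS and propagates coefficient uncertainty
    by Monte-Carlo simulation (see module docstring).  Effects are scaled
    by ``treat_value - control_value`` (default: one unit of treatment).
    """
    t = np.asarray(treatment, float)
    m = np.asarray(mediator, float)
    y = np.asarray(outcome, float)
    cov_arr = None
    if covariates is not None:
        cov_arr = np.asarray(covariates, float)
        if cov_arr.ndim == 1:
            cov_arr = cov_arr[:, None]
    complete = ~(np.isnan(t) | np.isnan(m) | np.isnan(y))
    if cov_arr is not None:
        complete &= ~np.isnan(cov_arr).any(axis=1)
    if not complete.all():
        raise ValueError("mediation requires complete cases; filter upstream")
    if n_draws < 1000:
        warnings.warn("fewer than 1000 draws: unstable mediation intervals")

    def _design(*blocks):
        return sm.add_constant(np.column_stack(blocks), has_constant="add")

    Xm = _design(t) if cov_arr is None else _design(t, cov_arr)
    Xy = _design(m, t) if cov_arr is None else _design(m, t, cov_arr)
    fit_m = sm.OLS(m, Xm).fit()
    fit_y = sm.OLS(y, Xy).fit()

    rng = np.random.default_rng(seed)
    draws_m = _draw_coefs(fit_m, n_draws, rng)
    draws_y = _draw_coefs(fit_y, n_draws, rng)
    contrast = treat_value - control_value
    a = draws_m[:, 1]          # treatment coefficient in the mediator model
    b = draws_y[:, 1]          # mediator coefficient in the outcome model
    c_prime = draws_y[:, 2]    # direct treatment coefficient
    acme = a * b * contrast
    ade = c_prime * contrast
    total = acme + ade
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(total != 0, acme / total, np.nan)

    def _ci(d):
        return (float(np.percentile(d, 2.5)), float(np.percentile(d, 97.5)))

    def _mc_p(d):
        pos = float(np.mean(d > 0))
        neg = float(np.mean(d < 0))
        return min(1.0, 2.0 * min(pos, neg))

    return MediationResult(
        acme=float(acme.mean()),
        ade=float(ade.mean()),
        total_effect=float(total.mean()),
        prop_mediated=float(np.nanmedian(prop)),
        ci={
            "acme": _ci(acme),
            "ade": _ci(ade),
            "total": _ci(total),
            "prop_mediated": (
                float(np.nanpercentile(prop, 2.5)),
                float(np.nanpercentile(prop, 97.5)),
            ),
        },
        mc_p={
            "acme": _mc_p(acme),
            "ade": _mc_p(ade),
            "total": _mc_p(total),
        },
        n_draws=n_draws,
        seed=seed,
        treat_value=treat_value,
        control_value=control_value,
        draws={"acme": acme, "ade": ade, "total": total, "prop_mediated": prop},
    )


def proportion_mediated(
    acme: float, total: float, draws: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[float, tuple[float, float] | None]:
    """Indirect share of the total effect, as a percentage.

    Point ratio ``100 * acme / total`` (undefined, NaN, for total = 0);
    when per-draw (acme, total) arrays are supplied, also returns the
    percentile 95% interval of the per-draw percentage ratios.
    """
    if total == 0:
        warnings.warn("total effect is zero: proportion mediated undefined")
        point = float("nan")
    else:
        point = 100.0 * acme / total
    interval = None
    if draws is not None:
        acme_d, total_d = draws
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(total_d != 0, 100.0 * acme_d / total_d, np.nan)
        interval = (
            float(np.nanpercentile(ratio, 2.5)),
            float(np.nanpercentile(ratio, 97.5)),
        )
    return point, interval
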