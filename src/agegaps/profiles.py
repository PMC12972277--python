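"""Latent lifestyle/health profiles: correlation-matrix PCA with Horn's
parallel analysis deciding how many components to keep.

Horn's criterion retains a component only while its observed eigenvalue
exceeds the reference eigenvalue of the same rank obtained from Monte-Carlo
simulated noise tables of identical dimensions; retention stops at the
first rank that fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "ParallelAnalysisResult",
    "cumulative_variance",
    "horn_parallel",
    "run_pca",
    "threshold_loadings",
]


@dataclass
class PCAResult:
    """Eigenstructure of the sample correlation matrix.

    ``loadings`` are eigenvectors scaled by the square root of their
    eigenvalue (so entries are variable-component correlations);
    ``eigenvectors`` keeps the raw orthonormal vectors.  Components are
    sign-flipped so each one's largest-magnitude loading is positive.
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray          # p x p, sqrt(eigenvalue)-scaled
    eigenvectors: np.ndarray      # p x p, raw
    scores: np.ndarray            # n x p
    pct_var: np.ndarray
    variable_names: list[str]
    sign_convention: str = "max_abs_loading_positive"
    loading_convention: str = "eigvec_times_sqrt_eigval"


def run_pca(Z: np.ndarray | pd.DataFrame) -> PCAResult:
    """PCA of the sample correlation matrix of a complete data table.

    ``Z`` is subjects x variables; columns are standardized internally so
    passing an already z-scored matrix is idempotent.  Eigenvalues sum to
    the number of variables; component scores are mutually uncorrelated
    with variance equal to their eigenvalue (ddof=1 convention throughout).
    """
    names = list(Z.columns) if isinstance(Z, pd.DataFrame) else [
        f"v{i}" for i in range(np.asarray(Z).shape[1])
    ]
    X = np.asarray(Z, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a subjects x variables matrix with >= 2 variables")
    if np.isnan(X).any():
        raise ValueError("PCA input must be complete (impute upstream)")
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant columns (correlation undefined): {bad}")
    if n <= p:
        warnings.warn(f"n={n} <= p={p}: eigenstructure will be rank-deficient")
    Zs = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Zs, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(p):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    eigval_clip = np.clip(eigval, 0.0, None)
    loadings = eigvec * np.sqrt(eigval_clip)
    scores = Zs @ eigvec
    return PCAResult(
        eigenvalues=eigval,
        loadings=loadings,
        eigenvectors=eigvec,
        scores=scores,
        pct_var=100.0 * eigval / p,
        variable_names=names,
    )


@dataclass
class ParallelAnalysisResult:
    observed_eigenvalues: np.ndarray
    reference_mean: np.ndarray
    reference_centile: np.ndarray
    n_iterations: int
    criterion: str
    centile: float
    retained: int
    seed: int


def horn_parallel(
    n: int,
    p: int,
    observed_eigenvalues: np.ndarray,
    n_iterations: int = 5000,
    criterion: str = "mean",
    centile: float = 95.0,
    seed: int = 0,
) -> ParallelAnalysisResult:
    """Horn's parallel analysis for correlation-matrix PCA.

    Simulates ``n_iterations`` standard-normal n x p tables, collects their
    sorted correlation-matrix eigenvalues, and retains component k while
    the observed k-th eigenvalue exceeds the reference (per-rank mean by
    default; a per-rank centile is available), stopping at the first
    failure.
    """
    obs = np.asarray(observed_eigenvalues, float)
    if criterion not in ("mean", "centile"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if n_iterations < 100:
        warnings.warn("fewer than 100 iterations: unstable reference")
    rng = np.random.default_rng(seed)
    sims = np.empty((n_iterations, p))
    for it in range(n_iterations):
        X = rng.standard_normal((n, p))
        R = np.corrcoef(X, rowvar=False)
        ev = np.linalg.eigvalsh(R)
        sims[it] = ev[::-1]
    ref_mean = sims.mean(axis=0)
    ref_centile = np.percentile(sims, centile, axis=0)
    reference = ref_mean if criterion == "mean" else ref_centile
    retained = 0
    for k in range(min(obs.size, p)):
        if obs[k] > reference[k]:
            retained += 1
        else:
            break
    return ParallelAnalysisResult(
        observed_eigenvalues=obs,
        reference_mean=ref_mean,
        reference_centile=ref_centile,
        n_iterations=n_iterations,
        criterion=criterion,
        centile=centile,
        retained=retained,
        seed=seed,
    )


def cumulative_variance(pca: PCAResult, k: int) -> float:
    """Percentage of total variance carried by the first ``k`` components."""
    if k <= 0:
        raise ValueError("k must be positive")
    p = pca.eigenvalues.size
    if k > p:
        raise ValueError(f"k={k} exceeds {p} components")
    return float(100.0 * np.sum(pca.eigenvalues[:k]) / p)


def threshold_loadings(
    pca: PCAResult, cutoff: float = 0.2, n_components: int | None = None
) -> pd.DataFrame:
    """Display table of loadings with |value| < cutoff blanked (NaN).

    Purely presentational: the stored result is never modified.
    """
    k = n_components or pca.eigenvalues.size
    table = pd.DataFrame(
        pca.loadings[:, :k].copy(),
        index=pca.variable_names,
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    return table.mask(table.abs() < cutoff)
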