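"""Correlation-matrix PCA with Kaiser retention, and OLS of WQI on scores.

This is the validation stage applied to a monitoring dataset: keep
complete cases, eigendecompose the correlation matrix of the criteria
parameters, retain components with eigenvalue > 1 (Kaiser criterion),
report correlation-scaled loadings with their diagnostics (SS loadings,
explained-variance proportions, communality h2 and uniqueness u2 per
variable), compute standardized component scores, and regress the computed
WQI on the retained scores to quantify how much of the index the principal
hydrochemical gradients explain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset_io import Dataset
from .wqi_core import MISSING, CriteriaSet, SampleRecord

__all__ = [
    "PCAResult",
    "RegressionResult",
    "filter_complete",
    "records_to_matrix",
    "pca_correlation",
    "kaiser_retain",
    "loading_diagnostics",
    "varimax",
    "ols_wqi_on_scores",
]


@dataclass
class PCAResult:
    """Unrotated (or varimax-rotated) principal components of a correlation matrix.

    ``loadings`` is variables x retained components, correlation-scaled
    (eigenvector * sqrt(eigenvalue)); ``eigenvalues`` covers all p
    components; ``scores`` are the retained component scores standardized
    to zero mean and unit variance.
    """

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    retained: list[int]
    ss_loadings: np.ndarray
    proportion_var: np.ndarray
    cumulative_var: np.ndarray
    proportion_explained: np.ndarray
    cumulative_proportion: np.ndarray
    h2: pd.Series
    u2: pd.Series
    scores: np.ndarray
    rotation: str = "none"


@dataclass
class RegressionResult:
    """OLS fit of WQI on component scores (intercept first)."""

    coefficients: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float


def _present(record: SampleRecord, name: str) -> bool:
    v = record.values.get(name, MISSING)
    if record.overrides.get(name, 1) == 0:
        return False
    try:
        return not np.isnan(float(v))
    except (TypeError, ValueError):
        return False


def filter_complete(
    dataset: Dataset, criteria: CriteriaSet | None = None
) -> list[SampleRecord]:
    """Complete-case filter: keep records with every included parameter present.

    Raises when fewer than p+1 records survive, where p is the number of
    included parameters — the correlation matrix would be singular or the
    PCA underdetermined below that.
    """
    criteria = criteria or dataset.criteria
    names = criteria.included_names
    kept = [
        rec for rec in dataset.records if all(_present(rec, n) for n in names)
    ]
    if len(kept) < len(names) + 1:
        raise ValueError(
            f"only {len(kept)} complete records for {len(names)} parameters; "
            "PCA needs at least p+1"
        )
    return kept


def records_to_matrix(
    records: Sequence[SampleRecord], names: Sequence[str]
) -> pd.DataFrame:
    """Stack record values into an n x p DataFrame (columns = parameters)."""
    return pd.DataFrame(
        [[float(rec.values[n]) for n in names] for rec in records],
        index=[rec.sample_id for rec in records],
        columns=list(names),
    )


def kaiser_retain(eigenvalues: Iterable[float]) -> list[int]:
    """Indices of components with eigenvalue strictly greater than one.

    Expects eigenvalues sorted descending; raises when none qualifies
    (choose k manually in that case).
    """
    ev = np.asarray(list(eigenvalues), dtype=float)
    if ev.size and np.any(np.diff(ev) > 1e-12):
        raise ValueError("eigenvalues must be sorted in descending order")
    retained = [i for i, v in enumerate(ev) if v > 1.0]
    if not retained:
        raise ValueError(
            "no eigenvalue exceeds 1; the Kaiser criterion retains nothing — "
            "specify the number of components manually"
        )
    return retained


def loading_diagnostics(
    loadings: np.ndarray | pd.DataFrame, p: int | None = None
) -> dict[str, np.ndarray]:
    """SS loadings, variance proportions and communalities of a loading matrix.

    ``ss_loadings`` are column sums of squares (equal to the eigenvalues
    for unrotated components); ``proportion_var`` divides by the number of
    variables p; ``proportion_explained`` divides by the total SS of the
    retained columns; ``h2`` is each variable's row sum of squares and
    ``u2 = 1 - h2`` its uniqueness.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2 or L.shape[1] < 1:
        raise ValueError("loadings must be a p x k matrix with k >= 1")
    if p is None:
        p = L.shape[0]
    h2 = (L**2).sum(axis=1)
    if np.any(h2 > 1 + 1e-6):
        bad = int(np.argmax(h2))
        raise ValueError(
            f"communality {h2[bad]:.4f} > 1 for variable {bad}: malformed loadings"
        )
    ss = (L**2).sum(axis=0)
    return {
        "ss_loadings": ss,
        "proportion_var": ss / p,
        "cumulative_var": np.cumsum(ss / p),
        "proportion_explained": ss / ss.sum(),
        "cumulative_proportion": np.cumsum(ss / ss.sum()),
        "h2": h2,
        "u2": 1.0 - h2,
    }


def varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Varimax rotation of a loading matrix (orthogonal, communality-preserving)."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return L @ R


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca_correlation(
    X: np.ndarray | pd.DataFrame,
    var_names: Sequence[str] | None = None,
    *,
    retain: str | int = "kaiser",
    rotate: str = "none",
) -> PCAResult:
    """PCA of the correlation matrix of an n x p data matrix.

    Columns are standardized to z-scores (ddof=1); the correlation matrix
    is eigendecomposed; loadings are eigenvector * sqrt(eigenvalue) with
    each component's sign fixed so its largest-|loading| entry is positive.
    ``retain`` is ``"kaiser"`` (eigenvalue > 1), ``"all"``, or an explicit
    component count.  ``rotate="varimax"`` rotates the retained loadings
    (diagnostics then describe the rotated solution, whose SS loadings no
    longer equal eigenvalues).  Scores are standardized to unit variance.
    """
    if isinstance(X, pd.DataFrame):
        if var_names is None:
            var_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    n, p = X.shape
    if var_names is None:
        var_names = [f"var{i + 1}" for i in range(p)]
    if n <= p:
        raise ValueError(f"PCA needs n > p; got n={n}, p={p}")
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing cells; filter complete cases first")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [var_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant column(s) {bad}: correlation undefined")

    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = _fix_signs(eigvec[:, order])

    if retain == "kaiser":
        retained = kaiser_retain(eigval)
    elif retain == "all":
        retained = list(range(p))
    else:
        k = int(retain)
        if not 1 <= k <= p:
            raise ValueError(f"retain must be in 1..{p}, got {k}")
        retained = list(range(k))

    vec_r = eigvec[:, retained]
    val_r = eigval[retained]
    loadings = vec_r * np.sqrt(val_r)
    if rotate == "varimax":
        loadings = _fix_signs(varimax(loadings))
    elif rotate != "none":
        raise ValueError(f"unknown rotation {rotate!r}; use 'none' or 'varimax'")

    # Z @ v has sample variance exactly eigval_j under ddof=1 z-scoring,
    # so dividing by sqrt(eigval) standardizes the scores.
    scores = (Z @ vec_r) / np.sqrt(val_r)

    diag = loading_diagnostics(loadings, p)
    comp_names = [f"PC{i + 1}" for i in range(len(retained))]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=list(var_names), columns=comp_names),
        eigenvalues=eigval,
        retained=retained,
        ss_loadings=diag["ss_loadings"],
        proportion_var=diag["proportion_var"],
        cumulative_var=diag["cumulative_var"],
        proportion_explained=diag["proportion_explained"],
        cumulative_proportion=diag["cumulative_proportion"],
        h2=pd.Series(diag["h2"], index=list(var_names), name="h2"),
        u2=pd.Series(diag["u2"], index=list(var_names), name="u2"),
        scores=scores,
        rotation=rotate,
    )


def ols_wqi_on_scores(
    wqi: Sequence[float] | np.ndarray, scores: np.ndarray
) -> RegressionResult:
    """OLS of the computed WQI on component scores, with intercept.

    With standardized (mean-zero) scores the intercept equals the WQI
    mean, so the fit decomposes the index into its hydrochemical gradients
    plus the overall level.
    """
    y = np.asarray(wqi, dtype=float)
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    n, k = S.shape
    if y.shape != (n,):
        raise ValueError(f"wqi length {y.shape} does not match scores rows {n}")
    if n <= k + 1:
        raise ValueError(f"OLS needs n > k+1; got n={n}, k={k}")
    design = sm.add_constant(S, has_constant="add")
    if np.linalg.matrix_rank(design) < k + 1:
        raise ValueError("rank-deficient design: scores are collinear")
    fit = sm.OLS(y, design).fit()
    return RegressionResult(
        coefficients=np.asarray(fit.params),
        std_errors=np.asarray(fit.bse),
        t_values=np.asarray(fit.tvalues),
        p_values=np.asarray(fit.pvalues),
        r_squared=float(fit.rsquared),
    )
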