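"""Mass univariate screening of connectivity on behavior.

For each ROI-pair ``a`` the model is ``y_a = X1 b1_a + X2 b2_a + e_a`` where
``X1`` holds the intercept and nuisance variables (age, sex, site dummies, ...)
and ``X2`` the behavioral covariates of interest.  The screening statistics
are the per-covariate t statistics for ``b2_a`` from the joint fit; hits in
the enrichment stage are large *positive* t values (one-sided screening —
negate a covariate to probe negative associations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

# An ROI-pair whose full-model residual sum of squares falls below this
# fraction of its total sum of squares is flagged degenerate (its t statistics
# would be numerically meaningless, e.g. y exactly collinear with the design).
_DEGENERATE_RTOL = 1e-10


@dataclass
class DesignMatrices:
    """Nuisance (X1) and interest (X2) design blocks plus bookkeeping."""

    X1: np.ndarray
    X2: np.ndarray
    nuisance_names: list[str]
    interest_names: list[str]
    subject_ids: list
    retained_mask: np.ndarray  # over the input table rows


@dataclass
class ScreeningResult:
    """Per-ROI-pair, per-covariate t statistics from the joint linear model."""

    tstats: np.ndarray  # (R, K)
    coefs: np.ndarray  # (R, K) estimates of b2
    df: int  # residual degrees of freedom N - (q + K)
    degenerate: np.ndarray  # (R,) bool

    @property
    def n_pairs(self) -> int:
        return self.tstats.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.tstats.shape[1]


def build_design(
    subjects: pd.DataFrame,
    interest: list[str],
    nuisance_continuous: list[str] = (),
    nuisance_binary: list[str] = (),
    nuisance_categorical: list[str] = (),
) -> DesignMatrices:
    """Assemble X1 (intercept + nuisance) and X2 (covariates of interest).

    Categorical nuisance variables are reference-coded (first level dropped);
    rows with any missing value among the used columns are dropped
    (complete-case filtering) and reported through ``retained_mask``.

    Raises
    ------
    ValueError
        If the combined design ``[X1 X2]`` is rank deficient; the message
        names candidate collinear columns.
    """
    interest = list(interest)
    nuisance_continuous = list(nuisance_continuous)
    nuisance_binary = list(nuisance_binary)
    nuisance_categorical = list(nuisance_categorical)
    used = interest + nuisance_continuous + nuisance_binary + nuisance_categorical
    missing_cols = [c for c in used if c not in subjects.columns]
    if missing_cols:
        raise KeyError(f"subject table lacks columns {missing_cols}")

    complete = subjects[used].notna().all(axis=1).to_numpy()
    sub = subjects.loc[complete]

    blocks = [np.ones((len(sub), 1))]
    names = ["intercept"]
    for col in nuisance_continuous + nuisance_binary:
        blocks.append(sub[col].to_numpy(dtype=float)[:, None])
        names.append(col)
    for col in nuisance_categorical:
        dummies = pd.get_dummies(sub[col].astype(str), prefix=col, drop_first=True)
        # constant columns (single-level categorical) contribute nothing
        if dummies.shape[1]:
            blocks.append(dummies.to_numpy(dtype=float))
            names.extend(dummies.columns)
    X1 = np.hstack(blocks)
    X2 = sub[interest].to_numpy(dtype=float)

    full = np.hstack([X1, X2])
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        all_names = names + interest
        # name columns that do not raise the rank when added incrementally
        culprits, acc = [], np.empty((len(sub), 0))
        for c in range(full.shape[1]):
            trial = np.hstack([acc, full[:, [c]]])
            if np.linalg.matrix_rank(trial) == acc.shape[1]:
                culprits.append(all_names[c])
            else:
                acc = trial
        raise ValueError(f"design is rank deficient; collinear columns: {culprits}")

    id_col = "subject_id" if "subject_id" in sub.columns else None
    ids = list(sub[id_col]) if id_col else list(sub.index)
    return DesignMatrices(
        X1=X1,
        X2=X2,
        nuisance_names=names,
        interest_names=interest,
        subject_ids=ids,
        retained_mask=complete,
    )


def _check_shapes(y: np.ndarray, X1: np.ndarray, X2: np.ndarray) -> None:
    if y.ndim != 2:
        raise ValueError("connectivity must be a subjects x ROI-pairs matrix")
    n = y.shape[0]
    if X1.shape[0] != n or X2.shape[0] != n:
        raise ValueError("design and connectivity row counts differ")
    p = X1.shape[1] + X2.shape[1]
    if n - p < 1:
        raise ValueError(f"not enough subjects: N={n}, parameters={p}")


def mass_univariate_screen(
    y: np.ndarray, X1: np.ndarray, X2: np.ndarray
) -> ScreeningResult:
    """OLS of every connectivity column on ``[X1 X2]`` jointly.

    Returns t statistics for the X2 block only, with residual degrees of
    freedom ``df = N - (q + K)``.  ROI-pairs with (numerically) zero residual
    variance are flagged degenerate and carry NaN statistics.
    """
    y = np.asarray(y, dtype=float)
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    _check_shapes(y, X1, X2)

    X = np.hstack([X1, X2])
    n, p = X.shape
    q = X1.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix [X1 X2] is rank deficient")
    df = n - p

    Q, R = np.linalg.qr(X)
    coef = solve_triangular(R, Q.T @ y)  # (p, R_pairs)
    resid = y - X @ coef
    rss = np.einsum("nr,nr->r", resid, resid)
    scale = np.einsum("nr,nr->r", y, y)
    degenerate = rss <= _DEGENERATE_RTOL * np.maximum(scale, 1.0)

    Rinv = solve_triangular(R, np.eye(p))
    xtx_inv_diag = np.einsum("ij,ij->i", Rinv, Rinv)  # diag of (X'X)^-1

    sigma2 = rss / df
    b2 = coef[q:, :].T  # (R_pairs, K)
    se = np.sqrt(sigma2[:, None] * xtx_inv_diag[q:][None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b2 / se
    t[degenerate, :] = np.nan
    return ScreeningResult(tstats=t, coefs=b2, df=df, degenerate=degenerate)


def tstats_by_residualization(
    y: np.ndarray, X1: np.ndarray, X2: np.ndarray, k: int
) -> np.ndarray:
    """t column for covariate ``k`` via the Frisch–Waugh residualization identity.

    Used as the second, algebraically independent route that must agree with
    :func:`mass_univariate_screen` (and as the backbone of the fast
    permutation path).
    """
    y = np.asarray(y, dtype=float)
    X = np.hstack([np.atleast_2d(X1), np.atleast_2d(X2)]).astype(float)
    n, p = X.shape
    q = np.atleast_2d(X1).shape[1]
    j = q + k
    others = np.delete(X, j, axis=1)
    Qo, _ = np.linalg.qr(others)
    xt = X[:, j] - Qo @ (Qo.T @ X[:, j])
    xtx = xt @ xt
    b = (xt @ y) / xtx

    Qf, _ = np.linalg.qr(X)
    rss = np.einsum("nr,nr->r", y, y) - np.einsum("pr,pr->r", Qf.T @ y, Qf.T @ y)
    df = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b * np.sqrt(xtx) / np.sqrt(rss / df)
    scale = np.einsum("nr,nr->r", y, y)
    t[rss <= _DEGENERATE_RTOL * np.maximum(scale, 1.0)] = np.nan
    return t
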