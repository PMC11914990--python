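"""Freedman–Lane permutation inference for enrichment counts.

Significance is assessed under the self-contained null (no association between
any member ROI-pair and behavior).  For a tested covariate, the reduced model
contains the nuisance block *and every other covariate of interest*; its
residuals are permuted by the same subject reordering for every ROI-pair
(preserving the cross-ROI covariance of connectivity), the reduced-model fit
is added back, and the full model is refit.  The permutation distribution of
the resulting enrichment counts gives one-sided p-values (excess hits only).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import RoiPairIndex
from .enrichment import OraConfig, nearest_rank_quantile, ora_counts, ora_threshold
from .screening import _DEGENERATE_RTOL, mass_univariate_screen


@dataclass
class PermutationScheme:
    """A fixed set of subject-row permutations shared across ROI-pairs."""

    indices: np.ndarray  # (P, N) each row a permutation of 0..N-1
    seed: int | None = None
    include_identity: bool = False

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)
        if self.indices.ndim != 2 or self.indices.shape[0] < 1:
            raise ValueError("need at least one permutation")
        n = self.indices.shape[1]
        if not np.all(np.sort(self.indices, axis=1) == np.arange(n)):
            raise ValueError("rows must be permutations of 0..N-1")

    @property
    def n_perm(self) -> int:
        return int(self.indices.shape[0])

    @property
    def n_subjects(self) -> int:
        return int(self.indices.shape[1])

    @classmethod
    def random(cls, n_subjects: int, n_perm: int, seed: int) -> "PermutationScheme":
        """``n_perm`` permutations drawn uniformly (with replacement across draws)."""
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        idx = np.array([rng.permutation(n_subjects) for _ in range(n_perm)])
        return cls(indices=idx, seed=seed, include_identity=False)

    @classmethod
    def exhaustive(cls, n_subjects: int) -> "PermutationScheme":
        """All ``n_subjects!`` permutations, identity included."""
        idx = np.array(list(itertools.permutations(range(n_subjects))), dtype=np.intp)
        return cls(indices=idx, include_identity=True)


class FreedmanLane:
    """Precomputed Freedman–Lane machinery for one tested covariate.

    All projections are computed once; each permutation then costs a single
    pass over the data.  The t statistics are numerically identical to a naive
    refit of the full model on the permuted-residual response.
    """

    def __init__(self, y: np.ndarray, X1: np.ndarray, X2: np.ndarray, k: int):
        y = np.asarray(y, dtype=float)
        X1 = np.atleast_2d(np.asarray(X1, dtype=float))
        X2 = np.atleast_2d(np.asarray(X2, dtype=float))
        X = np.hstack([X1, X2])
        n, p = X.shape
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("design matrix [X1 X2] is rank deficient")
        j = X1.shape[1] + k

        reduced = np.delete(X, j, axis=1)
        Qr, _ = np.linalg.qr(reduced)
        self.fitted = Qr @ (Qr.T @ y)  # reduced-model fit, (N, R)
        self.resid = y - self.fitted  # reduced-model residuals

        xj = X[:, j]
        xt = xj - Qr @ (Qr.T @ xj)  # covariate residualized on the reduced model
        self.xt = xt
        self.xtx = float(xt @ xt)

        Qf, _ = np.linalg.qr(X)
        self.Qf = Qf
        self.df = n - p

        # permutation-invariant pieces
        self.x_dot_fit = xt @ self.fitted  # (R,)
        self.Qt_fit = Qf.T @ self.fitted  # (p, R)
        self.ss_fit = np.einsum("nr,nr->r", self.fitted, self.fitted)
        self.ss_resid = np.einsum("nr,nr->r", self.resid, self.resid)
        self.scale = np.maximum(np.einsum("nr,nr->r", y, y), 1.0)

    def tstats(self, perms: np.ndarray) -> np.ndarray:
        """t columns for a batch of permutations; shape (n_perm, R)."""
        perms = np.atleast_2d(perms)
        Ep = self.resid[perms]  # (c, N, R)
        numer = self.x_dot_fit + np.einsum("n,cnr->cr", self.xt, Ep)
        cross = np.einsum("nr,cnr->cr", self.fitted, Ep)
        ssq = self.ss_fit + 2.0 * cross + self.ss_resid
        proj = self.Qt_fit[None, :, :] + np.einsum("np,cnr->cpr", self.Qf, Ep)
        rss = np.maximum(ssq - np.einsum("cpr,cpr->cr", proj, proj), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (numer / math.sqrt(self.xtx)) / np.sqrt(rss / self.df)
        t[rss <= _DEGENERATE_RTOL * self.scale] = np.nan
        return t


def permuted_screen(
    y: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    k: int,
    perm: np.ndarray,
) -> np.ndarray:
    """Freedman–Lane t column for covariate ``k`` under one permutation.

    Reference (naive) implementation: builds the permuted-residual response
    explicitly and refits the full model with the ordinary screening code.
    The fast path (:class:`FreedmanLane`) must agree with this to 1e-10
    relative and is what the batch routines use.
    """
    y = np.asarray(y, dtype=float)
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    X = np.hstack([X1, X2])
    j = X1.shape[1] + k
    reduced = np.delete(X, j, axis=1)
    Qr, _ = np.linalg.qr(reduced)
    fitted = Qr @ (Qr.T @ y)
    ystar = fitted + (y - fitted)[np.asarray(perm, dtype=np.intp)]
    return mass_univariate_screen(ystar, X1, X2).tstats[:, k]


def _threshold_for(
    cfg: OraConfig, df: int, tcol: np.ndarray | None
) -> float:
    if cfg.mode == "theoretical":
        return ora_threshold(cfg.alpha, df=df, mode="theoretical")
    return nearest_rank_quantile(tcol, cfg.alpha)


def permutation_count_stream(
    y: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    index: RoiPairIndex,
    cfg: OraConfig,
    scheme: PermutationScheme,
    k: int,
    chunk: int | None = None,
):
    """Yield (chunk_size, counts) blocks of permuted enrichment counts.

    ``counts`` has shape (chunk_size, n_network_pairs).  In empirical mode the
    threshold is re-estimated per permutation from that permutation's
    brain-wide statistics.
    """
    fl = FreedmanLane(y, X1, X2, k)
    n, R = y.shape
    if chunk is None:
        chunk = max(1, min(scheme.n_perm, int(4_000_000 / max(n * R, 1))))
    p2np = index.pair_to_network_pair
    n_np = index.n_network_pairs
    thr = None
    if cfg.mode == "theoretical":
        thr = ora_threshold(cfg.alpha, df=fl.df, mode="theoretical")
    for start in range(0, scheme.n_perm, chunk):
        perms = scheme.indices[start : start + chunk]
        t = fl.tstats(perms)
        counts = np.zeros((t.shape[0], n_np), dtype=np.intp)
        for c in range(t.shape[0]):
            thr_c = thr if thr is not None else nearest_rank_quantile(t[c], cfg.alpha)
            with np.errstate(invalid="ignore"):
                hits = t[c] > thr_c
            counts[c] = np.bincount(p2np[hits], minlength=n_np)
        yield counts


def permutation_counts(
    y, X1, X2, index, cfg, scheme, k, chunk=None
) -> np.ndarray:
    """Full (P, n_network_pairs) matrix of permuted counts for covariate k."""
    blocks = list(
        permutation_count_stream(y, X1, X2, index, cfg, scheme, k, chunk=chunk)
    )
    return np.vstack(blocks)


@dataclass
class EnrichmentResult:
    """Observed counts and their permutation p-values."""

    observed: np.ndarray  # (n_np, K) int
    pvalues: np.ndarray  # (n_np, K)
    alpha: float
    n_perm: int
    covariates: list[str] = field(default_factory=list)

    def to_frame(self, index: RoiPairIndex, target_p: float | None = None) -> pd.DataFrame:
        covs = self.covariates or [f"cov{k}" for k in range(self.observed.shape[1])]
        rows = []
        for p_id, pair in enumerate(index.network_pairs):
            for k, cov in enumerate(covs):
                row = {
                    "net_i": pair.i,
                    "net_j": pair.j,
                    "covariate": cov,
                    "alpha": self.alpha,
                    "size": pair.size,
                    "observed_count": int(self.observed[p_id, k]),
                    "p_value": float(self.pvalues[p_id, k]),
                    "n_perm": self.n_perm,
                }
                if target_p is not None:
                    row["significant"] = row["p_value"] <= target_p
                rows.append(row)
        return pd.DataFrame(rows)


def enrichment_pvalues(
    y: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    index: RoiPairIndex,
    cfg: OraConfig,
    scheme: PermutationScheme,
    covariates: list[str] | None = None,
    chunk: int | None = None,
) -> EnrichmentResult:
    """One-sided permutation p-values for every (network-pair, covariate).

    With random permutations, ``p = (1 + #{permuted count >= observed}) /
    (1 + P)`` (add-one validity convention).  With an exhaustive scheme the
    identity permutation is part of the draw and ``p = #{>= observed} / P``
    is exact.
    """
    K = np.atleast_2d(X2).shape[1]
    screen = mass_univariate_screen(y, X1, X2)
    observed = ora_counts(screen, index, cfg).counts
    ge = np.zeros_like(observed)
    for k in range(K):
        for counts in permutation_count_stream(
            y, X1, X2, index, cfg, scheme, k, chunk=chunk
        ):
            ge[:, k] += (counts >= observed[None, :, k]).sum(axis=0)
    if scheme.include_identity:
        pvals = ge / scheme.n_perm
    else:
        pvals = (1.0 + ge) / (1.0 + scheme.n_perm)
    return EnrichmentResult(
        observed=observed,
        pvalues=pvals,
        alpha=cfg.alpha,
        n_perm=scheme.n_perm,
        covariates=list(covariates) if covariates else [],
    )
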