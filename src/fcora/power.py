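"""Power simulation with covariance-realistic connectivity.

For one network-pair with R member ROI-pairs the generative model is

    f = X B' + Z C'          (N x R)

with behavior ``X ~ N(0, 1)`` (N x 1), per-ROI-pair regression coefficients
``B ~ N(mu, sigma^2)`` i.i.d. (redrawn every simulated dataset, so power
averages over effect heterogeneity), noise ``Z`` i.i.d. standard normal and
``C`` the Cholesky factor of a Ledoit–Wolf shrinkage estimate of the
connectivity covariance ``Omega`` (shrinkage is essential because N << R for
most network-pairs).  Power at (N, mu, sigma, alpha) is the fraction of
simulated datasets whose ORA count reaches a precalibrated cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.covariance import LedoitWolf

from .enrichment import ora_threshold


@dataclass
class CovModel:
    """A covariance matrix and its Cholesky factor for one network-pair."""

    omega: np.ndarray  # (R, R)
    chol: np.ndarray  # lower triangular, chol @ chol.T == omega
    shrinkage: float  # Ledoit-Wolf shrinkage intensity in [0, 1]
    source_size: int | None = None  # subjects used in estimation

    @property
    def n_pairs(self) -> int:
        return int(self.omega.shape[0])

    @classmethod
    def from_matrix(cls, omega: np.ndarray, shrinkage: float = 0.0,
                    source_size: int | None = None) -> "CovModel":
        omega = np.asarray(omega, dtype=float)
        try:
            chol = linalg.cholesky(omega, lower=True)
        except linalg.LinAlgError as err:
            raise ValueError("covariance matrix is not positive definite") from err
        return cls(omega=omega, chol=chol, shrinkage=shrinkage,
                   source_size=source_size)


@dataclass
class EffectSpec:
    """Mean and spread of per-ROI-pair regression coefficients."""

    mu: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class SimulatedDataset:
    """One draw of behavior, coefficients and connectivity."""

    x: np.ndarray  # (N,)
    b: np.ndarray  # (R,)
    f: np.ndarray  # (N, R)


def fit_cov_model(y: np.ndarray) -> CovModel:
    """Ledoit–Wolf covariance (scaled-identity target) of one network-pair.

    ``y`` is the (subjects x member-ROI-pairs) connectivity slice.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    sd = y.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant connectivity column(s) at positions {bad.tolist()}")
    lw = LedoitWolf(assume_centered=False).fit(y)
    return CovModel.from_matrix(
        lw.covariance_, shrinkage=float(lw.shrinkage_), source_size=y.shape[0]
    )


def simulate_dataset(
    cov: CovModel, n: int, eff: EffectSpec, rng: np.random.Generator
) -> SimulatedDataset:
    """Draw one dataset ``f = X B' + Z C'`` (B redrawn per dataset)."""
    if n < 3:
        raise ValueError("need n >= 3 subjects")
    R = cov.n_pairs
    b = rng.normal(eff.mu, eff.sigma, size=R)
    x = rng.standard_normal(n)
    z = rng.standard_normal((n, R))
    f = np.outer(x, b) + z @ cov.chol.T
    return SimulatedDataset(x=x, b=b, f=f)


def _screen_single_covariate(f: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, int]:
    """t statistics of each connectivity column on x, intercept-only nuisance."""
    n = x.size
    xc = x - x.mean()
    fc = f - f.mean(axis=0)
    sxx = xc @ xc
    b = (xc @ fc) / sxx
    rss = np.einsum("nr,nr->r", fc, fc) - b**2 * sxx
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b * np.sqrt(sxx) / np.sqrt(np.maximum(rss, 0.0) / df)
    return t, df


@dataclass
class PowerGrid:
    """Monte-Carlo power estimates keyed by (n, mu, sigma, alpha)."""

    table: pd.DataFrame  # columns n, mu, sigma, alpha, power, se, n_reps

    def power(self, n: int, mu: float, sigma: float, alpha: float) -> float:
        t = self.table
        row = t[
            (t.n == n) & (t.mu == mu) & (t.sigma == sigma) & (t.alpha == alpha)
        ]
        if row.empty:
            raise KeyError((n, mu, sigma, alpha))
        return float(row.power.iloc[0])


def estimate_power(
    cov: CovModel,
    grid,
    cutoffs: dict[float, int],
    n_reps: int = 500,
    seed: int = 0,
) -> PowerGrid:
    """ORA power over a grid of (n, mu, sigma, alpha) cells.

    ``grid`` iterates over (n, mu, sigma, alpha) tuples; ``cutoffs`` maps each
    alpha to the calibrated integer cutoff for this network-pair.  Cells whose
    cutoff is unattainable (cutoff > R) are reported with NaN power and a
    ``skipped`` reason rather than silently simulated.  Per-cell seeds derive
    from ``seed`` by enumeration order, so any cell is reproducible in
    isolation.
    """
    rows = []
    for cell_idx, (n, mu, sigma, alpha) in enumerate(grid):
        cutoff = cutoffs[alpha]
        if cutoff > cov.n_pairs:
            rows.append(
                dict(n=n, mu=mu, sigma=sigma, alpha=alpha, power=np.nan,
                     se=np.nan, n_reps=0, skipped="unattainable cutoff")
            )
            continue
        rng = np.random.default_rng((seed, cell_idx))
        eff = EffectSpec(mu=mu, sigma=sigma)
        hits = 0
        for _ in range(n_reps):
            sim = simulate_dataset(cov, n, eff, rng)
            t, df = _screen_single_covariate(sim.f, sim.x)
            thr = ora_threshold(alpha, df=df, mode="theoretical")
            count = int((t > thr).sum())
            hits += count >= cutoff
        p = hits / n_reps
        rows.append(
            dict(n=n, mu=mu, sigma=sigma, alpha=alpha, power=p,
                 se=float(np.sqrt(p * (1 - p) / n_reps)), n_reps=n_reps,
                 skipped="")
        )
    return PowerGrid(table=pd.DataFrame(rows))


def expected_r2(
    cov: CovModel, eff: EffectSpec, n_draws: int = 1000, seed: int = 0
) -> float:
    """Expected population R² of predicting behavior from connectivity.

    For fixed coefficients B the population multiple-R² of X on f is
    ``g / (1 + g)`` with ``g = B' Omega^{-1} B`` (X and f are jointly Gaussian
    with Var(X)=1, Cov(f)=BB'+Omega, Cov(f,X)=B; Sherman–Morrison gives the
    closed form).  The expectation is taken over B ~ N(mu, sigma²) by Monte
    Carlo; sigma = 0 needs a single draw.
    """
    rng = np.random.default_rng(seed)
    R = cov.n_pairs
    cho = (cov.chol, True)
    if eff.sigma == 0.0:
        n_draws = 1
    vals = np.empty(n_draws)
    for d in range(n_draws):
        b = rng.normal(eff.mu, eff.sigma, size=R)
        g = float(b @ linalg.cho_solve(cho, b))
        vals[d] = g / (1.0 + g)
    return float(vals.mean())


def univariate_power(
    b: float, noise_var: float, n: int, p_level: float = 1e-3
) -> float:
    """Power of the one-sided single-ROI-pair t test at level ``p_level``.

    Closed form via the noncentral t distribution: df = n - 2, noncentrality
    ``b * sqrt(n) / sqrt(noise_var)``, rejection above the upper ``p_level``
    t quantile.
    """
    if not 0.0 < p_level < 1.0:
        raise ValueError("p_level must lie in (0, 1)")
    if noise_var <= 0:
        raise ValueError("noise_var must be > 0")
    if n < 3:
        raise ValueError("need n >= 3")
    df = n - 2
    ncp = b * np.sqrt(n) / np.sqrt(noise_var)
    crit = stats.t.ppf(1.0 - p_level, df)
    return float(stats.nct.sf(crit, df, ncp))
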