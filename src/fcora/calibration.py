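"""Calibration of enrichment-count significance cutoffs.

Instead of running a permutation test for every new dataset, an integer
cutoff can be precomputed per (network-pair, covariate, alpha): the smallest
hit count whose permutation tail probability is at or below a target
significance level (default 1e-4, roughly Bonferroni for 91 network-pairs at
experiment-wide 0.05).  Cutoffs are estimated on many random-pairing null
datasets — connectivity matrices paired with behavior rows at random, which
breaks every connectivity–behavior and connectivity–nuisance association —
and a quantile (default the 75th) of the resulting cutoff distribution is
selected.  Small network-pairs may be unable to reach the target at all and
are flagged unattainable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import NetworkPair, RoiPairIndex
from .enrichment import OraConfig
from .permutation import PermutationScheme, permutation_counts
from .screening import mass_univariate_screen
from .enrichment import ora_counts


def min_attainable_tail(size: int, alpha: float) -> float:
    """Smallest possible null tail probability for a network-pair.

    Under independence the most extreme outcome is all ``size`` members
    hitting at once, with probability ``(1 - alpha)^size``; no count can have
    a smaller tail.  A network-pair whose minimum exceeds the target can never
    reach significance at that threshold quantile.
    """
    return (1.0 - alpha) ** size


@dataclass
class RandomPairingNull:
    """One null dataset built by randomly pairing connectivity with behavior."""

    y: np.ndarray  # (n, R)
    subjects: pd.DataFrame  # n behavior rows (reindexed)
    fc_rows: np.ndarray  # indices into the connectivity pool
    behavior_rows: np.ndarray  # indices into the behavior pool


def random_pairing_null(
    fc_pool: np.ndarray,
    behavior_pool: pd.DataFrame,
    n: int,
    rng: np.random.Generator,
) -> RandomPairingNull:
    """Sample ``n`` connectivity rows and ``n`` behavior rows (each without
    replacement) and join them by a uniform random matching."""
    fc_pool = np.asarray(fc_pool, dtype=float)
    if n > fc_pool.shape[0]:
        raise ValueError(f"n={n} exceeds connectivity pool size {fc_pool.shape[0]}")
    if n > len(behavior_pool):
        raise ValueError(f"n={n} exceeds behavior pool size {len(behavior_pool)}")
    fc_rows = rng.choice(fc_pool.shape[0], size=n, replace=False)
    beh_rows = rng.choice(len(behavior_pool), size=n, replace=False)
    # the matching itself: permute one side relative to the other
    matching = rng.permutation(n)
    fc_rows = fc_rows[matching]
    return RandomPairingNull(
        y=fc_pool[fc_rows],
        subjects=behavior_pool.iloc[beh_rows].reset_index(drop=True),
        fc_rows=fc_rows,
        behavior_rows=beh_rows,
    )


def cutoff_from_perm_counts(
    perm_counts: np.ndarray,
    sizes: np.ndarray,
    target_p: float,
    include_identity: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Smallest count k with permutation-estimated P(count >= k) <= target_p.

    Returns ``(cutoffs, attainable)`` per network-pair; an unattainable cell
    carries the sentinel ``size + 1`` (which no observed count can reach).
    """
    P, n_np = perm_counts.shape
    denom = P if include_identity else P + 1
    offset = 0 if include_identity else 1
    if 1.0 / denom > target_p:
        raise ValueError(
            f"resolution too coarse: {1.0/denom:.2e} > target_p={target_p:.2e}; "
            "increase the number of permutations"
        )
    cutoffs = np.empty(n_np, dtype=np.intp)
    attainable = np.empty(n_np, dtype=bool)
    for p_id in range(n_np):
        S = int(sizes[p_id])
        sorted_counts = np.sort(perm_counts[:, p_id])
        ks = np.arange(1, S + 1)
        m = P - np.searchsorted(sorted_counts, ks, side="left")
        tails = (offset + m) / denom
        ok = tails <= target_p
        if ok.any():
            cutoffs[p_id] = ks[int(np.argmax(ok))]
            attainable[p_id] = True
        else:
            cutoffs[p_id] = S + 1
            attainable[p_id] = False
    return cutoffs, attainable


def cutoff_for_dataset(
    y: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    index: RoiPairIndex,
    cfg: OraConfig,
    scheme: PermutationScheme,
    target_p: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-network-pair integer cutoffs for one (null) dataset.

    Runs the Freedman–Lane permutation distribution of enrichment counts for
    every covariate and inverts its tail at ``target_p``.  Returns arrays of
    shape (n_network_pairs, K): cutoffs and attainability flags.
    """
    K = np.atleast_2d(X2).shape[1]
    sizes = index.sizes
    cutoffs = np.empty((index.n_network_pairs, K), dtype=np.intp)
    attainable = np.empty((index.n_network_pairs, K), dtype=bool)
    for k in range(K):
        counts = permutation_counts(y, X1, X2, index, cfg, scheme, k)
        cutoffs[:, k], attainable[:, k] = cutoff_from_perm_counts(
            counts, sizes, target_p, include_identity=scheme.include_identity
        )
    return cutoffs, attainable


@dataclass
class CutoffTable:
    """Calibrated cutoffs per (alpha, network-pair, covariate).

    ``cutoffs[a, p, k]`` is the selected integer cutoff; unattainable cells
    carry the ``size + 1`` sentinel and ``attainable[a, p, k] = False``.
    ``pair_attainable[p]`` is the pair-level rule used for exclusion: a
    network-pair is retained only if it is attainable at *every* alpha and
    covariate (a pair that cannot reach the target for at least one threshold
    level is excluded from the analysis, as small pairs are).
    """

    alphas: tuple[float, ...]
    covariates: tuple[str, ...]
    network_pairs: tuple[NetworkPair, ...]
    cutoffs: np.ndarray  # (n_alpha, n_np, K) int
    attainable: np.ndarray  # (n_alpha, n_np, K) bool
    target_p: float
    quantile: float
    n_null: int
    n_perm: int

    @property
    def pair_attainable(self) -> np.ndarray:
        return self.attainable.all(axis=(0, 2))

    def unattainable_pairs(self) -> list[NetworkPair]:
        """Network-pairs unable to reach target_p for at least one alpha."""
        keep = self.pair_attainable
        return [p for p, ok in zip(self.network_pairs, keep) if not ok]

    def lookup(self, alpha: float, covariate: str) -> np.ndarray:
        a = self.alphas.index(alpha)
        k = self.covariates.index(covariate)
        return self.cutoffs[a, :, k]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, alpha in enumerate(self.alphas):
            for p_id, pair in enumerate(self.network_pairs):
                for k, cov in enumerate(self.covariates):
                    rows.append(
                        {
                            "net_i": pair.i,
                            "net_j": pair.j,
                            "covariate": cov,
                            "alpha": alpha,
                            "target_p": self.target_p,
                            "quantile": self.quantile,
                            "cutoff": int(self.cutoffs[a, p_id, k]),
                            "attainable": bool(self.attainable[a, p_id, k]),
                            "n_null": self.n_null,
                            "n_perm": self.n_perm,
                        }
                    )
        return pd.DataFrame(rows)


def select_cutoffs(
    per_dataset_cutoffs: np.ndarray,
    sizes: np.ndarray,
    q: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-rank q-quantile of per-dataset cutoffs (integer, no interpolation).

    ``per_dataset_cutoffs`` has shape (D, n_np, K) (sentinel ``S+1`` allowed).
    Returns the selected cutoffs (n_np, K) and attainability flags (selected
    cutoff <= S).
    """
    arr = np.asarray(per_dataset_cutoffs)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("need a (D, n_network_pairs, K) cutoff stack with D >= 1")
    D = arr.shape[0]
    idx = max(int(math.ceil(q * D)) - 1, 0)
    selected = np.sort(arr, axis=0)[idx]
    attainable = selected <= np.asarray(sizes)[:, None]
    return selected, attainable


def calibrate_cutoffs(
    fc_pool: np.ndarray,
    behavior_pool: pd.DataFrame,
    build_design,
    index: RoiPairIndex,
    alphas=(0.5,),
    mode: str = "theoretical",
    target_p: float = 1e-4,
    quantile: float = 0.75,
    n_null: int = 200,
    n_perm: int = 10_000,
    n_subjects: int | None = None,
    seed: int = 0,
) -> CutoffTable:
    """End-to-end cutoff calibration on random-pairing null datasets.

    ``build_design`` maps a behavior DataFrame to ``(X1, X2, covariate_names)``
    so that nuisance handling matches the intended analysis.  Desk-scale
    defaults (n_null=200, n_perm=1e4) keep a laptop run tractable; pass larger
    values for production calibration.
    """
    rng = np.random.default_rng(seed)
    n = n_subjects or min(fc_pool.shape[0], len(behavior_pool))
    stacks = {alpha: [] for alpha in alphas}
    covariate_names = None
    for _ in range(n_null):
        null = random_pairing_null(fc_pool, behavior_pool, n, rng)
        X1, X2, covariate_names = build_design(null.subjects)
        scheme = PermutationScheme.random(
            n, n_perm, seed=int(rng.integers(2**31 - 1))
        )
        for alpha in alphas:
            cfg = OraConfig(alpha=alpha, mode=mode)
            c, _ = cutoff_for_dataset(null.y, X1, X2, index, cfg, scheme, target_p)
            stacks[alpha].append(c)
    n_alpha, n_np = len(alphas), index.n_network_pairs
    K = len(covariate_names)
    cutoffs = np.empty((n_alpha, n_np, K), dtype=np.intp)
    attainable = np.empty((n_alpha, n_np, K), dtype=bool)
    for a, alpha in enumerate(alphas):
        cutoffs[a], attainable[a] = select_cutoffs(
            np.stack(stacks[alpha]), index.sizes, q=quantile
        )
    return CutoffTable(
        alphas=tuple(alphas),
        covariates=tuple(covariate_names),
        network_pairs=index.network_pairs,
        cutoffs=cutoffs,
        attainable=attainable,
        target_p=target_p,
        quantile=quantile,
        n_null=n_null,
        n_perm=n_perm,
    )


def exclude_small_network_pairs(
    pairs, min_size: int = 50
) -> tuple[list, list]:
    """Split network-pairs into (retained, removed) by member count.

    The default ``min_size=50`` mirrors the observation that ORA cannot reach
    Bonferroni-level significance in pairs with fewer than ~50 ROI-pairs.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    retained = [p for p in pairs if p.size >= min_size]
    removed = [p for p in pairs if p.size < min_size]
    return retained, removed


@dataclass
class FprReport:
    """Empirical false-positive rates of a set of cutoffs on null data."""

    fpr: np.ndarray  # per-cell rejection fraction
    se: np.ndarray  # binomial standard errors
    n_reps: int

    @property
    def mean(self) -> float:
        return float(self.fpr.mean())

    @property
    def mean_se(self) -> float:
        # s.e. of the across-cell mean, treating cells as a fixed family
        return float(np.sqrt((self.se**2).sum()) / self.se.size)


def validate_fpr(
    cutoffs: np.ndarray,
    null_generator,
    index: RoiPairIndex,
    cfg: OraConfig,
    n_reps: int,
) -> FprReport:
    """Fraction of null datasets whose observed count reaches the cutoff.

    ``null_generator(rep) -> (y, X1, X2)`` must yield independent null
    datasets; ``cutoffs`` has shape (n_network_pairs, K).  No permutations are
    run — this is the whole point of precalibrated cutoffs.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cutoffs = np.asarray(cutoffs)
    hits = np.zeros(cutoffs.shape, dtype=np.intp)
    for rep in range(n_reps):
        y, X1, X2 = null_generator(rep)
        screen = mass_univariate_screen(y, X1, X2)
        counts = ora_counts(screen, index, cfg).counts
        hits += counts >= cutoffs
    fpr = hits / n_reps
    se = np.sqrt(fpr * (1 - fpr) / n_reps)
    return FprReport(fpr=fpr, se=se, n_reps=n_reps)
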