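"""Over-representation (ORA) enrichment statistics.

Screening t statistics are binarized at a threshold quantile ``alpha`` and the
enrichment statistic of a network-pair is simply the number of member
ROI-pairs whose statistic exceeds the threshold ("hits").  ``alpha = 0.50``
with the theoretical null means any positive statistic is a hit;
``alpha = 0.95`` counts the top 5%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RoiPairIndex
from .screening import ScreeningResult

#: Default threshold grid for studies and power simulations: 10 values from
#: 0.50 to 0.95.
DEFAULT_ALPHA_GRID = tuple(np.round(np.linspace(0.50, 0.95, 10), 2))


@dataclass
class OraConfig:
    """Hit-threshold configuration.

    mode "theoretical" cuts at the alpha-quantile of the null t(df)
    distribution; "empirical" cuts at the nearest-rank alpha-quantile of the
    brain-wide screening statistics for the covariate at hand.
    """

    alpha: float = 0.95
    mode: str = "theoretical"
    threshold_value: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.mode not in ("theoretical", "empirical"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")


def nearest_rank_quantile(values: np.ndarray, alpha: float) -> float:
    """Nearest-rank (no interpolation) alpha-quantile of finite values."""
    finite = np.sort(values[np.isfinite(values)])
    if finite.size == 0:
        raise ValueError("no finite values to take a quantile of")
    idx = max(int(math.ceil(alpha * finite.size)) - 1, 0)
    return float(finite[idx])


def ora_threshold(
    alpha: float,
    df: int | None = None,
    mode: str = "theoretical",
    statistics: np.ndarray | None = None,
) -> float:
    """Realized cut point on the t scale for quantile ``alpha``.

    Theoretical mode needs ``df``; empirical mode needs the brain-wide
    ``statistics`` for the covariate.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if mode == "theoretical":
        if df is None or df < 1:
            raise ValueError("theoretical threshold requires df >= 1")
        return float(stats.t.ppf(alpha, df))
    if mode == "empirical":
        if statistics is None:
            raise ValueError("empirical threshold requires the screening statistics")
        return nearest_rank_quantile(np.asarray(statistics, dtype=float), alpha)
    raise ValueError(f"unknown threshold mode {mode!r}")


@dataclass
class EnrichmentCounts:
    """Hit counts per (network-pair, covariate) at one alpha."""

    counts: np.ndarray  # (n_network_pairs, K) int
    alpha: float
    df: int
    thresholds: np.ndarray  # (K,) realized cut points

    def to_frame(self, index: RoiPairIndex, covariates: list[str]) -> pd.DataFrame:
        rows = []
        for p_id, pair in enumerate(index.network_pairs):
            for k, cov in enumerate(covariates):
                rows.append(
                    {
                        "net_i": pair.i,
                        "net_j": pair.j,
                        "size": pair.size,
                        "covariate": cov,
                        "alpha": self.alpha,
                        "count": int(self.counts[p_id, k]),
                    }
                )
        return pd.DataFrame(rows)


def count_hits(
    tcol: np.ndarray,
    index: RoiPairIndex,
    threshold: float,
) -> np.ndarray:
    """Hit count per network-pair for one covariate's t column.

    Strict ``t > threshold``; NaN (degenerate) statistics count as misses.
    """
    with np.errstate(invalid="ignore"):
        hits = tcol > threshold
    return np.bincount(
        index.pair_to_network_pair[hits], minlength=index.n_network_pairs
    ).astype(np.intp)


def ora_counts(
    screen: ScreeningResult, index: RoiPairIndex, cfg: OraConfig
) -> EnrichmentCounts:
    """Enrichment counts for every covariate at the configured threshold."""
    if screen.n_pairs != index.n_pairs:
        raise ValueError("screening result and ROI-pair index are misaligned")
    K = screen.n_covariates
    counts = np.zeros((index.n_network_pairs, K), dtype=np.intp)
    thresholds = np.zeros(K)
    for k in range(K):
        thr = ora_threshold(
            cfg.alpha,
            df=screen.df,
            mode=cfg.mode,
            statistics=screen.tstats[:, k] if cfg.mode == "empirical" else None,
        )
        thresholds[k] = thr
        counts[:, k] = count_hits(screen.tstats[:, k], index, thr)
    cfg.threshold_value = float(thresholds[0]) if K else None
    return EnrichmentCounts(counts=counts, alpha=cfg.alpha, df=screen.df, thresholds=thresholds)
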