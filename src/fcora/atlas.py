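"""Atlas parsing and ROI-pair / network-pair topology.

An atlas assigns each region of interest (ROI) to exactly one functional
network.  The unit of inference for enrichment analysis is the *network-pair*
``N_ij``: the set of all unordered ROI-pairs with one ROI in network ``i`` and
the other in network ``j`` (``i == j`` gives a within-network pair).  This
module owns the one vectorization convention used everywhere else: ROI-pairs
are ordered row-major over the strict upper triangle of the ROI x ROI matrix,
0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: ROIs carrying this network label are dropped before pair enumeration
#: (e.g. parcels excluded for insufficient SNR).
EXCLUDED_LABEL = "excluded"


@dataclass(frozen=True)
class Atlas:
    """ROI -> functional network assignment.

    Networks are kept in first-appearance order of the source table; that
    order is canonical for network-pair ids.
    """

    roi_ids: tuple[str, ...]
    network_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.roi_ids) == 0:
            raise ValueError("atlas has no ROIs")
        if len(self.roi_ids) != len(self.network_labels):
            raise ValueError("roi_ids and network_labels length mismatch")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            dupes = pd.Series(self.roi_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate roi_id entries: {dupes}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def networks(self) -> tuple[str, ...]:
        """Distinct network labels in first-appearance (canonical) order."""
        return tuple(dict.fromkeys(self.network_labels))

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def network_index(self) -> np.ndarray:
        """Per-ROI integer network id in canonical order."""
        lookup = {lab: i for i, lab in enumerate(self.networks)}
        return np.array([lookup[lab] for lab in self.network_labels], dtype=np.intp)


def load_atlas(path) -> Atlas:
    """Read a TSV with columns ``roi_id`` and ``network_label``.

    Optional extra columns (e.g. x, y, z coordinates) are ignored.  ROIs
    labelled :data:`EXCLUDED_LABEL` are dropped before pair enumeration.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.empty:
        raise ValueError(f"atlas file {path} is empty")
    for col in ("roi_id", "network_label"):
        if col not in table.columns:
            raise ValueError(f"atlas file {path} lacks required column {col!r}")
    table = table[table["network_label"] != EXCLUDED_LABEL]
    if table.empty:
        raise ValueError(f"atlas file {path} has no non-excluded ROIs")
    return Atlas(
        roi_ids=tuple(table["roi_id"]),
        network_labels=tuple(table["network_label"]),
    )


def _pair_rank(i: np.ndarray, j: np.ndarray, k: int) -> np.ndarray:
    """Row-major rank of (i, j), i <= j, in the upper triangle incl. diagonal."""
    return i * k - (i * (i - 1)) // 2 + (j - i)


@dataclass(frozen=True)
class NetworkPair:
    """One unordered pair of networks and its member ROI-pairs."""

    i: str
    j: str
    members: np.ndarray = field(repr=False)  # positions into RoiPairIndex

    @property
    def name(self) -> str:
        return f"{self.i}-{self.j}"

    @property
    def size(self) -> int:
        return int(self.members.size)


@dataclass(frozen=True)
class RoiPairIndex:
    """Enumeration of all unordered ROI-pairs and their network-pair ids.

    ``pairs[p] = (a, b)`` with ``a < b`` in atlas order; ``pair_to_network_pair[p]``
    is the canonical network-pair id of pair ``p``.
    """

    atlas: Atlas
    pairs: np.ndarray = field(repr=False)  # (R, 2) intp
    pair_to_network_pair: np.ndarray = field(repr=False)  # (R,) intp
    network_pairs: tuple[NetworkPair, ...] = field(repr=False)

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])

    @property
    def n_network_pairs(self) -> int:
        return len(self.network_pairs)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([np_.size for np_ in self.network_pairs], dtype=np.intp)

    def pair_labels(self) -> list[str]:
        """``roiA|roiB`` labels in vectorization order."""
        ids = self.atlas.roi_ids
        return [f"{ids[a]}|{ids[b]}" for a, b in self.pairs]

    def vectorize(self, matrix: np.ndarray) -> np.ndarray:
        """Strict-upper-triangle values of a square ROI x ROI matrix."""
        n = self.atlas.n_rois
        if matrix.shape != (n, n):
            raise ValueError(f"expected a {n} x {n} matrix, got {matrix.shape}")
        return matrix[self.pairs[:, 0], self.pairs[:, 1]]

    def devectorize(self, values: np.ndarray, diagonal: float = 0.0) -> np.ndarray:
        """Rebuild the symmetric matrix from a vector of pair values."""
        if values.shape != (self.n_pairs,):
            raise ValueError("value vector length does not match index")
        n = self.atlas.n_rois
        out = np.full((n, n), float(diagonal))
        out[self.pairs[:, 0], self.pairs[:, 1]] = values
        out[self.pairs[:, 1], self.pairs[:, 0]] = values
        return out


def build_roi_pair_index(atlas: Atlas) -> RoiPairIndex:
    """Enumerate all ROI-pairs and partition them into network-pairs."""
    n = atlas.n_rois
    k = atlas.n_networks
    rows, cols = np.triu_indices(n, k=1)  # row-major over the strict upper triangle
    pairs = np.column_stack([rows, cols]).astype(np.intp)

    net = atlas.network_index()
    ni, nj = net[rows], net[cols]
    lo, hi = np.minimum(ni, nj), np.maximum(ni, nj)
    pair_to_np = _pair_rank(lo, hi, k)

    networks = atlas.networks
    network_pairs = []
    for i in range(k):
        for j in range(i, k):
            np_id = _pair_rank(np.array(i), np.array(j), k)
            members = np.flatnonzero(pair_to_np == np_id)
            network_pairs.append(
                NetworkPair(i=networks[i], j=networks[j], members=members)
            )
    return RoiPairIndex(
        atlas=atlas,
        pairs=pairs,
        pair_to_network_pair=pair_to_np,
        network_pairs=tuple(network_pairs),
    )


def enumerate_network_pairs(atlas: Atlas) -> list[NetworkPair]:
    """All k(k+1)/2 network-pairs (within-network pairs included)."""
    return list(build_roi_pair_index(atlas).network_pairs)


def network_pair_report(index: RoiPairIndex) -> pd.DataFrame:
    """Tidy ``net_i, net_j, size`` table of network-pair sizes."""
    return pd.DataFrame(
        {
            "net_i": [p.i for p in index.network_pairs],
            "net_j": [p.j for p in index.network_pairs],
            "size": [p.size for p in index.network_pairs],
        }
    )
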