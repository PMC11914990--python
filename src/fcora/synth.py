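"""Synthetic atlases, connectivity, behaviors and nuisance variables.

Stands in for restricted study data so the whole pipeline is runnable and
testable offline.  The default study emulates the scale of a multi-site
school-age neuroimaging sample: 230 ROIs over 13 functional networks
(91 network-pairs), N = 105 subjects, six behavioral covariates with the
distribution shapes behavioral instruments actually produce (Gaussian,
uniform, thresholded Gaussian, zero-inflated, long-tailed), and nuisance
variables age (continuous), sex (binary) and scan site (4-level categorical).

Connectivity is simulated directly at the ROI-pair level: ROI-pair values
within the same network-pair share an exchangeable correlation ``rho_block``,
values in different network-pairs share ``rho_base``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import Atlas, RoiPairIndex, build_roi_pair_index
from .power import CovModel

#: Default 13-network composition (sums to 230 ROIs).  Chosen so that, like
#: the reference school-age atlas, exactly 19 of the 91 network-pairs have
#: fewer than 50 member ROI-pairs and the smallest within-network pair has
#: 6 ROI-pairs (a 4-ROI network).
DEFAULT_COMPOSITION = (45, 40, 30, 27, 20, 18, 14, 8, 7, 7, 6, 4, 4)

#: Placeholder correlation magnitudes for the exchangeable block model; the
#: real data's within-network-pair correlations are not published.
DEFAULT_RHO_BLOCK = 0.3
DEFAULT_RHO_BASE = 0.05


@dataclass
class BehaviorSpec:
    """One behavioral covariate: a named marginal distribution."""

    name: str
    kind: str = "gaussian"  # gaussian | uniform | thresholded_gaussian |
    #                         zero_inflated | long_tailed
    threshold: float = 0.0  # thresholded_gaussian floor (on the z scale)
    p_zero: float = 0.3  # zero_inflated point mass
    log_sigma: float = 1.0  # long_tailed (log-normal) shape

    _KINDS = ("gaussian", "uniform", "thresholded_gaussian", "zero_inflated",
              "long_tailed")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown behavior kind {self.kind!r}")


DEFAULT_BEHAVIORS = (
    BehaviorSpec("social_affect", "thresholded_gaussian", threshold=-0.5),
    BehaviorSpec("repetitive_behavior", "zero_inflated", p_zero=0.3),
    BehaviorSpec("motor_skill", "gaussian"),
    BehaviorSpec("anxiety", "long_tailed", log_sigma=0.6),
    BehaviorSpec("nonverbal_iq", "gaussian"),
    BehaviorSpec("inattention", "uniform"),
)


@dataclass
class SyntheticStudySpec:
    """Everything needed to generate one reproducible synthetic study."""

    rois_per_network: tuple[int, ...] = DEFAULT_COMPOSITION
    n_subjects: int = 105
    behaviors: tuple[BehaviorSpec, ...] = DEFAULT_BEHAVIORS
    n_sites: int = 4
    sex_proportion: float = 0.5
    age_range: tuple[float, float] = (8.0, 12.0)
    rho_block: float = DEFAULT_RHO_BLOCK
    rho_base: float = DEFAULT_RHO_BASE
    var_scale: float = 1.0
    seed: int = 0


def make_synthetic_atlas(
    n_networks: int = 13,
    rois_per_network=DEFAULT_COMPOSITION,
    seed: int = 0,
) -> Atlas:
    """Deterministic atlas with the requested per-network ROI counts."""
    sizes = list(rois_per_network)
    if len(sizes) != n_networks:
        raise ValueError("rois_per_network length must equal n_networks")
    if any(s < 1 for s in sizes):
        raise ValueError("every network needs at least one ROI")
    roi_ids, labels = [], []
    counter = 1
    for i, s in enumerate(sizes):
        net = f"net{i + 1:02d}"
        for _ in range(s):
            roi_ids.append(f"roi{counter:04d}")
            labels.append(net)
            counter += 1
    return Atlas(roi_ids=tuple(roi_ids), network_labels=tuple(labels))


def make_block_covariance(
    index: RoiPairIndex,
    rho_block: float = DEFAULT_RHO_BLOCK,
    rho_base: float = DEFAULT_RHO_BASE,
    var_scale: float = 1.0,
    max_pairs: int = 4000,
) -> CovModel:
    """Dense exchangeable-block covariance over all ROI-pairs.

    Unit variances scaled by ``var_scale``; correlation ``rho_block`` within a
    network-pair block, ``rho_base`` across blocks.  Positive definiteness is
    verified by attempted factorization.  For large atlases (R > ``max_pairs``)
    build the matrix per network-pair or sample via
    :func:`sample_connectivity`, which never forms the dense matrix.
    """
    R = index.n_pairs
    if R > max_pairs:
        raise ValueError(
            f"R={R} ROI-pairs would need a dense {R}x{R} matrix; "
            "use sample_connectivity for full-brain studies"
        )
    p2np = index.pair_to_network_pair
    same_block = p2np[:, None] == p2np[None, :]
    omega = np.where(same_block, rho_block, rho_base) * var_scale
    np.fill_diagonal(omega, var_scale)
    try:
        return CovModel.from_matrix(omega)
    except ValueError as err:
        raise ValueError(
            "requested block covariance is not positive definite; need "
            "0 <= rho_base <= rho_block < 1 (strictly below 1 within blocks)"
        ) from err


def sample_connectivity(
    index: RoiPairIndex,
    n: int,
    rng: np.random.Generator,
    rho_block: float = DEFAULT_RHO_BLOCK,
    rho_base: float = DEFAULT_RHO_BASE,
    var_scale: float = 1.0,
) -> np.ndarray:
    """Draw (n x R) connectivity with the exchangeable block structure.

    Uses the latent-factor construction
    ``y = sqrt(rho_base) g0 + sqrt(rho_block - rho_base) g_block +
    sqrt(1 - rho_block) eps`` so no dense R x R matrix is ever formed;
    requires ``0 <= rho_base <= rho_block < 1``.
    """
    if not (0.0 <= rho_base <= rho_block < 1.0):
        raise ValueError("need 0 <= rho_base <= rho_block < 1")
    R = index.n_pairs
    p2np = index.pair_to_network_pair
    g0 = rng.standard_normal((n, 1))
    gb = rng.standard_normal((n, index.n_network_pairs))
    eps = rng.standard_normal((n, R))
    y = (
        np.sqrt(rho_base) * g0
        + np.sqrt(rho_block - rho_base) * gb[:, p2np]
        + np.sqrt(1.0 - rho_block) * eps
    )
    return y * np.sqrt(var_scale)


def make_behaviors(
    n: int, specs, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Behavior columns with the requested marginal shapes.

    Returns the table and, for point-mass kinds, the realized point-mass
    fraction per column.
    """
    cols = {}
    mass = {}
    for spec in specs:
        if spec.kind == "gaussian":
            x = rng.standard_normal(n)
        elif spec.kind == "uniform":
            x = rng.uniform(-np.sqrt(3), np.sqrt(3), n)  # unit variance
        elif spec.kind == "thresholded_gaussian":
            x = np.maximum(rng.standard_normal(n), spec.threshold)
            mass[spec.name] = float(np.mean(x == spec.threshold))
        elif spec.kind == "zero_inflated":
            tail = rng.lognormal(0.0, 0.5, n)
            zero = rng.random(n) < spec.p_zero
            x = np.where(zero, 0.0, tail)
            mass[spec.name] = float(np.mean(x == 0.0))
        elif spec.kind == "long_tailed":
            x = rng.lognormal(0.0, spec.log_sigma, n)
        else:  # pragma: no cover - guarded in BehaviorSpec
            raise ValueError(spec.kind)
        cols[spec.name] = x
    return pd.DataFrame(cols), mass


def make_nuisance(
    n: int,
    rng: np.random.Generator,
    n_sites: int = 4,
    sex_proportion: float = 0.5,
    age_range: tuple[float, float] = (8.0, 12.0),
) -> pd.DataFrame:
    """Age (uniform), sex (Bernoulli) and site (uniform categorical) columns."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return pd.DataFrame(
        {
            "age": rng.uniform(age_range[0], age_range[1], n),
            "sex": (rng.random(n) < sex_proportion).astype(int),
            "site": [f"site{int(s) + 1}" for s in rng.integers(0, n_sites, n)],
        }
    )


@dataclass
class SyntheticStudy:
    """A complete synthetic dataset: atlas, connectivity, subject table."""

    spec: SyntheticStudySpec
    atlas: Atlas
    index: RoiPairIndex
    connectivity: np.ndarray  # (N, R)
    subjects: pd.DataFrame  # subject_id + behaviors + nuisance
    behavior_names: tuple[str, ...]
    point_mass: dict[str, float] = field(default_factory=dict)


def make_study(spec: SyntheticStudySpec) -> SyntheticStudy:
    """Generate a full null study (no embedded connectivity/behavior effect).

    Deterministic in ``spec.seed``; connectivity and behaviors are
    independent, so any downstream association is a false positive.
    """
    rng = np.random.default_rng(spec.seed)
    atlas = make_synthetic_atlas(len(spec.rois_per_network), spec.rois_per_network)
    index = build_roi_pair_index(atlas)
    y = sample_connectivity(
        index, spec.n_subjects, rng,
        rho_block=spec.rho_block, rho_base=spec.rho_base,
        var_scale=spec.var_scale,
    )
    behaviors, mass = make_behaviors(spec.n_subjects, spec.behaviors, rng)
    nuisance = make_nuisance(
        spec.n_subjects, rng, n_sites=spec.n_sites,
        sex_proportion=spec.sex_proportion, age_range=spec.age_range,
    )
    subjects = pd.concat(
        [
            pd.DataFrame({"subject_id": [f"sub{i + 1:04d}" for i in range(spec.n_subjects)]}),
            behaviors,
            nuisance,
        ],
        axis=1,
    )
    return SyntheticStudy(
        spec=spec,
        atlas=atlas,
        index=index,
        connectivity=y,
        subjects=subjects,
        behavior_names=tuple(b.name for b in spec.behaviors),
        point_mass=mass,
    )


def embed_effect(
    study: SyntheticStudy,
    network_pair_id: int,
    mu: float,
    sigma: float,
    behavior: str | None = None,
    seed: int = 0,
) -> SyntheticStudy:
    """Return a copy of the study with an effect added to one network-pair.

    Coefficients ``B ~ N(mu, sigma^2)`` link the (standardized) chosen
    behavior to each member ROI-pair: ``y_members += x_std B'``.
    """
    rng = np.random.default_rng(seed)
    behavior = behavior or study.behavior_names[0]
    x = study.subjects[behavior].to_numpy(dtype=float)
    x_std = (x - x.mean()) / x.std()
    members = study.index.network_pairs[network_pair_id].members
    b = rng.normal(mu, sigma, size=members.size)
    y = study.connectivity.copy()
    y[:, members] += np.outer(x_std, b)
    return SyntheticStudy(
        spec=study.spec,
        atlas=study.atlas,
        index=study.index,
        connectivity=y,
        subjects=study.subjects,
        behavior_names=study.behavior_names,
        point_mass=study.point_mass,
    )
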