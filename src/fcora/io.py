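"""File readers/writers, run configuration and the end-to-end pipeline.

Connectivity input dialects:

* a directory of per-subject square symmetric matrices (whitespace- or
  tab-delimited text, filename stem = subject id); or
* one stacked subjects x ROI-pairs TSV with a ``subject_id`` column and a
  header of ``roiA|roiB`` pair labels.

Both are vectorized by the canonical row-major upper-triangle convention of
:class:`~fcora.atlas.RoiPairIndex`.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import Atlas, RoiPairIndex, build_roi_pair_index, load_atlas
from .enrichment import OraConfig
from .permutation import PermutationScheme, enrichment_pvalues
from .screening import build_design, mass_univariate_screen
from .calibration import exclude_small_network_pairs

log = logging.getLogger("fcora")

_SYMMETRY_ATOL = 1e-8


@dataclass
class ConnectivityTable:
    """Subjects x ROI-pairs connectivity values in canonical pair order."""

    values: np.ndarray  # (N, R)
    subject_ids: list[str]
    index: RoiPairIndex


def _read_square_matrix(path: Path, index: RoiPairIndex) -> np.ndarray:
    mat = np.loadtxt(path)
    n = index.atlas.n_rois
    if mat.shape != (n, n):
        raise ValueError(
            f"{path}: expected a {n}x{n} matrix for this atlas, got {mat.shape}"
        )
    asym = np.abs(mat - mat.T).max()
    if asym > _SYMMETRY_ATOL:
        raise ValueError(f"{path}: matrix asymmetric (max |A - A'| = {asym:.3g})")
    return index.vectorize(mat)


def read_connectivity(path, atlas: Atlas) -> ConnectivityTable:
    """Read connectivity from a directory of matrices or a stacked table."""
    path = Path(path)
    index = build_roi_pair_index(atlas)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise ValueError(f"no connectivity files in {path}")
        rows = [_read_square_matrix(f, index) for f in files]
        return ConnectivityTable(
            values=np.vstack(rows),
            subject_ids=[f.stem for f in files],
            index=index,
        )
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "subject_id" not in table.columns:
        raise ValueError(f"{path}: stacked table needs a subject_id column")
    labels = [c for c in table.columns if c != "subject_id"]
    expected = index.pair_labels()
    if set(labels) != set(expected):
        missing = sorted(set(expected) - set(labels))[:5]
        extra = sorted(set(labels) - set(expected))[:5]
        raise ValueError(
            f"{path}: pair labels do not match the atlas "
            f"(missing e.g. {missing}, unexpected e.g. {extra})"
        )
    values = table[expected].to_numpy(dtype=float)
    return ConnectivityTable(
        values=values,
        subject_ids=[str(s) for s in table["subject_id"]],
        index=index,
    )


def write_connectivity(path, conn_values: np.ndarray, subject_ids,
                       index: RoiPairIndex) -> None:
    """Write the stacked subjects x ROI-pairs dialect."""
    table = pd.DataFrame(conn_values, columns=index.pair_labels())
    table.insert(0, "subject_id", list(subject_ids))
    # %.17g keeps the write -> read round trip bit-exact for float64
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_atlas(path, atlas: Atlas) -> None:
    pd.DataFrame(
        {"roi_id": atlas.roi_ids, "network_label": atlas.network_labels}
    ).to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Configuration for one analysis run (YAML-loadable)."""

    atlas: str
    connectivity: str
    behaviors: str
    interest: list[str]
    nuisance_continuous: list[str] = field(default_factory=list)
    nuisance_binary: list[str] = field(default_factory=list)
    nuisance_categorical: list[str] = field(default_factory=list)
    alphas: list[float] = field(default_factory=lambda: [0.95])
    threshold_mode: str = "theoretical"
    n_perm: int = 10_000
    target_p: float = 1e-4
    min_pair_size: int = 50
    bonferroni: str | int | None = None  # "auto", an integer M, or None
    seed: int = 0
    out_dir: str = "fcora_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def align_subjects(
    conn: ConnectivityTable, subjects: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Intersect connectivity and behavior tables on subject id."""
    if "subject_id" not in subjects.columns:
        raise ValueError("behavior table needs a subject_id column")
    beh_ids = [str(s) for s in subjects["subject_id"]]
    common = [s for s in conn.subject_ids if s in set(beh_ids)]
    if not common:
        raise ValueError("no subjects shared between connectivity and behavior")
    conn_pos = {s: i for i, s in enumerate(conn.subject_ids)}
    beh_pos = {s: i for i, s in enumerate(beh_ids)}
    y = conn.values[[conn_pos[s] for s in common]]
    sub = subjects.iloc[[beh_pos[s] for s in common]].reset_index(drop=True)
    return y, sub, common


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """screen -> ORA -> permutation p-values; writes TSVs and a log.

    Returns a mapping of output names to file paths.  All randomness flows
    from ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    written: dict[str, Path] = {}
    try:
        atlas = load_atlas(config.atlas)
        conn = read_connectivity(config.connectivity, atlas)
        subjects = pd.read_csv(config.behaviors)
        y, sub, common = align_subjects(conn, subjects)
        log.info(
            "subjects: %d connectivity, %d behavior, %d aligned",
            len(conn.subject_ids), len(subjects), len(common),
        )
        design = build_design(
            sub,
            interest=config.interest,
            nuisance_continuous=config.nuisance_continuous,
            nuisance_binary=config.nuisance_binary,
            nuisance_categorical=config.nuisance_categorical,
        )
        y = y[design.retained_mask]
        n_dropped = int((~design.retained_mask).sum())
        log.info("complete-case filter dropped %d subjects", n_dropped)

        index = conn.index
        retained, removed = exclude_small_network_pairs(
            index.network_pairs, config.min_pair_size
        )
        log.info(
            "network-pairs: %d total, %d below size %d excluded from testing",
            index.n_network_pairs, len(removed), config.min_pair_size,
        )
        target_p = config.target_p
        if config.bonferroni is not None:
            m = (
                len(retained) * len(config.interest)
                if config.bonferroni == "auto"
                else int(config.bonferroni)
            )
            target_p = 0.05 / m
            log.info("Bonferroni target_p = 0.05 / %d = %.3g", m, target_p)

        screen = mass_univariate_screen(y, design.X1, design.X2)
        scheme = PermutationScheme.random(
            y.shape[0], config.n_perm, seed=config.seed
        )
        frames = []
        removed_names = {p.name for p in removed}
        for alpha in config.alphas:
            cfg = OraConfig(alpha=alpha, mode=config.threshold_mode)
            result = enrichment_pvalues(
                y, design.X1, design.X2, index, cfg, scheme,
                covariates=design.interest_names,
            )
            frame = result.to_frame(index, target_p=target_p)
            frame["tested"] = ~(frame.net_i + "-" + frame.net_j).isin(removed_names)
            frames.append(frame)
        enrich = pd.concat(frames, ignore_index=True)
        enrich_path = out / "enrichment.tsv"
        enrich.to_csv(enrich_path, sep="\t", index=False)
        written["enrichment"] = enrich_path

        sizes = pd.DataFrame(
            {
                "net_i": [p.i for p in index.network_pairs],
                "net_j": [p.j for p in index.network_pairs],
                "size": [p.size for p in index.network_pairs],
            }
        )
        sizes_path = out / "network_pairs.tsv"
        sizes.to_csv(sizes_path, sep="\t", index=False)
        written["network_pairs"] = sizes_path
        log.info("run complete: seed=%d, n_perm=%d", config.seed, config.n_perm)
        return written
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
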