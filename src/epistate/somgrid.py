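"""From-scratch online self-organizing map on a toroidal ("circular") grid,
plus feature preparation for multi-assay integration.

Default configuration mirrors the analysis setup: 10 x 10 wrap-around grid,
5000 training cycles, learning rate declining linearly from 0.09 to 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SOMConfig:
    rows: int = 10
    cols: int = 10
    toroidal: bool = True
    rlen: int = 5000
    alpha_start: float = 0.09
    alpha_end: float = 0.01
    neighborhood: str = "bubble"  # bubble | gaussian
    initial_radius: Optional[float] = None  # default: 2/3 quantile of grid distances
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols < 2:
            raise ValueError("grid must have at least 2 units")
        if self.rlen < 1:
            raise ValueError("rlen must be >= 1")
        if not (self.alpha_start > self.alpha_end > 0):
            raise ValueError("require alpha_start > alpha_end > 0")
        if self.neighborhood not in ("bubble", "gaussian"):
            raise ValueError("neighborhood must be bubble or gaussian")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols


@dataclass
class FeatureMatrix:
    """Region x feature matrix after transform + z-scaling.

    ``transforms`` records per-feature whether log2(x+1) was applied;
    ``centers``/``scales`` hold the scaling parameters so node summaries can
    be mapped back to the original scale.
    """

    values: pd.DataFrame
    transforms: Dict[str, str]
    centers: Dict[str, float]
    scales: Dict[str, float]

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature matrix contains non-finite values")


@dataclass
class SOMFit:
    config: SOMConfig
    codebook: np.ndarray  # (n_nodes, n_features)
    feature_names: list
    assignment: pd.Series  # region id -> node index
    qe_trajectory: list = field(default_factory=list)  # (cycle, mean QE)

    @property
    def n_nodes(self) -> int:
        return self.codebook.shape[0]

    def node_grid_position(self, node: int):
        return divmod(node, self.config.cols)


def prepare_features(
    datasets: Mapping[str, pd.Series],
    meth: Optional[Sequence] = None,
) -> FeatureMatrix:
    """Assemble the SOM input: log2(x+1) + z-scale for signal/accessibility/
    expression features, z-scale only for methylation.

    ``datasets`` maps feature name -> region-indexed Series; ``meth`` is a
    list of exprmeth.RegionMeth, or a mapping of feature name -> such a list
    when several methylation tracks enter. Regions lacking defined
    methylation are dropped (logged); constant features are dropped with a
    warning.
    """
    frame = pd.DataFrame({name: series for name, series in datasets.items()})
    transforms = {name: "log2(x+1)" for name in frame.columns}
    frame = np.log2(frame + 1.0)

    if meth is not None:
        meth_tracks = meth if isinstance(meth, Mapping) else {"5mC": meth}
        for name, track in meth_tracks.items():
            meth_series = pd.Series(
                {rm.region_id: rm.mean for rm in track if rm.defined}, name=name
            )
            before = len(frame)
            frame = frame.loc[frame.index.intersection(meth_series.index)]
            dropped = before - len(frame)
            if dropped:
                logger.info(
                    "prepare_features: dropped %d regions without defined %s", dropped, name
                )
            frame[name] = meth_series.loc[frame.index]
            transforms[name] = "identity"

    if frame.isna().any().any():
        raise ValueError("features do not share a complete region index")

    centers, scales = {}, {}
    keep = []
    for name in frame.columns:
        sd = float(frame[name].std(ddof=0))
        if sd == 0.0:
            logger.warning("prepare_features: dropping constant feature %s", name)
            del transforms[name]
            continue
        centers[name] = float(frame[name].mean())
        scales[name] = sd
        frame[name] = (frame[name] - centers[name]) / sd
        keep.append(name)
    return FeatureMatrix(values=frame[keep], transforms=transforms, centers=centers, scales=scales)


def grid_distances(config: SOMConfig) -> np.ndarray:
    """Pairwise node distances on the (optionally toroidal) grid."""
    rows = np.arange(config.n_nodes) // config.cols
    cols = np.arange(config.n_nodes) % config.cols
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    if config.toroidal:
        dr = np.minimum(dr, config.rows - dr)
        dc = np.minimum(dc, config.cols - dc)
    return np.sqrt(dr**2 + dc**2)


def _default_radius(dist: np.ndarray) -> float:
    return float(np.quantile(dist[np.triu_indices_from(dist, k=1)], 2.0 / 3.0))


def quantization_error(data: np.ndarray, codebook: np.ndarray) -> float:
    d = np.linalg.norm(data[:, None, :] - codebook[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


def best_matching_units(data: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(data[:, None, :] - codebook[None, :, :], axis=2)
    return d.argmin(axis=1)


def train_som(features: FeatureMatrix, config: SOMConfig = SOMConfig()) -> SOMFit:
    """Online SOM training.

    Each cycle presents one sample (uniform random with replacement), finds
    the best-matching unit by Euclidean distance, and moves nodes within the
    shrinking neighborhood radius toward the sample at the linearly declining
    learning rate. Deterministic for a fixed seed.
    """
    data = features.values.to_numpy(dtype=float)
    n, d = data.shape
    if n == 0:
        raise ValueError("cannot train on empty feature matrix")
    if n < config.n_nodes:
        logger.warning("fewer regions (%d) than map units (%d)", n, config.n_nodes)

    rng = np.random.default_rng(config.seed)
    node_dist = grid_distances(config)
    radius0 = config.initial_radius if config.initial_radius is not None else _default_radius(node_dist)

    # initialize at the data centroid with a small jitter: the whole map
    # starts as the 1-node quantizer, so training can only spread it out
    center = data.mean(axis=0)
    spread = data.std(axis=0, ddof=0)
    codebook = center + rng.normal(0.0, 0.05, size=(config.n_nodes, d)) * np.maximum(spread, 1e-9)

    trajectory = [(0, quantization_error(data, codebook))]
    record_every = max(config.rlen // 10, 1)
    denom = max(config.rlen - 1, 1)
    for t in range(config.rlen):
        frac = t / denom
        alpha = config.alpha_start + (config.alpha_end - config.alpha_start) * frac
        radius = radius0 * (1.0 - frac)
        x = data[rng.integers(0, n)]
        bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
        gd = node_dist[bmu]
        if config.neighborhood == "bubble":
            influence = (gd <= radius).astype(float)
        else:
            sigma = max(radius, 1e-12)
            influence = np.exp(-(gd**2) / (2 * sigma**2))
            influence[gd > max(radius, 0.0)] = 0.0
        influence[bmu] = 1.0  # the winner always learns
        codebook += alpha * influence[:, None] * (x - codebook)
        if (t + 1) % record_every == 0:
            trajectory.append((t + 1, quantization_error(data, codebook)))

    assignment = pd.Series(best_matching_units(data, codebook), index=features.values.index, name="node")
    return SOMFit(
        config=config,
        codebook=codebook,
        feature_names=list(features.values.columns),
        assignment=assignment,
        qe_trajectory=trajectory,
    )


def node_summary(
    fit: SOMFit,
    features: FeatureMatrix,
    annotations: Optional[Mapping[str, str]] = None,
):
    """Per-node label counts and mean feature values on the original scale.

    Returns (counts DataFrame indexed by node, means DataFrame; empty nodes
    have zero counts and NaN means).
    """
    nodes = range(fit.n_nodes)
    raw = features.values.copy()
    for name in raw.columns:
        # unscaled feature matrices (no recorded center/scale) pass through
        raw[name] = raw[name] * features.scales.get(name, 1.0) + features.centers.get(name, 0.0)
        if features.transforms.get(name) == "log2(x+1)":
            raw[name] = 2.0 ** raw[name] - 1.0

    labels = pd.Series(
        {rid: (annotations or {}).get(rid, "all") for rid in fit.assignment.index}
    )
    counts = (
        pd.crosstab(fit.assignment, labels)
        .reindex(nodes, fill_value=0)
        .rename_axis(index="node")
    )
    means = raw.groupby(fit.assignment).mean().reindex(nodes).rename_axis(index="node")
    return counts, means
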