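"""Voxelwise thresholding, cluster-extent filtering and Monte-Carlo calibration.

Component statistic maps are thresholded voxelwise (default p < 0.001,
one-sided positive tail), contiguous suprathreshold clusters are found and
clusters below a minimum extent (default 20 voxels) are discarded.  The
probability that smoothed Gaussian noise produces a cluster of a given size
under this rule is estimated by Monte-Carlo simulation: white noise is
smoothed to the stated FWHM, re-standardized
within the analysis mask so the voxelwise cutoff stays calibrated,
thresholded, and the maximum cluster size recorded per iteration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .data import BinaryMask, StatMap, VolumeGrid

__all__ = [
    "ThresholdSpec",
    "Cluster",
    "ClusterCalibration",
    "threshold_map",
    "find_clusters",
    "filter_clusters",
    "cluster_mask",
    "threshold_and_cluster",
    "calibrate_cluster_null",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class ThresholdSpec:
    """Voxelwise p threshold, degrees of freedom and minimum cluster extent.

    ``df=None`` treats map values as z scores (normal quantile); an integer
    uses the Student-t quantile.  ``sided="one"`` keeps the positive tail,
    ``"two"`` thresholds on |value|.
    """

    voxel_p: float = 0.001
    df: int | None = None
    min_cluster: int = 20
    sided: str = "one"

    def __post_init__(self) -> None:
        if not 0.0 < self.voxel_p < 1.0:
            raise ValueError(f"voxel_p must be in (0, 1), got {self.voxel_p}")
        if self.min_cluster < 1:
            raise ValueError(f"min_cluster must be >= 1, got {self.min_cluster}")
        if self.sided not in ("one", "two"):
            raise ValueError(f"sided must be 'one' or 'two', got {self.sided!r}")
        if self.df is not None and self.df < 1:
            raise ValueError(f"df must be >= 1 or None, got {self.df}")

    @property
    def cutoff(self) -> float:
        p = self.voxel_p if self.sided == "one" else self.voxel_p / 2.0
        if self.df is None:
            return float(stats.norm.isf(p))
        return float(stats.t.isf(p, self.df))


@dataclass
class Cluster:
    """One contiguous suprathreshold cluster."""

    voxels: np.ndarray  # (size, 3) integer voxel indices
    size: int
    bbox: tuple[int, int, int]  # bounding-box side lengths, voxels
    peak_voxel: tuple[int, int, int]
    peak_value: float

    @property
    def bbox_volume(self) -> int:
        return int(np.prod(self.bbox))


def threshold_map(stat_map: StatMap, spec: ThresholdSpec) -> BinaryMask:
    """Binary mask of voxels exceeding the voxelwise p cutoff."""
    values = stat_map.values
    if values.size == 0:
        raise ValueError("empty statistic map")
    cutoff = spec.cutoff
    if spec.sided == "one":
        member = values > cutoff
    else:
        member = np.abs(values) > cutoff
    return BinaryMask(stat_map.grid, member)


def find_clusters(
    mask: BinaryMask,
    connectivity: int = 6,
    source: StatMap | None = None,
) -> list[Cluster]:
    """Partition the true voxels of ``mask`` into contiguous clusters.

    ``connectivity`` is the 3D neighbourhood (6 = faces, 18 = +edges,
    26 = +corners).  Peak voxel/value come from ``source`` when given,
    otherwise from nothing (peak_value NaN, peak at the lowest linear
    index of the cluster).  Cluster order follows first-encountered voxel
    in C (raster) order, which is deterministic.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    labels, n = ndimage.label(mask.membership, structure=_STRUCTURES[connectivity])
    clusters: list[Cluster] = []
    if n == 0:
        return clusters
    values = source.values if source is not None else None
    objects = ndimage.find_objects(labels)
    order = np.argsort(
        [np.ravel_multi_index(tuple(s.start for s in sl), mask.grid.dims) for sl in objects]
    )
    for lab in (np.asarray(order) + 1):
        sl = objects[lab - 1]
        sub = labels[sl] == lab
        vox = np.argwhere(sub) + np.array([s.start for s in sl])
        size = int(vox.shape[0])
        bbox = tuple(int(vox[:, ax].max() - vox[:, ax].min() + 1) for ax in range(3))
        if values is not None:
            cluster_vals = values[tuple(vox.T)]
            # ties broken by lowest linear index: voxels are in raster order
            best = int(np.argmax(cluster_vals))
            peak_voxel = tuple(int(v) for v in vox[best])
            peak_value = float(cluster_vals[best])
        else:
            peak_voxel = tuple(int(v) for v in vox[0])
            peak_value = float("nan")
        clusters.append(Cluster(vox, size, bbox, peak_voxel, peak_value))
    return clusters


def filter_clusters(clusters: list[Cluster], min_cluster: int) -> list[Cluster]:
    """Keep clusters with at least ``min_cluster`` voxels, order preserved."""
    if min_cluster < 1:
        raise ValueError(f"min_cluster must be >= 1, got {min_cluster}")
    return [c for c in clusters if c.size >= min_cluster]


def cluster_mask(clusters: list[Cluster], grid: VolumeGrid) -> BinaryMask:
    """Union of the given clusters as a binary mask."""
    member = np.zeros(grid.dims, dtype=bool)
    for c in clusters:
        member[tuple(c.voxels.T)] = True
    return BinaryMask(grid, member)


def threshold_and_cluster(
    stat_map: StatMap,
    spec: ThresholdSpec,
    connectivity: int = 6,
) -> tuple[BinaryMask, list[Cluster]]:
    """The full filtering rule: voxelwise threshold, cluster, extent filter.

    Returns the suprathreshold mask restricted to retained clusters, and the
    retained clusters themselves.
    """
    supra = threshold_map(stat_map, spec)
    clusters = filter_clusters(find_clusters(supra, connectivity, source=stat_map), spec.min_cluster)
    return cluster_mask(clusters, stat_map.grid), clusters


@dataclass
class ClusterCalibration:
    """Monte-Carlo estimate of P(max cluster size >= k) under smoothed noise."""

    fwhm_mm: float
    voxel_p: float
    n_iter: int
    grid: VolumeGrid
    prob_by_size: dict[int, float]
    seed: int
    connectivity: int = 6
    max_sizes: np.ndarray = field(default=None, repr=False)

    def prob(self, k: int) -> float:
        """Estimated probability that noise produces a cluster of >= k voxels."""
        if k <= 0:
            return 1.0
        return self.prob_by_size.get(int(k), 0.0)

    def to_json(self, path: str) -> None:
        payload = {
            "fwhm_mm": self.fwhm_mm,
            "voxel_p": self.voxel_p,
            "n_iter": self.n_iter,
            "dims": list(self.grid.dims),
            "voxel_size": list(self.grid.voxel_size),
            "seed": self.seed,
            "connectivity": self.connectivity,
            "prob_by_size": {str(k): v for k, v in self.prob_by_size.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def calibrate_cluster_null(
    grid: VolumeGrid,
    mask: BinaryMask | None,
    fwhm_mm: float,
    voxel_p: float = 0.001,
    n_iter: int = 2000,
    seed: int = 0,
    connectivity: int = 6,
) -> ClusterCalibration:
    """Estimate the cluster-size null distribution by Monte-Carlo simulation.

    Each iteration draws unit Gaussian white noise on the grid, smooths it
    with an isotropic Gaussian kernel of the given FWHM (in mm), re-scales it
    to unit variance within the mask, thresholds at the one-sided z cutoff
    for ``voxel_p`` and records the maximum cluster size within the mask.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100 for a usable estimate")
    if mask is None:
        mask = BinaryMask(grid, np.ones(grid.dims, dtype=bool))
    if mask.n_true == 0:
        raise ValueError("degenerate mask: no voxels to simulate in")
    if not mask.grid.compatible(grid):
        raise ValueError("mask grid does not match the simulation grid")

    sigma_vox = tuple(fwhm_mm * FWHM_TO_SIGMA / vs for vs in grid.voxel_size)
    cutoff = float(stats.norm.isf(voxel_p))
    rng = np.random.default_rng(seed)
    structure = _STRUCTURES[connectivity]
    member = mask.membership
    max_sizes = np.zeros(n_iter, dtype=np.int64)
    for it in range(n_iter):
        noise = rng.standard_normal(grid.dims)
        if fwhm_mm > 0:
            noise = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        inside = noise[member]
        sd = inside.std()
        if sd == 0:  # pragma: no cover - only for pathological masks
            warnings.warn("zero variance inside mask; iteration skipped")
            continue
        noise = (noise - inside.mean()) / sd
        supra = (noise > cutoff) & member
        if supra.any():
            labels, n = ndimage.label(supra, structure=structure)
            if n:
                max_sizes[it] = int(np.bincount(labels.ravel())[1:].max())

    kmax = int(max_sizes.max()) if max_sizes.size else 0
    prob_by_size = {
        k: float(np.mean(max_sizes >= k)) for k in range(1, max(kmax, 1) + 1)
    }
    return ClusterCalibration(
        fwhm_mm=fwhm_mm,
        voxel_p=voxel_p,
        n_iter=n_iter,
        grid=grid,
        prob_by_size=prob_by_size,
        seed=seed,
        connectivity=connectivity,
        max_sizes=max_sizes,
    )
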