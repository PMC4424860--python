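"""Shared spatial data model for ICA component analysis.

Everything downstream (thresholding, feature extraction, classification,
tracking) operates on these containers.  Components live on a common voxel
grid that is assumed to be pre-aligned: the affine is carried for I/O
fidelity but never used to resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RFN = "RFN"
ART = "ART"
VALID_LABELS = frozenset({RFN, ART})


class GridMismatchError(ValueError):
    """Raised when two objects that must share a voxel grid do not."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel grid: dimensions, voxel size in mm and voxel-to-world affine."""

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        vox = tuple(float(v) for v in self.voxel_size)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"grid dims must be three integers >= 1, got {self.dims}")
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size", vox)
        affine = self.affine
        if affine is None:
            affine = np.diag([vox[0], vox[1], vox[2], 1.0])
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        object.__setattr__(self, "affine", affine)

    @classmethod
    def isotropic(cls, dims: tuple[int, int, int], voxel_size: float = 3.0) -> "VolumeGrid":
        return cls(tuple(dims), (voxel_size,) * 3)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def compatible(self, other: "VolumeGrid") -> bool:
        return self.dims == other.dims and np.allclose(self.voxel_size, other.voxel_size)


def check_same_grid(a: VolumeGrid, b: VolumeGrid, what: str = "objects") -> None:
    if not a.compatible(b):
        raise GridMismatchError(
            f"{what} are on different grids: {a.dims}@{a.voxel_size} vs {b.dims}@{b.voxel_size}"
        )


@dataclass
class StatMap:
    """One component's 3D voxelwise statistic volume (t or z units)."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"value array shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("statistic map contains non-finite values")


@dataclass
class BinaryMask:
    """A boolean membership volume on a grid (tissue mask, suprathreshold mask)."""

    grid: VolumeGrid
    membership: np.ndarray

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership).astype(bool)
        if self.membership.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.membership.shape} does not match grid dims {self.grid.dims}"
            )

    @property
    def n_true(self) -> int:
        return int(self.membership.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        check_same_grid(self.grid, other.grid, "masks")
        return BinaryMask(self.grid, self.membership & other.membership)


@dataclass
class ICTimeCourse:
    """A component's time course, sampled every ``tr`` seconds."""

    samples: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        # spectral features additionally require >= 8 samples; the container
        # itself only demands a non-trivial series
        if self.samples.size < 2:
            raise ValueError(f"time course must have >= 2 samples, got {self.samples.size}")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("time course contains non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)


@dataclass
class Component:
    """One independent component: spatial statistic map plus time course."""

    id: int
    map: StatMap
    timecourse: ICTimeCourse


@dataclass
class ICASet:
    """A full ICA decomposition: NIC components on one grid.

    ``nic`` is the model order (the number of independent components the
    decomposition was asked to extract).
    """

    components: list[Component]
    source_tag: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ValueError("component ids must be unique within a set")
        if self.components:
            grid = self.components[0].map.grid
            n = self.components[0].timecourse.n_samples
            tr = self.components[0].timecourse.tr
            for c in self.components:
                check_same_grid(grid, c.map.grid, "components of one ICA set")
                if c.timecourse.n_samples != n or c.timecourse.tr != tr:
                    raise ValueError("all time courses in a set must share length and tr")

    @property
    def nic(self) -> int:
        return len(self.components)

    @property
    def grid(self) -> VolumeGrid:
        if not self.components:
            raise ValueError("empty ICA set has no grid")
        return self.components[0].map.grid

    def component(self, comp_id: int) -> Component:
        for c in self.components:
            if c.id == comp_id:
                return c
        raise KeyError(f"no component with id {comp_id}")

    def ids(self) -> list[int]:
        return [c.id for c in self.components]


@dataclass
class LabelTable:
    """Mapping from component id to class label (RFN or ART)."""

    entries: dict[int, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.entries.values() if v not in VALID_LABELS}
        if bad:
            raise ValueError(f"labels must be in {sorted(VALID_LABELS)}, got {sorted(bad)}")
        self.entries = {int(k): str(v) for k, v in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, comp_id: int) -> str:
        return self.entries[int(comp_id)]

    def ids(self) -> list[int]:
        return sorted(self.entries)

    def count(self, label: str) -> int:
        return sum(1 for v in self.entries.values() if v == label)
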