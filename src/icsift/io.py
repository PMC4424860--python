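"""Readers and writers for the standard on-disk formats.

NIfTI-1 for statistic maps and masks (melodic-style ``melodic_IC`` 4D
stacks), whitespace-delimited text for mixing matrices (``melodic_mix``
dialect: T rows, NIC columns, column j is component j's time course), and
two-column TSV for label tables.  Readers reject grid mismatches and NaNs
rather than silently repairing them.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .data import (
    ART,
    RFN,
    BinaryMask,
    Component,
    GridMismatchError,
    ICASet,
    ICTimeCourse,
    LabelTable,
    StatMap,
    VolumeGrid,
    check_same_grid,
)

__all__ = [
    "read_ic_maps",
    "write_ic_maps",
    "read_mixing_matrix",
    "write_mixing_matrix",
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
    "read_ica_set",
    "write_ica_set",
]


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    dims = tuple(int(d) for d in img.shape[:3])
    return VolumeGrid(dims, zooms, np.asarray(img.affine, dtype=float))


def read_ic_maps(path: str | os.PathLike) -> list[StatMap]:
    """Read a 4D NIfTI stack of component statistic maps (one 3D volume each)."""
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4D image (x, y, z, component), got {img.ndim}D: {path}")
    data = np.asarray(img.get_fdata(), dtype=float)
    if np.isnan(data).any():
        raise ValueError(f"IC map file contains NaN voxels: {path}")
    grid = _grid_from_img(img)
    return [StatMap(grid, data[..., j]) for j in range(data.shape[3])]


def write_ic_maps(maps: list[StatMap], path: str | os.PathLike) -> None:
    if not maps:
        raise ValueError("cannot write an empty list of maps")
    grid = maps[0].grid
    for m in maps:
        check_same_grid(grid, m.grid, "IC maps")
    data = np.stack([m.values for m in maps], axis=-1)
    img = nib.Nifti1Image(data.astype(np.float32), grid.affine)
    img.header.set_zooms(tuple(grid.voxel_size) + (1.0,))
    nib.save(img, str(path))


def read_mixing_matrix(path: str | os.PathLike, tr: float) -> list[ICTimeCourse]:
    """Read a melodic-style mixing matrix; column j becomes time course j."""
    try:
        mat = np.loadtxt(str(path), dtype=float, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"mixing matrix is ragged or non-numeric: {path}") from exc
    if np.isnan(mat).any():
        raise ValueError(f"mixing matrix contains NaN: {path}")
    return [ICTimeCourse(mat[:, j], tr) for j in range(mat.shape[1])]


def write_mixing_matrix(timecourses: list[ICTimeCourse], path: str | os.PathLike) -> None:
    if not timecourses:
        raise ValueError("cannot write an empty mixing matrix")
    n = timecourses[0].n_samples
    if any(tc.n_samples != n for tc in timecourses):
        raise ValueError("all time courses must have the same length")
    mat = np.column_stack([tc.samples for tc in timecourses])
    np.savetxt(str(path), mat, fmt="%.10g")


def read_mask(path: str | os.PathLike, grid: VolumeGrid | None = None) -> BinaryMask:
    """Read a binary NIfTI mask (thresholded at 0.5); optionally check the grid."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D mask image, got {img.ndim}D: {path}")
    data = np.asarray(img.get_fdata(), dtype=float)
    if np.isnan(data).any():
        raise ValueError(f"mask contains NaN voxels: {path}")
    mask = BinaryMask(_grid_from_img(img), data > 0.5)
    if grid is not None:
        check_same_grid(grid, mask.grid, "mask and IC maps")
    return mask


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(mask.membership.astype(np.uint8), mask.grid.affine)
    img.header.set_zooms(tuple(mask.grid.voxel_size))
    nib.save(img, str(path))


def read_labels(path: str | os.PathLike) -> LabelTable:
    """Read a two-column (id, label) whitespace/tab-delimited label file."""
    entries: dict[int, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns (id, label)")
            comp_id, label = parts
            if label not in (RFN, ART):
                raise ValueError(f"{path}:{lineno}: label must be RFN or ART, got {label!r}")
            entries[int(comp_id)] = label
    return LabelTable(entries)


def write_labels(table: LabelTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for comp_id in table.ids():
            fh.write(f"{comp_id}\t{table[comp_id]}\n")


def read_ica_set(
    ics_path: str | os.PathLike,
    mix_path: str | os.PathLike,
    tr: float,
    source_tag: str = "",
) -> ICASet:
    """Assemble an ICASet from a 4D IC map stack and its mixing matrix."""
    maps = read_ic_maps(ics_path)
    tcs = read_mixing_matrix(mix_path, tr)
    if len(maps) != len(tcs):
        raise ValueError(
            f"IC map count ({len(maps)}) does not match mixing-matrix columns ({len(tcs)})"
        )
    comps = [Component(j, maps[j], tcs[j]) for j in range(len(maps))]
    return ICASet(comps, source_tag=source_tag or str(ics_path))


def write_ica_set(ica_set: ICASet, ics_path: str | os.PathLike, mix_path: str | os.PathLike) -> None:
    order = sorted(ica_set.components, key=lambda c: c.id)
    write_ic_maps([c.map for c in order], ics_path)
    write_mixing_matrix([c.timecourse for c in order], mix_path)
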