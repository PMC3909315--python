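"""Volume and mask I/O, grid checks, and pattern vectorization.

All downstream statistics operate on :class:`MaskedVolume` — a 3D scalar
field of voxel weights together with a boolean brain mask — and on the
flat :class:`PatternVector` obtained by reading the in-mask voxels in a
fixed plane/row/column order.  Volumes must already live on a common
grid; no resampling is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MaskedVolume",
    "PatternVector",
    "read_volume",
    "write_volume",
    "vectorize",
    "scatter",
    "common_nonzero_vectors",
]


@dataclass(frozen=True)
class MaskedVolume:
    """A 3D scalar field plus a boolean brain mask on the same grid.

    Parameters
    ----------
    data
        3D array of voxel weights (unitless).  Values outside the mask are
        ignored by every statistic in the package.
    mask
        Boolean array of the same shape; True marks in-brain voxels.
    spacing
        Voxel size per axis in mm.  Metadata only — no computation in the
        package is spacing-aware (windows and kernels are in voxels).
    """

    data: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {data.shape}")
        if mask.shape != data.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match data shape {data.shape}"
            )
        if not mask.any():
            raise ValueError("mask is empty (no in-brain voxels)")
        if not np.isfinite(data[mask]).all():
            raise ValueError("non-finite voxel weights inside the mask")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels."""
        return int(self.mask.sum())

    def with_data(self, data: np.ndarray) -> "MaskedVolume":
        """Return a new volume with the same mask/spacing but new data."""
        return MaskedVolume(data=data, mask=self.mask, spacing=self.spacing)


@dataclass(frozen=True)
class PatternVector:
    """Flat view of a masked volume's voxel weights.

    ``values[k]`` is the weight at grid coordinate ``voxel_index[k]``
    (0-based array indices).  Ordering is plane-by-plane along the third
    array axis, then row (first axis), then column (second axis).
    """

    values: np.ndarray
    voxel_index: np.ndarray  # (n, 3) int array
    source_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        idx = np.asarray(self.voxel_index, dtype=np.intp)
        if idx.ndim != 2 or idx.shape[1] != 3:
            raise ValueError("voxel_index must be an (n, 3) array")
        if len(values) != len(idx):
            raise ValueError("values and voxel_index lengths differ")
        shape = tuple(int(s) for s in self.source_shape)
        if (idx < 0).any() or (idx >= np.array(shape)).any():
            raise ValueError("voxel coordinates outside source_shape")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voxel_index", idx)
        object.__setattr__(self, "source_shape", shape)

    def __len__(self) -> int:
        return len(self.values)


def _load_nifti(path: Path) -> tuple[np.ndarray, nib.spatialimages.SpatialImage]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim} non-singleton dimensions"
        )
    return np.asarray(data, dtype=float), img


def read_volume(path: str | Path, mask_path: str | Path | None = None) -> MaskedVolume:
    """Read a 3D NIfTI volume (and optional mask) into a :class:`MaskedVolume`.

    Without a mask file the mask is taken as the finite, nonzero voxels of
    the volume (the convention of pattern images stored with zero
    background).  A supplied mask file is binarized as ``label != 0`` —
    a parcellation image with background label 0 therefore works directly —
    and intersected with the finiteness rule.  Non-finite voxels are always
    excluded, with a warning.
    """
    path = Path(path)
    data, img = _load_nifti(path)
    finite = np.isfinite(data)
    n_bad = data.size - int(finite.sum())
    if n_bad:
        logger.warning("%s: %d non-finite voxels excluded from mask", path, n_bad)
    if mask_path is None:
        mask = finite & (data != 0)
    else:
        mask_data, _ = _load_nifti(Path(mask_path))
        if mask_data.shape != data.shape:
            raise ValueError(
                f"mask {mask_path} shape {mask_data.shape} does not match "
                f"volume shape {data.shape}"
            )
        mask = finite & (mask_data != 0)
    data = np.where(finite, data, 0.0)
    zooms = img.header.get_zooms()[:3]
    return MaskedVolume(data=data, mask=mask, spacing=tuple(float(z) for z in zooms))


def write_volume(vol: MaskedVolume, path: str | Path, fill: float = 0.0) -> None:
    """Write a masked volume as NIfTI with ``fill`` outside the mask."""
    out = np.where(vol.mask, vol.data, fill).astype(np.float64)
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(out, affine), str(path))


def _flat_order_index(mask: np.ndarray) -> tuple[np.ndarray, ...]:
    """In-mask coordinates in plane (axis 2) → row (axis 0) → column (axis 1) order."""
    k, i, j = np.nonzero(np.transpose(mask, (2, 0, 1)))
    return i, j, k


def vectorize(vol: MaskedVolume) -> PatternVector:
    """Flatten the in-mask voxels of a volume into a pattern vector.

    Entries are ordered plane-by-plane along the third axis; within a
    plane, rows are appended in index order.
    """
    i, j, k = _flat_order_index(vol.mask)
    coords = np.stack([i, j, k], axis=1)
    return PatternVector(
        values=vol.data[i, j, k], voxel_index=coords, source_shape=vol.shape
    )


def scatter(vec: PatternVector, fill: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize`: place vector entries back on the grid."""
    out = np.full(vec.source_shape, fill, dtype=float)
    i, j, k = vec.voxel_index.T
    out[i, j, k] = vec.values
    return out


def common_nonzero_vectors(
    a: MaskedVolume, b: MaskedVolume
) -> tuple[PatternVector, PatternVector]:
    """Paired vectors over voxels in-mask and nonzero in *both* volumes.

    The intersection rule guarantees that every paired entry is a
    meaningful weight in both patterns.  Both outputs use the same voxel
    ordering, so entry k of each refers to the same grid location.
    """
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    common = a.mask & b.mask & (a.data != 0) & (b.data != 0)
    if not common.any():
        raise ValueError("no voxels are nonzero inside both masks")
    i, j, k = _flat_order_index(common)
    coords = np.stack([i, j, k], axis=1)
    vec_a = PatternVector(values=a.data[i, j, k], voxel_index=coords, source_shape=a.shape)
    vec_b = PatternVector(values=b.data[i, j, k], voxel_index=coords, source_shape=b.shape)
    return vec_a, vec_b
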