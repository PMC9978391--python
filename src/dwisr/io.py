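"""Reading and writing diffusion-weighted volumes with FSL-style gradient tables.

A diffusion-weighted acquisition is a 4-D image (three spatial axes plus one
gradient axis) accompanied by one b-value (diffusion weighting, s/mm^2) and
one unit b-vector (gradient direction) per entry along the 4th axis.  The
on-disk representation is NIfTI-1 for the image and the FSL text dialect for
the gradient table: a ``.bval`` file with a single row of b-values and a
``.bvec`` file with three rows holding the x/y/z components.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "DWIVolume",
    "MetadataError",
    "DataError",
    "read_dwi",
    "write_dwi",
    "read_gradient_table",
    "write_gradient_table",
]

_UNIT_NORM_TOL = 1e-3


class MetadataError(ValueError):
    """Image and gradient-table metadata disagree."""


class DataError(ValueError):
    """Voxel data violate a basic contract (e.g. non-finite values)."""


@dataclasses.dataclass
class DWIVolume:
    """A 4-D diffusion-weighted volume plus its gradient table.

    Attributes
    ----------
    data : ndarray, shape (x, y, z, n)
        Intensities; the gradient index is always the 4th axis.
    voxel_size : tuple of 3 floats
        Voxel edge lengths in mm.
    bvals : ndarray, shape (n,)
        Diffusion weightings in s/mm^2.
    bvecs : ndarray, shape (n, 3)
        Unit gradient directions in the image frame; zero vectors are
        permitted where the b-value is 0.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform; defaults to a scaling by ``voxel_size``.
    """

    data: np.ndarray
    voxel_size: tuple
    bvals: np.ndarray
    bvecs: np.ndarray
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise MetadataError(
                f"expected 3-D or 4-D data, got {self.data.ndim}-D"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise MetadataError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=np.float64))
        self.bvecs = np.asarray(self.bvecs, dtype=np.float64).reshape(-1, 3)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self._validate()

    def _validate(self):
        n = self.data.shape[3]
        if len(self.bvals) != n or len(self.bvecs) != n:
            raise MetadataError(
                f"gradient axis has {n} entries but gradient table has "
                f"{len(self.bvals)} b-values and {len(self.bvecs)} b-vectors"
            )
        if not np.all(np.isfinite(self.data)):
            raise DataError("volume contains non-finite intensities")
        if not (np.all(np.isfinite(self.bvals)) and np.all(np.isfinite(self.bvecs))):
            raise MetadataError("gradient table contains non-finite values")
        if np.any(self.bvals < 0):
            raise MetadataError("negative b-value in gradient table")
        norms = np.linalg.norm(self.bvecs, axis=1)
        weighted = self.bvals > 0
        bad = weighted & (np.abs(norms - 1.0) > _UNIT_NORM_TOL)
        if np.any(bad):
            idx = int(np.flatnonzero(bad)[0])
            raise MetadataError(
                f"b-vector {idx} has norm {norms[idx]:.6f}, expected unit "
                f"length within {_UNIT_NORM_TOL} for b > 0"
            )
        # Renormalize the near-unit vectors so downstream dot products are exact.
        fix = weighted & (norms > 0)
        self.bvecs[fix] /= norms[fix, np.newaxis]

    @property
    def n_gradients(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def shells(self) -> np.ndarray:
        """Distinct b-values, ascending."""
        return np.unique(self.bvals)


def read_gradient_table(bval_path, bvec_path):
    """Read FSL-dialect bval/bvec text files -> (bvals, bvecs (n, 3))."""
    bvals = np.atleast_1d(np.loadtxt(bval_path, dtype=np.float64))
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=np.float64))
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # FSL convention: rows are x/y/z components, columns are entries.
        bvecs = bvecs.T
    elif bvecs.shape == (1, 3):
        pass
    elif bvecs.shape[1] != 3:
        raise MetadataError(f"b-vector table has shape {bvecs.shape}, expected 3 x n")
    return bvals, bvecs


def write_gradient_table(bvals, bvecs, bval_path, bvec_path):
    """Write FSL-dialect files: one row of b-values, three rows of components."""
    bvals = np.atleast_1d(np.asarray(bvals, dtype=np.float64))
    bvecs = np.asarray(bvecs, dtype=np.float64).reshape(-1, 3)
    with open(bval_path, "w") as fh:
        fh.write(" ".join(format(v, ".17g") for v in bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in bvecs.T:
            fh.write(" ".join(format(v, ".17g") for v in row) + "\n")


def read_dwi(image_path, bval_path, bvec_path) -> DWIVolume:
    """Load a NIfTI volume with its gradient table into a validated DWIVolume.

    3-D images are promoted to 4-D with a single gradient entry.  A count
    mismatch between the 4th axis and the tables raises :class:`MetadataError`;
    non-finite voxels raise :class:`DataError`.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise MetadataError(f"{image_path}: expected 3-D or 4-D image, got {data.ndim}-D")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    bvals, bvecs = read_gradient_table(bval_path, bvec_path)
    return DWIVolume(
        data=data,
        voxel_size=voxel_size,
        bvals=bvals,
        bvecs=bvecs,
        affine=np.asarray(img.affine, dtype=np.float64),
    )


def write_dwi(vol: DWIVolume, image_path, bval_path, bvec_path) -> None:
    """Write a DWIVolume as float32 NIfTI plus FSL bval/bvec text tables."""
    image_path = Path(image_path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(tuple(vol.voxel_size) + (1.0,))
    img.header.set_data_dtype(np.float32)
    nib.save(img, str(image_path))
    write_gradient_table(vol.bvals, vol.bvecs, bval_path, bvec_path)
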