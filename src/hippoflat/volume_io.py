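"""Segmented label volumes: NIfTI I/O, through-plane interpolation, gray-matter derivation.

The substrate of the unfolding pipeline is a 3D integer label volume over an
anisotropic voxel grid.  Label codes:

=====  =======================
code   tissue
=====  =======================
0      background
1      white matter (WM)
2      cerebrospinal fluid (CSF)
3      gray matter (GM), no subregion assigned
10-16  GM subregions CA23DG, CA1, SUB, ERC, PRC, PHC, FUS
=====  =======================

World position of voxel (i, j, k) is ``index * spacing`` (0-based, mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

LABEL_BACKGROUND = 0
LABEL_WM = 1
LABEL_CSF = 2
LABEL_GM = 3

#: subregion label codes in fixed anatomical flat-map order
SUBREGION_NAMES = ("CA23DG", "CA1", "SUB", "ERC", "PRC", "PHC", "FUS")
SUBREGION_CODES = tuple(range(10, 17))
SUBREGION_BY_CODE = dict(zip(SUBREGION_CODES, SUBREGION_NAMES))
CODE_BY_SUBREGION = dict(zip(SUBREGION_NAMES, SUBREGION_CODES))

VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_WM, LABEL_CSF, LABEL_GM, *SUBREGION_CODES})


class VolumeFormatError(ValueError):
    """Raised for volumes violating the label/spacing contract."""


class SegmentationConflictError(ValueError):
    """Raised when WM and CSF masks overlap."""


@dataclass
class TissueLabelVolume:
    """A segmented 3D label volume with per-axis spacing in mm."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeFormatError(
                f"labels must be 3D, got {self.labels.ndim}D array"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeFormatError(f"labels must be integer, got {self.labels.dtype}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise VolumeFormatError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        present = set(np.unique(self.labels).tolist())
        unknown = present - VALID_LABELS
        if unknown:
            raise VolumeFormatError(f"unknown label codes present: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def gm_mask(self) -> np.ndarray:
        """Boolean mask of all gray-matter voxels (plain GM plus subregions)."""
        return (self.labels == LABEL_GM) | (
            (self.labels >= SUBREGION_CODES[0]) & (self.labels <= SUBREGION_CODES[-1])
        )

    def wm_mask(self) -> np.ndarray:
        return self.labels == LABEL_WM

    def csf_mask(self) -> np.ndarray:
        return self.labels == LABEL_CSF


def write_label_volume(vol: TissueLabelVolume, path) -> None:
    """Write a label volume as NIfTI-1 with spacing in the header zooms."""
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    img = nib.Nifti1Image(vol.labels.astype(np.int16), affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))


def read_label_volume(path) -> TissueLabelVolume:
    """Read and validate a segmented label volume from NIfTI.

    Rejects non-3D images, missing/degenerate spacing, and unknown label
    codes, naming the offense.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got {data.ndim}D")
    if not np.allclose(data, np.round(data)):
        raise VolumeFormatError(f"{path}: non-integer voxel values in a label volume")
    zooms = img.header.get_zooms()[:3]
    if len(zooms) != 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: missing or non-positive voxel spacing {zooms}")
    # spacing preserved to 6 decimals across round trips
    spacing = tuple(round(float(z), 6) for z in zooms)
    return TissueLabelVolume(labels=data.astype(np.int16), spacing_mm=spacing)


def upsample_through_plane(vol: TissueLabelVolume, factor: int) -> TissueLabelVolume:
    """Nearest-neighbour interpolation of the through-plane (last) axis.

    Each slice is replicated ``factor`` times and the through-plane spacing is
    divided by ``factor``, taking e.g. (0.39, 0.39, 3.0) mm acquisitions to
    near-isotropic (0.39, 0.39, ~0.43) mm grids.  In-plane axes are untouched;
    the label set is unchanged (labels are categorical, so only
    nearest-neighbour assignment is valid).
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"interpolation factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return TissueLabelVolume(vol.labels.copy(), vol.spacing_mm)
    labels = np.repeat(vol.labels, factor, axis=2)
    sx, sy, sz = vol.spacing_mm
    return TissueLabelVolume(labels, (sx, sy, sz / factor))


def derive_gray_matter(vol: TissueLabelVolume) -> np.ndarray:
    """Return the GM mask, checking WM/CSF disjointness and GM connectivity.

    WM and CSF overlapping is impossible for a single label array but the
    check is kept for volumes assembled from separate masks upstream.  A GM
    compartment with more than one connected component is reported with a
    warning listing component sizes (disconnected GM cannot be unfolded as
    one sheet).
    """
    overlap = int(np.count_nonzero(vol.wm_mask() & vol.csf_mask()))
    if overlap:
        raise SegmentationConflictError(
            f"WM and CSF masks overlap on {overlap} voxels"
        )
    gm = vol.gm_mask()
    lab, n = ndimage.label(gm)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        warnings.warn(
            f"gray matter has {n} connected components "
            f"(sizes {sorted(sizes.tolist(), reverse=True)}); "
            "only the sheet reachable from WM will be unfolded",
            stacklevel=2,
        )
    return gm


def check_masks_disjoint(wm: np.ndarray, csf: np.ndarray) -> None:
    overlap = int(np.count_nonzero(wm & csf))
    if overlap:
        raise SegmentationConflictError(f"WM and CSF masks overlap on {overlap} voxels")
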