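"""Reading, writing, smoothing and validating gray-matter volumes and atlases.

The pipeline consumes already-segmented gray-matter intensity maps (NIfTI-1/2,
optionally gzipped) together with an integer label atlas on the same voxel
grid.  Intensities are never rescaled on read; the gray-matter mask is derived
from a configurable intensity floor (default: strictly positive voxels).
World/affine coordinates are not used downstream — all analysis is
index-addressed and mask/atlas-relative — so only the voxel dimensions are
taken from the header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "GMVolume",
    "AtlasVolume",
    "read_volume",
    "write_volume",
    "read_atlas",
    "write_atlas",
    "smooth_gaussian",
    "validate_pair",
    "fwhm_to_sigma_voxels",
]

#: FWHM = sigma * sqrt(8 ln 2) for a Gaussian kernel.
FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


@dataclass
class GMVolume:
    """A 3D gray-matter intensity grid with voxel dimensions and a mask.

    Parameters
    ----------
    intensities
        3D float array of gray-matter intensity (or tissue-probability) values.
    voxel_size_mm
        Physical voxel edge lengths in mm, one per axis, strictly positive.
    mask
        3D boolean array marking voxels considered gray matter.  If omitted,
        derived as ``intensities > mask_floor``.
    """

    intensities: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    mask: np.ndarray = None  # type: ignore[assignment]
    mask_floor: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"gray-matter volume must be 3D, got {self.intensities.ndim}D"
            )
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be 3 positive reals, got {vs}")
        self.voxel_size_mm = vs
        if self.mask is None:
            self.mask = self.intensities > self.mask_floor
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.intensities.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != intensity shape "
                f"{self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities[self.mask])):
            raise ValueError("non-finite intensities inside the gray-matter mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]


@dataclass
class AtlasVolume:
    """An integer parcellation on a voxel grid: 0 = background, 1..K = ROIs."""

    labels: np.ndarray
    roi_names: list[str] | None = None
    roi_ids: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"atlas must be 3D, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            if not np.all(lab == np.round(lab)):
                raise ValueError("atlas labels must be integers")
            self.labels = lab.astype(np.int32)
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        self.roi_ids = np.unique(self.labels[self.labels > 0])
        if self.roi_names is not None and len(self.roi_names) != len(self.roi_ids):
            raise ValueError("roi_names length must match number of ROIs")

    @property
    def n_rois(self) -> int:
        return int(len(self.roi_ids))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D image, got {data.ndim}D with shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    return np.asarray(data), tuple(float(z) for z in zooms)


def read_volume(path: str | Path, mask_floor: float = 0.0) -> GMVolume:
    """Read a NIfTI gray-matter volume.

    Voxel sizes come from the header; no intensity rescaling is applied.
    The mask is ``intensities > mask_floor``.
    """
    data, zooms = _load_nifti(path)
    data = data.astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    return GMVolume(data, zooms, mask_floor=mask_floor)


def write_volume(volume: GMVolume, path: str | Path) -> Path:
    """Write a :class:`GMVolume` as NIfTI-1 with voxel sizes in the header."""
    path = Path(path)
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(volume.intensities.astype(np.float64), affine)
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))
    return path


def read_atlas(path: str | Path) -> AtlasVolume:
    """Read an integer label atlas from NIfTI."""
    data, _ = _load_nifti(path)
    return AtlasVolume(np.round(data).astype(np.int32))


def write_atlas(atlas: AtlasVolume, path: str | Path,
                voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), affine)
    img.header.set_zooms(voxel_size_mm)
    nib.save(img, str(path))
    return path


def fwhm_to_sigma_voxels(
    fwhm_mm: float, voxel_size_mm: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    if fwhm_mm <= 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm}")
    return tuple(fwhm_mm / FWHM_PER_SIGMA / v for v in voxel_size_mm)


def smooth_gaussian(volume: GMVolume, fwhm_mm: float) -> GMVolume:
    """Smooth a gray-matter volume with an isotropic-in-mm Gaussian kernel.

    The kernel is specified by its full width at half maximum in mm and
    converted per axis to voxel sigmas (anisotropic voxels give anisotropic
    sigmas).  Smoothing is applied to the raw intensity grid before masking;
    the mask is re-derived from the smoothed intensities with the volume's
    own floor.  Total intensity is conserved up to boundary truncation.
    """
    sigmas = fwhm_to_sigma_voxels(fwhm_mm, volume.voxel_size_mm)
    smoothed = gaussian_filter(volume.intensities, sigma=sigmas, mode="constant")
    return GMVolume(smoothed, volume.voxel_size_mm, mask_floor=volume.mask_floor)


def validate_pair(volume: GMVolume, atlas: AtlasVolume) -> dict:
    """Check grid congruence of a volume/atlas pair.

    Returns a report dict with per-ROI voxel counts inside the gray-matter
    mask.  Raises on shape mismatch or on any ROI with zero masked voxels.
    """
    if volume.shape != atlas.shape:
        raise ValueError(
            f"grid shape mismatch: volume {volume.shape} vs atlas {atlas.shape}"
        )
    counts = {}
    masked_labels = atlas.labels[volume.mask]
    binc = np.bincount(masked_labels.ravel(), minlength=int(atlas.labels.max()) + 1)
    empty = []
    for rid in atlas.roi_ids:
        c = int(binc[rid]) if rid < len(binc) else 0
        counts[int(rid)] = c
        if c == 0:
            empty.append(int(rid))
    if empty:
        raise ValueError(
            f"ROIs with no voxels inside the gray-matter mask: labels {empty}"
        )
    return {
        "shape": volume.shape,
        "n_rois": atlas.n_rois,
        "roi_voxel_counts": counts,
    }
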