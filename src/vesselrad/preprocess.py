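"""Volume loading, intensity normalization, resampling and maximum-intensity
projection.

Angiographic volumes (TOF-MRA and the like) arrive as 3D intensity grids with
anisotropic voxels.  The pipeline operates on 2D maximum-intensity projections
(MIPs) of configurable slab thickness, after resampling to isotropic 0.23 mm
pixels so that radii reported later in pixel units have a fixed physical
meaning (1 px = 0.23 mm).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from PIL import Image
from scipy import ndimage

#: isotropic pixel size (mm) the pipeline standardizes on
DEFAULT_PIXEL_MM = 0.23

_INTERP_ORDER = {"nearest": 0, "linear": 1, "bilinear": 1, "cubic": 3, "bicubic": 3}


@dataclass
class ImageVolume:
    """A 3D grid of non-negative intensities with per-axis voxel size in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    axis_labels: tuple[str, str, str] = ("R-L", "A-P", "S-I")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:  # promote a 2D image to a single-slice volume
            self.data = self.data[:, :, np.newaxis]
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume must be a non-empty 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values (mm)")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative (clamp on load)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def extent_mm(self, axis: int) -> float:
        return self.shape[axis] * self.spacing[axis]


@dataclass
class ProjectionImage:
    """A 2D projection with provenance (axis, slab center and thickness).

    ``pixel_size`` is mm per pixel in the projection plane; ``thickness_mm``
    is the projected slab depth ('full' projections record the whole extent).
    """

    data: np.ndarray
    pixel_size: float
    thickness_mm: float
    center_index: int
    axis: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("projection must be a non-empty 2D grid")
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def provenance(self) -> dict:
        return {
            "axis": int(self.axis),
            "center_index": int(self.center_index),
            "thickness_mm": float(self.thickness_mm),
            "pixel_size_mm": float(self.pixel_size),
        }


def load_volume(path: str | Path, fallback_spacing: float = 1.0) -> ImageVolume:
    """Read a NIfTI volume (or a 2D PNG/TIFF promoted to one slice).

    Spacing comes from the NIfTI header; plain raster images carry no spacing
    metadata, so ``fallback_spacing`` (mm) is used for them.  Negative voxels
    are clamped to zero with a warning: intensities are magnitudes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        zooms = img.header.get_zooms()[:3]
        if data.ndim == 2:
            data = data[:, :, np.newaxis]
            zooms = tuple(zooms[:2]) + (fallback_spacing,)
        if data.ndim != 3:
            raise ValueError(f"expected a 2D/3D image, got {data.ndim}D: {path}")
        if len(zooms) < 3 or any(z <= 0 for z in zooms):
            raise ValueError(f"missing or invalid spacing metadata in {path}")
        spacing = tuple(float(z) for z in zooms)
    elif suffixes.endswith((".png", ".tif", ".tiff")):
        data = np.asarray(Image.open(path).convert("F"), dtype=np.float64)
        data = data[:, :, np.newaxis]
        spacing = (fallback_spacing, fallback_spacing, fallback_spacing)
    else:
        raise ValueError(f"unsupported image format: {path}")
    if np.any(data < 0):
        warnings.warn(f"{path.name}: negative intensities clamped to zero")
        data = np.clip(data, 0, None)
    return ImageVolume(data=data, spacing=spacing)  # type: ignore[arg-type]


def normalize_intensity(img):
    """Divide intensities by the global maximum, mapping the image to [0, 1].

    Accepts an :class:`ImageVolume`, :class:`ProjectionImage` or bare array and
    returns the same kind.  Idempotent; raises on an all-zero image.
    """
    data = img.data if hasattr(img, "data") else np.asarray(img, dtype=np.float64)
    m = float(np.max(data))
    if m <= 0:
        raise ValueError("degenerate image: maximum intensity is not positive")
    out = data / m
    if isinstance(img, (ImageVolume, ProjectionImage)):
        return replace(img, data=out)
    return out


def resample_inplane(
    img: ImageVolume,
    target_spacing: float = DEFAULT_PIXEL_MM,
    method: str = "bicubic",
) -> ImageVolume:
    """Resample a volume to isotropic ``target_spacing`` mm.

    Output dimensions are ``round(dim * spacing / target)`` per axis.  Cubic
    interpolation can overshoot below zero; the result is clamped to >= 0.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    order = _INTERP_ORDER.get(method)
    if order is None:
        raise ValueError(f"unknown interpolation method {method!r}")
    new_shape = tuple(
        int(round(d * s / target_spacing)) for d, s in zip(img.shape, img.spacing)
    )
    if any(n < 1 for n in new_shape):
        raise ValueError("target spacing coarser than the field of view")
    factors = [n / d for n, d in zip(new_shape, img.shape)]
    out = ndimage.zoom(img.data, factors, order=order, grid_mode=True, mode="nearest")
    out = np.clip(out, 0, None)
    return ImageVolume(
        data=out,
        spacing=(target_spacing, target_spacing, target_spacing),
        axis_labels=img.axis_labels,
    )


def _slab_bounds(volume: ImageVolume, axis: int, center_index: int, thickness_mm) -> tuple[int, int]:
    n = volume.shape[axis]
    s = volume.spacing[axis]
    if thickness_mm in (None, "full"):
        return 0, n
    t = float(thickness_mm)
    if t <= 0:
        raise ValueError("thickness_mm must be positive")
    if t > n * s + 1e-9:
        raise ValueError(
            f"slab thickness {t} mm exceeds volume extent {n * s:.2f} mm (use 'full')"
        )
    # symmetric half-open slab of round(t/s) slices centred on center_index
    # (a single-slice slab is exactly that slice)
    n_slab = max(int(round(t / s)), 1)
    lo = center_index - n_slab // 2
    hi = lo + n_slab
    lo, hi = max(lo, 0), min(hi, n)
    if hi <= lo:
        raise ValueError("empty slab: slab entirely outside the volume")
    return lo, hi


def mip(
    volume: ImageVolume,
    axis: int = 2,
    center_index: int | None = None,
    thickness_mm=None,
) -> ProjectionImage:
    """Maximum-intensity projection of a slab along ``axis``.

    ``thickness_mm=None`` or ``'full'`` projects the whole volume.  Each
    output pixel is the maximum voxel value along the projection line through
    the slab.
    """
    n = volume.shape[axis]
    if center_index is None:
        center_index = n // 2
    lo, hi = _slab_bounds(volume, axis, center_index, thickness_mm)
    sl = [slice(None)] * 3
    sl[axis] = slice(lo, hi)
    proj = np.max(volume.data[tuple(sl)], axis=axis)
    inplane = [volume.spacing[a] for a in range(3) if a != axis]
    if abs(inplane[0] - inplane[1]) > 1e-9:
        warnings.warn("anisotropic in-plane spacing; pixel_size set to first axis")
    thickness = (hi - lo) * volume.spacing[axis]
    return ProjectionImage(
        data=proj,
        pixel_size=inplane[0],
        thickness_mm=thickness,
        center_index=center_index,
        axis=axis,
    )


def mip_series(
    volume: ImageVolume,
    thickness_mm,
    axis: int = 2,
    overlap_policy: str = "tile",
) -> list[ProjectionImage]:
    """Ordered non-overlapping MIP slabs tiling the volume along ``axis``.

    With ``thickness_mm='full'`` a single whole-volume projection is returned.
    Consecutive slabs are contiguous and their union covers every slice, so
    the pixelwise maximum over the series equals the full MIP.
    """
    if overlap_policy != "tile":
        raise ValueError("only the non-overlapping 'tile' policy is implemented")
    if thickness_mm in (None, "full"):
        return [mip(volume, axis=axis, thickness_mm="full")]
    n = volume.shape[axis]
    s = volume.spacing[axis]
    t = float(thickness_mm)
    if t > n * s + 1e-9:
        raise ValueError("thickness exceeds volume extent; pass 'full' instead")
    step = max(int(round(t / s)), 1)
    out = []
    for lo in range(0, n, step):
        hi = min(lo + step, n)
        center = (lo + hi) // 2
        sl = [slice(None)] * 3
        sl[axis] = slice(lo, hi)
        proj = np.max(volume.data[tuple(sl)], axis=axis)
        inplane = [volume.spacing[a] for a in range(3) if a != axis]
        out.append(
            ProjectionImage(
                data=proj,
                pixel_size=inplane[0],
                thickness_mm=(hi - lo) * s,
                center_index=center,
                axis=axis,
            )
        )
    return out


def central_projection(series: Sequence[ProjectionImage]) -> ProjectionImage:
    """The slab containing the volume's central slice (used for evaluation)."""
    if not series:
        raise ValueError("empty series")
    volume_center = (min(p.center_index for p in series) + max(p.center_index for p in series)) / 2
    return min(series, key=lambda p: abs(p.center_index - volume_center))


def write_projection(proj: ProjectionImage, path: str | Path) -> Path:
    """Write a projection as NIfTI or 16-bit PNG with a JSON sidecar."""
    path = Path(path)
    if path.suffix == ".png":
        arr = proj.data.astype(np.float64)
        m = arr.max() if arr.max() > 0 else 1.0
        Image.fromarray((arr / m * 65535).astype(np.uint16)).save(path)
    else:
        affine = np.diag([proj.pixel_size, proj.pixel_size, 1.0, 1.0])
        nib.save(nib.Nifti1Image(proj.data.astype(np.float32), affine), str(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(proj.provenance(), indent=2))
    return path
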