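"""Preprocessing of co-registered multi-contrast MRI volumes.

Turns three co-registered single-channel volumes per lesion (T1-weighted,
T2-weighted, ultrashort-echo-time) plus a lesion region-of-interest mask
into normalized 64x64 pseudo-color axial slices ready for the autoencoder:

1.  :func:`normalize_cohort` — per-contrast linear intensity normalization
    pooled across all lesions (1st percentile -> 0, 99th -> 255, clipped).
2.  :func:`fuse_contrasts` — voxelwise RGB stack: red = T1w, green = T2w,
    blue = UTE.
3.  :func:`extract_axial_mpr` — axial multiplanar reconstruction restricted
    to the outlined lesion.
4.  :func:`autocrop` — minimal bounding box of non-background pixels.
5.  :func:`resize_to_standard` — bilinear resample to 64x64.
6.  :func:`remove_hex_range` — blank pixels whose packed 24-bit RGB value
    falls in a configurable interval (default 0x800000-0xff0000, the
    red/pink arterial-wall signal), isolating the hard/soft occlusion
    tissue.

Volumes are assumed co-registered on input; registration is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ContrastVolume",
    "RoiMask",
    "CONTRASTS",
    "normalize_cohort",
    "fuse_contrasts",
    "extract_axial_mpr",
    "autocrop",
    "resize_to_standard",
    "remove_hex_range",
    "preprocess_lesion",
    "load_contrast_volume",
    "load_roi_mask",
]

CONTRASTS = ("T1w", "T2w", "UTE")

#: Default packed 24-bit interval blanked by :func:`remove_hex_range`.
HEX_LO_DEFAULT = 0x800000
HEX_HI_DEFAULT = 0xFF0000


@dataclass
class ContrastVolume:
    """One 3-D scalar MRI volume with its contrast label and voxel spacing."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    contrast: str = "T1w"
    lesion_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a non-empty 3-D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive")
        if self.contrast not in CONTRASTS:
            raise ValueError(f"contrast must be one of {CONTRASTS}, got {self.contrast!r}")


@dataclass
class RoiMask:
    """Binary lesion outline congruent with the volumes it annotates."""

    voxels: np.ndarray
    lesion_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.voxels.any():
            raise ValueError(f"ROI mask for lesion {self.lesion_id!r} has no foreground voxels")


def normalize_cohort(volumes: Sequence[ContrastVolume]) -> list[ContrastVolume]:
    """Equalize image contrasts across all lesions of a cohort.

    For each contrast, the 1st/99th percentiles of the voxel intensities
    pooled over *all* volumes of that contrast are mapped linearly to 0/255
    and the result is clipped to [0, 255]; volumes of the same contrast thus
    share one mapping, so intensities are comparable across lesions.

    Raises
    ------
    ValueError
        If a contrast is missing, or its pooled intensities are constant
        (1st percentile == 99th percentile).
    """
    by_contrast: dict[str, list[ContrastVolume]] = {c: [] for c in CONTRASTS}
    for vol in volumes:
        by_contrast[vol.contrast].append(vol)
    for c in CONTRASTS:
        if not by_contrast[c]:
            raise ValueError(f"no volume supplied for contrast {c}")

    out: list[ContrastVolume] = []
    for c in CONTRASTS:
        pooled = np.concatenate([v.voxels.ravel() for v in by_contrast[c]])
        p1, p99 = np.percentile(pooled, [1.0, 99.0])
        if p99 <= p1:
            raise ValueError(
                f"contrast {c} has constant pooled intensity (p1 == p99 == {p1}); "
                "cannot normalize"
            )
        scale = 255.0 / (p99 - p1)
        for v in by_contrast[c]:
            mapped = np.clip((v.voxels - p1) * scale, 0.0, 255.0)
            out.append(
                ContrastVolume(mapped, v.spacing_mm, v.contrast, v.lesion_id)
            )
    return out


def fuse_contrasts(
    t1: ContrastVolume, t2: ContrastVolume, ute: ContrastVolume
) -> np.ndarray:
    """Stack three normalized contrasts into a pseudo-color volume.

    Channel semantics: red = T1w, green = T2w, blue = UTE.  No resampling is
    performed; the three volumes must be congruent in shape and spacing.
    Returns an (X, Y, Z, 3) uint8 array.
    """
    shapes = (t1.voxels.shape, t2.voxels.shape, ute.voxels.shape)
    if len(set(shapes)) != 1:
        raise ValueError(f"contrast volumes are not congruent: shapes {shapes}")
    if not (t1.spacing_mm == t2.spacing_mm == ute.spacing_mm):
        raise ValueError("contrast volumes have mismatched voxel spacing")
    for vol, want in zip((t1, t2, ute), CONTRASTS):
        if vol.contrast != want:
            raise ValueError(
                f"expected contrast order (T1w, T2w, UTE); got {vol.contrast!r} "
                f"in the {want} position"
            )
    rgb = np.stack([t1.voxels, t2.voxels, ute.voxels], axis=-1)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def extract_axial_mpr(volume: np.ndarray, roi: RoiMask) -> list[np.ndarray]:
    """Axial multiplanar reconstruction of the outlined lesion.

    One slice per axial index (third array axis) intersecting the ROI
    bounding box, at the original in-plane resolution; voxels outside the
    outline are set to black.  Slices are ordered by increasing axial index.
    """
    volume = np.asarray(volume)
    if volume.ndim != 4 or volume.shape[-1] != 3:
        raise ValueError("volume must be (X, Y, Z, 3) pseudo-color")
    if roi.voxels.shape != volume.shape[:3]:
        raise ValueError(
            f"ROI shape {roi.voxels.shape} does not match volume {volume.shape[:3]}"
        )
    axial_any = roi.voxels.any(axis=(0, 1))
    idx = np.nonzero(axial_any)[0]
    if idx.size == 0:
        raise ValueError("ROI is empty along the axial axis")
    slices = []
    for k in range(idx.min(), idx.max() + 1):
        sl = volume[:, :, k, :].copy()
        sl[~roi.voxels[:, :, k]] = 0
        slices.append(sl)
    return slices


def autocrop(image: np.ndarray, background: tuple[int, int, int] = (0, 0, 0)) -> np.ndarray:
    """Crop to the minimal bounding box of non-background pixels."""
    image = np.asarray(image)
    fg = (image != np.asarray(background, dtype=image.dtype)).any(axis=-1)
    if not fg.any():
        raise ValueError("image contains only background; nothing to crop")
    rows = np.nonzero(fg.any(axis=1))[0]
    cols = np.nonzero(fg.any(axis=0))[0]
    return image[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1].copy()


def resize_to_standard(image: np.ndarray, side: int = 64) -> np.ndarray:
    """Bilinear resample to ``side`` x ``side``, channelwise, clipped to [0, 255].

    An image already at the target size is returned unchanged (bit-identical).
    """
    from skimage.transform import resize

    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) image")
    if image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("empty image")
    if image.shape[:2] == (side, side):
        return image.copy()
    out = resize(
        image.astype(np.float64),
        (side, side),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def packed_rgb(image: np.ndarray) -> np.ndarray:
    """Packed 24-bit value red*65536 + green*256 + blue per pixel."""
    img = np.asarray(image).astype(np.int64)
    return img[..., 0] * 65536 + img[..., 1] * 256 + img[..., 2]


def remove_hex_range(
    image: np.ndarray, lo: int = HEX_LO_DEFAULT, hi: int = HEX_HI_DEFAULT
) -> np.ndarray:
    """Blank every pixel whose packed 24-bit RGB value lies in [lo, hi].

    The default interval 0x800000-0xff0000 captures the red/pink arterial
    wall signal, leaving the dark/bright blue occlusion tissue and the green
    lumen untouched.  "Removed" pixels are set to black so the image keeps
    its dense fixed-size layout.  Idempotent.
    """
    if lo > hi:
        raise ValueError(f"lo (0x{lo:06x}) must not exceed hi (0x{hi:06x})")
    image = np.asarray(image)
    v = packed_rgb(image)
    out = image.copy()
    out[(v >= lo) & (v <= hi)] = 0
    return out


def preprocess_lesion(
    t1: ContrastVolume,
    t2: ContrastVolume,
    ute: ContrastVolume,
    roi: RoiMask,
    side: int = 64,
    hex_lo: int = HEX_LO_DEFAULT,
    hex_hi: int = HEX_HI_DEFAULT,
) -> list[np.ndarray]:
    """Full single-lesion chain: fuse, reslice, crop, resize, hex-filter.

    Expects volumes already normalized (see :func:`normalize_cohort`, which
    operates cohort-wide).  Returns the ordered list of 64x64 pseudo-color
    axial slices.
    """
    fused = fuse_contrasts(t1, t2, ute)
    slices = extract_axial_mpr(fused, roi)
    out = []
    for sl in slices:
        sl = autocrop(sl)
        sl = resize_to_standard(sl, side=side)
        sl = remove_hex_range(sl, hex_lo, hex_hi)
        out.append(sl)
    return out


def standardize_slice(
    image: np.ndarray,
    side: int = 64,
    hex_lo: int = HEX_LO_DEFAULT,
    hex_hi: int = HEX_HI_DEFAULT,
) -> np.ndarray:
    """Per-slice standardization: autocrop, resize, hex-filter.

    The tail of the preprocessing chain, applied identically to resliced
    patient data and to synthetic phantom slices so the autoencoder always
    sees wall-stripped, size-normalized input.
    """
    return remove_hex_range(
        resize_to_standard(autocrop(image), side=side), hex_lo, hex_hi
    )


def load_contrast_volume(
    path: str | Path, contrast: str, lesion_id: str = ""
) -> ContrastVolume:
    """Read a NIfTI volume as a :class:`ContrastVolume`.

    The NIfTI affine is honored for axis identification in the sense that
    voxel axes are used as stored; callers are expected to supply volumes
    co-registered into a common voxel grid.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ContrastVolume(data, spacing, contrast, lesion_id)


def load_roi_mask(path: str | Path, lesion_id: str = "") -> RoiMask:
    """Read a NIfTI binary mask as a :class:`RoiMask`."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    return RoiMask(data > 0, lesion_id)
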