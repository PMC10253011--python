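"""Synthetic multi-contrast vessel cross-section phantoms.

Generates stacks of 64x64 pseudo-color axial slices of a diseased peripheral
artery with known per-slice tissue class, so the whole preprocessing /
autoencoder / classification chain can be exercised and validated without
patient data.  Each slice shows an annular arterial wall (red/pink) around a
lumen that is, depending on the tissue class, patent (green blood signal),
partially in-grown with soft tissue (bright blue), mostly occluded by soft
tissue, or mostly occluded by hard tissue (dark-blue collagen with black
calcium inclusions).

Tissue classes follow the four-level taxonomy used for chronic total
occlusions:

====== ================================== ============
class  morphology                         tissue score
====== ================================== ============
1      lumen patent                       0
2      lumen partially patent             1
3      mostly occluded, soft tissue       3
4      mostly occluded, hard tissue       5
====== ================================== ============

Occlusions are irregular blobs region-grown from random seed points inside
the lumen, so the ground-truth occupancy mask is exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PhantomSpec",
    "LabelledStack",
    "COLOR_PROTOTYPES",
    "OCCLUSION_FRACTIONS",
    "generate_phantom",
    "write_stack",
    "read_stack",
]

#: Prototype colors (R, G, B) on the 0-255 scale, before noise.
COLOR_PROTOTYPES: dict[str, tuple[int, int, int]] = {
    "wall": (200, 120, 120),      # arterial wall, red/pink
    "lumen": (0, 200, 0),         # free lumen / blood, green
    "soft": (60, 60, 230),        # soft tissue, bright blue
    "collagen": (20, 20, 90),     # dense collagen, dark blue
    "calcium": (0, 0, 0),         # calcium, black
}

#: Lumen-area occlusion fraction ranges per tissue class.
#: "partially patent" = 30-70 % of the lumen occluded, "mostly occluded"
#: = more than 70 %.  These are generator conventions (echoed in the stack
#: metadata), not literature values.
OCCLUSION_FRACTIONS: dict[int, tuple[float, float]] = {
    1: (0.0, 0.0),
    2: (0.35, 0.65),
    3: (0.75, 0.95),
    4: (0.75, 0.95),
}

_VALID_CLASSES = frozenset({1, 2, 3, 4})


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic lesion stack.

    Parameters
    ----------
    class_sequence
        Tissue class (1-4) of each axial slice, proximal to distal.
    image_side
        Slice edge length in pixels (square slices).
    wall_thickness_px
        Radial thickness of the arterial wall annulus.
    noise_sd
        Standard deviation of i.i.d. additive Gaussian channel noise,
        expressed on the [0, 1] intensity scale (applied on 0-255 then
        clipped).
    seed
        Seed for all generator randomness; equal specs give bit-identical
        stacks.
    """

    class_sequence: tuple[int, ...]
    image_side: int = 64
    wall_thickness_px: int = 5
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_sequence", tuple(self.class_sequence))
        if len(self.class_sequence) == 0:
            raise ValueError("class_sequence must contain at least one slice")
        for i, c in enumerate(self.class_sequence):
            if c not in _VALID_CLASSES:
                raise ValueError(
                    f"invalid tissue class {c!r} at slice index {i}; "
                    "classes must be in {1, 2, 3, 4}"
                )
        if self.image_side < 16:
            raise ValueError("image_side must be >= 16")
        if self.wall_thickness_px < 1:
            raise ValueError("wall_thickness_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_slices(self) -> int:
        return len(self.class_sequence)


@dataclass
class LabelledStack:
    """Ordered pseudo-color slices of one lesion with ground-truth classes.

    ``slices[i]`` is a (side, side, 3) uint8 array; ``labels[i]`` its tissue
    class.  ``meta`` echoes the generating spec and, for synthetic stacks,
    carries the exact per-slice lumen geometry (lumen mask, occlusion mask,
    occluded fraction) used by label-fidelity oracles.
    """

    slices: list[np.ndarray]
    labels: list[int]
    lesion_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.slices) != len(self.labels):
            raise ValueError("slices and labels must have equal length")
        for i, lab in enumerate(self.labels):
            if lab not in _VALID_CLASSES:
                raise ValueError(
                    f"invalid tissue class {lab!r} at slice index {i}"
                )

    def __len__(self) -> int:
        return len(self.slices)

    def as_array(self) -> np.ndarray:
        """Stack slices into an (n, side, side, 3) uint8 array."""
        return np.stack(self.slices, axis=0)


def _disc_mask(side: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _grow_blob(
    lumen: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Region-grow an irregular blob of ``target`` pixels inside ``lumen``.

    Random-frontier growth from a random interior seed: at each step one
    frontier pixel is chosen uniformly and absorbed.  Produces connected,
    irregular shapes with an exact mask.
    """
    side = lumen.shape[0]
    ys, xs = np.nonzero(lumen)
    start = rng.integers(len(ys))
    blob = np.zeros_like(lumen)
    blob[ys[start], xs[start]] = True
    frontier = [(int(ys[start]), int(xs[start]))]
    count = 1
    while count < target and frontier:
        idx = rng.integers(len(frontier))
        y, x = frontier[idx]
        neighbors = [
            (y + dy, x + dx)
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= y + dy < side
            and 0 <= x + dx < side
            and lumen[y + dy, x + dx]
            and not blob[y + dy, x + dx]
        ]
        if not neighbors:
            frontier.pop(idx)
            continue
        ny, nx = neighbors[rng.integers(len(neighbors))]
        blob[ny, nx] = True
        frontier.append((ny, nx))
        count += 1
    return blob


def _render_slice(
    tissue_class: int, spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    side = spec.image_side
    # vessel center jitters slightly; outer radius fills most of the frame
    cx = side / 2 + rng.uniform(-side * 0.03, side * 0.03)
    cy = side / 2 + rng.uniform(-side * 0.03, side * 0.03)
    r_outer = side * rng.uniform(0.38, 0.45)
    r_lumen = max(3.0, r_outer - spec.wall_thickness_px)

    outer = _disc_mask(side, cx, cy, r_outer)
    lumen = _disc_mask(side, cx, cy, r_lumen)
    wall = outer & ~lumen

    img = np.zeros((side, side, 3), dtype=np.float64)
    img[wall] = COLOR_PROTOTYPES["wall"]
    img[lumen] = COLOR_PROTOTYPES["lumen"]

    lo, hi = OCCLUSION_FRACTIONS[tissue_class]
    frac = float(rng.uniform(lo, hi)) if hi > 0 else 0.0
    n_lumen = int(lumen.sum())
    occlusion = np.zeros_like(lumen)
    if frac > 0:
        target = max(1, int(round(frac * n_lumen)))
        # grow 1-3 blobs that jointly reach the target area
        n_blobs = int(rng.integers(1, 4))
        remaining = target
        for b in range(n_blobs):
            if remaining <= 0:
                break
            size = remaining if b == n_blobs - 1 else max(
                1, int(round(remaining * rng.uniform(0.4, 0.8)))
            )
            free = lumen & ~occlusion
            if not free.any():
                break
            occlusion |= _grow_blob(free, min(size, int(free.sum())), rng)
            remaining = target - int(occlusion.sum())
    if tissue_class in (2, 3):
        img[occlusion] = COLOR_PROTOTYPES["soft"]
        calcium = np.zeros_like(occlusion)
    elif tissue_class == 4:
        img[occlusion] = COLOR_PROTOTYPES["collagen"]
        # calcium speckle: a sub-blob covering ~20-40 % of the occlusion
        n_occ = int(occlusion.sum())
        calcium = np.zeros_like(occlusion)
        if n_occ > 4:
            cal_target = max(1, int(round(n_occ * rng.uniform(0.2, 0.4))))
            calcium = _grow_blob(occlusion, cal_target, rng)
            img[calcium] = COLOR_PROTOTYPES["calcium"]
    else:
        calcium = np.zeros_like(occlusion)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd * 255.0, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    geometry = {
        "lumen_mask": lumen,
        "occlusion_mask": occlusion,
        "calcium_mask": calcium,
        "occluded_fraction": float(occlusion.sum()) / n_lumen,
    }
    return img, geometry


def generate_phantom(spec: PhantomSpec, lesion_id: str = "phantom") -> LabelledStack:
    """Render a labelled stack of vessel cross-sections from ``spec``.

    Deterministic in the spec (including ``seed``): two calls with equal
    specs return bit-identical stacks.  The returned ``meta`` dict records
    the spec echo, the occlusion-fraction conventions and the exact
    per-slice geometry masks.
    """
    rng = np.random.default_rng(spec.seed)
    slices: list[np.ndarray] = []
    geometries: list[dict] = []
    for tissue_class in spec.class_sequence:
        img, geom = _render_slice(tissue_class, spec, rng)
        slices.append(img)
        geometries.append(geom)
    meta = {
        "spec": {
            "class_sequence": list(spec.class_sequence),
            "image_side": spec.image_side,
            "wall_thickness_px": spec.wall_thickness_px,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
        "occlusion_fractions": {str(k): list(v) for k, v in OCCLUSION_FRACTIONS.items()},
        "color_prototypes": {k: list(v) for k, v in COLOR_PROTOTYPES.items()},
        "geometry": geometries,
    }
    return LabelledStack(
        slices=slices,
        labels=list(spec.class_sequence),
        lesion_id=lesion_id,
        meta=meta,
    )


def classify_slice_by_geometry(stack: LabelledStack, index: int) -> int:
    """Pixel-counting oracle: recover a slice's class from its geometry mask.

    Uses only the generator's internal lumen/occlusion/calcium masks and the
    documented occlusion-fraction conventions — independent of the rendered
    colors.  Intended for label-fidelity checks on noise-free stacks.
    """
    geom = stack.meta["geometry"][index]
    frac = geom["occluded_fraction"]
    if frac <= 0.30:
        return 1
    if frac <= 0.70:
        return 2
    # mostly occluded: hard if any calcium / dark-collagen material present
    img = stack.slices[index]
    occ = geom["occlusion_mask"]
    occ_pixels = img[occ].astype(int)
    # hard tissue renders dark (mean intensity low); soft renders bright blue
    return 4 if occ_pixels.mean() < 60 else 3


def write_stack(stack: LabelledStack, out_dir: str | Path) -> Path:
    """Write per-slice PNGs plus a JSON sidecar; returns the sidecar path."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, img in enumerate(stack.slices):
        name = f"{stack.lesion_id}_slice{i:04d}.png"
        Image.fromarray(img, mode="RGB").save(out / name)
        names.append(name)
    sidecar = {
        "lesion_id": stack.lesion_id,
        "labels": list(map(int, stack.labels)),
        "files": names,
        "spec": stack.meta.get("spec"),
        "occlusion_fractions": stack.meta.get("occlusion_fractions"),
    }
    sidecar_path = out / f"{stack.lesion_id}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar_path


def read_stack(sidecar_path: str | Path) -> LabelledStack:
    """Load a stack previously written by :func:`write_stack`."""
    from PIL import Image

    sidecar_path = Path(sidecar_path)
    info = json.loads(sidecar_path.read_text())
    slices = [
        np.asarray(Image.open(sidecar_path.parent / name).convert("RGB"))
        for name in info["files"]
    ]
    return LabelledStack(
        slices=slices,
        labels=list(info["labels"]),
        lesion_id=info["lesion_id"],
        meta={"spec": info.get("spec")},
    )


def write_stack_nifti(stack: LabelledStack, path: str | Path) -> Path:
    """Export the stack as a 4-D NIfTI volume (slice, H, W, channel)."""
    import nibabel as nib

    arr = stack.as_array()
    img = nib.Nifti1Image(arr, affine=np.eye(4))
    path = Path(path)
    nib.save(img, str(path))
    return path
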