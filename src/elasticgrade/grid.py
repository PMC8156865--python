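"""Patch-grid geometry for sliding-window tiling of microscopy images.

A large image of size ``W x H`` is cut into overlapping or non-overlapping
patches of size ``w x h`` advanced by a stride ``s``.  The number of patches
per axis follows the standard sliding-window count

    n_cols = 1 + floor((W - w) / s),    n_rows = 1 + floor((H - h) / s),

with the grid anchored at the top-left pixel and any right/bottom margin
narrower than one stride step discarded.  Coordinates are 0-based; each patch
covers the half-open pixel window ``[x, x+w) x [y, y+h)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _skimage_resize

__all__ = [
    "GridSpec",
    "PatchGrid",
    "Patch",
    "GeometryError",
    "count_patches",
    "tile",
    "extract_patches",
    "augment",
    "resize_image",
]


class GeometryError(ValueError):
    """Raised when patch/image geometry is inconsistent."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a patch grid over an image.

    Parameters
    ----------
    image_width, image_height : int
        Full image dimensions ``W``, ``H`` in pixels.
    patch_width, patch_height : int
        Patch dimensions ``w``, ``h`` in pixels.
    stride : int
        Step ``s`` in pixels between consecutive patch origins (both axes).
    """

    image_width: int
    image_height: int
    patch_width: int
    patch_height: int
    stride: int

    def __post_init__(self) -> None:
        for name in ("image_width", "image_height", "patch_width",
                     "patch_height", "stride"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise GeometryError(f"{name} must be a positive integer, got {value!r}")
        if self.patch_width > self.image_width or self.patch_height > self.image_height:
            raise GeometryError(
                f"patch {self.patch_width}x{self.patch_height} does not fit in "
                f"image {self.image_width}x{self.image_height}"
            )


@dataclass(frozen=True)
class PatchGrid:
    """Row-major grid of patch origins produced by :func:`tile`."""

    n_rows: int
    n_cols: int
    origins: tuple[tuple[int, int], ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.origins)


@dataclass(frozen=True)
class Patch:
    """One extracted patch: raster plus its position in the grid."""

    origin: tuple[int, int]
    pixels: np.ndarray = field(repr=False)
    grid_index: tuple[int, int]


def count_patches(spec: GridSpec) -> tuple[int, int, int]:
    """Number of grid rows, columns and total patches ``k`` for a spec.

    Each directional quotient is floored, so a margin narrower than one
    stride step contributes no patch.

    Returns
    -------
    (n_rows, n_cols, k) with ``k = n_rows * n_cols``.
    """
    n_cols = 1 + (spec.image_width - spec.patch_width) // spec.stride
    n_rows = 1 + (spec.image_height - spec.patch_height) // spec.stride
    return n_rows, n_cols, n_rows * n_cols


def tile(image: np.ndarray, spec: GridSpec) -> PatchGrid:
    """Enumerate patch origins over ``image`` according to ``spec``.

    The image must match the spec's dimensions exactly.  Origins are listed
    row-major (top row first, left to right), anchored at (0, 0).
    """
    h, w = image.shape[:2]
    if w != spec.image_width or h != spec.image_height:
        raise GeometryError(
            f"image is {w}x{h} but spec declares "
            f"{spec.image_width}x{spec.image_height}"
        )
    n_rows, n_cols, _ = count_patches(spec)
    origins = tuple(
        (c * spec.stride, r * spec.stride)
        for r in range(n_rows)
        for c in range(n_cols)
    )
    return PatchGrid(n_rows=n_rows, n_cols=n_cols, origins=origins)


def extract_patches(image: np.ndarray, spec: GridSpec) -> list[Patch]:
    """Cut the image into :class:`Patch` objects following :func:`tile`."""
    grid = tile(image, spec)
    patches = []
    for idx, (x, y) in enumerate(grid.origins):
        r, c = divmod(idx, grid.n_cols)
        patches.append(
            Patch(
                origin=(x, y),
                pixels=image[y:y + spec.patch_height, x:x + spec.patch_width],
                grid_index=(r, c),
            )
        )
    return patches


# Dihedral variants used for augmentation.  Patch-level training uses 90-degree
# rotation (requires square patches); image-level training uses 180 degrees.
_PATCH_OPS = (
    ("identity", lambda a: a),
    ("rot90", lambda a: np.rot90(a)),
    ("hflip", lambda a: a[:, ::-1]),
    ("vflip", lambda a: a[::-1, :]),
)
_IMAGE_OPS = (
    ("identity", lambda a: a),
    ("rot180", lambda a: a[::-1, ::-1]),
    ("hflip", lambda a: a[:, ::-1]),
    ("vflip", lambda a: a[::-1, :]),
)


def augment(
    raster: np.ndarray,
    mode: str = "patch",
    *,
    jitter_delta: float = 0.0,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Deterministic dihedral augmentation with optional color jitter.

    ``mode="patch"`` yields {identity, rot90, hflip, vflip} and requires a
    square raster; ``mode="image"`` yields {identity, rot180, hflip, vflip}.
    When ``jitter_delta > 0`` each variant's channels are scaled by factors
    drawn uniformly from ``[1 - delta, 1 + delta]`` using ``seed``.
    """
    if mode == "patch":
        ops = _PATCH_OPS
        if raster.shape[0] != raster.shape[1]:
            raise GeometryError(
                "90-degree rotation requires a square raster; got "
                f"{raster.shape[1]}x{raster.shape[0]}"
            )
    elif mode == "image":
        ops = _IMAGE_OPS
    else:
        raise ValueError(f"unknown augmentation mode {mode!r}")

    rng = np.random.default_rng(seed)
    out = []
    for _, op in ops:
        variant = np.ascontiguousarray(op(raster))
        if jitter_delta > 0.0:
            factors = rng.uniform(1.0 - jitter_delta, 1.0 + jitter_delta,
                                  size=variant.shape[-1])
            if np.issubdtype(variant.dtype, np.integer):
                jittered = np.clip(variant * factors, 0, 255)
                variant = jittered.astype(variant.dtype)
            else:
                variant = np.clip(variant * factors, 0.0, 1.0)
        out.append(variant)
    return out


def resize_image(image: np.ndarray, width: int, height: int) -> np.ndarray:
    """Bilinear resize preserving dtype (uint8 stays uint8)."""
    resized = _skimage_resize(
        image, (height, width), order=1, preserve_range=True, anti_aliasing=False
    )
    return resized.astype(image.dtype)
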