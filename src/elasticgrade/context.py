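"""Multi-level contextual groupings of per-patch feature maps.

Each patch of a tiled image yields one feature map, arranged in a grid that
mirrors the patch grid (3 rows x 4 columns for the default large-image
layout).  An ensemble member ("image-wise" model) consumes a spatial
concatenation of a rectangular window of neighboring feature maps; the window
shape determines the member's contextual level (1x2 = two neighboring maps,
full grid = global context).  This module enumerates the distinct rectangular
shapes, their placements within the grid, assembles the concatenated maps, and
defines the member-classifier contract (a softmax-normalized probability
vector per contextual map).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import sobel
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .grid import GeometryError, GridSpec, extract_patches

__all__ = [
    "ContextShape",
    "ContextGroup",
    "FeatureGrid",
    "MemberModel",
    "ContractViolation",
    "enumerate_shapes",
    "placements",
    "concat_features",
    "member_predict",
    "default_descriptor",
    "build_feature_grid",
    "LogisticContextMember",
]

PROB_TOL = 1e-6


class ContractViolation(ValueError):
    """A member or feature grid violated its interface contract."""


@dataclass(frozen=True)
class ContextShape:
    """Rectangular window of grid cells combined into one member input."""

    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("shape dimensions must be >= 1")

    @property
    def level(self) -> int:
        """Contextual level: number of feature maps combined."""
        return self.height * self.width


@dataclass(frozen=True)
class ContextGroup:
    """A concrete placement of a :class:`ContextShape` in a grid."""

    shape: ContextShape
    origin: tuple[int, int]  # (row, col) of top-left cell


@dataclass(frozen=True)
class FeatureGrid:
    """Grid of per-patch feature maps for a single image.

    ``cells`` has shape ``(n_rows, n_cols, *cell_shape)``; every cell map
    shares the same dimensions.
    """

    n_rows: int
    n_cols: int
    cells: np.ndarray = field(repr=False)
    source_image_id: str = ""

    def __post_init__(self) -> None:
        if self.cells.shape[:2] != (self.n_rows, self.n_cols):
            raise ContractViolation(
                f"cells array {self.cells.shape} disagrees with grid "
                f"{self.n_rows}x{self.n_cols}"
            )

    @property
    def cell_shape(self) -> tuple[int, ...]:
        return self.cells.shape[2:]

    def __getitem__(self, rc: tuple[int, int]) -> np.ndarray:
        return self.cells[rc[0], rc[1]]


@runtime_checkable
class MemberModel(Protocol):
    """Contract for an ensemble member.

    ``predict`` maps one contextual feature map to a probability vector over
    the classes (non-negative, summing to 1 within 1e-6).  ``fit`` is
    optional: trainable backends learn from labeled contextual maps under
    categorical cross-entropy against image-level labels.
    """

    member_id: str
    shape: ContextShape

    def predict(self, contextual_map: np.ndarray) -> np.ndarray: ...


def enumerate_shapes(n_rows: int, n_cols: int, min_level: int = 1) -> list[ContextShape]:
    """All distinct rectangular context shapes fitting an ``n_rows x n_cols`` grid.

    Shapes with ``height * width < min_level`` are dropped; the result is
    sorted by (level, height) and contains exactly one entry per shape.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if not 1 <= min_level <= n_rows * n_cols:
        raise ValueError(
            f"min_level must be in [1, {n_rows * n_cols}], got {min_level}"
        )
    shapes = [
        ContextShape(h, w)
        for h in range(1, n_rows + 1)
        for w in range(1, n_cols + 1)
        if h * w >= min_level
    ]
    shapes.sort(key=lambda s: (s.level, s.height))
    return shapes


def placements(shape: ContextShape, n_rows: int, n_cols: int) -> list[ContextGroup]:
    """All row-major placements of ``shape`` inside an ``n_rows x n_cols`` grid."""
    if shape.height > n_rows or shape.width > n_cols:
        raise GeometryError(
            f"shape {shape.height}x{shape.width} does not fit in "
            f"{n_rows}x{n_cols} grid"
        )
    return [
        ContextGroup(shape=shape, origin=(r, c))
        for r in range(n_rows - shape.height + 1)
        for c in range(n_cols - shape.width + 1)
    ]


def concat_features(grid: FeatureGrid, group: ContextGroup) -> np.ndarray:
    """Assemble a contextual feature map from a window of grid cells.

    Cell maps keep their 2-D spatial arrangement: row-adjacent cells abut
    horizontally, column-adjacent cells vertically.  For cell maps of spatial
    size ``(fh, fw)`` the output is ``(height*fh, width*fw, ...)``.
    """
    r0, c0 = group.origin
    h, w = group.shape.height, group.shape.width
    if r0 < 0 or c0 < 0 or r0 + h > grid.n_rows or c0 + w > grid.n_cols:
        raise GeometryError(f"group {group} exceeds grid {grid.n_rows}x{grid.n_cols}")
    rows = [
        np.concatenate([grid[(r, c)] for c in range(c0, c0 + w)], axis=1)
        for r in range(r0, r0 + h)
    ]
    return np.concatenate(rows, axis=0)


def validate_probability_vector(p: np.ndarray, member_id: str = "") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    tag = f" (member {member_id})" if member_id else ""
    if p.ndim != 1 or p.size < 2:
        raise ContractViolation(f"probability vector must be 1-D with c >= 2{tag}")
    if np.any(p < -PROB_TOL):
        raise ContractViolation(f"negative probability entry{tag}: {p}")
    if abs(p.sum() - 1.0) > PROB_TOL:
        raise ContractViolation(f"probabilities sum to {p.sum()!r}, not 1{tag}")
    return np.clip(p, 0.0, None)


def member_predict(member: MemberModel, grid: FeatureGrid) -> np.ndarray:
    """Apply a member to every placement of its shape and average the outputs.

    Averaging over placements lets every member see the whole image
    regardless of its window size; single-placement shapes (e.g. the
    full-grid shape) return that placement's output unchanged.  The mean is
    renormalized so the result is a valid probability vector.
    """
    groups = placements(member.shape, grid.n_rows, grid.n_cols)
    outputs = []
    for group in groups:
        p = validate_probability_vector(
            member.predict(concat_features(grid, group)), member.member_id
        )
        outputs.append(p)
    mean = np.mean(outputs, axis=0)
    return mean / mean.sum()


def default_descriptor(patch: np.ndarray, pool: tuple[int, int] = (2, 2)) -> np.ndarray:
    """Deterministic hand-crafted patch descriptor.

    Splits the patch into ``pool`` spatial cells and computes, per cell,
    channel-wise mean and standard deviation plus Sobel edge energy of the
    gray-scale patch — 7 features per cell for RGB input.  Serves as the
    default trained-weights-free feature extractor; a CNN backend can be
    plugged in through the same ``patch -> feature map`` signature.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim == 2:
        patch = patch[:, :, None]
    if patch.max() > 1.0:
        patch = patch / 255.0
    gray = rgb2gray(patch) if patch.shape[2] == 3 else patch[:, :, 0]
    edges = sobel(gray)

    ph, pw = pool
    h_edges = np.linspace(0, patch.shape[0], ph + 1).astype(int)
    w_edges = np.linspace(0, patch.shape[1], pw + 1).astype(int)
    out = np.empty((ph, pw, 2 * patch.shape[2] + 1))
    for i in range(ph):
        for j in range(pw):
            block = patch[h_edges[i]:h_edges[i + 1], w_edges[j]:w_edges[j + 1]]
            eblock = edges[h_edges[i]:h_edges[i + 1], w_edges[j]:w_edges[j + 1]]
            out[i, j] = np.concatenate([
                block.mean(axis=(0, 1)),
                block.std(axis=(0, 1)),
                [eblock.mean()],
            ])
    return out


def build_feature_grid(
    image: np.ndarray,
    spec: GridSpec,
    extractor: Callable[[np.ndarray], np.ndarray] = default_descriptor,
    image_id: str = "",
) -> FeatureGrid:
    """Tile an image and extract one feature map per patch."""
    patches = extract_patches(image, spec)
    n_rows = patches[-1].grid_index[0] + 1
    n_cols = patches[-1].grid_index[1] + 1
    maps = [np.asarray(extractor(p.pixels), dtype=float) for p in patches]
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ContractViolation(f"extractor produced heterogeneous shapes: {shapes}")
    cells = np.stack(maps).reshape(n_rows, n_cols, *maps[0].shape)
    return FeatureGrid(n_rows=n_rows, n_cols=n_cols, cells=cells,
                       source_image_id=image_id)


class LogisticContextMember:
    """Trainable member: multinomial logistic regression on flattened maps.

    A lightweight stand-in for the image-wise CNN of the reference design:
    it consumes the same contextual feature maps and emits a softmax
    probability vector, fit by minimizing categorical cross-entropy against
    image-level labels.
    """

    def __init__(self, member_id: str, shape: ContextShape, *, C: float = 1.0,
                 max_iter: int = 200):
        self.member_id = member_id
        self.shape = shape
        self.C = C
        self.max_iter = max_iter
        self._model: LogisticRegression | None = None
        self._classes: np.ndarray | None = None

    def fit(self, grids: Sequence[FeatureGrid], labels: Sequence[int],
            n_classes: int | None = None) -> "LogisticContextMember":
        """Fit on every placement of this member's shape in every grid."""
        X, y = [], []
        for grid, label in zip(grids, labels):
            for group in placements(self.shape, grid.n_rows, grid.n_cols):
                X.append(concat_features(grid, group).ravel())
                y.append(label)
        self._model = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=self.C, max_iter=self.max_iter),
        )
        self._model.fit(np.asarray(X), np.asarray(y))
        self._classes = self._model[-1].classes_
        self._n_classes = n_classes or len(self._classes)
        return self

    def predict(self, contextual_map: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise ContractViolation(f"member {self.member_id} is not fitted")
        proba = self._model.predict_proba(contextual_map.ravel()[None, :])[0]
        if self._n_classes > len(self._classes):
            # classes absent from this member's training fold get mass 0
            full = np.zeros(self._n_classes)
            full[self._classes.astype(int)] = proba
            return full
        return proba
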