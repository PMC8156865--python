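"""Scikit-learn-style estimators wrapping the elastic-ensemble pipeline.

``PatchFeatureExtractor`` is a transformer turning raw RGB images into
per-patch feature grids; ``ElasticEnsembleClassifier`` is a classifier with a
reject option: it tiles each image, extracts per-patch features, trains one
logistic member per rectangular context shape, and at prediction time gates
members by Shannon entropy against ``beta``, soft-voting the survivors.
Images on which every member is too uncertain receive the sentinel grade
:data:`~elasticgrade.elastic.ABSTAIN` (-1).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .context import (
    ContextShape,
    FeatureGrid,
    LogisticContextMember,
    build_feature_grid,
    default_descriptor,
    enumerate_shapes,
)
from .elastic import ABSTAIN, ElasticResult, grade_image
from .grid import GridSpec

__all__ = ["PatchFeatureExtractor", "ElasticEnsembleClassifier"]


def _as_feature_grids(
    X: Sequence,
    patch_width: int,
    patch_height: int,
    stride: int,
    extractor: Callable[[np.ndarray], np.ndarray],
) -> list[FeatureGrid]:
    if len(X) and isinstance(X[0], FeatureGrid):
        return list(X)
    grids = []
    for i, img in enumerate(X):
        img = np.asarray(img)
        spec = GridSpec(
            image_width=img.shape[1], image_height=img.shape[0],
            patch_width=patch_width, patch_height=patch_height, stride=stride,
        )
        grids.append(build_feature_grid(img, spec, extractor, image_id=str(i)))
    return grids


class PatchFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform RGB images into grids of per-patch descriptors.

    Parameters
    ----------
    patch_width, patch_height : int
        Patch size in pixels.
    stride : int
        Stride between patch origins; equal to the patch side for
        non-overlapping tiling.
    extractor : callable, optional
        ``patch -> feature map``; defaults to the hand-crafted
        mean/variance/edge-energy descriptor.
    """

    def __init__(self, patch_width: int = 56, patch_height: int = 56,
                 stride: int = 56, extractor: Callable | None = None):
        self.patch_width = patch_width
        self.patch_height = patch_height
        self.stride = stride
        self.extractor = extractor

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X) -> list[FeatureGrid]:
        return _as_feature_grids(
            X, self.patch_width, self.patch_height, self.stride,
            self.extractor or default_descriptor,
        )


class ElasticEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Entropy-gated elastic ensemble over patch-context members.

    Parameters
    ----------
    beta : float
        Entropy gate in bits; a member participates in an image's grade only
        if the Shannon entropy of its output is strictly below ``beta``.
        Values above ``log2(n_classes)`` disable abstention entirely.
    patch_width, patch_height, stride : int
        Patch-grid geometry applied to each input image.
    min_level : int
        Smallest contextual level (number of combined feature maps) for the
        auto-enumerated member shapes.
    shapes : sequence of (height, width), optional
        Explicit member shapes, overriding auto-enumeration.
    member_C, member_max_iter :
        Regularization and iteration cap of the logistic members.
    extractor : callable, optional
        Patch descriptor function; defaults to the hand-crafted descriptor.
    on_member_error : {"skip", "raise"}
        Whether a failing member is silently excluded or fatal.

    Attributes
    ----------
    classes_ : ndarray
        Sorted unique labels seen in ``fit``.
    members_ : list
        Fitted members, one per context shape.
    grid_shape_ : (n_rows, n_cols)
        Feature-grid geometry inferred from the training images.

    Notes
    -----
    ``predict`` returns -1 (:data:`ABSTAIN`) for rejected images, so labels
    must not include -1.  ``score`` counts abstentions as errors; use
    :meth:`decision_details` for coverage-aware evaluation.
    """

    def __init__(self, beta: float = 0.5, *, patch_width: int = 56,
                 patch_height: int = 56, stride: int = 56, min_level: int = 1,
                 shapes: Sequence[tuple[int, int]] | None = None,
                 member_C: float = 1.0, member_max_iter: int = 200,
                 extractor: Callable | None = None,
                 on_member_error: str = "skip"):
        self.beta = beta
        self.patch_width = patch_width
        self.patch_height = patch_height
        self.stride = stride
        self.min_level = min_level
        self.shapes = shapes
        self.member_C = member_C
        self.member_max_iter = member_max_iter
        self.extractor = extractor
        self.on_member_error = on_member_error

    def fit(self, X, y):
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        self.classes_ = np.unique(y)
        if ABSTAIN in self.classes_:
            raise ValueError(f"label {ABSTAIN} is reserved for abstention")
        y_idx = np.searchsorted(self.classes_, y)

        grids = self._grids(X)
        self.grid_shape_ = (grids[0].n_rows, grids[0].n_cols)
        if self.shapes is not None:
            shapes = [ContextShape(h, w) for h, w in self.shapes]
        else:
            shapes = enumerate_shapes(*self.grid_shape_, min_level=self.min_level)
        self.members_ = []
        for shape in shapes:
            member = LogisticContextMember(
                member_id=f"ctx_{shape.height}x{shape.width}",
                shape=shape, C=self.member_C, max_iter=self.member_max_iter,
            )
            member.fit(grids, y_idx, n_classes=len(self.classes_))
            self.members_.append(member)
        return self

    def _grids(self, X) -> list[FeatureGrid]:
        return _as_feature_grids(
            X, self.patch_width, self.patch_height, self.stride,
            self.extractor or default_descriptor,
        )

    def decision_details(self, X) -> list[ElasticResult]:
        """Full elastic grading outcome per image (selection, entropy gate)."""
        check_is_fitted(self, "members_")
        return [
            grade_image(self.members_, grid, self.beta,
                        on_member_error=self.on_member_error)
            for grid in self._grids(X)
        ]

    def predict(self, X) -> np.ndarray:
        """Predicted labels; abstained images get -1."""
        out = []
        for res in self.decision_details(X):
            out.append(ABSTAIN if res.abstained else self.classes_[res.grade])
        return np.asarray(out)

    def predict_proba(self, X) -> np.ndarray:
        """Aggregated class probabilities; abstained rows are NaN."""
        check_is_fitted(self, "members_")
        rows = []
        for res in self.decision_details(X):
            if res.abstained:
                rows.append(np.full(len(self.classes_), np.nan))
            else:
                rows.append(res.aggregated)
        return np.vstack(rows)
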