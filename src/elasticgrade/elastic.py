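"""Entropy-gated elastic ensemble core.

Every ensemble member emits a class-probability distribution for the image;
the Shannon entropy (in bits) of that distribution measures the member's
uncertainty.  Members whose entropy falls strictly below a threshold beta are
selected; the selected distributions are soft-voted (arithmetic mean,
renormalized) into the final grade.  If no member passes the gate the image
is abstained and referred for manual expert review.

Entropy uses log base 2 throughout, so both member entropies and beta are in
bits and the admissible beta range for a c-class problem is (0, log2 c]:
any beta above log2 c selects every member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .context import (
    ContractViolation,
    FeatureGrid,
    MemberModel,
    member_predict,
    validate_probability_vector,
)

__all__ = [
    "ABSTAIN",
    "MemberPrediction",
    "ElasticResult",
    "shannon_entropy",
    "select_members",
    "aggregate",
    "grade_predictions",
    "grade_image",
    "predict_members",
]

logger = logging.getLogger(__name__)

#: Sentinel grade for images on which the ensemble abstains.
ABSTAIN = -1


def shannon_entropy(p: Sequence[float] | np.ndarray, *, validate: bool = True) -> float:
    """Shannon entropy ``H = -sum p_i log2 p_i`` of a probability vector, in bits.

    Zero entries contribute nothing (``0 * log2 0 = 0`` by convention, with
    no epsilon flooring), so a one-hot vector has exactly H = 0.  The result
    lies in ``[0, log2 c]`` for a length-``c`` vector.
    """
    p = np.asarray(p, dtype=float)
    if validate:
        p = validate_probability_vector(p)
    nz = p[p > 0.0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass(frozen=True)
class MemberPrediction:
    """One member's probability distribution and its entropy for one image."""

    member_id: str
    probs: np.ndarray = field(repr=False)
    entropy_bits: float

    @classmethod
    def from_probs(cls, member_id: str, probs: np.ndarray) -> "MemberPrediction":
        probs = validate_probability_vector(probs, member_id)
        return cls(member_id=member_id, probs=probs,
                   entropy_bits=shannon_entropy(probs, validate=False))


@dataclass(frozen=True)
class ElasticResult:
    """Outcome of elastic grading for one image."""

    image_id: str
    beta: float
    selected_member_ids: tuple[str, ...]
    aggregated: np.ndarray | None
    grade: int
    n_selected: int

    @property
    def abstained(self) -> bool:
        return self.grade == ABSTAIN


def select_members(predictions: Sequence[MemberPrediction], beta: float) -> list[str]:
    """IDs of members whose entropy is strictly below ``beta``, in input order.

    An empty selection is a valid outcome and signals abstention downstream.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if not predictions:
        raise ValueError("predictions must be non-empty")
    return [p.member_id for p in predictions if p.entropy_bits < beta]


def aggregate(predictions: Sequence[MemberPrediction],
              selected: Sequence[str]) -> np.ndarray:
    """Soft vote: arithmetic mean of the selected members' distributions.

    The mean is renormalized to sum to exactly 1.  ``selected`` must be
    non-empty and every id must be present among ``predictions``.
    """
    if not selected:
        raise ValueError("cannot aggregate an empty selection (abstention)")
    by_id = {p.member_id: p for p in predictions}
    missing = [m for m in selected if m not in by_id]
    if missing:
        raise KeyError(f"selected member(s) not found: {missing}")
    mean = np.mean([by_id[m].probs for m in selected], axis=0)
    return mean / mean.sum()


def grade_predictions(
    predictions: Sequence[MemberPrediction],
    beta: float,
    image_id: str = "",
) -> ElasticResult:
    """Gate cached member predictions by beta and aggregate or abstain.

    Argmax ties in the aggregated distribution break toward the lowest class
    index, deterministically.
    """
    selected = select_members(predictions, beta)
    if not selected:
        logger.info("image %s: no member below beta=%g, abstaining", image_id, beta)
        return ElasticResult(image_id=image_id, beta=beta, selected_member_ids=(),
                             aggregated=None, grade=ABSTAIN, n_selected=0)
    agg = aggregate(predictions, selected)
    grade = int(np.argmax(agg))  # np.argmax returns the first (lowest) maximizer
    return ElasticResult(
        image_id=image_id, beta=beta, selected_member_ids=tuple(selected),
        aggregated=agg, grade=grade, n_selected=len(selected),
    )


def predict_members(
    members: Sequence[MemberModel],
    grid: FeatureGrid,
    on_error: str = "skip",
) -> list[MemberPrediction]:
    """Run every member on a feature grid, collecting entropy-tagged predictions.

    ``on_error="skip"`` logs a failing member and leaves it out (it can then
    never be selected); ``"raise"`` propagates the failure.
    """
    if on_error not in ("skip", "raise"):
        raise ValueError(f"on_error must be 'skip' or 'raise', got {on_error!r}")
    out = []
    for member in members:
        try:
            probs = member_predict(member, grid)
        except (ContractViolation, ValueError) as exc:
            if on_error == "raise":
                raise
            logger.warning("member %s failed on image %s: %s; skipping",
                           member.member_id, grid.source_image_id, exc)
            continue
        out.append(MemberPrediction.from_probs(member.member_id, probs))
    return out


def grade_image(
    members: Sequence[MemberModel],
    grid: FeatureGrid,
    beta: float,
    *,
    image_id: str | None = None,
    on_member_error: str = "skip",
) -> ElasticResult:
    """Full per-image elastic grading: predict, gate, aggregate or abstain."""
    if not members:
        raise ValueError("members must be non-empty")
    image_id = grid.source_image_id if image_id is None else image_id
    predictions = predict_members(members, grid, on_error=on_member_error)
    if not predictions:
        # every member failed; treat as abstention
        return ElasticResult(image_id=image_id, beta=beta, selected_member_ids=(),
                             aggregated=None, grade=ABSTAIN, n_selected=0)
    return grade_predictions(predictions, beta, image_id=image_id)
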