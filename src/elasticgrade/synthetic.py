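"""Synthetic H&E-like images and calibrated mock ensemble members.

The generator emulates the statistical structure a patch-based grading
pipeline relies on, not visual realism: an eosin-pink noisy background with
randomly placed hematoxylin-purple elliptical blobs ("nuclei") whose density
and size depend on the grade.  Densities increase strictly with grade, so the
classes are statistically separable by texture alone.

Mock members replace trained image-wise CNNs for GPU-free testing: each has a
target accuracy (probability that the mode of its output is the true class)
and a concentration knob that maps monotonically to the expected Shannon
entropy of its output distribution (high concentration = sharp, low-entropy
predictions; low concentration = near-uniform, high-entropy predictions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse

from .context import ContextShape

__all__ = [
    "SyntheticConfig",
    "MockMember",
    "generate_image",
    "mock_predict",
    "build_demo_ensemble",
    "DemoFixture",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic image population.

    ``blob_density_by_grade`` is the mean blob count per ``area_unit`` pixels
    (one default patch area); actual counts are Poisson.  Default geometry is
    a 224x168 image with 56x56 patches — a 3-row by 4-column grid mirroring
    the large-image layout at 1/16 area.
    """

    image_width: int = 224
    image_height: int = 168
    patch_size: int = 56
    n_per_grade: int = 20
    n_grades: int = 3
    blob_density_by_grade: tuple[float, ...] = (4.0, 9.0, 16.0)
    blob_radius_range_by_grade: tuple[tuple[float, float], ...] = (
        (3.0, 5.0), (3.5, 6.0), (4.0, 7.0),
    )
    background_color: tuple[float, float, float] = (228.0, 180.0, 192.0)
    blob_color: tuple[float, float, float] = (96.0, 64.0, 140.0)
    color_noise_std: float = 8.0
    area_unit: int = 56 * 56
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.blob_density_by_grade) != self.n_grades:
            raise ValueError("blob_density_by_grade must have length n_grades")
        if len(self.blob_radius_range_by_grade) != self.n_grades:
            raise ValueError("blob_radius_range_by_grade must have length n_grades")
        d = self.blob_density_by_grade
        if any(d[i] >= d[i + 1] for i in range(len(d) - 1)):
            raise ValueError("densities must be strictly increasing across grades")
        max_r = max(hi for _, hi in self.blob_radius_range_by_grade)
        if 2 * max_r >= min(self.image_width, self.image_height):
            raise ValueError("blob radius too large for the image geometry")


def sample_blob_count(grade: int, config: SyntheticConfig, seed: int) -> int:
    """Blob count that :func:`generate_image` will draw for (grade, seed).

    Reconstructs the same random stream, so the returned count is exactly the
    number of blobs placed in the corresponding image.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, grade, seed]))
    h, w = config.image_height, config.image_width
    rng.normal(0.0, config.color_noise_std, size=(h, w, 3))  # background draw
    density = config.blob_density_by_grade[grade]
    return int(rng.poisson(density * h * w / config.area_unit))


def generate_image(grade: int, config: SyntheticConfig, seed: int) -> tuple[np.ndarray, int]:
    """One synthetic RGB image of the given grade; deterministic in (grade, seed).

    Returns ``(uint8 raster of shape (H, W, 3), grade)``.
    """
    if not 0 <= grade < config.n_grades:
        raise ValueError(f"grade must be in [0, {config.n_grades}), got {grade}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, grade, seed]))
    h, w = config.image_height, config.image_width

    img = np.array(config.background_color, dtype=float) + rng.normal(
        0.0, config.color_noise_std, size=(h, w, 3))

    density = config.blob_density_by_grade[grade]
    lo, hi = config.blob_radius_range_by_grade[grade]
    n_blobs = rng.poisson(density * h * w / config.area_unit)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(lo, hi, size=2)
        angle = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w), rotation=angle)
        color = np.array(config.blob_color) + rng.normal(0.0, config.color_noise_std, 3)
        img[rr, cc] = color
    return np.clip(img, 0, 255).astype(np.uint8), grade


@dataclass(frozen=True)
class MockMember:
    """Calibrated fake classifier standing in for a trained image-wise model.

    With probability ``target_accuracy`` the mode of the output distribution
    is the true class, otherwise a uniformly chosen wrong class.  The vector
    is a Dirichlet draw with parameter ``base`` on every class plus
    ``concentration`` on the mode (the mode is enforced exactly), so
    concentration -> infinity approaches one-hot (entropy -> 0) and
    concentration -> 0 approaches the uniform vector for base >> 1
    (entropy -> log2 c).
    """

    member_id: str
    shape: ContextShape
    target_accuracy: float
    concentration: float
    seed: int
    n_classes: int = 3
    base: float = 5.0

    def __post_init__(self) -> None:
        if not 1.0 / self.n_classes < self.target_accuracy <= 1.0:
            raise ValueError("target_accuracy must be in (1/c, 1]")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


def mock_predict(member: MockMember, true_grade: int, image_seed: int) -> np.ndarray:
    """Simulated probability vector, deterministic in (member.seed, image_seed)."""
    c = member.n_classes
    rng = np.random.default_rng(np.random.SeedSequence([member.seed, image_seed]))
    if rng.random() < member.target_accuracy:
        mode = true_grade
    else:
        wrong = [k for k in range(c) if k != true_grade]
        mode = wrong[rng.integers(len(wrong))]
    alpha = np.full(c, member.base)
    alpha[mode] += member.concentration
    p = rng.dirichlet(alpha)
    top = int(np.argmax(p))
    if top != mode:  # enforce the chosen mode exactly
        p[top], p[mode] = p[mode], p[top]
    return p


@dataclass(frozen=True)
class DemoFixture:
    """In-memory end-to-end fixture: images, labels, manifest, members."""

    images: list[np.ndarray] = field(repr=False)
    manifest: pd.DataFrame
    members: list[MockMember]
    config: SyntheticConfig


#: (accuracy, concentration) of the default demo members: half reliable and
#: sharp, half barely-better-than-chance and diffuse.
_DEMO_MEMBER_PARAMS = (
    (0.90, 200.0), (0.90, 200.0), (0.90, 200.0),
    (0.40, 0.8), (0.40, 0.8), (0.40, 0.8),
)


def build_demo_ensemble(
    config: SyntheticConfig | None = None,
    out_dir: str | Path | None = None,
) -> DemoFixture:
    """Materialize a runnable fixture: images, manifest, mixed member registry.

    When ``out_dir`` is given, writes ``images/*.png``, ``manifest.csv``
    (image_id, path, grade, image_seed) and a ``members/`` registry with one
    ``member.json`` per member.
    """
    config = config or SyntheticConfig()
    images, rows = [], []
    idx = 0
    for grade in range(config.n_grades):
        for j in range(config.n_per_grade):
            img, label = generate_image(grade, config, seed=idx)
            image_id = f"img_{grade}_{j:03d}"
            images.append(img)
            rows.append({"image_id": image_id, "path": f"images/{image_id}.png",
                         "grade": label, "image_seed": idx})
            idx += 1
    manifest = pd.DataFrame(rows)

    full_shape = ContextShape(1, 1)
    members = [
        MockMember(member_id=f"mock_{i:02d}", shape=full_shape,
                   target_accuracy=acc, concentration=conc,
                   seed=config.seed * 1000 + i, n_classes=config.n_grades)
        for i, (acc, conc) in enumerate(_DEMO_MEMBER_PARAMS)
    ]

    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        for img, row in zip(images, manifest.itertuples()):
            iio.imwrite(out / row.path, img)
        manifest.to_csv(out / "manifest.csv", index=False)
        reg = out / "members"
        for m in members:
            mdir = reg / m.member_id
            mdir.mkdir(parents=True, exist_ok=True)
            (mdir / "member.json").write_text(json.dumps({
                "member_id": m.member_id,
                "shape": [m.shape.height, m.shape.width],
                "backend": "mock",
                "params": {
                    "target_accuracy": m.target_accuracy,
                    "concentration": m.concentration,
                    "seed": m.seed,
                    "n_classes": m.n_classes,
                    "base": m.base,
                },
            }, indent=2))
    return DemoFixture(images=images, manifest=manifest, members=members,
                       config=config)


def load_member_registry(registry_dir: str | Path) -> list[MockMember]:
    """Load mock members from a ``members/`` registry directory."""
    members = []
    for mdir in sorted(Path(registry_dir).iterdir()):
        spec_file = mdir / "member.json"
        if not spec_file.is_file():
            continue
        meta = json.loads(spec_file.read_text())
        if meta.get("backend") != "mock":
            raise ValueError(
                f"registry backend {meta.get('backend')!r} not loadable here; "
                "trained backends are constructed through the Python API"
            )
        p = meta["params"]
        members.append(MockMember(
            member_id=meta["member_id"],
            shape=ContextShape(*meta["shape"]),
            target_accuracy=p["target_accuracy"],
            concentration=p["concentration"],
            seed=p["seed"],
            n_classes=p.get("n_classes", 3),
            base=p.get("base", 5.0),
        ))
    if not members:
        raise ValueError(f"no members found in {registry_dir}")
    return members


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Convenience: copy a config with a different master seed."""
    return replace(config, seed=seed)
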