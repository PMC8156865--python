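import numpy as np
import pytest

from elasticgrade import MockMember, SyntheticConfig
from elasticgrade.context import ContextShape
from elasticgrade.elastic import MemberPrediction
from elasticgrade.synthetic import mock_predict


@pytest.fixture
def small_config():
    """Desk-scale synthetic population: 112x84 images, 28px patches (3x4 grid)."""
    return SyntheticConfig(
        image_width=112, image_height=84, patch_size=28,
        n_per_grade=8, area_unit=28 * 28,
        blob_radius_range_by_grade=((1.5, 2.5), (1.75, 3.0), (2.0, 3.5)),
        seed=7,
    )


def make_mixed_members(run_seed: int, n_classes: int = 3):
    """Half sharp/reliable, half diffuse/unreliable mock members."""
    params = [(0.90, 200.0)] * 3 + [(0.40, 0.8)] * 3
    return [
        MockMember(member_id=f"m{i}", shape=ContextShape(1, 1),
                   target_accuracy=acc, concentration=conc,
                   seed=run_seed * 17 + i, n_classes=n_classes)
        for i, (acc, conc) in enumerate(params)
    ]


def mock_prediction_set(members, labels, run_seed: int):
    """Cached member predictions for a labeled image list."""
    return {
        f"im{i}": [
            MemberPrediction.from_probs(
                m.member_id, mock_predict(m, int(y), run_seed * 1000 + i))
            for m in members
        ]
        for i, y in enumerate(labels)
    }


def random_simplex(rng, c):
    """Uniform Dirichlet(1,...,1) point on the c-simplex."""
    return rng.dirichlet(np.ones(c))
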