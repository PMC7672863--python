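import numpy as np
import pytest

from paindraw.preprocess import PainDrawing
from paindraw.template import build_default_template


@pytest.fixture(scope="session")
def default_spec():
    """Full-resolution default sheet (1200x900)."""
    return build_default_template()


@pytest.fixture(scope="session")
def small_spec():
    """Third-scale sheet for fast unit tests (400x300)."""
    return build_default_template(400, 300)


def make_drawing(id, label, mask):
    return PainDrawing(id=id, label=label, mask=np.asarray(mask, dtype=bool))


@pytest.fixture()
def tiny_records():
    """Hand-built separable records: 3 of each class."""
    from paindraw.classify import ClassificationRecord

    rows = [
        ("a1", "A", 0.9), ("a2", "A", 0.8), ("a3", "A", 0.4),
        ("b1", "B", 0.7), ("b2", "B", 0.3), ("b3", "B", 0.2),
    ]
    return [
        ClassificationRecord(id=i, true_label=lab, sim_a=s, sim_b=1 - s,
                             score_a=s,
                             predicted_label="A" if s >= 0.5 else "B",
                             cutoff_used=0.5)
        for i, lab, s in rows
    ]
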