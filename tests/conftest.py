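import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


from hyperkds.panels import GradePanel  # noqa: E402


@pytest.fixture
def two_rater_panel() -> GradePanel:
    """Eight images, two raters, one-step disagreements (frozen fixture)."""
    a = (0, 0, 1, 1, 2, 2, 3, 3)
    b = (0, 1, 1, 2, 2, 3, 3, 3)
    records = []
    for i, (ga, gb) in enumerate(zip(a, b)):
        records.append((f"img{i}", "X", ga))
        records.append((f"img{i}", "Y", gb))
    return GradePanel.from_records(records)


@pytest.fixture
def three_rater_panel() -> GradePanel:
    """Three raters over eight images; pairwise kappas frozen from the oracle."""
    r1 = (0, 1, 2, 3, 1, 2, 0, 3)
    r2 = (0, 1, 1, 3, 2, 2, 1, 3)
    r3 = (1, 1, 2, 2, 1, 3, 0, 3)
    records = []
    for i, (g1, g2, g3) in enumerate(zip(r1, r2, r3)):
        records += [(f"img{i}", "R1", g1), (f"img{i}", "R2", g2), (f"img{i}", "R3", g3)]
    return GradePanel.from_records(records)


@pytest.fixture
def tagged_panel() -> GradePanel:
    """Small panel with AB/CD subset tags, four graders and one responder."""
    rng = np.random.default_rng(7)
    records = []
    for i in range(40):
        subset = "AB" if i < 20 else "CD"
        truth = int(rng.integers(0, 4))
        for rater in ("A", "B", "C", "D", "N"):
            g = truth
            if rng.random() < 0.25:
                g = int(np.clip(truth + rng.choice([-1, 1]), 0, 3))
            records.append((f"img{i:02d}", rater, g, subset))
    return GradePanel.from_records(records)
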