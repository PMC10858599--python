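import numpy as np
import pytest
from dataclasses import replace

from harshift.data import WindowSet
from harshift.preprocess import preprocess_recordings
from harshift.synthetic import generate_cohort, preset


@pytest.fixture(scope="session")
def easy_cohort_ws() -> WindowSet:
    """A small, well-separated 4-activity cohort (5 subjects, 39 s/activity)."""
    spec = preset("mhealth-like", n_subjects=5, duration_scale=0.65)
    keep = ("standing", "lying", "walking", "running")
    spec = replace(spec, activities=tuple(a for a in spec.activities if a.activity_name in keep))
    return preprocess_recordings(generate_cohort(spec, seed=11))


@pytest.fixture(scope="session")
def random_ws() -> WindowSet:
    """Random windows for transform tests (no learnable structure)."""
    rng = np.random.default_rng(7)
    n = 24
    return WindowSet(
        windows=rng.normal(size=(n, 150, 6)),
        labels=np.array((["walking", "sitting", "standing"] * n)[:n], dtype=object),
        subject_ids=np.array([f"s{i % 4}" for i in range(n)], dtype=object),
        dataset_name="random",
    )
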