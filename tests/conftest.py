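import numpy as np
import pandas as pd
import pytest

from seedfill.io import OmicsMatrix, SampleDesign


@pytest.fixture
def design_2x3() -> SampleDesign:
    """Two time points (25, 50 DAF), three replicates each."""
    return SampleDesign(
        sample_ids=tuple(f"s{i}" for i in range(6)),
        time_points=(25.0, 25.0, 25.0, 50.0, 50.0, 50.0),
        replicates=(1, 2, 3, 1, 2, 3),
    )


@pytest.fixture
def design_5x2() -> SampleDesign:
    """The study layout on the transcript side: 5 time points x 2 reps."""
    times, reps, ids = [], [], []
    for t in (25, 30, 35, 45, 50):
        for r in (1, 2):
            ids.append(f"t{t}r{r}")
            times.append(float(t))
            reps.append(r)
    return SampleDesign(tuple(ids), tuple(times), tuple(reps))


def make_matrix(values, design, feature_ids=None, scale="raw") -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=feature_ids, columns=design.sample_ids)
    return OmicsMatrix(df, design, value_scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
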