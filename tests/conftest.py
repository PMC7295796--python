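import numpy as np
import pytest

from vipnomics.containers import ProfileMatrix


@pytest.fixture
def toy_presence_matrix() -> ProfileMatrix:
    """4 HN + 4 LN samples, 8 features with hand-placed missingness.

    Per-feature observed counts (HN, LN) out of 4:
      f0: (4, 4)  kept (complete)
      f1: (3, 1)  kept (0.75 in HN)
      f2: (2, 2)  dropped
      f3: (1, 3)  kept (0.75 in LN)
      f4: (0, 4)  kept (1.00 in LN)
      f5: (2, 3)  kept (0.75 in LN)
      f6: (1, 1)  dropped
      f7: (3, 2)  kept (0.75 in HN)
    """
    rng = np.random.default_rng(42)
    values = rng.uniform(10, 100, size=(8, 8))
    observed_counts = {
        0: (4, 4), 1: (3, 1), 2: (2, 2), 3: (1, 3),
        4: (0, 4), 5: (2, 3), 6: (1, 1), 7: (3, 2),
    }
    for j, (n_hn, n_ln) in observed_counts.items():
        values[n_hn:4, j] = np.nan      # rows 0..3 are HN
        values[4 + n_ln : 8, j] = np.nan  # rows 4..7 are LN
    return ProfileMatrix(
        [f"S{i}" for i in range(8)],
        [f"f{j}" for j in range(8)],
        values,
        ["HN"] * 4 + ["LN"] * 4,
        "day8",
    )


@pytest.fixture
def knn_fixture() -> ProfileMatrix:
    """5 samples x 5 features with a single missing cell at (0, 0).

    Columns are built so that features f1 and f2 are the two nearest
    neighbours of f0 (Euclidean over the four shared samples), giving a
    hand-computable imputation with k=2.
    """
    values = np.array(
        [
            # f0     f1    f2    f3     f4
            [np.nan, 10.0, 12.0, 50.0, 80.0],
            [20.0, 21.0, 19.0, 55.0, 70.0],
            [30.0, 29.0, 31.0, 60.0, 60.0],
            [40.0, 41.0, 39.0, 65.0, 50.0],
            [50.0, 49.0, 51.0, 70.0, 40.0],
        ]
    )
    return ProfileMatrix(
        [f"S{i}" for i in range(5)],
        [f"f{j}" for j in range(5)],
        values,
        ["HN", "HN", "HN", "LN", "LN"],
        "day8",
    )
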