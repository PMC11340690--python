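import numpy as np
import pytest

from microtopics import CountTable, SampleMetadata


@pytest.fixture
def small_table() -> CountTable:
    return CountTable(
        ["s1", "s2", "s3", "s4"],
        ["gA", "gB", "gC"],
        np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9], [2, 0, 1]], dtype=float),
    )


@pytest.fixture
def small_meta() -> SampleMetadata:
    return SampleMetadata(["s1", "s2", "s3", "s4"], ["MS", "MS", "HC", "HC"])


def cosine_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise cosine similarity matrix between two stacks of vectors."""
    A = A / np.linalg.norm(A, axis=1, keepdims=True)
    B = B / np.linalg.norm(B, axis=1, keepdims=True)
    return A @ B.T


def matched_mean_cosine(beta_hat: np.ndarray, beta_true: np.ndarray) -> float:
    """Mean cosine between recovered and true topic rows under the optimal
    one-to-one (Hungarian) assignment."""
    from scipy.optimize import linear_sum_assignment

    C = cosine_rows(beta_hat, beta_true)
    r, c = linear_sum_assignment(-C)
    return float(C[r, c].mean())
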