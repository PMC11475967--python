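import numpy as np
import pandas as pd
import pytest

from gwtgnn import FeatureTable, SyntheticSpec, generate
from gwtgnn.preprocess import FeatureMatrix


@pytest.fixture
def small_table() -> FeatureTable:
    """A tiny hand-built mixed-type descriptor table."""
    df = pd.DataFrame({
        "pdb": ["1abc", "2def", "3ghi", "4jkl"],
        "peptide_size": [10.0, 12.0, 9.0, 15.0],
        "interface_area": [350.0, 420.0, 300.0, 500.0],
        "classification": ["B", "A", "B", "A"],
        "is_centroid": [True, False, True, False],
        "motor_updrs": [20.0, 25.0, 18.0, 30.0],
    })
    spec = {"pdb": "identifier", "peptide_size": "numeric",
            "interface_area": "numeric", "classification": "categorical",
            "is_centroid": "numeric", "motor_updrs": "numeric"}
    return FeatureTable(df=df, column_spec=spec, target_columns=("motor_updrs",))


@pytest.fixture
def latent_table():
    """Clean latent-order data (no nuisance columns) for ordering tests."""
    spec = SyntheticSpec(n_samples=200, n_numeric_features=16,
                         latent_correlation_length=3.0, seed=7,
                         n_categorical=0, n_text=0,
                         missing_rate=0.0, duplicate_rate=0.0)
    return generate(spec)


def as_matrix(values: np.ndarray) -> FeatureMatrix:
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(values=values,
                         feature_names=[f"f{i}" for i in range(values.shape[1])],
                         sample_ids=list(range(values.shape[0])))


def greedy_oracle(dis: np.ndarray, mode: str, start: int) -> list[int]:
    """Independent step-by-step greedy simulator over explicit candidate sets.

    Scans unvisited vertices one by one, keeping the best (smallest or
    largest) distance seen so far, with ties resolved to the lowest index.
    Shares no code with the vectorized implementation under test.
    """
    n = dis.shape[0]
    path = [start]
    unvisited = set(range(n)) - {start}
    current = start
    while unvisited:
        best, best_d = None, None
        for v in sorted(unvisited):
            d = dis[current, v]
            if best is None:
                best, best_d = v, d
            elif mode == "min" and d < best_d:
                best, best_d = v, d
            elif mode == "max" and d > best_d:
                best, best_d = v, d
        path.append(best)
        unvisited.remove(best)
        current = best
    return path


def haar_periodic_oracle(x: np.ndarray, levels: int):
    """Direct pairwise Haar analysis, one level at a time.

    cA_i = (x[2i] + x[2i+1]) / sqrt(2); cD_i = (x[2i] - x[2i+1]) / sqrt(2);
    odd lengths repeat the final sample. Independent of pywt.
    """
    x = np.asarray(x, dtype=float)
    details = []
    for _ in range(levels):
        if len(x) % 2:
            x = np.concatenate([x, x[-1:]])
        even, odd = x[0::2], x[1::2]
        details.append((even - odd) / np.sqrt(2.0))
        x = (even + odd) / np.sqrt(2.0)
    return details, x
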