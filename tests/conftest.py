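import numpy as np
import pandas as pd
import pytest

from markermi import CellTable, OutcomeSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def fixed_pairs():
    """The 5-cell, 2-marker dataset used against the brute-force oracles."""
    return np.array(
        [(0.1, 0.2), (0.2, 0.1), (0.5, 0.5), (0.9, 0.8), (0.8, 0.9)]
    )


@pytest.fixture
def two_subject_table():
    """Two subjects, three cells each, two markers."""
    frame = pd.DataFrame(
        {
            "subject_id": ["a", "a", "a", "b", "b", "b"],
            "CK": [0.1, 0.5, 0.9, 0.2, 0.4, 0.8],
            "HLADR": [0.2, 0.4, 0.7, 0.1, 0.6, 0.9],
        }
    )
    return CellTable(frame=frame, marker_names=["CK", "HLADR"])


def make_table(rng, n_subjects=6, ncells=50, p=2, dependent=False):
    """Random uniform CellTable; optionally marker 2 = marker 1 (dependence)."""
    frames = []
    markers = [f"M{k+1}" for k in range(p)]
    for j in range(n_subjects):
        X = rng.random((ncells, p))
        if dependent:
            X[:, 1] = X[:, 0]
        df = pd.DataFrame(X, columns=markers)
        df.insert(0, "subject_id", f"S{j}")
        frames.append(df)
    return CellTable(frame=pd.concat(frames, ignore_index=True),
                     marker_names=markers)


@pytest.fixture
def continuous_outcome():
    def _make(subject_order, y, covariates=None):
        return OutcomeSpec(
            outcome_type="continuous", y=np.asarray(y, dtype=float),
            subject_order=list(subject_order), covariates=covariates,
        )
    return _make
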