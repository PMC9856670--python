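import numpy as np
import pandas as pd
import pytest

from pshscreen import CompetingRisksDataset


def build_dataset(time, cause, X=None, Z=None):
    """Assemble a small dataset from raw arrays (test helper)."""
    time = np.asarray(time, float)
    n = len(time)
    X = pd.DataFrame(np.zeros((n, 0))) if X is None else pd.DataFrame(np.atleast_2d(np.asarray(X, float).T).T)
    Z = pd.DataFrame(np.zeros((n, 0))) if Z is None else pd.DataFrame(np.atleast_2d(np.asarray(Z, float).T).T)
    X.columns = [f"x{j}" for j in range(X.shape[1])]
    Z.columns = [f"z{j}" for j in range(Z.shape[1])]
    return CompetingRisksDataset(
        subject_id=np.arange(n), time=time, cause=np.asarray(cause, int), X=X, Z=Z
    )


def random_survival_dataset(rng, n=15, p=1, event_rate=0.7):
    """Random cause-{0,1} dataset (no competing events) for Cox-limit checks."""
    time = rng.exponential(1.0, size=n).round(4)
    cause = (rng.uniform(size=n) < event_rate).astype(int)
    X = rng.standard_normal((n, p)).round(3)
    return build_dataset(time, cause, X=X)


@pytest.fixture
def tiny_data():
    # 8 subjects, hand-checkable: mix of cause-1, competing and censored
    return build_dataset(
        time=[1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
        cause=[1, 0, 2, 1, 0, 1, 2, 0],
        X=[[0.5], [-0.2], [1.1], [0.0], [0.3], [-1.0], [0.8], [0.1]],
        Z=[[1.0], [0.0], [1.0], [0.0], [1.0], [0.0], [1.0], [0.0]],
    )
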