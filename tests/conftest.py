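import numpy as np
import pytest


def total_variation(values: np.ndarray, probs: np.ndarray) -> float:
    """TV distance between an empirical integer sample and a model PMF."""
    emp = np.bincount(np.asarray(values, dtype=np.int64), minlength=len(probs))
    emp = emp / emp.sum()
    n = max(len(emp), len(probs))
    emp = np.pad(emp, (0, n - len(emp)))
    probs = np.pad(np.asarray(probs, dtype=float), (0, n - len(probs)))
    return 0.5 * float(np.abs(emp - probs).sum())


@pytest.fixture(scope="session")
def tv():
    return total_variation
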