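import numpy as np
import pytest

import samplecast as sc


@pytest.fixture(scope="session")
def wdbc():
    """The 569x30 breast-FNA cohort (212 malignant / 357 benign)."""
    return sc.wdbc_cohort()


@pytest.fixture(scope="session")
def null_wdbc(wdbc):
    """Label-permuted copy of the breast-FNA cohort (no information)."""
    return sc.permute_labels(wdbc, seed=0)


@pytest.fixture()
def tiny_cohort():
    """4 rows, 2 features, 2 per class."""
    x = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 5.0], [4.0, 15.0]])
    return sc.Cohort(x, np.array([1, 1, 0, 0]), ["a", "b"], name="tiny")


@pytest.fixture()
def separable_cohort():
    """Simulated cohort with one overwhelming feature (perfect separation)."""
    spec = sc.SimulationSpec(40, 40, 5, [10, 0, 0, 0, 0], seed=3)
    return sc.simulate_cohort(spec)
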