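import numpy as np
import pandas as pd
import pytest

import dlbcl_coo as dc


@pytest.fixture(scope="session")
def panel():
    return dc.DEFAULT_PANEL


@pytest.fixture(scope="session")
def train_cohort():
    """Well-separated two-class cohort (effect 2 SD, 100 per class)."""
    spec = dc.CohortSpec(n_abc=100, n_gcb=100, effect_size=2.0, seed=1)
    expr, ann = dc.generate_expression(spec)
    return spec, expr, ann


@pytest.fixture(scope="session")
def fitted(train_cohort):
    spec, expr, ann = train_cohort
    y = [a.reference_label for a in ann]
    model = dc.CooSubtypeModel(
        expr, y, panel_genes=list(dc.DEFAULT_PANEL.target_genes)
    )
    return model.fit(seed=0)


@pytest.fixture(scope="session")
def test_cohort():
    """Independent cohort from the same generative conditions."""
    spec = dc.CohortSpec(n_abc=100, n_gcb=100, effect_size=2.0, seed=9)
    expr, ann = dc.generate_expression(spec)
    truth = pd.Series({a.sample_id: a.reference_label for a in ann})
    return expr, truth


def labels_of(annotations) -> np.ndarray:
    return np.array([a.reference_label for a in annotations])
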