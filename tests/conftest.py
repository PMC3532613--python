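import numpy as np
import pytest

from oncorule.rules import Node, RuleTree
from oncorule.synthetic import CohortConfig, generate_cohort


def planted_ratio_rule() -> RuleTree:
    """The canonical planted signal: relative expression of two genes."""
    return RuleTree(root=Node.call("div", Node.g("BMI1"), Node.g("ETV6")))


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 150-patient cohort with a planted ratio rule."""
    cfg = CohortConfig(
        n_patients=150, n_target_genes=20, planted_rule=planted_ratio_rule(), seed=11
    )
    panel, clinical = generate_cohort(cfg)
    return cfg, panel, clinical


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
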