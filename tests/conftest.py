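import numpy as np
import pandas as pd
import pytest

import combkit as ck
from combkit.simulate import GroundTruthParams


@pytest.fixture(scope="session")
def spec():
    return ck.default_instrument()


@pytest.fixture(scope="session")
def truth(spec):
    return ck.default_ground_truth(spec)


@pytest.fixture(scope="session")
def responses(spec, truth):
    """One survey-sized sample from the calibrated generator."""
    return ck.generate_responses(spec, truth, 484, seed=1)


@pytest.fixture(scope="session")
def small_spec():
    """Three-module instrument for fast mediation fits (one domain each)."""
    return ck.InstrumentSpec(
        domains={"Capability": ("CX",), "Motivation": ("MX",)},
        items={"CX": ("CX1", "CX2", "CX3"), "MX": ("MX1", "MX2", "MX3")},
        behavior_items=("BY1", "BY2", "BY3"),
    )


def small_mediation_params(b_m: float, spec) -> GroundTruthParams:
    """Ground truth for the small X -> M -> Y instrument."""
    return GroundTruthParams(
        loadings={i: 0.8 for i in spec.all_items},
        second_order_loadings={d: 1.0 for d in spec.non_behavior_domains},
        structural_paths={
            "M~C": 0.4, "M~O": 0.0, "B~C": 0.2, "B~O": 0.0, "B~M": b_m,
        },
    )


SMALL_MEDIATION_MODEL = """
factor Capability =~ CX1 CX2 CX3
factor Motivation =~ MX1 MX2 MX3
factor Behavior =~ BY1 BY2 BY3
path Motivation ~ Capability
path Behavior ~ Capability Motivation
"""
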