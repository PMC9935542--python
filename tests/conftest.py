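import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from connsig.expression import profile_from_scores
from connsig.glm import EffectMatrix, edges_to_matrix

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230216)


def random_effect_matrix(labels, rng, name=""):
    """A random symmetric effect matrix with zero diagonal."""
    r = len(labels)
    vec = rng.standard_normal(r * (r - 1) // 2)
    return EffectMatrix(
        region_labels=list(labels),
        effect=edges_to_matrix(vec, list(labels)),
        t=np.zeros((r, r)),
        p=np.ones((r, r)),
        contrast_name=name,
    )


def identity_ranking(labels):
    """Expression ranking that ranks regions in their given order."""
    return profile_from_scores(
        pd.Series(np.arange(len(labels), 0, -1, dtype=float), index=list(labels))
    )


@pytest.fixture
def labels6():
    return [f"R{i}" for i in range(1, 7)]
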