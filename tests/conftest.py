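import math

import numpy as np
import pytest

from hccmeta.records import EffectEstimate, EffectOrigin, Scale


def make_effect(log_effect, se, study_id="s", scale=Scale.LOG_HR):
    return EffectEstimate(
        study_id=study_id,
        outcome_or_feature="OS",
        log_effect=float(log_effect),
        se=float(se),
        scale=scale,
        source=EffectOrigin.REPORTED_CI,
    )


def make_effects(pairs, scale=Scale.LOG_HR):
    return [make_effect(y, s, study_id=f"s{i}", scale=scale) for i, (y, s) in enumerate(pairs)]


@pytest.fixture(scope="session")
def table1_studies():
    """The nine published source studies shipped with the package."""
    from hccmeta.datasets import included_studies

    return included_studies()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160)
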