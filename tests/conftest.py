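import logging

import pandas as pd
import pytest

from rulemine import DiscretizedDataset, SyntheticSpec, VariableMeta, generate

# the intercept-only fallback is expected on null data; keep test output clean
logging.getLogger("rulemine.models").setLevel(logging.ERROR)


@pytest.fixture
def tiny_dataset() -> DiscretizedDataset:
    """Six subjects, one 4-bin ordinal and one binary nominal variable."""
    variables = [
        VariableMeta("bucket 1.00", "ordinal", 4),
        VariableMeta("Sex", "nominal", 2, level_labels=("F", "M")),
    ]
    data = pd.DataFrame(
        {
            "bucket 1.00": [1, 2, 2, 3, 4, 4],
            "Sex": ["F", "M", "F", "M", "M", "F"],
        },
        index=[f"s{i}" for i in range(6)],
    )
    target = pd.Series(
        ["below60", "below60", "below60", "below60", "at_least_60", "at_least_60"],
        index=data.index,
    )
    return DiscretizedDataset(data=data, variables=variables, target=target)


@pytest.fixture
def planted_dataset():
    """Small cohort with strong planted 1D shifts and one balanced 2D pair."""
    spec = SyntheticSpec(
        n_buckets=30,
        planted_1d=((0, (1, 5), 0.9), (1, (1, 5), 0.9)),
        planted_2d=(((10, 11), 0.9, True),),
        seed=11,
    )
    ds, truth = generate(spec)
    return ds, truth, spec


@pytest.fixture
def null_dataset():
    """Pure-noise cohort at the study's class imbalance."""
    spec = SyntheticSpec(n_buckets=30, seed=5)
    ds, _ = generate(spec)
    return ds
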