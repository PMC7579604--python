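import numpy as np
import pandas as pd
import pytest

from mineinjury.narrative_vectors import EmbeddingParams
from mineinjury.synthetic import GeneratorConfig, generate_dataset

#: small, fast embedding settings used wherever the 300-dim default is not the point
FAST_EMBEDDING = EmbeddingParams(dimension=16, window=3, epochs=5, seed=0)


@pytest.fixture(scope="session")
def small_dataset() -> pd.DataFrame:
    """2000 records under the default study conditions."""
    return generate_dataset(GeneratorConfig(n_records=2000, seed=42))


@pytest.fixture(scope="session")
def clean_small_dataset(small_dataset) -> pd.DataFrame:
    from mineinjury.preprocessing import clean_records, engineer_time_features

    return engineer_time_features(clean_records(small_dataset).records)


def three_class_config(n: int, seed: int, q: float = 0.9, **kwargs) -> GeneratorConfig:
    """A balanced-ish three-class design with narrative-only outcome signal."""
    from mineinjury.records import CLASS_LABELS

    classes = {CLASS_LABELS[1]: 0.5, CLASS_LABELS[6]: 0.3, CLASS_LABELS[2]: 0.2}
    return GeneratorConfig(
        n_records=n,
        seed=seed,
        class_proportions=classes,
        narrative_signal_q=q,
        missing_field_rate=0.0,
        nonemployee_rate=0.0,
        **kwargs,
    )
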