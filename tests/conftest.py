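import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nervede import ExpressionMatrix

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with simple values."""
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        np.array([[1.0, 2.0, 3.0, 4.0],
                  [10.0, 10.0, 10.0, 10.0],
                  [0.0, 0.0, 5.0, 0.0]]),
    )


@pytest.fixture
def meta_frame() -> pd.DataFrame:
    """Minimal clinical table covering all cohorts and one exclusion."""
    rows = []
    for i, (sex, t2d, arth, sepsis) in enumerate([
        ("male", "no", "no", "no"),
        ("female", "no", "no", "no"),
        ("male", "yes", "no", "no"),
        ("female", "no", "yes", "no"),
        ("male", "yes", "yes", "no"),
        ("female", "no", "no", "yes"),
    ]):
        rows.append({
            "SAMPID": f"d{i}", "SEX": sex, "AGE": 40 + i,
            "MHT1D": "no", "MHT2D": t2d, "MHARTHTS": arth, "MHRA": "no",
            "MHSEPSIS": sepsis, "LBHIV1NT": "negative",
        })
    from nervede.io_model import normalize_metadata
    return normalize_metadata(pd.DataFrame(rows))
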