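import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from macpolar import ExpressionMatrix, SampleAnnotation, SyntheticConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: compact cluster layout for fast tests (3 M1 + 3 M2 clusters of 3 genes)
SMALL_CLUSTERS = tuple([("M1", 3, -1.0 / 3)] * 3 + [("M2", 3, 1.0 / 3)] * 3)


def small_config(**kw) -> SyntheticConfig:
    defaults = dict(n_pre=20, n_post=20, clusters=SMALL_CLUSTERS,
                    n_null_genes=20, seed=0)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


def brute_force_step(values, min_segment=1):
    """Independent exhaustive-enumeration oracle for the one-step fit.

    Returns (best_sse, low_mean, high_mean, step_index) by direct evaluation
    of every split of the sorted values.
    """
    xs = np.sort(np.asarray(values, dtype=float))
    n = xs.size
    best = None
    for k in range(min_segment, n - min_segment + 1):
        low, high = xs[:k], xs[k:]
        sse = np.sum((low - low.mean()) ** 2) + np.sum((high - high.mean()) ** 2)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, low.mean(), high.mean(), k)
    return best


def matrix_from_rows(rows: dict, samples=None) -> ExpressionMatrix:
    frame = pd.DataFrame(rows).T
    frame.columns = samples or [f"s{i+1}" for i in range(frame.shape[1])]
    return ExpressionMatrix(frame.astype(float))


def annotation_for(samples, conditions, **extra) -> SampleAnnotation:
    table = pd.DataFrame({"condition": conditions, **extra},
                         index=pd.Index(samples, name="sample_id"))
    return SampleAnnotation(table)


@pytest.fixture()
def small_cohort():
    from macpolar import generate_cohort
    return generate_cohort(small_config(seed=11))


@pytest.fixture()
def shifted_cohort():
    from macpolar import generate_cohort
    return generate_cohort(small_config(seed=12, shift=-1.0, shift_arm="M1"))
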