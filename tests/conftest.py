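import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

from mapel import Cohort

hyp_settings.register_profile("ci", derandomize=True, max_examples=50)
hyp_settings.load_profile("ci")


def make_cohort(axes, responses, mediators=None, vp_ids=None) -> Cohort:
    """Build a cohort from plain dicts: axes {name: values}, responses {(therapy, months): values}."""
    n = len(next(iter(axes.values())))
    ids = pd.Index(vp_ids or [f"vp{i + 1}" for i in range(n)], name="vp_id")
    axes_df = pd.DataFrame({k: np.asarray(v, float) for k, v in axes.items()}, index=ids)
    resp_df = pd.DataFrame(
        {(t, float(m)): np.asarray(v, float) for (t, m), v in responses.items()}, index=ids
    )
    resp_df.columns = pd.MultiIndex.from_tuples(resp_df.columns, names=["therapy", "months"])
    med_df = None
    if mediators is not None:
        med_df = pd.DataFrame(
            {k: np.asarray(v, float) for k, v in mediators.items()}, index=ids
        )
    return Cohort(axes=axes_df, responses=resp_df, mediators=med_df)


@pytest.fixture
def quadrant_cohort() -> Cohort:
    """4 VPs covering the four (lower/upper) bin patterns of two axes."""
    return make_cohort(
        axes={"a1": [1, 1, 2, 2], "a2": [1, 2, 1, 2]},
        responses={("rtx", 6.0): [10.0, 30.0, 60.0, 80.0]},
    )


@pytest.fixture
def random_cohort_factory():
    """Small random cohorts (uniform axes, linear responses) for property tests."""

    def build(n_vps: int, n_axes: int, seed: int) -> Cohort:
        rng = np.random.default_rng(seed)
        axes = {f"ax{j}": rng.uniform(0, 1, n_vps) for j in range(n_axes)}
        load = rng.normal(0, 25, n_axes)
        x = 40 + np.column_stack(list(axes.values())) @ load + rng.normal(0, 5, n_vps)
        return make_cohort(axes, {("rtx", 6.0): np.clip(x, -21, 100)})

    return build
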