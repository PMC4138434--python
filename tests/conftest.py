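import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_trials(first3, recall, subject_id="s1", extra_ext=(), acq=()):
    """Minimal trials table: first-3 extinction trials plus 3 recall trials."""
    rows = []
    for j, v in enumerate(acq, start=1):
        rows.append((subject_id, "acquisition", j, v))
    for j, v in enumerate(list(first3) + list(extra_ext), start=1):
        rows.append((subject_id, "extinction", j, v))
    for j, v in enumerate(recall, start=1):
        rows.append((subject_id, "recall", j, v))
    return pd.DataFrame(rows, columns=["subject_id", "session", "trial_index", "freezing_pct"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gauss_config():
    """SimConfig factory on the Gaussian (identity-marginal) phenotype scale."""
    from fearsel.config import SimConfig

    def factory(true_h2, n_families=30, n_tested=8, seed=0, litter_size=None,
                **kwargs):
        litter_size = n_tested if litter_size is None else litter_size
        return SimConfig(
            n_founder_males=n_families, n_founder_females=n_families,
            true_h2=true_h2,
            acq_marginal_params={"kind": "identity"},
            ext_marginal_params={"kind": "identity"},
            litter_size_distribution={"kind": "fixed", "size": litter_size},
            cull_max=max(12, litter_size),
            offspring_tested_per_litter=n_tested,
            seed=seed, **kwargs,
        )

    return factory
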