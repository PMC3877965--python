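import numpy as np
import pandas as pd
import pytest

from pathsurv import SyntheticConfig, generate_cohort


def make_surv(times, events, prefix="s"):
    """Survival table from parallel time/event lists."""
    idx = pd.Index([f"{prefix}{i}" for i in range(len(times))], name="sample")
    return pd.DataFrame({"time": np.asarray(times, float), "event": list(events)}, index=idx)


@pytest.fixture
def toy_surv():
    """Six patients, staggered event times, one censored."""
    return make_surv([2, 4, 6, 8, 10, 12], [1, 1, 0, 1, 1, 1])


@pytest.fixture
def null_cohort():
    """A small global-null cohort: no gene is linked to survival."""
    cfg = SyntheticConfig(n_patients=120, n_genes=300, baseline_hazard=0.02,
                          censoring_rate=0.01, seed=424)
    return generate_cohort(cfg)


@pytest.fixture
def planted_cohort():
    """A cohort with a strongly planted 8-gene signature (|beta| = 1)."""
    genes = [f"G{i:04d}" for i in range(1, 9)]
    betas = {g: (1.0 if i % 2 == 0 else -1.0) for i, g in enumerate(genes)}
    cfg = SyntheticConfig(n_patients=300, n_genes=150, planted_genes=genes,
                          betas=betas, baseline_hazard=0.02, censoring_rate=0.01,
                          seed=77)
    return generate_cohort(cfg), genes, betas
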