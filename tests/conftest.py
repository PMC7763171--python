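import numpy as np
import pandas as pd
import pytest

from serapept.preprocess_align import AlignedTable


def make_table(x: np.ndarray, groups: list[str], signals=None,
               ages=None, genders=None) -> AlignedTable:
    """AlignedTable from a raw (signals × samples) array and group labels."""
    n_sig, n_samp = x.shape
    assert len(groups) == n_samp
    if signals is None:
        signals = 800.0 + np.arange(n_sig)
    cols = [f"s{i:03d}" for i in range(n_samp)]
    ab = pd.DataFrame(x, index=pd.Index(np.asarray(signals, float), name="mz"),
                      columns=cols)
    ann = pd.DataFrame({"group": groups,
                        "age": ages if ages is not None else np.full(n_samp, 60.0),
                        "gender": genders if genders is not None else ["F"] * n_samp},
                       index=pd.Index(cols, name="sample_id"))
    return AlignedTable(ab, ann)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort with default panel and noise, shared read-only."""
    import serapept as sp
    cfg = sp.CohortConfig(seed=123, group_sizes={"control": 6, "non_metastatic": 8,
                                                 "metastatic": 8})
    samples, manifest = sp.generate_cohort(cfg)
    return cfg, samples, manifest
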