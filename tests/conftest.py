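import numpy as np
import pandas as pd
import pytest

from heatmir.containers import ExpressionMatrix
from heatmir.simulate import SimulationConfig, simulate_study


def make_matrix(values, timepoints, n_replicates=2, flags=None, probe_prefix="p"):
    """Small ExpressionMatrix builder for hand-written examples."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    assert n_samples == len(timepoints) * n_replicates
    sample_ids, tp_col, rep_col = [], [], []
    for tp in timepoints:
        for rep in range(1, n_replicates + 1):
            sample_ids.append(f"{tp}_r{rep}")
            tp_col.append(tp)
            rep_col.append(rep)
    probes = [f"{probe_prefix}{i}" for i in range(n_probes)]
    samples = pd.DataFrame(
        {
            "timepoint": pd.Categorical(tp_col, categories=list(timepoints),
                                        ordered=True),
            "replicate": rep_col,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    flag_df = None
    if flags is not None:
        flag_df = pd.DataFrame(np.asarray(flags), index=probes, columns=sample_ids)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=sample_ids),
        samples=samples,
        flags=flag_df,
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study shared by integration-style tests."""
    cfg = SimulationConfig(
        n_mirnas=40, n_genes=200, frac_de_mirnas=0.3, frac_de_genes=0.25,
        n_ppi_modules=1, ppi_module_size=3, n_ppi_background=60, seed=11,
    )
    return simulate_study(cfg)
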