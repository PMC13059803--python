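import numpy as np
import pandas as pd
import pytest

from acylscan import (
    ImputationConfig,
    LFQMatrix,
    SampleDescriptor,
    SimConfig,
    differential_table,
    drop_outlier_replicates,
    impute_missing,
    simulate_experiment,
)


def make_matrix(values, conditions, control_label="EV", protein_ids=None):
    """Build an LFQMatrix from a 2-D array and a list of condition labels.

    Replicate indices are assigned per condition in column order; sample ids
    are "<condition>_<replicate>".
    """
    values = np.asarray(values, dtype=float)
    counters: dict[str, int] = {}
    samples = []
    for cond in conditions:
        counters[cond] = counters.get(cond, 0) + 1
        samples.append(SampleDescriptor(f"{cond}_{counters[cond]}", cond, counters[cond]))
    if protein_ids is None:
        protein_ids = [f"P{i}" for i in range(1, values.shape[0] + 1)]
    df = pd.DataFrame(values, index=protein_ids, columns=[s.sample_id for s in samples])
    df.index.name = "protein"
    return LFQMatrix(values=df, samples=tuple(samples), control_label=control_label)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated screen (300 proteins, 4 baits) with its truth."""
    config = SimConfig(
        n_proteins=300,
        baits=("IcsB", "H1", "H2", "H3"),
        seed=11,
    )
    return simulate_experiment(config), config


@pytest.fixture(scope="session")
def default_sim_pipeline():
    """Default-shape simulation run through QC, imputation and testing once."""
    config = SimConfig(seed=0)
    matrix, truth = simulate_experiment(config)
    cleaned, qc_report = drop_outlier_replicates(matrix, alpha=0.05)
    imputed = impute_missing(cleaned, ImputationConfig(seed=0))
    diff = differential_table(imputed)
    return {
        "config": config,
        "matrix": matrix,
        "truth": truth,
        "cleaned": cleaned,
        "qc_report": qc_report,
        "imputed": imputed,
        "differential": diff,
    }
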