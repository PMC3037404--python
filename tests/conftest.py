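import numpy as np
import pandas as pd
import pytest

from pbmcsig import ExpressionMatrix, SampleTable, SimulationConfig, simulate_expression


@pytest.fixture
def tiny_matrix():
    """4 spots x 4 samples with one missing cell and a duplicate gene symbol."""
    values = pd.DataFrame(
        [[0.1, -0.2, 0.3, 0.4],
         [1.0, 1.1, np.nan, 0.9],
         [-0.5, -0.4, -0.6, -0.55],
         [0.05, 0.0, -0.05, 0.1]],
        index=pd.Index(["s1", "s2", "s3", "s4"], name="spot_id"),
        columns=["a1", "a2", "a3", "a4"],
    )
    genes = pd.Series(["GA", "GB", "GC", "GA"], index=values.index, name="gene_symbol")
    return ExpressionMatrix(values=values, gene_symbols=genes)


@pytest.fixture
def tiny_samples():
    return SampleTable(pd.DataFrame(
        {"subject_id": ["p1", "p1", "p2", "p3"],
         "group": ["case", "case", "control", "control"]},
        index=pd.Index(["a1", "a2", "a3", "a4"], name="sample_id")))


def clean_config(**overrides):
    """A small, noise-free-able simulation config for unit tests."""
    base = dict(
        n_case_subjects=10, n_control_subjects=10,
        samples_per_subject_case=1, samples_per_subject_control=1,
        n_genes=50, n_de_genes=5,
        subject_sd=0.0, residual_sd=0.1, baseline_sd=0.0,
        array_offset_sd=0.0, dye_bias_amplitude=0.0,
        missing_rate=0.0, duplicate_spot_fraction=0.0, seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def small_experiment():
    """Two-group experiment with repeated samples, strong signal, no nuisance."""
    cfg = clean_config(
        n_case_subjects=12, n_control_subjects=12,
        samples_per_subject_case=("total", 16), samples_per_subject_control=1,
        n_genes=300, n_de_genes=30, de_log2fc_range=(1.5, 2.5),
        subject_sd=0.2, residual_sd=0.3, baseline_sd=0.5, seed=11)
    return simulate_expression(cfg)
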