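import numpy as np
import pandas as pd
import pytest

from evsort.io import CountMatrix
from evsort.simulate import SimConfig, generate_count_experiment, generate_sequences


@pytest.fixture
def small_experiment():
    """A compact synthetic experiment with a strong planted export effect."""
    cfg = SimConfig(n_mirna=120, n_exported=20, export_effect=-2.0,
                    dispersion=0.05, motif_plant_prob=1.0, seed=7)
    counts, truth = generate_count_experiment(cfg)
    seqs = generate_sequences(cfg, truth)
    return cfg, counts, truth, seqs


@pytest.fixture
def planted_30():
    """30 sequences of length 22 with the exact hexamer AUUGCA planted in 20
    of them — the canonical motif-recovery fixture."""
    cfg = SimConfig(n_mirna=30, n_exported=20, motif_consensus="AUUGCA",
                    motif_plant_prob=1.0, seq_length_range=(22, 22), seed=11)
    _, truth = generate_count_experiment(cfg)
    seqs = generate_sequences(cfg, truth)
    return cfg, truth, seqs


def toy_counts(mat, compartments, conditions):
    """Build a CountMatrix from a dense array and per-sample labels."""
    mat = np.asarray(mat)
    samples = [f"s{i}" for i in range(mat.shape[1])]
    meta = pd.DataFrame(
        {
            "compartment": compartments,
            "condition": conditions,
            "replicate": [f"r{i}" for i in range(mat.shape[1])],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    frame = pd.DataFrame(mat, columns=samples,
                         index=pd.Index([f"m{i}" for i in range(mat.shape[0])],
                                        name="mirna_id"))
    return CountMatrix(frame, meta)
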