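import numpy as np
import pandas as pd
import pytest

from methscore.io import MethylationMatrix, PhenotypeTable, ProbeAnnotation


def make_annotation(positions, chroms=None, prefix="cg"):
    """Annotation from raw positions (one chromosome unless chroms given)."""
    n = len(positions)
    chroms = chroms or ["chr1"] * n
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": [f"{prefix}{i:04d}" for i in range(n)],
                "chrom": chroms,
                "pos": list(positions),
            }
        )
    )


def make_matrix(values, probe_ids=None, sample_prefix="s"):
    values = np.asarray(values, float)
    m, n = values.shape
    probe_ids = probe_ids or [f"cg{i:04d}" for i in range(m)]
    return MethylationMatrix(
        probe_ids, [f"{sample_prefix}{j}" for j in range(n)], values
    )


def make_phenotypes(y, sample_prefix="s", sample_ids=None):
    ids = sample_ids or [f"{sample_prefix}{j}" for j in range(len(y))]
    return PhenotypeTable(pd.DataFrame({"sample_id": ids, "y": list(y)}))


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def small_study():
    """A small but non-trivial synthetic study shared across tests."""
    from methscore.synth import SimConfig, generate_study

    return generate_study(
        SimConfig(
            m_probes=120,
            n_train=400,
            n_test=150,
            block_size=6,
            rho=0.5,
            h2_true=0.4,
            p_true=0.1,
            prevalence=0.4,
            seed=11,
        )
    )
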