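import numpy as np
import pandas as pd
import pytest

from primertrace import CountTable, SimulationParams, generate_primer, generate_sources


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def tiny_table():
    counts = pd.DataFrame(
        [[3, 0], [1, 2]], index=["s1", "s2"], columns=["asv1", "asv2"], dtype="int64"
    )
    metadata = pd.DataFrame(
        {
            "role": ["soil", "soil"],
            "soil_type": ["DF", "DF"],
            "substrate_type": ["none", "none"],
            "replicate": [1, 2],
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    return CountTable(counts, metadata)


def make_table(counts_arr, roles, **meta):
    """Quick CountTable from an array and per-sample roles."""
    n = len(counts_arr)
    index = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    counts = pd.DataFrame(
        np.asarray(counts_arr),
        index=index,
        columns=[f"asv{j}" for j in range(np.asarray(counts_arr).shape[1])],
        dtype="int64",
    )
    metadata = pd.DataFrame(
        {
            "role": roles,
            "soil_type": meta.get(
                "soil_type", ["DF" if r != "substrate" else "none" for r in roles]
            ),
            "substrate_type": meta.get(
                "substrate_type", ["Oat" if r not in ("soil",) else "none" for r in roles]
            ),
            "replicate": meta.get("replicate", list(range(1, n + 1))),
        },
        index=index,
    )
    return CountTable(counts, metadata)


@pytest.fixture(scope="session")
def small_simulation():
    """A small but complete simulated experiment shared across tests."""
    params = SimulationParams(
        n_soil_taxa=60,
        n_substrate_taxa=15,
        n_shared_taxa=8,
        n_primer_taxa=40,
        seq_length=120,
        depth_source=5000,
        depth_primer=5000,
        seed=42,
    )
    sources = generate_sources(params)
    primer = generate_primer(sources, params)
    return params, sources, primer
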