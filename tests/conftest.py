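import numpy as np
import pandas as pd
import pytest

from pbscreen.sim import SimScreenConfig, simulate_annotation, simulate_screen


def naive_ttaa_scan(seq: str) -> list[int]:
    """Independent exhaustive oracle for TTAA start positions."""
    return [i for i in range(len(seq) - 3) if seq[i : i + 4] == "TTAA"]


@pytest.fixture(scope="session")
def small_screen():
    """A small simulated screen shared by read-only tests."""
    cfg = SimScreenConfig(
        n_chroms=2,
        chrom_length_bp=300_000,
        ttaa_rate=1.5,
        n_genes=6,
        n_experiments=3,
        events_per_experiment=200,
        window_bp=5_000,
        seed=101,
    )
    genome, genes, ttaa = simulate_annotation(cfg)
    records, truth = simulate_screen(cfg, genes, ttaa)
    return cfg, genome, genes, ttaa, records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_records(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random read-level integration records for set-construction oracles."""
    return pd.DataFrame(
        {
            "experiment_id": rng.choice(["e1", "e2", "e3"], n),
            "sample_id": rng.choice(["s1", "s2"], n),
            "chrom": rng.choice(["chr1", "chr2"], n),
            "pos": rng.integers(0, 50, n),
            "orientation": rng.choice(["+", "-"], n),
            "read_count": rng.integers(1, 20, n),
        }
    )
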