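import numpy as np
import pandas as pd
import pytest

from transcompr import (
    ExpressionMatrix,
    HomologMap,
    SimConfig,
    TransCompR,
    generate_paired_datasets,
)


@pytest.fixture(scope="session")
def default_sim():
    """One default-parameter synthetic dataset (fixed seed)."""
    return generate_paired_datasets(SimConfig(seed=123))


@pytest.fixture(scope="session")
def small_sim():
    """A fast reduced-size dataset for unit tests."""
    return generate_paired_datasets(SimConfig(n_genes=400, seed=42))


def build_model(sim, **kwargs):
    mouse, mouse_meta, human, human_meta, _ = sim
    hmap = HomologMap(list(zip(mouse.genes, human.genes)))
    return TransCompR(mouse, human, mouse_meta, human_meta, hmap, **kwargs)


@pytest.fixture(scope="session")
def fitted(small_sim):
    """A fitted model on the small dataset (reduced rounds for speed)."""
    return build_model(small_sim).fit(rounds=25, seed=5)


def random_expr(rng, n_genes=30, n_samples=8, species="human", state="log2", prefix="g"):
    data = pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)),
        index=[f"{prefix}{i:04d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(data, species=species, state=state)
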