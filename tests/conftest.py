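import numpy as np
import pytest

from phenoarc import EventMask, PhenoDataset


@pytest.fixture
def tiny_dataset() -> PhenoDataset:
    """2 genes x 2 phenotypes x 3 times, fully observed."""
    return PhenoDataset(
        genes=["g1", "g2"],
        phenotypes=["A", "B"],
        n_timepoints=3,
        values={
            ("g1", "A"): np.array([0.9, 0.8, 0.1]),
            ("g1", "B"): np.array([0.1, 0.2, 0.9]),
            ("g2", "A"): np.array([0.7, 0.1, 0.2]),
            ("g2", "B"): np.array([0.2, 0.6, 0.8]),
        },
    )


def random_dataset(
    rng: np.random.Generator,
    n_genes: int = 6,
    n_phenotypes: int = 3,
    n_timepoints: int = 4,
    missing_rate: float = 0.0,
) -> PhenoDataset:
    genes = [f"g{i}" for i in range(n_genes)]
    phenotypes = [f"P{i}" for i in range(n_phenotypes)]
    values = {}
    for g in genes:
        for p in phenotypes:
            vec = rng.normal(size=n_timepoints).round(4)
            if missing_rate > 0:
                vec[rng.random(n_timepoints) < missing_rate] = np.nan
            values[(g, p)] = vec
    return PhenoDataset(genes, phenotypes, n_timepoints, values)


def random_mask(
    rng: np.random.Generator,
    n_genes: int = 20,
    n_phenotypes: int = 5,
    n_timepoints: int = 10,
    density: float = 0.4,
) -> EventMask:
    arr = rng.random((n_genes, n_phenotypes, n_timepoints)) < density
    return EventMask(
        [f"g{i}" for i in range(n_genes)],
        [f"P{i}" for i in range(n_phenotypes)],
        arr,
    )
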