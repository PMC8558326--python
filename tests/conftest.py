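import numpy as np
import pandas as pd
import pytest

from prefexpr import CountMatrix, ExpressionMatrix, ScreenConfig, SimulationConfig


@pytest.fixture
def small_config():
    """A tiny noise-free experiment: truth must be recovered exactly."""
    return SimulationConfig(
        n_genes=50,
        n_planted_preferential=5,
        n_planted_specific=2,
        planted_fold=4.0,
        dispersion=0.0,
        seed=7,
    )


@pytest.fixture
def screen_config():
    cfg = SimulationConfig()
    return ScreenConfig(
        target_samples=list(cfg.target_groups),
        comparator_samples=list(cfg.comparator_groups),
        developing_samples=list(cfg.developing_groups),
    )


def make_expr(rows: dict[str, list[float]], samples: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=samples))


def make_counts(matrix, genes, samples, lengths=None, libsizes=None) -> CountMatrix:
    counts = pd.DataFrame(np.asarray(matrix), index=genes, columns=samples)
    lengths = pd.Series(lengths if lengths is not None else [1000] * len(genes), index=genes)
    if libsizes is not None:
        libsizes = pd.Series(libsizes, index=samples, dtype=float)
    return CountMatrix(counts=counts, gene_lengths=lengths, library_sizes=libsizes)
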