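import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ncec import (
    ExpressionMatrix,
    GeneratorConfig,
    generate_expression_truth,
    generate_spot_table,
)
from ncec.preprocess import preprocess_chain

settings.register_profile("ncec", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ncec")


def make_tiny_cfg(**overrides) -> GeneratorConfig:
    """A fast, internally consistent scaled-down design for unit tests."""
    base = dict(
        n_spots=400,
        n_identifiable=300,
        n_pass_pvalue=250,
        n_control_pass=10,
        n_unannotated_pass=10,
        n_annotated_genes=200,
        n_non_endoderm=150,
        category_sizes={"angiogenesis": 20, "somitogenesis": 20, "neurogenesis": 20},
        shared_up=10,
        shared_down=10,
        unique_up_etsrp=5,
        unique_down_etsrp=5,
        unique_up_npas4l=5,
        unique_down_npas4l=5,
        promoter_length=200,
        n_motif_positive=3,
        n_motif_negative=3,
        seed=0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def matrix_from(columns: dict, genes=None, **kwargs) -> ExpressionMatrix:
    genes = genes or [f"g{i}" for i in range(len(next(iter(columns.values()))))]
    values = pd.DataFrame(
        {k: np.asarray(v, dtype=float) for k, v in columns.items()},
        index=pd.Index(genes, name="gene"),
    )
    return ExpressionMatrix(values, **kwargs)


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def default_chain(default_cfg):
    """Default-scale synthetic spot table run through the full filter chain."""
    spots, truth = generate_spot_table(default_cfg)
    matrix, excluded, report = preprocess_chain(spots)
    return spots, truth, matrix, excluded, report


@pytest.fixture(scope="session")
def noisefree_expr():
    """Default-scale expression matrix with zero replicate noise, plus truth."""
    cfg = GeneratorConfig(seed=0, replicate_noise_sd=0.0)
    m, truth = generate_expression_truth(cfg)
    return cfg, m, truth


@pytest.fixture()
def tiny_cfg() -> GeneratorConfig:
    return make_tiny_cfg()
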