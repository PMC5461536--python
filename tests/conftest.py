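import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, print_blob=False)
settings.load_profile("deterministic")

from inhibnet.catalog import (
    CatalyticClass,
    CompatibilityRule,
    PairKey,
    ProteinRecord,
    Role,
    build_gold_standard,
)
from inhibnet.coexpression import ExpressionMatrix
from inhibnet.synth import SynthConfig, generate_world


@pytest.fixture(scope="session")
def small_catalog():
    """Two serine + two metallo proteases, one serpin-like + one TIMP-like inhibitor."""
    return [
        ProteinRecord("prt_s1", Role.PROTEASE, CatalyticClass.SERINE, "S1"),
        ProteinRecord("prt_s2", Role.PROTEASE, CatalyticClass.SERINE, "S1"),
        ProteinRecord("prt_m1", Role.PROTEASE, CatalyticClass.METALLO, "M10"),
        ProteinRecord("prt_m2", Role.PROTEASE, CatalyticClass.METALLO, "M10"),
        ProteinRecord("inh_serpin", Role.INHIBITOR, CatalyticClass.NONE, "I4"),
        ProteinRecord("inh_timp", Role.INHIBITOR, CatalyticClass.NONE, "I35"),
    ]


@pytest.fixture(scope="session")
def small_rules():
    return [
        CompatibilityRule("I4", frozenset({CatalyticClass.SERINE})),
        CompatibilityRule("I35", frozenset({CatalyticClass.METALLO})),
    ]


@pytest.fixture(scope="session")
def small_gold(small_catalog, small_rules):
    annotations = [PairKey("inh_serpin", "prt_s1"), PairKey("inh_timp", "prt_m1")]
    return build_gold_standard(small_catalog, annotations, small_rules)


@pytest.fixture(scope="session")
def planted_world():
    """Fully planted world: every true inhibition carries expression signal."""
    return generate_world(SynthConfig(seed=11, frac_coexpressed_truth=1.0))


@pytest.fixture(scope="session")
def null_world():
    """No planted signal: expression is independent of the truth."""
    return generate_world(SynthConfig(seed=11, frac_coexpressed_truth=0.0))


def make_expression(values: np.ndarray, genes=None, tissue_sizes=None) -> ExpressionMatrix:
    """Small expression fixture; samples split evenly into tissues."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    if tissue_sizes is None:
        tissue_sizes = [n_samples]
    samples, tissue_of = [], {}
    k = 0
    for t, size in enumerate(tissue_sizes):
        for j in range(size):
            s = f"t{t}_s{j}"
            samples.append(s)
            tissue_of[s] = f"t{t}"
            k += 1
    assert k == n_samples
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), pd.Series(tissue_of)
    )
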