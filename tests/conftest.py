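import numpy as np
import pandas as pd
import pytest

from anchorscope import (
    ExpressionMatrix,
    PreprocessConfig,
    SyntheticSpec,
    generate_cohort,
    preprocess,
)


@pytest.fixture(scope="session")
def planted_spec() -> SyntheticSpec:
    """Two cohorts with three planted correlates, one differential ratio pair
    and one pivot wired to both its members; no background edges."""
    return SyntheticSpec(
        n_samples_per_cohort=(300, 200),
        n_genes=200,
        planted_correlates=(("POS1", 0.75), ("POS2", 0.5), ("NEG1", -0.55)),
        planted_ratio_pairs=(("RA", "RB", 2.0),),
        planted_pivots=(("PIV", (0,)),),
        seed=7,
    )


@pytest.fixture(scope="session")
def cohort_a_log(planted_spec) -> ExpressionMatrix:
    return preprocess(generate_cohort(planted_spec, 0), PreprocessConfig())


@pytest.fixture(scope="session")
def cohort_b_log(planted_spec) -> ExpressionMatrix:
    return preprocess(generate_cohort(planted_spec, 1), PreprocessConfig())


def make_matrix(values, genes=None, samples=None, scale_state="intensity", **kw) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale_state=scale_state, **kw
    )
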