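import numpy as np
import pandas as pd
import pytest

from tfactivity import ExpressionMatrix, PWM, default_matrix_library


@pytest.fixture(scope="session")
def matrix_library():
    return default_matrix_library()


@pytest.fixture
def sharp_pwm():
    """Single-consensus 4-mer: TGCA with near-deterministic columns."""
    counts = np.zeros((4, 4))
    for i, base in enumerate("TGCA"):
        counts[i, "ACGT".index(base)] = 20
    return PWM("SHARP_TGCA", counts)


@pytest.fixture
def two_pos_pwm():
    return PWM("TWO_POS", np.array([[8, 0, 0, 0], [4, 4, 0, 0]]))


def make_expression(
    values: dict[str, list[float]],
    groups: list[str],
    covariates: pd.DataFrame | None = None,
    pairing: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Small expression matrix from literal per-gene sample values."""
    samples = [f"S{i}" for i in range(len(groups))]
    return ExpressionMatrix(
        values=pd.DataFrame.from_dict(values, orient="index", columns=samples),
        groups=pd.Series(groups, index=samples),
        covariates=covariates.set_axis(samples) if covariates is not None else None,
        pairing=pairing,
    )


@pytest.fixture
def expression_factory():
    return make_expression
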