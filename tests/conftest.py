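import numpy as np
import pandas as pd
import pytest

from endosig.preprocess import ExpressionStudy


def two_group_matrix(
    n_genes: int,
    n_per_group: int,
    n_de: int = 0,
    effect: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Gene x sample matrix with the first ``n_de`` genes shifted in group 2."""
    rng = np.random.default_rng(seed)
    X = rng.normal(8.0, 1.0, size=(n_genes, 1)) + rng.normal(
        0.0, noise_sd, size=(n_genes, 2 * n_per_group)
    )
    if n_de:
        signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
        X[:n_de, n_per_group:] += effect * noise_sd * signs[:, None]
    matrix = pd.DataFrame(
        X,
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=[f"s{i:02d}" for i in range(2 * n_per_group)],
    )
    labels = ["control"] * n_per_group + ["exposed"] * n_per_group
    return matrix, labels


@pytest.fixture
def two_probe_study() -> ExpressionStudy:
    """Two probes for gene G (means 5 and 7), one probe for gene H."""
    matrix = pd.DataFrame(
        {
            "s1": [4.0, 6.0, 1.0],
            "s2": [6.0, 8.0, 3.0],
        },
        index=["pG_a", "pG_b", "pH"],
    )
    probe_map = {
        "pG_a": ("G", "111"),
        "pG_b": ("G", "111"),
        "pH": ("H", None),
    }
    return ExpressionStudy(
        study_id="fix",
        matrix=matrix,
        groups={"s1": "control", "s2": "exposed"},
        probe_map=probe_map,
    )
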