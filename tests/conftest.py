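"""Shared fixtures: small synthetic studies and canonical item sets."""

import numpy as np
import pytest

from likertdif import (
    GroupSpec,
    GRMItemParams,
    ResponseMatrix,
    ScaleDefinition,
    StudySpec,
    generate_study,
)


@pytest.fixture(scope="session")
def eight_item_scale() -> ScaleDefinition:
    return ScaleDefinition({"scale": [f"i{j}" for j in range(8)]})


@pytest.fixture(scope="session")
def two_group_study(eight_item_scale):
    """DIF-free two-group study, 300 persons per group, 8 items."""
    spec = StudySpec(
        groups=[GroupSpec("A", 300), GroupSpec("B", 300)],
        scale=eight_item_scale,
        seed=11,
    )
    return generate_study(spec)


@pytest.fixture(scope="session")
def standard_items() -> list[GRMItemParams]:
    """Eight identical well-behaved graded items."""
    return [GRMItemParams(f"i{j}", 1.8, np.array([-1.0, 0.0, 1.0])) for j in range(8)]


def make_matrix(codes, K=4, item_ids=None) -> ResponseMatrix:
    codes = np.asarray(codes, dtype=float)
    n, j = codes.shape
    return ResponseMatrix(
        codes,
        [f"p{i}" for i in range(n)],
        item_ids or [f"i{k}" for k in range(j)],
        K,
    )
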