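"""Shared fixtures and hypothesis strategies for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings, strategies as st

from mgrm.model import ItemBank, ItemParameters

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@st.composite
def valid_items(draw, max_H: int = 3, max_K: int = 4):
    """Random valid simple-structure items with well-separated boundaries."""
    H = draw(st.integers(1, max_H))
    K = draw(st.integers(1, max_K))
    dim = draw(st.integers(1, H))
    a_val = draw(st.floats(0.3, 3.0, allow_nan=False))
    b1 = draw(st.floats(-2.5, 0.5, allow_nan=False))
    gaps = draw(
        st.lists(st.floats(0.2, 1.5, allow_nan=False), min_size=K - 1, max_size=K - 1)
    )
    b = np.concatenate(([b1], b1 + np.cumsum(gaps))) if K > 1 else np.array([b1])
    a = np.zeros(H)
    a[dim - 1] = a_val
    return ItemParameters(item_id=1, loading_dim=dim, a=a, b=b)


@st.composite
def thetas_for(draw, H: int):
    vals = draw(
        st.lists(st.floats(-3.5, 3.5, allow_nan=False), min_size=H, max_size=H)
    )
    return np.array(vals)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


def tiny_bank(H: int = 1, K: int = 3, L: int = 4, seed: int = 5, D: float = 1.0) -> ItemBank:
    """Deterministic small bank for likelihood/EM fixtures."""
    r = np.random.default_rng(seed)
    items = []
    per_dim = L // H
    for j in range(L):
        dim = j // per_dim + 1
        a = np.zeros(H)
        a[dim - 1] = r.uniform(1.1, 2.8)
        b1 = r.uniform(-2.0, -0.5)
        b = b1 + np.concatenate(([0.0], np.cumsum(r.uniform(0.5, 1.2, K - 1))))
        items.append(ItemParameters(item_id=j + 1, loading_dim=dim, a=a, b=b[:K], D=D))
    return ItemBank(items=tuple(items))
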