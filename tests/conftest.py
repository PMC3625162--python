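"""Shared fixtures and builders for the test suite."""

import numpy as np
import pandas as pd
import pytest

from zygoct import CtMatrix, RQMatrix


def make_ct(values, cards=None, assay_meta=None):
    """Build a CtMatrix from a dict-of-dicts / DataFrame; one card by default."""
    df = pd.DataFrame(values, dtype=float)
    if cards is None:
        cards = pd.Series({s: "card1" for s in df.columns})
    elif isinstance(cards, dict):
        cards = pd.Series(cards)
    return CtMatrix(df, cards, assay_meta)


def random_ct(rng, n_assays=5, n_samples=6, n_cards=2, nondetect_rate=0.1):
    """Random CtMatrix with values in a safe range and scattered non-detects."""
    assays = [f"A{i}" for i in range(n_assays)]
    samples = [f"S{j}" for j in range(n_samples)]
    vals = rng.uniform(18, 33, size=(n_assays, n_samples))
    mask = rng.random((n_assays, n_samples)) < nondetect_rate
    vals[mask] = np.nan
    # keep every card non-degenerate: force one detected value per sample
    for j in range(n_samples):
        if np.isnan(vals[:, j]).all():
            vals[0, j] = rng.uniform(18, 33)
    cards = pd.Series(
        {s: f"card{j % n_cards}" for j, s in enumerate(samples)}
    )
    return CtMatrix(pd.DataFrame(vals, index=assays, columns=samples), cards)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_card_ct():
    """Card A medians 22, card B median 23 — the worked correction example."""
    return make_ct(
        {
            "s1": {"g1": 20.0, "g2": 22.0, "g3": 24.0},
            "s2": {"g1": 21.0, "g2": 23.0, "g3": 25.0},
        },
        cards={"s1": "A", "s2": "B"},
    )


@pytest.fixture
def simple_rq():
    return RQMatrix(
        pd.DataFrame(
            {"s1": {"g1": 1.0, "g2": 4.0}, "s2": {"g1": 2.0, "g2": 1.0}}
        )
    )
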