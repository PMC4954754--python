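import numpy as np
import pandas as pd
import pytest

from uprtriage import synthetic


@pytest.fixture
def small_screen_config():
    """Small, fast screen: one 384-well plate, 16+16 controls."""
    return synthetic.ScreenSimConfig(
        n_plates=1,
        wells_per_plate=384,
        n_high_controls=16,
        n_low_controls=16,
        high_mean=620.0,
        low_mean=100.0,
        cv=0.05,
        seed=11,
    )


@pytest.fixture
def noise_free_screen_config(small_screen_config):
    cfg = small_screen_config
    return synthetic.ScreenSimConfig(
        n_plates=cfg.n_plates,
        wells_per_plate=cfg.wells_per_plate,
        n_high_controls=cfg.n_high_controls,
        n_low_controls=cfg.n_low_controls,
        high_mean=cfg.high_mean,
        low_mean=cfg.low_mean,
        cv=0.0,
        seed=cfg.seed,
    )


@pytest.fixture
def geneset_catalog():
    return synthetic.default_geneset_catalog()


def make_records(rows):
    """Per-compound funnel records from (id, primary, confirm_mean, counter_mean)."""
    return pd.DataFrame(
        rows, columns=["compound_id", "primary_pct", "confirm_mean", "counter_mean"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)
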