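"""Shared fixtures: simulated herds at a few scales, processed artifacts."""

import numpy as np
import pandas as pd
import pytest

from feedphen.cfi import build_cfi_series, fit_all_cfi_lines
from feedphen.config import SimConfig
from feedphen.growth import RobustGrowthFit, fit_all_growth
from feedphen.pipeline import aggregate_daily
from feedphen.qc import apply_qc
from feedphen.simulate import simulate_population


@pytest.fixture(scope="session")
def clean_config():
    """Anomaly-free default herd, small enough for per-test reuse."""
    return SimConfig(n_pigs=30, seed=42, anomaly_rates={})


@pytest.fixture(scope="session")
def clean_herd(clean_config):
    return simulate_population(clean_config)


@pytest.fixture(scope="session")
def noisy_herd():
    """Default herd with the standard anomaly rates."""
    return simulate_population(SimConfig(n_pigs=30, seed=43))


@pytest.fixture(scope="session")
def processed_herd(clean_herd):
    """Clean herd taken through QC, daily aggregation, growth fits and the
    cumulative-intake series — the shared substrate of downstream tests."""
    clean, report = apply_qc(clean_herd.events)
    daily = aggregate_daily(clean)
    growth_fits = fit_all_growth(daily)
    series = build_cfi_series(daily)
    cfi_fits = fit_all_cfi_lines(series)
    return {
        "sim": clean_herd,
        "clean": clean,
        "qc_report": report,
        "daily": daily,
        "growth_fits": growth_fits,
        "series": series,
        "cfi_fits": cfi_fits,
    }


def make_linear_animal(pig_id: int, fcr: float, adg: float = 1.0,
                       bw0: float = 28.0, days: int = 100):
    """An animal with exactly linear growth and exactly linear CFI vs BW.

    Returns (series DataFrame with pig_id/day/cfi_kg/bw_kg, growth fit).
    """
    day = np.arange(days, dtype=float)
    bw = bw0 + adg * day
    cfi = fcr * (bw - bw0)
    series = pd.DataFrame({
        "pig_id": pig_id, "day": day, "cfi_kg": cfi, "bw_kg": bw,
    })
    fit = RobustGrowthFit(pig_id=pig_id, slope=adg, intercept=bw0,
                          pseudo_r2=1.0, n_days=days, retained=True)
    return series, fit
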