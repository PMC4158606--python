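from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from lspdetrend import PlantedSignal, SimConfig, simulate_counts

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def comorbidity_table() -> pd.DataFrame:
    """Published case/control co-occurrence counts for a myasthenia gravis
    exacerbation screen (case cohort 204, control cohort 2582), with the
    incidence ratios as printed."""
    return pd.read_csv(DATA_DIR / "comorbidity_table.tsv", sep="\t")


@pytest.fixture(scope="session")
def confound_sim():
    """200 chronic-fraction codes riding a growing, 6-month-seasonal total.

    Ten background codes carry the hospital-wide traffic; the chronic codes
    are fixed proportions of it, so any apparent seasonality they show is
    entirely the shared hospitalization trend.
    """
    fractions = {10 + i: 0.003 + 0.005 * (i / 199) for i in range(200)}
    cfg = SimConfig(
        n_codes=210,
        months=156,
        baseline_rates=2000.0,
        chronic_fraction=fractions,
        seed=2024,
    )
    sim = simulate_counts(cfg, materialize_events=False)
    chronic_codes = [f"C{i:04d}" for i in sorted(fractions)]
    return sim, chronic_codes


@pytest.fixture(scope="session")
def planted_sim():
    """50 codes with a 12-month signal (amplitude 0.3, Poisson mean 200)
    over 120 months; phases spread evenly so the summed series carries no
    net seasonal component."""
    cfg = SimConfig(
        n_codes=50,
        months=120,
        baseline_rates=200.0,
        growth_doubling_years=None,
        total_season_amplitude=0.0,
        planted_signals=tuple(
            PlantedSignal(code_index=i, period=12.0, phase=12.0 * i / 50,
                          amplitude=0.3)
            for i in range(50)
        ),
        seed=7,
    )
    return simulate_counts(cfg, materialize_events=False)
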