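import numpy as np
import pytest

from fishstatus import SimConfig, simulate_panel
from fishstatus.ramio import StockPanel, StockSeries


@pytest.fixture(scope="session")
def msy_panel():
    """25 stocks held exactly at the MSY equilibrium (no noise, no missingness)."""
    cfg = SimConfig(
        n_stocks=25,
        n_years=67,
        start_year=1950,
        exploitation_scenario="constant",
        constant_u_multiplier=1.0,
        b0_fraction=0.5,
        obs_sd=0.0,
        missing_recent_fraction=0.0,
        seed=11,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def noisy_panel():
    """Small realistic panel: fish-down-then-rebuild with noise and missingness."""
    cfg = SimConfig(n_stocks=40, n_years=50, start_year=1960, seed=7)
    return simulate_panel(cfg)


def build_target_panel(n_stocks=25, n_years=68, start_year=1949, seed=3):
    """Panel sitting exactly at (B/B_MSY, U/U_MSY) = (1, 1) from the second year on.

    Year one starts unfished at K with a pulse harvest U=1/2, which moves the
    stock to K/2 exactly (growth is zero at B=K) and makes K the historical
    maximum, so half the historical maximum equals B_MSY = K/2 and both
    target definitions coincide at 1 thereafter. The pulse-year exploitation
    is unreported (as in real assessments' patchy early years), so every
    reported (b, u) pair sits exactly on the target lines.
    """
    rng = np.random.default_rng(seed)
    years = start_year + np.arange(n_years)
    stocks = []
    for i in range(n_stocks):
        K = float(np.exp(rng.normal(np.log(1e5), 1.0)))
        r = float(rng.uniform(0.2, 0.6))
        B = np.full(n_years, K / 2.0)
        B[0] = K
        U = np.full(n_years, r / 2.0)
        U[0] = np.nan
        stocks.append(
            StockSeries(
                stock_id=f"at_target_{i:02d}",
                years=years,
                B=B,
                U=U,
                catch=U * B,
                B_MSY_assess=K / 2.0,
                U_MSY_assess=r / 2.0,
            )
        )
    return StockPanel(stocks=stocks, provenance={"source": "build_target_panel"})


@pytest.fixture(scope="session")
def at_target_panel():
    return build_target_panel()
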