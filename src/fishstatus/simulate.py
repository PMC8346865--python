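"""Synthetic assessed-stock panels with known truth.

Stocks follow Schaefer (logistic) surplus-production dynamics,

    B_{t+1} = B_t + r B_t (1 - B_t / K) - C_t,      C_t = U_t B_t,

which has closed-form reference points B_MSY = K/2 and U_MSY = r/2, so
recovery of targets from simulated panels can be checked exactly. The
generator emulates the statistical structure of a real assessment panel:
carrying capacities spanning orders of magnitude (lognormal K), heterogeneous
productivities, lognormal observation error on biomass and exploitation rate,
and truncated recent years for a fraction of stocks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ramio import StockPanel, StockSeries

EXPLOITATION_SCENARIOS = ("fish_down_then_rebuild", "constant", "random_walk")

#: biomass floor, as a fraction of K, below which a trajectory is flagged
BIOMASS_FLOOR_FRAC = 1e-3
_MAX_RETRIES = 20


class SimulationError(RuntimeError):
    """Dynamics collapsed to the biomass floor for every retry."""


@dataclass
class SimConfig:
    """Study conditions for a synthetic panel.

    Defaults describe a panel of 200 stocks observed 1950-2016 with carrying
    capacities spanning several orders of magnitude, moderate observation
    error, and a fifth of stocks missing up to five recent years.
    """

    n_stocks: int = 200
    n_years: int = 67
    start_year: int = 1950
    carrying_capacity_log_mean: float = math.log(1e5)
    carrying_capacity_log_sd: float = 1.5
    growth_rate_range: tuple[float, float] = (0.1, 0.8)
    exploitation_scenario: str = "fish_down_then_rebuild"
    obs_sd: float = 0.2
    missing_recent_fraction: float = 0.2
    max_missing_years: int = 5
    seed: int = 0
    # constant-scenario knobs: U = constant_u_multiplier * U_MSY, B_0 = b0_fraction * K
    constant_u_multiplier: float = 1.0
    b0_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.n_stocks < 1 or self.n_years < 2:
            raise ValueError("need n_stocks >= 1 and n_years >= 2")
        lo, hi = self.growth_rate_range
        if not (0 < lo <= hi < 2):
            raise ValueError("growth_rate_range must lie within (0, 2)")
        if self.obs_sd < 0:
            raise ValueError("obs_sd must be >= 0")
        if not 0 <= self.missing_recent_fraction <= 1:
            raise ValueError("missing_recent_fraction must be in [0, 1]")
        if self.max_missing_years < 0:
            raise ValueError("max_missing_years must be >= 0")
        if self.exploitation_scenario not in EXPLOITATION_SCENARIOS:
            raise ValueError(f"unknown scenario {self.exploitation_scenario!r}")


@dataclass
class TrueStock:
    """Ground truth for one simulated stock (B_MSY = K/2, U_MSY = r/2)."""

    stock_id: str
    K: float
    r: float
    B: np.ndarray
    U: np.ndarray
    C: np.ndarray
    floored: bool = False

    @property
    def B_MSY(self) -> float:
        return self.K / 2.0

    @property
    def U_MSY(self) -> float:
        return self.r / 2.0


def _exploitation_path(config: SimConfig, r: float, rng: np.random.Generator) -> np.ndarray:
    """Per-year exploitation rate under the configured scenario."""
    n = config.n_years
    umsy = r / 2.0
    if config.exploitation_scenario == "constant":
        return np.full(n, config.constant_u_multiplier * umsy)
    if config.exploitation_scenario == "fish_down_then_rebuild":
        # ramp up to overfishing over the first 60% of years, then ease back
        # below U_MSY: reproduces a depletion low roughly a third from the end.
        n_up = max(int(round(0.6 * n)), 1)
        up = np.linspace(0.2 * umsy, 1.8 * umsy, n_up)
        down = np.linspace(1.8 * umsy, 0.9 * umsy, n - n_up + 1)[1:]
        return np.concatenate([up, down])
    # random walk on log U, clipped to a plausible band around U_MSY
    steps = rng.normal(0.0, 0.1, size=n - 1)
    logu = np.log(umsy) + np.concatenate([[0.0], np.cumsum(steps)])
    return np.clip(np.exp(logu), 0.01 * umsy, min(3.0 * umsy, 0.95))


def _project(K: float, r: float, U: np.ndarray, B0: float) -> tuple[np.ndarray, np.ndarray, bool]:
    """Run Schaefer dynamics; returns (B, C, hit_floor)."""
    n = len(U)
    B = np.empty(n)
    C = np.empty(n)
    floor = BIOMASS_FLOOR_FRAC * K
    hit = False
    B[0] = B0
    for t in range(n):
        C[t] = U[t] * B[t]
        if t + 1 < n:
            nxt = B[t] + r * B[t] * (1.0 - B[t] / K) - C[t]
            if nxt < floor:
                nxt = floor
                hit = True
            B[t + 1] = nxt
    return B, C, hit


def simulate_panel(config: SimConfig) -> StockPanel:
    """Simulate a panel; truths are attached to each StockSeries.

    Observed biomass and exploitation carry independent lognormal error of
    log-SD ``obs_sd``; catch is reported exactly. If a stock's dynamics hit
    the biomass floor, its exploitation history (and K, r) is redrawn up to a
    bounded number of times before erroring out.
    """
    rng = np.random.default_rng(config.seed)
    years = config.start_year + np.arange(config.n_years)
    width = len(str(config.n_stocks))
    stocks: list[StockSeries] = []
    n_missing = int(round(config.missing_recent_fraction * config.n_stocks))
    missing_ids = set(rng.choice(config.n_stocks, size=n_missing, replace=False).tolist())

    for i in range(config.n_stocks):
        for attempt in range(_MAX_RETRIES):
            K = float(np.exp(rng.normal(config.carrying_capacity_log_mean,
                                        config.carrying_capacity_log_sd)))
            r = float(rng.uniform(*config.growth_rate_range))
            U = _exploitation_path(config, r, rng)
            if config.b0_fraction is not None:
                b0 = config.b0_fraction * K
            elif config.exploitation_scenario == "constant":
                b0 = 0.5 * K
            else:
                b0 = K
            B, C, hit = _project(K, r, U, b0)
            if not hit:
                break
        else:
            raise SimulationError(
                f"stock {i}: extinction under scenario after {_MAX_RETRIES} retries"
            )
        truth = TrueStock(stock_id=f"stock_{i:0{width}d}", K=K, r=r, B=B, U=U, C=C, floored=hit)

        if config.obs_sd > 0:
            b_err = np.exp(rng.normal(0.0, config.obs_sd, size=config.n_years))
            u_err = np.exp(rng.normal(0.0, config.obs_sd, size=config.n_years))
        else:
            b_err = u_err = np.ones(config.n_years)
        B_obs = B * b_err
        U_obs = U * u_err

        yrs = years
        if i in missing_ids and config.max_missing_years > 0:
            cut = int(rng.integers(1, config.max_missing_years + 1))
            cut = min(cut, config.n_years - 1)
            yrs, B_obs, U_obs, Cc = years[:-cut], B_obs[:-cut], U_obs[:-cut], C[:-cut]
        else:
            Cc = C

        stocks.append(
            StockSeries(
                stock_id=truth.stock_id,
                years=yrs,
                B=B_obs,
                U=U_obs,
                catch=Cc,
                B_MSY_assess=truth.B_MSY,
                U_MSY_assess=truth.U_MSY,
                truth={"K": K, "r": r, "B": B, "U": U, "C": C,
                       "B_MSY": truth.B_MSY, "U_MSY": truth.U_MSY,
                       "floored": truth.floored},
            )
        )
    return StockPanel(
        stocks=stocks,
        provenance={"source": "simulate_panel", "config": asdict(config), "seed": config.seed},
    )


def export_ram_like(panel: StockPanel, timeseries_path, refpoints_path) -> None:
    """Write the panel in the long CSV dialect read by :func:`~fishstatus.ramio.read_ram_long`.

    Series ids: TB (total biomass), ER (exploitation rate), TC (catch), plus
    BdivBmsy / UdivUmsy when pre-divided ratios are present; reference points
    Bmsy / Umsy. A JSON metadata sidecar recording provenance (including the
    seed, for simulated panels) is written next to the time-series file.
    """
    if not panel.stocks:
        raise ValueError("cannot export an empty panel")
    ts_rows: list[tuple[str, str, int, float]] = []
    rp_rows: list[tuple[str, str, float]] = []
    series_ids = {"B": "TB", "U": "ER", "catch": "TC", "b_ratio": "BdivBmsy", "u_ratio": "UdivUmsy"}
    for s in panel.stocks:
        for attr, sid in series_ids.items():
            arr = getattr(s, attr)
            if arr is None:
                continue
            for yr, val in zip(s.years, arr):
                if not np.isnan(val):
                    ts_rows.append((s.stock_id, sid, int(yr), float(val)))
        if s.B_MSY_assess is not None:
            rp_rows.append((s.stock_id, "Bmsy", float(s.B_MSY_assess)))
        if s.U_MSY_assess is not None:
            rp_rows.append((s.stock_id, "Umsy", float(s.U_MSY_assess)))
    pd.DataFrame(ts_rows, columns=["stock_id", "series_id", "year", "value"]).to_csv(
        timeseries_path, index=False
    )
    pd.DataFrame(rp_rows, columns=["stock_id", "parameter_id", "value"]).to_csv(
        refpoints_path, index=False
    )
    meta = {k: v for k, v in panel.provenance.items()}
    Path(str(timeseries_path) + ".meta.json").write_text(json.dumps(meta, indent=2, default=str))
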