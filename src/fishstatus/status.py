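"""Per-stock diagnostics: Kobe quadrants, 10-year trends, within-target proportions.

The Kobe plane classifies a stock by its most recent (B/B_target, U/U_MSY)
pair: green when both targets are met, red when neither is, yellow when only
one fails. Boundary values (ratio exactly 1) count as within target. Trends
are ordinary-least-squares slopes of each ratio on calendar year over the
stock's most recent 10 observed years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .targets import RatioPanel

QUADRANTS = ("green", "yellow_b", "yellow_u", "red")


def kobe_classify(b: float, u: float) -> str:
    """Quadrant for one (B/B_target, U/U_MSY) pair; boundaries count as within target."""
    if b < 0 or u < 0:
        raise ValueError("ratios must be non-negative")
    b_ok = b >= 1.0
    u_ok = u <= 1.0
    if b_ok and u_ok:
        return "green"
    if b_ok:
        return "yellow_u"  # only the exploitation criterion fails
    if u_ok:
        return "yellow_b"  # only the biomass criterion fails
    return "red"


def trend_slope(
    years: np.ndarray,
    values: np.ndarray,
    window_years: int = 10,
    min_trend_years: int = 8,
) -> tuple[float, int]:
    """OLS slope (per year) over the most recent ``window_years`` observed years.

    "Most recent" means the stock's last observed years, not a fixed calendar
    window. Returns (slope, n_used); slope is NaN when fewer than
    ``min_trend_years`` observations are available in the window.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    yrs, vals = years[ok], values[ok]
    if len(yrs) == 0:
        return np.nan, 0
    yrs, vals = yrs[-window_years:], vals[-window_years:]
    n = len(yrs)
    if n < min_trend_years or n < 2:
        return np.nan, n
    slope = float(np.polyfit(yrs, vals, 1)[0])
    return slope, n


def stock_status(
    ratios: RatioPanel,
    window_years: int = 10,
    min_trend_years: int = 8,
) -> pd.DataFrame:
    """Per-stock status table: last estimates, Kobe quadrant, recent trends.

    ``last_year`` is the most recent year with both ratios; stocks with no
    such year are omitted.
    """
    rows = []
    for sid in ratios.stock_ids:
        b = ratios.b[sid].to_numpy(dtype=float)
        u = ratios.u[sid].to_numpy(dtype=float)
        yrs = ratios.years
        both = ~np.isnan(b) & ~np.isnan(u)
        if not both.any():
            continue
        last_idx = np.flatnonzero(both)[-1]
        b_slope, b_n = trend_slope(yrs, b, window_years, min_trend_years)
        u_slope, u_n = trend_slope(yrs, u, window_years, min_trend_years)
        rows.append(
            {
                "stock_id": sid,
                "last_year": int(yrs[last_idx]),
                "b_last": float(b[last_idx]),
                "u_last": float(u[last_idx]),
                "quadrant": kobe_classify(float(b[last_idx]), float(u[last_idx])),
                "b_slope": b_slope,
                "u_slope": u_slope,
                "slope_n": int(min(b_n, u_n)),
                "target_kind": ratios.target_kind,
            }
        )
    if not rows:
        raise ValueError("no stock has both ratios in any year")
    return pd.DataFrame(rows)


def ratio_histogram(values: np.ndarray, bin_width: float = 0.1) -> pd.DataFrame:
    """Fixed-width histogram of a ratio distribution (bins from 0)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    top = max(float(np.max(v, initial=0.0)), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(v, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def status_summary(statuses: dict[str, pd.DataFrame], bin_width: float = 0.1) -> dict:
    """Distribution summaries per target kind plus the across-target maxima.

    ``statuses`` maps target_kind -> stock_status table. Percentages are on
    the 0-100 scale. Trend percentages are among stocks with a defined slope.
    The "up to" figures are the maxima across target definitions.
    """
    if not statuses:
        raise ValueError("no statuses given")
    per_kind: dict[str, dict] = {}
    for kind, st in statuses.items():
        n = len(st)
        b_slopes = st["b_slope"].dropna()
        u_slopes = st["u_slope"].dropna()
        per_kind[kind] = {
            "n_stocks": int(n),
            "pct_below_biomass_target": 100.0 * float((st["b_last"] < 1.0).mean()),
            "pct_above_exploitation_target": 100.0 * float((st["u_last"] > 1.0).mean()),
            "pct_biomass_trending_down": (
                100.0 * float((b_slopes < 0).mean()) if len(b_slopes) else np.nan
            ),
            "pct_exploitation_trending_up": (
                100.0 * float((u_slopes > 0).mean()) if len(u_slopes) else np.nan
            ),
            "n_with_trend": int(len(b_slopes)),
            "mean_b_slope": float(b_slopes.mean()) if len(b_slopes) else np.nan,
            "mean_u_slope": float(u_slopes.mean()) if len(u_slopes) else np.nan,
            "quadrant_fractions": (
                st["quadrant"].value_counts(normalize=True).to_dict()
            ),
            "b_last_histogram": ratio_histogram(st["b_last"].to_numpy(), bin_width),
            "u_last_histogram": ratio_histogram(st["u_last"].to_numpy(), bin_width),
        }
    keys = (
        "pct_below_biomass_target",
        "pct_above_exploitation_target",
        "pct_biomass_trending_down",
        "pct_exploitation_trending_up",
    )
    up_to = {
        f"up_to_{k}": float(np.nanmax([per_kind[kind][k] for kind in per_kind]))
        for k in keys
    }
    return {"per_target": per_kind, **up_to}


def proportion_series(
    ratios: RatioPanel,
    start_year: int = 1950,
    min_stocks_per_year: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """Yearly within-target fractions since ``start_year``, plus extrema.

    Within biomass target: b >= 1; within exploitation target: u <= 1, among
    stocks reporting that ratio in that year. Years with fewer than
    ``min_stocks_per_year`` reporting stocks are undefined. The extrema
    report gives the maximum proportion below the biomass target / above the
    exploitation target (earliest year on ties, ties logged) and the
    improvement to the final defined year, in percentage points.
    """
    b, u = ratios.b, ratios.u
    years = [y for y in ratios.years if y >= start_year]
    rows = []
    for y in years:
        bv = b.loc[y].to_numpy(dtype=float)
        uv = u.loc[y].to_numpy(dtype=float)
        nb = int(np.sum(~np.isnan(bv)))
        nu = int(np.sum(~np.isnan(uv)))
        fb = float(np.mean(bv[~np.isnan(bv)] >= 1.0)) if nb >= min_stocks_per_year else np.nan
        fu = float(np.mean(uv[~np.isnan(uv)] <= 1.0)) if nu >= min_stocks_per_year else np.nan
        rows.append(
            {"year": int(y), "frac_within_b": fb, "frac_within_u": fu,
             "n_stocks_b": nb, "n_stocks_u": nu}
        )
    table = pd.DataFrame(rows).set_index("year")
    if table[["frac_within_b", "frac_within_u"]].isna().all().all():
        raise ValueError("no year meets min_stocks_per_year")

    def _extremum(frac_within: pd.Series) -> dict:
        below = (100.0 * (1.0 - frac_within)).dropna()
        peak = float(below.max())
        at = below.index[np.isclose(below, peak)]
        final = float(below.iloc[-1])
        return {
            "max_pct": peak,
            "max_year": int(at[0]),
            "tied_years": [int(y) for y in at] if len(at) > 1 else [],
            "final_year": int(below.index[-1]),
            "final_pct": final,
            "improvement_pct_points": peak - final,
        }

    extrema = {
        "below_biomass_target": _extremum(table["frac_within_b"]),
        "above_exploitation_target": _extremum(table["frac_within_u"]),
        "target_kind": ratios.target_kind,
    }
    return table, extrema
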