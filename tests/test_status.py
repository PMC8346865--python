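import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fishstatus import (
    kobe_classify,
    make_ratios,
    proportion_series,
    status_summary,
    stock_status,
    trend_slope,
)
from fishstatus.targets import RatioPanel

from oracles import loop_ols_slope


def ratio_panel_from_arrays(b_by_stock, u_by_stock=None, years=None):
    some = next(iter(b_by_stock.values()))
    years = np.arange(1950, 1950 + len(some)) if years is None else years
    idx = pd.Index(years, name="year")
    b = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in b_by_stock.items()}, index=idx)
    u = (
        b.copy()
        if u_by_stock is None
        else pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in u_by_stock.items()}, index=idx)
    )
    cols = b.columns
    return RatioPanel(
        b=b, u=u, target_kind="assessment_bmsy",
        mean_biomass=pd.Series(1.0, index=cols), mean_catch=pd.Series(1.0, index=cols),
    )


@pytest.mark.parametrize(
    "b,u,expect",
    [
        (1.2, 0.8, "green"),
        (0.5, 1.5, "red"),
        (1.0, 1.0, "green"),  # boundaries count as within target
        (0.9, 0.9, "yellow_b"),
        (1.5, 1.5, "yellow_u"),
    ],
)
def test_kobe_quadrants(b, u, expect):
    assert kobe_classify(b, u) == expect


def test_kobe_rejects_negative():
    with pytest.raises(ValueError):
        kobe_classify(-0.1, 0.5)


@given(st.lists(st.tuples(st.floats(0, 5), st.floats(0, 5)), min_size=1, max_size=50))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_kobe_partition(pairs):
    """Quadrant fractions always partition the classified stocks."""
    quads = [kobe_classify(b, u) for b, u in pairs]
    counts = pd.Series(quads).value_counts(normalize=True)
    assert counts.sum() == pytest.approx(1.0)
    assert set(counts.index) <= {"green", "yellow_b", "yellow_u", "red"}


def test_trend_slope_exact_line():
    years = np.arange(2000, 2010)
    slope, n = trend_slope(years, 0.1 * (years - 2000) + 1.0)
    assert slope == pytest.approx(0.1) and n == 10


def test_trend_slope_constant_is_zero():
    years = np.arange(2000, 2010)
    slope, _ = trend_slope(years, np.full(10, 1.3))
    assert slope == pytest.approx(0.0, abs=1e-12)


def test_trend_slope_matches_normal_equations():
    rng = np.random.default_rng(9)
    years = np.arange(1995.0, 2005.0)
    vals = rng.uniform(0.2, 2.0, 10)
    slope, _ = trend_slope(years, vals)
    assert slope == pytest.approx(loop_ols_slope(years, vals), rel=1e-10)


def test_trend_slope_uses_last_observed_window():
    """The window is the last 10 observed years, not the last 10 calendar years."""
    years = np.arange(2000, 2020)
    vals = np.where(years < 2010, 1.0, np.nan)  # only the first decade observed
    vals[:10] = 0.05 * (years[:10] - 2000)
    slope, n = trend_slope(years, vals)
    assert n == 10 and slope == pytest.approx(0.05)


def test_trend_slope_equivariance():
    rng = np.random.default_rng(10)
    years = np.arange(2000.0, 2010.0)
    vals = rng.uniform(0.5, 1.5, 10)
    s0, _ = trend_slope(years, vals)
    s_scaled, _ = trend_slope(years, 3.0 * vals)
    s_shift, _ = trend_slope(years, vals + 5.0)
    assert s_scaled == pytest.approx(3.0 * s0)
    assert s_shift == pytest.approx(s0)


def test_trend_slope_insufficient_data():
    years = np.arange(2000, 2010)
    vals = np.full(10, np.nan)
    vals[-3:] = 1.0
    slope, n = trend_slope(years, vals, min_trend_years=8)
    assert np.isnan(slope) and n == 3


def test_stock_status_counts_match_enumeration(noisy_panel):
    """Summary percentages equal direct enumeration over the status table."""
    ratios = make_ratios(noisy_panel, "assessment_bmsy")
    st_tab = stock_status(ratios)
    summ = status_summary({"assessment_bmsy": st_tab})["per_target"]["assessment_bmsy"]
    below = sum(1 for _, r in st_tab.iterrows() if r["b_last"] < 1)
    above = sum(1 for _, r in st_tab.iterrows() if r["u_last"] > 1)
    assert summ["pct_below_biomass_target"] == pytest.approx(100 * below / len(st_tab))
    assert summ["pct_above_exploitation_target"] == pytest.approx(100 * above / len(st_tab))
    down = [r["b_slope"] for _, r in st_tab.iterrows() if np.isfinite(r["b_slope"])]
    assert summ["pct_biomass_trending_down"] == pytest.approx(
        100 * np.mean([s < 0 for s in down])
    )
    fracs = summ["quadrant_fractions"]
    assert sum(fracs.values()) == pytest.approx(1.0)


def test_status_summary_reports_across_target_maxima(noisy_panel):
    statuses = {
        kind: stock_status(make_ratios(noisy_panel, kind))
        for kind in ("assessment_bmsy", "half_max_biomass")
    }
    summ = status_summary(statuses)
    per = summ["per_target"]
    assert summ["up_to_pct_below_biomass_target"] == pytest.approx(
        max(per[k]["pct_below_biomass_target"] for k in per)
    )


def test_lower_target_never_increases_below_fraction(noisy_panel):
    """Assessment B_MSY <= half-max target implies fewer stocks flagged below."""
    st_a = stock_status(make_ratios(noisy_panel, "assessment_bmsy"))
    st_h = stock_status(make_ratios(noisy_panel, "half_max_biomass"))
    merged = st_a.merge(st_h, on="stock_id", suffixes=("_a", "_h"))
    # ratios under the (lower) assessment target are scaled up stock-by-stock
    only_lower = merged[merged["b_last_a"] >= merged["b_last_h"]]
    assert ((only_lower["b_last_a"] < 1) <= (only_lower["b_last_h"] < 1)).all()


def test_proportions_all_within():
    rp = ratio_panel_from_arrays({f"s{i}": np.full(30, 1.2) for i in range(25)})
    table, extrema = proportion_series(rp, min_stocks_per_year=20)
    np.testing.assert_allclose(table["frac_within_b"], 1.0)
    assert extrema["below_biomass_target"]["max_pct"] == 0.0


def test_proportion_extrema_and_improvement():
    """Max-below proportion, its (earliest) year, and the improvement to the
    final year follow the max-minus-final arithmetic."""
    n = 25
    years = np.arange(2000, 2003)
    b = {}
    for i in range(n):
        below_y0 = i < 10   # 40% below in 2000
        below_y1 = i < 15   # 60% below in 2001
        below_y2 = i < 5    # 20% below in 2002
        b[f"s{i}"] = [0.5 if below_y0 else 1.5,
                      0.5 if below_y1 else 1.5,
                      0.5 if below_y2 else 1.5]
    rp = ratio_panel_from_arrays(b, years=years)
    _, extrema = proportion_series(rp, min_stocks_per_year=20)
    ext = extrema["below_biomass_target"]
    assert ext["max_pct"] == pytest.approx(60.0)
    assert ext["max_year"] == 2001
    assert ext["improvement_pct_points"] == pytest.approx(40.0)


def test_proportion_tie_reports_earliest_year():
    n = 25
    b = {f"s{i}": [0.5, 0.5, 1.5] if i < 10 else [1.5, 1.5, 1.5] for i in range(n)}
    rp = ratio_panel_from_arrays(b, years=np.arange(2000, 2003))
    _, extrema = proportion_series(rp, min_stocks_per_year=20)
    ext = extrema["below_biomass_target"]
    assert ext["max_year"] == 2000 and 2001 in ext["tied_years"]


def test_proportions_consistent_with_status_at_final_year(msy_panel):
    """1 - within-target fraction at a stock's last year equals the status-table
    below-target percentage when every stock reports through that year."""
    ratios = make_ratios(msy_panel, "assessment_bmsy")
    table, _ = proportion_series(ratios, min_stocks_per_year=10)
    st_tab = stock_status(ratios)
    final = table.index.max()
    assert (st_tab["last_year"] == final).all()
    pct_below = 100.0 * (st_tab["b_last"] < 1).mean()
    assert 100.0 * (1 - table.loc[final, "frac_within_b"]) == pytest.approx(pct_below)


def test_proportions_require_enough_stocks():
    rp = ratio_panel_from_arrays({"s0": np.ones(5), "s1": np.ones(5)})
    with pytest.raises(ValueError, match="min_stocks_per_year"):
        proportion_series(rp, min_stocks_per_year=20)
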