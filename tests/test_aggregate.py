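import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fishstatus import (
    EnsembleConfig,
    aggregate_year,
    build_ensemble,
    classify_recovery,
    recovery_summary,
    run_method,
)
from fishstatus.aggregate import MEDIAN_SE_FACTOR, WeightUnavailableError
from fishstatus.targets import RatioPanel

from oracles import loop_weighted_mean_se


def flat_ratio_panel(values_by_stock, catches=None, biomasses=None, years=None,
                     target_kind="assessment_bmsy"):
    """RatioPanel where each stock's b and u are constant over the years."""
    stocks = list(values_by_stock)
    years = np.arange(2000, 2030) if years is None else years
    b = pd.DataFrame(
        {s: np.full(len(years), v) for s, v in values_by_stock.items()},
        index=pd.Index(years, name="year"),
    )
    return RatioPanel(
        b=b,
        u=b.copy(),
        target_kind=target_kind,
        mean_biomass=pd.Series(biomasses or {s: 1.0 for s in stocks}, dtype=float),
        mean_catch=pd.Series(catches or {s: 1.0 for s in stocks}, dtype=float),
    )


def test_aggregate_year_simple_cases():
    assert aggregate_year(np.array([1.0, 3.0]))[0] == pytest.approx(2.0)
    est, se, n = aggregate_year(np.array([1.0, 3.0]), np.array([1.0, 0.0]))
    assert (est, se, n) == (pytest.approx(1.0), pytest.approx(0.0), 2)
    est, se, n = aggregate_year(np.array([np.nan, np.nan]))
    assert np.isnan(est) and n == 0


def test_aggregate_year_negative_weight_rejected():
    with pytest.raises(ValueError, match="negative"):
        aggregate_year(np.array([1.0, 2.0]), np.array([1.0, -0.5]))


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_weighted_mean_se_matches_loops(seed):
    """Weighted mean and SE agree with explicit summation loops (n=7)."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.1, 3.0, 7)
    w = rng.uniform(0.0, 5.0, 7)
    w[0] = max(w[0], 0.1)  # not all zero
    est, se, _ = aggregate_year(x, w)
    mean_o, se_o = loop_weighted_mean_se(x, w)
    assert est == pytest.approx(mean_o, rel=1e-12)
    assert se == pytest.approx(se_o, rel=1e-12)


def test_median_estimate_and_se():
    x = np.array([1.0, 2.0, 10.0])
    est, se, n = aggregate_year(x, method="median")
    assert est == 2.0
    _, se_mean, _ = aggregate_year(x)
    assert se == pytest.approx(MEDIAN_SE_FACTOR * se_mean)


def test_constant_panel_gives_flat_unit_trajectory():
    rp = flat_ratio_panel({f"s{i}": 1.0 for i in range(25)})
    for method in ("unweighted_mean", "biomass_weighted", "catch_weighted"):
        t = run_method(rp, method, min_stocks_per_year=5).table
        np.testing.assert_allclose(t["estimate"], 1.0)
        np.testing.assert_allclose(t["se"], 0.0)


def test_catch_weighting_example():
    rp = flat_ratio_panel({"a": 1.0, "b": 3.0}, catches={"a": 1.0, "b": 3.0})
    cw = run_method(rp, "catch_weighted", min_stocks_per_year=1).table
    uw = run_method(rp, "unweighted_mean", min_stocks_per_year=1).table
    np.testing.assert_allclose(cw["estimate"], 2.5)
    np.testing.assert_allclose(uw["estimate"], 2.0)


def test_equal_weights_reduce_to_unweighted(noisy_panel):
    from fishstatus.targets import make_ratios

    ratios = make_ratios(noisy_panel, "assessment_bmsy")
    equal = RatioPanel(
        b=ratios.b, u=ratios.u, target_kind=ratios.target_kind,
        mean_biomass=pd.Series(7.0, index=ratios.b.columns),
        mean_catch=pd.Series(7.0, index=ratios.b.columns),
    )
    uw = run_method(equal, "unweighted_mean", min_stocks_per_year=5).table
    for method in ("biomass_weighted", "catch_weighted"):
        t = run_method(equal, method, min_stocks_per_year=5).table
        np.testing.assert_allclose(t["estimate"], uw["estimate"], equal_nan=True)
        np.testing.assert_allclose(t["se"], uw["se"], equal_nan=True)


def test_stock_order_is_irrelevant(noisy_panel):
    from fishstatus.targets import make_ratios

    ratios = make_ratios(noisy_panel, "assessment_bmsy")
    perm = list(ratios.b.columns[::-1])
    shuffled = RatioPanel(
        b=ratios.b[perm], u=ratios.u[perm], target_kind=ratios.target_kind,
        mean_biomass=ratios.mean_biomass, mean_catch=ratios.mean_catch,
    )
    for method in ("unweighted_mean", "median", "catch_weighted", "state_space"):
        t1 = run_method(ratios, method, min_stocks_per_year=5).table
        t2 = run_method(shuffled, method, min_stocks_per_year=5).table
        np.testing.assert_allclose(t1["estimate"], t2["estimate"], equal_nan=True)


def test_median_more_robust_than_mean_to_one_outlier_stock():
    values = {f"s{i}": 1.0 + 0.01 * i for i in range(21)}
    rp = flat_ratio_panel(values)
    blown = dict(values)
    blown["s0"] = values["s0"] * 100
    rp2 = flat_ratio_panel(blown)
    d_mean = abs(
        run_method(rp2, "unweighted_mean", min_stocks_per_year=5).table["estimate"]
        - run_method(rp, "unweighted_mean", min_stocks_per_year=5).table["estimate"]
    ).max()
    d_median = abs(
        run_method(rp2, "median", min_stocks_per_year=5).table["estimate"]
        - run_method(rp, "median", min_stocks_per_year=5).table["estimate"]
    ).max()
    assert d_median < d_mean


def test_sparse_years_masked_in_every_member(noisy_panel):
    """Years with fewer than min_stocks_per_year stocks are missing everywhere."""
    ens = build_ensemble(noisy_panel, EnsembleConfig(min_stocks_per_year=39))
    for q in ("b", "u"):
        for m in ens[q].members:
            thin = m.table["n_stocks"] < 39
            assert m.table.loc[thin, "estimate"].isna().all()


def test_missing_weight_data_raises_listing_stocks():
    rp = flat_ratio_panel({"a": 1.0, "b": 2.0}, catches={"a": 1.0, "b": np.nan})
    with pytest.raises(WeightUnavailableError, match="b"):
        run_method(rp, "catch_weighted", min_stocks_per_year=1)


def test_ensemble_structure_and_bracketing(noisy_panel):
    ens = build_ensemble(noisy_panel, EnsembleConfig(min_stocks_per_year=10))
    for q in ("b", "u"):
        res = ens[q]
        assert len(res.members) == 10
        est = pd.DataFrame(
            {m.label: m.table["estimate"].reindex(res.ensemble.index) for m in res.members}
        )
        ok = res.ensemble["n_members"] > 0
        assert (est.min(axis=1)[ok] <= res.ensemble["mean"][ok] + 1e-12).all()
        assert (est.max(axis=1)[ok] >= res.ensemble["mean"][ok] - 1e-12).all()
        both = res.ensemble["n_members"] >= 2
        assert (res.ensemble["lo"][both] <= res.ensemble["mean"][both]).all()
        assert (res.ensemble["hi"][both] >= res.ensemble["mean"][both]).all()


def test_identical_members_collapse_interval(at_target_panel):
    ens = build_ensemble(at_target_panel, EnsembleConfig(min_stocks_per_year=10))
    res = ens["u"]
    final = res.ensemble.loc[res.last_year]
    assert final["mean"] == pytest.approx(1.0, abs=1e-6)
    assert final["hi"] - final["lo"] == pytest.approx(0.0, abs=1e-4)


def test_recovery_verdicts():
    tables = {}
    for label, (b, u) in {
        "m1": (1.2, 0.8),   # recovered
        "m2": (0.99, 0.5),  # biomass below target
        "m3": (1.05, 1.2),  # overfishing
    }.items():
        tables[label] = (b, u)
    # build two one-member ensembles by hand through the public API surface
    from fishstatus.aggregate import AggregateTrajectory, EnsembleResult

    years = pd.Index([2016], name="year")

    def member(label, value, se=0.1):
        return AggregateTrajectory(
            method=label, target_kind="assessment_bmsy", quantity="b",
            table=pd.DataFrame({"estimate": [value], "se": [se], "n_stocks": [30]},
                               index=years),
        )

    ens = {
        "b": EnsembleResult(
            quantity="b",
            members=[member(k, b) for k, (b, _) in tables.items()],
            ensemble=pd.DataFrame(), first_year=2016, last_year=2016,
        ),
        "u": EnsembleResult(
            quantity="u",
            members=[member(k, u) for k, (_, u) in tables.items()],
            ensemble=pd.DataFrame(), first_year=2016, last_year=2016,
        ),
    }
    v = classify_recovery(ens, 2016)
    assert list(v["verdict"]) == ["support", "refute", "refute"]
    # (1.05, se=0.1): the 95% CI straddles the B = B_MSY line
    assert bool(v.loc[2, "straddles_b_line"])
    summ = recovery_summary(v)
    assert summ["support"] + summ["refute"] + summ["undetermined"] == summ["n_members"]
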