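"""The five averaging methods, the 10-member ensemble, and recovery verdicts.

Members are the cross of five yearly averaging methods (unweighted mean,
biomass-weighted mean, catch-weighted mean, median, hierarchical state-space
smoother) with the two rebuilding targets (assessment B_MSY, half the
historical maximum biomass), applied separately to B/B_target and U/U_MSY.
Averaging is done on the arithmetic ratio scale (a geometric-mean variant is
available but excluded from the ensemble). Weights are time-invariant
per-stock means of observed biomass or catch, so trends in the weights cannot
masquerade as trends in status. The ensemble summary per year is the
unweighted mean across available members with a normal-approximation 95%
interval (mean +/- 1.96 * SD across members).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ramio import StockPanel
from .statespace import fit_ss
from .targets import TARGET_KINDS, RatioPanel, make_ratios

METHODS = ("unweighted_mean", "biomass_weighted", "catch_weighted", "median", "state_space")
EXTRA_METHODS = ("geometric_mean",)  # available, never in the 10-member ensemble

#: half-width of the normal-theory 95% interval
Z95 = 1.96
#: multiplier converting the SE of the mean to the large-sample SE of the median
MEDIAN_SE_FACTOR = 1.2533

#: numerical slack when comparing an estimate to the target line at 1
BOUNDARY_TOL = 1e-9


class WeightUnavailableError(ValueError):
    """A weighted method was requested for stocks with no weight data."""

    def __init__(self, weight_source: str, stocks: list[str]):
        self.stocks = stocks
        super().__init__(
            f"{weight_source} weights unavailable for {len(stocks)} stocks: "
            + ", ".join(stocks[:10])
            + ("..." if len(stocks) > 10 else "")
        )


@dataclass
class AggregateTrajectory:
    """One method x target x quantity: yearly estimate, SE and stock count."""

    method: str
    target_kind: str
    quantity: str  # "b" or "u"
    table: pd.DataFrame  # index: year; columns: estimate, se, n_stocks

    @property
    def label(self) -> str:
        return f"{self.method}:{self.target_kind}"

    def at(self, year: int) -> pd.Series | None:
        if year in self.table.index and np.isfinite(self.table.loc[year, "estimate"]):
            return self.table.loc[year]
        return None


@dataclass
class EnsembleConfig:
    min_stocks_per_year: int = 20
    endpoint_start_year: int = 1980
    last_year_coverage: float = 0.5  # last reporting year: >= this fraction of stocks report
    interval_z: float = Z95
    ss_restarts: int = 3
    ss_x0_var: float = 1e6


@dataclass
class EnsembleResult:
    quantity: str
    members: list[AggregateTrajectory]
    ensemble: pd.DataFrame  # index: year; columns: mean, lo, hi, n_members
    first_year: int
    last_year: int
    config: EnsembleConfig = field(default_factory=EnsembleConfig)

    def member_table(self) -> pd.DataFrame:
        """Tidy long table over all members."""
        rows = []
        for m in self.members:
            t = m.table.reset_index()
            t.insert(0, "quantity", m.quantity)
            t.insert(1, "method", m.method)
            t.insert(2, "target_kind", m.target_kind)
            rows.append(t)
        return pd.concat(rows, ignore_index=True)


def aggregate_year(
    values: np.ndarray,
    weights: np.ndarray | None = None,
    method: str = "unweighted_mean",
) -> tuple[float, float, int]:
    """One year's cross-stock average: (estimate, SE, n used).

    Weighted mean: xbar = sum(w x)/sum(w); SE = sqrt(sum w^2 (x-xbar)^2)/sum w.
    Median: sample median with SE = 1.2533 x the equal-weight SE of the mean.
    Missing values (NaN) are dropped; an all-missing year returns NaN.
    """
    x = np.asarray(values, dtype=float)
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w[~np.isnan(w)] < 0):
            raise ValueError("negative weights")
    keep = ~np.isnan(x) & ~np.isnan(w)
    x, w = x[keep], w[keep]
    n = len(x)
    if n == 0 or w.sum() == 0:
        return np.nan, np.nan, 0
    if method == "median":
        est = float(np.median(x))
        xb = x.mean()
        se = MEDIAN_SE_FACTOR * float(np.sqrt(np.sum((x - xb) ** 2))) / n
        return est, se, n
    if method == "geometric_mean":
        if np.any(x <= 0):
            raise ValueError("geometric mean requires positive values")
        lx = np.log(x)
        m = float(np.sum(w * lx) / w.sum())
        se_log = float(np.sqrt(np.sum(w**2 * (lx - m) ** 2)) / w.sum())
        return float(np.exp(m)), float(np.exp(m)) * se_log, n
    xb = float(np.sum(w * x) / w.sum())
    se = float(np.sqrt(np.sum(w**2 * (x - xb) ** 2)) / w.sum())
    return xb, se, n


def _weights_for(ratios: RatioPanel, method: str) -> tuple[pd.Series | None, str | None]:
    if method == "biomass_weighted":
        return ratios.mean_biomass, "biomass"
    if method == "catch_weighted":
        return ratios.mean_catch, "catch"
    return None, None


def run_method(
    ratios: RatioPanel,
    method: str,
    quantity: str = "b",
    min_stocks_per_year: int = 20,
    window: tuple[int, int] | None = None,
    ss_restarts: int = 3,
    ss_x0_var: float = 1e6,
) -> AggregateTrajectory:
    """Yearly global trajectory for one method on one quantity.

    Years with fewer than ``min_stocks_per_year`` reporting stocks are masked.
    The state-space method fits the hierarchical smoother to log ratios over
    the (consecutive) window and back-transforms to the ratio scale.
    """
    if method not in METHODS + EXTRA_METHODS:
        raise ValueError(f"unknown method {method!r}")
    if quantity not in ("b", "u"):
        raise ValueError("quantity must be 'b' or 'u'")
    frame = ratios.b if quantity == "b" else ratios.u
    if window is not None:
        frame = frame.loc[window[0] : window[1]]

    weights, wname = _weights_for(ratios, method)
    if weights is not None:
        missing = [c for c in frame.columns if not np.isfinite(weights.get(c, np.nan))]
        if missing:
            raise WeightUnavailableError(wname or method, missing)

    if method == "state_space":
        years = frame.index.to_numpy(dtype=int)
        full = pd.RangeIndex(years.min(), years.max() + 1)
        dense = frame.reindex(full)
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.log(dense.where(dense > 0))
        n_nonpos = int(((dense <= 0) & dense.notna()).to_numpy().sum())
        if n_nonpos:
            warnings.warn(f"{n_nonpos} non-positive ratios masked before log fit", stacklevel=2)
        fit = fit_ss(logs, x0_var=ss_x0_var, restarts=ss_restarts)
        est, se = fit.ratio_scale()
        table = pd.DataFrame(
            {"estimate": est, "se": se, "n_stocks": fit.n_obs},
            index=pd.Index(fit.years, name="year"),
        )
    else:
        rows = {}
        for year, row in frame.iterrows():
            v = row.to_numpy(dtype=float)
            w = None if weights is None else weights.reindex(frame.columns).to_numpy()
            est, se, n = aggregate_year(v, w, method=method)
            rows[year] = (est, se, n)
        table = pd.DataFrame.from_dict(
            rows, orient="index", columns=["estimate", "se", "n_stocks"]
        )
        table.index.name = "year"
    low = table["n_stocks"] < min_stocks_per_year
    table.loc[low, ["estimate", "se"]] = np.nan
    return AggregateTrajectory(
        method=method, target_kind=ratios.target_kind, quantity=quantity, table=table
    )


def reporting_window(
    ratios: RatioPanel,
    quantity: str,
    min_stocks_per_year: int,
    last_year_coverage: float,
) -> tuple[int, int]:
    """(first, last) reporting years.

    First: earliest year with at least ``min_stocks_per_year`` stocks.
    Last: latest year where at least ``last_year_coverage`` of the panel's
    stocks report — the operational "last year with sufficient data".
    """
    frame = ratios.b if quantity == "b" else ratios.u
    counts = frame.notna().sum(axis=1)
    enough = counts[counts >= min_stocks_per_year]
    if enough.empty:
        raise ValueError("no year reaches min_stocks_per_year")
    first = int(enough.index.min())
    need = max(min_stocks_per_year, int(np.ceil(last_year_coverage * frame.shape[1])))
    covered = counts[counts >= need]
    last = int(covered.index.max()) if not covered.empty else int(enough.index.max())
    return first, last


def build_ensemble(
    panel: StockPanel,
    config: EnsembleConfig | None = None,
) -> dict[str, EnsembleResult]:
    """The 10-member ensemble (5 methods x 2 targets) for each quantity.

    Stocks without an absolute biomass series are dropped from the half-max
    members only; stocks without weight data are dropped from the
    corresponding weighted members (both recorded in provenance via warnings).
    Returns ``{"b": EnsembleResult, "u": EnsembleResult}``.
    """
    cfg = config or EnsembleConfig()
    panels = {kind: make_ratios(panel, kind) for kind in TARGET_KINDS}

    out: dict[str, EnsembleResult] = {}
    for quantity in ("b", "u"):
        first, last = reporting_window(
            panels["assessment_bmsy"], quantity, cfg.min_stocks_per_year, cfg.last_year_coverage
        )
        members: list[AggregateTrajectory] = []
        for kind in TARGET_KINDS:
            ratios = panels[kind]
            for method in METHODS:
                r = ratios
                w, _ = _weights_for(ratios, method)
                if w is not None:
                    frame_cols = ratios.b.columns
                    bad = [c for c in frame_cols if not np.isfinite(w.get(c, np.nan))]
                    if bad:
                        warnings.warn(
                            f"{len(bad)} stocks lack {method} weights; excluded from "
                            f"that member",
                            stacklevel=2,
                        )
                        r = RatioPanel(
                            b=ratios.b.drop(columns=bad),
                            u=ratios.u.drop(columns=bad),
                            target_kind=kind,
                            mean_biomass=ratios.mean_biomass.drop(bad, errors="ignore"),
                            mean_catch=ratios.mean_catch.drop(bad, errors="ignore"),
                            provenance=ratios.provenance,
                        )
                members.append(
                    run_method(
                        r,
                        method,
                        quantity=quantity,
                        min_stocks_per_year=cfg.min_stocks_per_year,
                        window=(first, last),
                        ss_restarts=cfg.ss_restarts,
                        ss_x0_var=cfg.ss_x0_var,
                    )
                )
        years = pd.Index(range(first, last + 1), name="year")
        est = pd.DataFrame(
            {m.label: m.table["estimate"].reindex(years) for m in members}, index=years
        )
        n_members = est.notna().sum(axis=1)
        mean = est.mean(axis=1)
        sd = est.std(axis=1, ddof=1)
        lo = mean - cfg.interval_z * sd
        hi = mean + cfg.interval_z * sd
        lo[n_members < 2] = np.nan
        hi[n_members < 2] = np.nan
        ensemble = pd.DataFrame(
            {"mean": mean, "lo": lo, "hi": hi, "n_members": n_members}, index=years
        )
        out[quantity] = EnsembleResult(
            quantity=quantity,
            members=members,
            ensemble=ensemble,
            first_year=max(first, cfg.endpoint_start_year),
            last_year=last,
            config=cfg,
        )
    return out


def classify_recovery(
    ensembles: dict[str, EnsembleResult],
    year: int | None = None,
    z: float = Z95,
) -> pd.DataFrame:
    """Per-member recovery verdicts at ``year`` (default: last reporting year).

    A member supports recovery when its biomass ratio is at or above 1 and its
    exploitation ratio at or below 1 (target lines count as within target; a
    tiny numerical slack absorbs floating-point jitter exactly on the line).
    Also reports whether each member's 95% CI straddles the B=B_MSY and
    U=U_MSY lines.
    """
    ens_b, ens_u = ensembles["b"], ensembles["u"]
    yr = ens_b.last_year if year is None else year
    rows = []
    for mb, mu in zip(ens_b.members, ens_u.members):
        assert mb.label == mu.label
        rb, ru = mb.at(yr), mu.at(yr)
        if rb is None or ru is None:
            verdict = "undetermined"
            b = u = b_se = u_se = np.nan
            straddle_b = straddle_u = None
        else:
            b, b_se = float(rb["estimate"]), float(rb["se"])
            u, u_se = float(ru["estimate"]), float(ru["se"])
            recovered = (b >= 1.0 - BOUNDARY_TOL) and (u <= 1.0 + BOUNDARY_TOL)
            verdict = "support" if recovered else "refute"
            straddle_b = bool(abs(b - 1.0) <= z * b_se + BOUNDARY_TOL)
            straddle_u = bool(abs(u - 1.0) <= z * u_se + BOUNDARY_TOL)
        rows.append(
            {
                "method": mb.method,
                "target_kind": mb.target_kind,
                "year": yr,
                "b": b,
                "b_se": b_se,
                "u": u,
                "u_se": u_se,
                "verdict": verdict,
                "straddles_b_line": straddle_b,
                "straddles_u_line": straddle_u,
            }
        )
    return pd.DataFrame(rows)


def recovery_summary(verdicts: pd.DataFrame) -> dict:
    counts = verdicts["verdict"].value_counts().to_dict()
    return {
        "year": int(verdicts["year"].iloc[0]) if len(verdicts) else None,
        "support": int(counts.get("support", 0)),
        "refute": int(counts.get("refute", 0)),
        "undetermined": int(counts.get("undetermined", 0)),
        "n_members": int(len(verdicts)),
        "n_straddle_b": int(verdicts["straddles_b_line"].fillna(False).sum()),
        "n_straddle_u": int(verdicts["straddles_u_line"].fillna(False).sum()),
    }
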