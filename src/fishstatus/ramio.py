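"""Read RAM-Legacy-style long tables into a validated stock panel.

The expected input is the long export of a stock-assessment database:
a time-series table with columns ``stock_id, series_id, year, value`` and an
optional reference-point table with columns ``stock_id, parameter_id, value``.
Series identifiers vary across database versions, so roles (total biomass,
spawning biomass, pre-divided B/B_MSY, exploitation rate, catch, ...) are
resolved through an editable alias mapping rather than hard-coded names.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_TS_COLUMNS = ("stock_id", "series_id", "year", "value")
REQUIRED_RP_COLUMNS = ("stock_id", "parameter_id", "value")

#: role -> accepted series_id spellings (RAM tsid stems and plain names).
DEFAULT_SERIES_ALIASES: dict[str, tuple[str, ...]] = {
    "total_biomass": ("TB", "TBbest", "TBbest-MT", "total_biomass"),
    "spawning_biomass": ("SSB", "SSBbest", "SSBbest-MT", "spawning_biomass"),
    "b_ratio": (
        "BdivBmsy",
        "BdivBmsypref",
        "BdivBmsypref-dimensionless",
        "TBdivTBmsy-dimensionless",
        "SSBdivSSBmsy-dimensionless",
        "b_ratio",
    ),
    "exploitation": ("ER", "ERbest", "ERbest-ratio", "U", "exploitation"),
    "u_ratio": (
        "UdivUmsy",
        "UdivUmsypref",
        "UdivUmsypref-dimensionless",
        "ERdivERmsy-dimensionless",
        "u_ratio",
    ),
    "catch": ("TC", "TCbest", "TCbest-MT", "catch"),
}

#: role -> accepted parameter_id spellings in the reference-point table.
DEFAULT_REFPOINT_ALIASES: dict[str, tuple[str, ...]] = {
    "b_msy_total": ("Bmsy", "TBmsy", "TBmsybest", "TBmsy-MT"),
    "b_msy_spawning": ("SSBmsy", "SSBmsybest", "SSBmsy-MT"),
    "u_msy": ("Umsy", "ERmsy", "ERmsybest", "Fmsy"),
}

SERIES_PREFERENCES = ("total_biomass", "spawning_biomass")


class PanelError(ValueError):
    """Malformed input table or panel."""


@dataclass
class StockSeries:
    """One stock's annual series on its own (strictly increasing) year axis.

    Missing values are NaN; absent series are None.  ``B_MSY_assess`` and
    ``U_MSY_assess`` are the assessment-estimated reference points; ``truth``
    optionally carries simulator ground truth (K, r, true biomass, ...).
    """

    stock_id: str
    years: np.ndarray
    B: np.ndarray | None = None
    b_ratio: np.ndarray | None = None
    U: np.ndarray | None = None
    u_ratio: np.ndarray | None = None
    catch: np.ndarray | None = None
    B_MSY_assess: float | None = None
    U_MSY_assess: float | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if self.years.size and np.any(np.diff(self.years) <= 0):
            raise PanelError(f"{self.stock_id}: years must be strictly increasing")
        for name in ("B", "b_ratio", "U", "u_ratio", "catch"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.years.shape:
                raise PanelError(f"{self.stock_id}: {name} not aligned to years")
            if np.nanmin(arr, initial=0.0) < 0:
                raise PanelError(f"{self.stock_id}: negative values in {name}")
            setattr(self, name, arr)

    def assessment_ratios(self) -> tuple[np.ndarray, np.ndarray]:
        """(b, u) ratios on the assessment-B_MSY basis, NaN where unavailable.

        A pre-divided ratio series always wins over B / B_MSY_assess.
        """
        nan = np.full(self.years.shape, np.nan)
        if self.b_ratio is not None:
            b = self.b_ratio
        elif self.B is not None and self.B_MSY_assess:
            b = self.B / self.B_MSY_assess
        else:
            b = nan
        if self.u_ratio is not None:
            u = self.u_ratio
        elif self.U is not None and self.U_MSY_assess:
            u = self.U / self.U_MSY_assess
        else:
            u = nan
        return b, u

    def n_ratio_years(self, require_both: bool = False) -> int:
        b, u = self.assessment_ratios()
        if require_both:
            return int(np.sum(~np.isnan(b) & ~np.isnan(u)))
        return int(np.sum(~np.isnan(b) | ~np.isnan(u)))


@dataclass
class StockPanel:
    """Collection of StockSeries plus provenance of how it was built."""

    stocks: list[StockSeries]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.stock_id for s in self.stocks]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate stock_ids in panel")

    @property
    def stock_ids(self) -> list[str]:
        return [s.stock_id for s in self.stocks]

    @property
    def years(self) -> np.ndarray:
        """Global year axis: union of all stock years."""
        if not self.stocks:
            return np.array([], dtype=int)
        return np.unique(np.concatenate([s.years for s in self.stocks]))

    def __len__(self) -> int:
        return len(self.stocks)

    def get(self, stock_id: str) -> StockSeries:
        for s in self.stocks:
            if s.stock_id == stock_id:
                return s
        raise KeyError(stock_id)


def _alias_map(aliases: dict[str, tuple[str, ...]]) -> dict[str, str]:
    out: dict[str, str] = {}
    for role, names in aliases.items():
        for name in names:
            out[name] = role
    return out


def read_ram_long(
    timeseries_path,
    refpoints_path=None,
    series_preference: str = "total_biomass",
    series_aliases: dict[str, tuple[str, ...]] | None = None,
    refpoint_aliases: dict[str, tuple[str, ...]] | None = None,
) -> StockPanel:
    """Read long-format time series (and optional reference points) into a panel.

    ``series_preference`` selects which biomass family ("total_biomass" or
    "spawning_biomass") populates the absolute-biomass slot; exploitation,
    pre-divided ratios and catch are preference-independent. Rows with
    negative values are rejected with a warning; duplicate
    (stock, series, year) rows are an error. Absent (stock, year) cells stay
    missing — nothing is zero-filled.
    """
    if series_preference not in SERIES_PREFERENCES:
        raise PanelError(f"unknown series_preference {series_preference!r}")
    ts = pd.read_csv(timeseries_path, float_precision="round_trip")
    missing = set(REQUIRED_TS_COLUMNS) - set(ts.columns)
    if missing:
        raise PanelError(f"time-series table missing columns {sorted(missing)}")
    ts = ts.loc[:, list(REQUIRED_TS_COLUMNS)].copy()
    ts["value"] = pd.to_numeric(ts["value"], errors="coerce")
    ts = ts.dropna(subset=["value"])
    neg = ts["value"] < 0
    if neg.any():
        warnings.warn(f"dropping {int(neg.sum())} negative-valued rows", stacklevel=2)
        ts = ts.loc[~neg]
    if ts.duplicated(["stock_id", "series_id", "year"]).any():
        raise PanelError("duplicate (stock_id, series_id, year) rows")

    role_of = _alias_map(series_aliases or DEFAULT_SERIES_ALIASES)
    ts["role"] = ts["series_id"].map(role_of)
    ts = ts.dropna(subset=["role"])

    rp_of: dict[str, dict[str, float]] = {}
    if refpoints_path is not None:
        rp = pd.read_csv(refpoints_path, float_precision="round_trip")
        missing = set(REQUIRED_RP_COLUMNS) - set(rp.columns)
        if missing:
            raise PanelError(f"reference-point table missing columns {sorted(missing)}")
        rp_roles = _alias_map(refpoint_aliases or DEFAULT_REFPOINT_ALIASES)
        rp["role"] = rp["parameter_id"].map(rp_roles)
        rp = rp.dropna(subset=["role"])
        for (sid, role), grp in rp.groupby(["stock_id", "role"]):
            rp_of.setdefault(str(sid), {})[role] = float(grp["value"].iloc[0])

    biomass_role = series_preference
    bmsy_role = "b_msy_total" if series_preference == "total_biomass" else "b_msy_spawning"

    stocks: list[StockSeries] = []
    for sid, grp in ts.groupby("stock_id", sort=True):
        sid = str(sid)
        wide = grp.pivot_table(index="year", columns="role", values="value", aggfunc="first")
        wide = wide.sort_index()
        years = wide.index.to_numpy(dtype=int)

        def col(role: str) -> np.ndarray | None:
            if role in wide.columns and wide[role].notna().any():
                return wide[role].to_numpy(dtype=float)
            return None

        refs = rp_of.get(sid, {})
        b_ratio = col("b_ratio")
        B = col(biomass_role)
        bmsy = refs.get(bmsy_role)
        if b_ratio is not None and B is not None and bmsy:
            implied = B / bmsy
            ok = ~np.isnan(b_ratio) & ~np.isnan(implied)
            if ok.any() and not np.allclose(b_ratio[ok], implied[ok], rtol=0.05):
                logger.warning(
                    "%s: pre-divided B/B_MSY disagrees with B / B_MSY_assess; "
                    "using the pre-divided series",
                    sid,
                )
        stocks.append(
            StockSeries(
                stock_id=sid,
                years=years,
                B=B,
                b_ratio=b_ratio,
                U=col("exploitation"),
                u_ratio=col("u_ratio"),
                catch=col("catch"),
                B_MSY_assess=bmsy,
                U_MSY_assess=refs.get("u_msy"),
            )
        )
    return StockPanel(
        stocks=stocks,
        provenance={
            "source": str(timeseries_path),
            "refpoints": None if refpoints_path is None else str(refpoints_path),
            "series_preference": series_preference,
            "n_stocks_read": len(stocks),
        },
    )


def filter_panel(
    panel: StockPanel,
    min_years: int = 0,
    require_both_ratios: bool = False,
) -> StockPanel:
    """Retain stocks with at least ``min_years`` of assessment-basis ratio data.

    With ``require_both_ratios`` a year only counts when both the biomass and
    exploitation ratios are present, and stocks lacking either series entirely
    are excluded. Removal counts are recorded in provenance.
    """
    kept = [
        s
        for s in panel.stocks
        if s.n_ratio_years(require_both=require_both_ratios) >= min_years
        and (not require_both_ratios or s.n_ratio_years(require_both=True) > 0)
    ]
    removed = len(panel.stocks) - len(kept)
    if not kept:
        warnings.warn("filter_panel removed every stock", stacklevel=2)
    prov = dict(panel.provenance)
    prov.update(
        {
            "filter_min_years": min_years,
            "filter_require_both_ratios": require_both_ratios,
            "filter_removed": removed,
        }
    )
    return StockPanel(stocks=kept, provenance=prov)
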