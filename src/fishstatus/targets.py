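"""Ratio panels under the two rebuilding-target definitions.

The biomass target is either the assessment-estimated B_MSY (``assessment_bmsy``)
or the precautionary target of half the historically observed maximum biomass
(``half_max_biomass``). Exploitation ratios U/U_MSY are identical under both:
only the biomass denominator changes, so switching targets rescales each
stock's biomass-ratio series by one positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ramio import StockPanel

TARGET_KINDS = ("assessment_bmsy", "half_max_biomass")


@dataclass
class RatioPanel:
    """Wide per-stock B/B_target and U/U_MSY frames on a common year index.

    ``b`` and ``u`` are DataFrames (rows: years, columns: stock ids, NaN for
    missing). ``mean_biomass`` and ``mean_catch`` are per-stock time means of
    the observed absolute series, used as time-invariant aggregation weights.
    """

    b: pd.DataFrame
    u: pd.DataFrame
    target_kind: str
    mean_biomass: pd.Series
    mean_catch: pd.Series
    provenance: dict = field(default_factory=dict)

    @property
    def stock_ids(self) -> list[str]:
        return list(self.b.columns)

    @property
    def years(self) -> np.ndarray:
        return self.b.index.to_numpy(dtype=int)

    def to_tidy(self) -> pd.DataFrame:
        """Long table (stock_id, year, b, u, target_kind)."""
        b = self.b.stack(future_stack=True).rename("b")
        u = self.u.stack(future_stack=True).rename("u")
        out = pd.concat([b, u], axis=1).reset_index()
        out.columns = ["year", "stock_id", "b", "u"]
        out["target_kind"] = self.target_kind
        return out.dropna(subset=["b", "u"], how="all")


def make_ratios(panel: StockPanel, target_kind: str) -> RatioPanel:
    """Build the ratio panel for one target definition.

    ``half_max_biomass`` needs an absolute biomass series: the target is half
    the maximum over the stock's non-missing observed years. Stocks for which
    the requested target cannot be formed are excluded with a warning.
    """
    if target_kind not in TARGET_KINDS:
        raise ValueError(f"unknown target_kind {target_kind!r}")
    years = panel.years
    b_cols: dict[str, pd.Series] = {}
    u_cols: dict[str, pd.Series] = {}
    mean_b: dict[str, float] = {}
    mean_c: dict[str, float] = {}
    dropped: list[str] = []
    for s in panel.stocks:
        b_assess, u = s.assessment_ratios()
        if target_kind == "assessment_bmsy":
            b = b_assess
        else:
            if s.B is None or np.all(np.isnan(s.B)):
                dropped.append(s.stock_id)
                continue
            target = 0.5 * np.nanmax(s.B)
            b = s.B / target
        if np.all(np.isnan(b)) and np.all(np.isnan(u)):
            dropped.append(s.stock_id)
            continue
        b_cols[s.stock_id] = pd.Series(b, index=s.years)
        u_cols[s.stock_id] = pd.Series(u, index=s.years)
        mean_b[s.stock_id] = float(np.nanmean(s.B)) if s.B is not None else np.nan
        mean_c[s.stock_id] = float(np.nanmean(s.catch)) if s.catch is not None else np.nan
    if dropped:
        warnings.warn(
            f"{len(dropped)} stocks excluded under {target_kind} "
            f"(no usable biomass series)",
            stacklevel=2,
        )
    idx = pd.Index(years, name="year")
    b_frame = pd.DataFrame(b_cols, index=idx)
    u_frame = pd.DataFrame(u_cols, index=idx)
    return RatioPanel(
        b=b_frame,
        u=u_frame,
        target_kind=target_kind,
        mean_biomass=pd.Series(mean_b, dtype=float),
        mean_catch=pd.Series(mean_c, dtype=float),
        provenance={
            **panel.provenance,
            "target_kind": target_kind,
            "stocks_excluded_for_target": dropped,
        },
    )
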