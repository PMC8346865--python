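"""End-to-end runs: configuration, artifact writing, and report assembly."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import EnsembleConfig, build_ensemble, classify_recovery, recovery_summary
from .ramio import StockPanel, filter_panel, read_ram_long
from .simulate import SimConfig, simulate_panel
from .status import proportion_series, status_summary, stock_status
from .targets import TARGET_KINDS, make_ratios

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"  # fixed formatting => byte-identical reruns


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    output_dir: str = "fishstatus_run"
    # input: either simulate, or paths to long-format tables
    simulate: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    timeseries_path: str | None = None
    refpoints_path: str | None = None
    series_preference: str = "total_biomass"
    # filtering
    min_years: int = 10
    require_both_ratios: bool = True
    # aggregation
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    # trends / proportions
    trend_window_years: int = 10
    min_trend_years: int = 8
    proportions_start_year: int = 1950
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {})) if "sim" in raw else SimConfig()
        if isinstance(sim.growth_rate_range, list):
            sim.growth_rate_range = tuple(sim.growth_rate_range)
        ens = EnsembleConfig(**raw.pop("ensemble", {})) if "ensemble" in raw else EnsembleConfig()
        return cls(sim=sim, ensemble=ens, **raw)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _load_panel(config: RunConfig) -> StockPanel:
    if config.simulate:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        return simulate_panel(sim)
    if not config.timeseries_path:
        raise PipelineError("input", "either --simulate or a time-series path is required")
    return read_ram_long(
        config.timeseries_path,
        config.refpoints_path,
        series_preference=config.series_preference,
    )


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis and write all artifacts; returns the output dir.

    Artifacts: members.csv (one row per quantity/method/target/year),
    ensemble.csv, recovery.csv + recovery_summary.json, stock_status.csv,
    proportions.csv, extrema.json, status_summary.json, provenance.json and
    the echoed config.yaml.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    try:
        panel = _load_panel(config)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("input", str(e)) from e

    try:
        panel = filter_panel(panel, config.min_years, config.require_both_ratios)
        if not panel.stocks:
            raise ValueError("no stocks survive filtering")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("filter", str(e)) from e

    try:
        ensembles = build_ensemble(panel, config.ensemble)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("aggregation", str(e)) from e

    try:
        verdicts = classify_recovery(ensembles)
        rec_summary = recovery_summary(verdicts)

        statuses: dict[str, pd.DataFrame] = {}
        proportions: list[pd.DataFrame] = []
        extrema: dict[str, dict] = {}
        for kind in TARGET_KINDS:
            ratios = make_ratios(panel, kind)
            statuses[kind] = stock_status(
                ratios, config.trend_window_years, config.min_trend_years
            )
            tab, ext = proportion_series(
                ratios, config.proportions_start_year, config.ensemble.min_stocks_per_year
            )
            tab = tab.reset_index()
            tab.insert(0, "target_kind", kind)
            proportions.append(tab)
            extrema[kind] = ext
        summary = status_summary(statuses)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("status", str(e)) from e

    try:
        members = pd.concat(
            [ensembles[q].member_table() for q in ("b", "u")], ignore_index=True
        )
        members.to_csv(out / "members.csv", index=False, float_format=_FLOAT_FORMAT)
        ens_rows = []
        for q in ("b", "u"):
            t = ensembles[q].ensemble.reset_index()
            t.insert(0, "quantity", q)
            ens_rows.append(t)
        pd.concat(ens_rows, ignore_index=True).to_csv(
            out / "ensemble.csv", index=False, float_format=_FLOAT_FORMAT
        )
        verdicts.to_csv(out / "recovery.csv", index=False, float_format=_FLOAT_FORMAT)
        pd.concat(list(statuses.values()), ignore_index=True).to_csv(
            out / "stock_status.csv", index=False, float_format=_FLOAT_FORMAT
        )
        pd.concat(proportions, ignore_index=True).to_csv(
            out / "proportions.csv", index=False, float_format=_FLOAT_FORMAT
        )
        (out / "extrema.json").write_text(json.dumps(extrema, indent=2))
        (out / "recovery_summary.json").write_text(json.dumps(rec_summary, indent=2))

        summary_json = {
            "per_target": {
                kind: {
                    k: v
                    for k, v in d.items()
                    if not isinstance(v, pd.DataFrame)
                }
                for kind, d in summary["per_target"].items()
            },
            **{k: v for k, v in summary.items() if k != "per_target"},
        }
        (out / "status_summary.json").write_text(
            json.dumps(summary_json, indent=2, default=float)
        )
        for kind, d in summary["per_target"].items():
            d["b_last_histogram"].to_csv(
                out / f"hist_b_{kind}.csv", index=False, float_format=_FLOAT_FORMAT
            )
            d["u_last_histogram"].to_csv(
                out / f"hist_u_{kind}.csv", index=False, float_format=_FLOAT_FORMAT
            )

        prov = {
            "fishstatus_version": __version__,
            "seed": config.seed,
            "ensemble_interval_rule": "mean +/- 1.96 * SD across members",
            "panel_provenance": panel.provenance,
            "n_stocks_analyzed": len(panel.stocks),
            "endpoints": {
                q: [ensembles[q].first_year, ensembles[q].last_year] for q in ("b", "u")
            },
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
        config.to_yaml(out / "config.yaml")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("write", str(e)) from e
    return out


def make_report(run_dir) -> str:
    """Assemble a human-readable summary from the run's CSV/JSON artifacts."""
    run_dir = Path(run_dir)
    needed = ["recovery.csv", "recovery_summary.json", "extrema.json", "status_summary.json"]
    for name in needed:
        if not (run_dir / name).exists():
            raise FileNotFoundError(f"missing artifact {name} in {run_dir}")
    verdicts = pd.read_csv(run_dir / "recovery.csv")
    rec = json.loads((run_dir / "recovery_summary.json").read_text())
    extrema = json.loads((run_dir / "extrema.json").read_text())
    summ = json.loads((run_dir / "status_summary.json").read_text())

    lines = [
        "# Global stock-status ensemble report",
        "",
        f"Endpoint year: {rec['year']}",
        f"Members supporting recovery (B at/above target and U at/below target): "
        f"{rec['support']} of {rec['n_members']}; refuting: {rec['refute']}; "
        f"undetermined: {rec['undetermined']}.",
        f"Members whose 95% CI straddles the B=B_MSY line: {rec['n_straddle_b']}; "
        f"the U=U_MSY line: {rec['n_straddle_u']}.",
        "",
        "## Member endpoints",
        "",
        verdicts.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        "",
        "## Individual-stock status ('up to' figures are maxima across the two targets)",
        "",
        f"Up to {summ['up_to_pct_below_biomass_target']:.1f}% of stocks below the "
        f"biomass target; up to {summ['up_to_pct_above_exploitation_target']:.1f}% "
        f"above the exploitation target.",
        f"Up to {summ['up_to_pct_biomass_trending_down']:.1f}% trending down in "
        f"biomass; up to {summ['up_to_pct_exploitation_trending_up']:.1f}% trending "
        f"up in exploitation (last {10} observed years).",
        "",
        "## Proportion-series extrema",
        "",
    ]
    for kind, ext in extrema.items():
        if kind == "target_kind":
            continue
        bb = ext["below_biomass_target"]
        uu = ext["above_exploitation_target"]
        lines += [
            f"- {kind}: max below-biomass-target proportion {bb['max_pct']:.1f}% "
            f"in {bb['max_year']} (improvement {bb['improvement_pct_points']:.1f} "
            f"points by {bb['final_year']}); max above-exploitation proportion "
            f"{uu['max_pct']:.1f}% in {uu['max_year']} (improvement "
            f"{uu['improvement_pct_points']:.1f} points).",
        ]
    report = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(report)
    return report
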