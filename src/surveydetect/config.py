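"""Run configuration and the end-to-end study pipeline.

``run_study`` chains the stages in survey order: simulate (or ingest)
events -> per-method detection histories -> fused method combinations
-> stacked occupancy design -> candidate model fits with AICc ranking,
bootstrap goodness of fit, back-transformed predictions and minimum
effort -> survey-time equalization curves -> design economics summary.
Every artifact is a CSV or JSON under the output directory, and a run
manifest records the seed, configuration hash and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import __version__
from .detection_data import (
    DetectionHistory,
    ValidationError,
    build_sensor_history,
    build_transect_history,
    fuse_histories,
    hourly_profile,
    naive_summary,
    read_events,
    read_sites,
    stack_histories,
)
from .design import design_summary
from .effort import anova_windows, crossing_time, effort_curve
from .occupancy import (
    fit,
    gof_parboot,
    n_min,
    predict_p,
    rank_models,
    standard_model_set,
)
from .simulate import SimulationScenario, scenario_field_defaults, simulate_campaign

log = logging.getLogger("surveydetect")


@dataclass
class RunConfig:
    """Everything one study run needs; the seed is mandatory."""

    out_dir: str
    seed: int
    events_path: str | None = None       # ingest instead of simulating
    sites_path: str | None = None
    scenario: str = "field"              # "field" (emulated campaign) or "default"
    occasion_days: int = 5
    n_occasions: int = 8
    pt_visits: int = 3
    psi_mode: str = "fixed_one"
    n_boot: int = 1000
    effort_grid_hours: tuple[float, float, float] = (5.0, 576.0, 5.0)
    effort_reps: int = 1000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ValidationError("configuration must state a seed")
        if "effort_grid_hours" in data:
            data["effort_grid_hours"] = tuple(data["effort_grid_hours"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _scenario_for(config: RunConfig) -> SimulationScenario:
    if config.scenario == "field":
        return scenario_field_defaults()
    return SimulationScenario()


def _ci_logit(p: float, se_eta: float) -> tuple[float, float]:
    from scipy.special import logit

    eta = logit(p)
    return float(expit(eta - 1.96 * se_eta)), float(expit(eta + 1.96 * se_eta))


def run_study(config: RunConfig) -> dict:
    """Run the full synthetic (or ingested) study; returns artifact paths."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        artifacts[name] = str(path)

    def save_json(obj, name: str) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
        artifacts[name] = str(path)

    # ---- stage 1: events ---------------------------------------------------
    if config.events_path:
        log.info("ingesting events from %s", config.events_path)
        events = read_events(config.events_path)
        sites = read_sites(config.sites_path)
        coverage = None
    else:
        log.info("simulating campaign (seed=%d)", config.seed)
        scenario = _scenario_for(config)
        campaign = simulate_campaign(scenario, seed=config.seed)
        events, sites, coverage = campaign.events, campaign.sites, campaign.coverage
        save_json({k: v for k, v in campaign.truth.z.items()}, "truth_occupancy.json")
    ev_out = events.copy()
    ev_out["detected"] = ev_out["detected"].astype(int)
    save_csv(ev_out, "events.csv")
    save_csv(sites, "sites.csv")

    # ---- stage 2: detection histories -------------------------------------
    singles: dict[str, DetectionHistory] = {}
    pt_events = events.loc[events["method"] == "PT"]
    if len(pt_events):
        singles["PT"] = build_transect_history(pt_events, sites, n_visits=config.pt_visits)
    for method in ("CT", "PAM"):
        mev = events.loc[events["method"] == method]
        cov_m = (
            coverage.loc[coverage["site_id"].isin(
                sites.loc[sites["method"] == method, "site_id"]
            )]
            if coverage is not None
            else None
        )
        if (cov_m is not None and len(cov_m)) or len(mev):
            singles[method] = build_sensor_history(
                mev, sites, coverage=cov_m,
                occasion_days=config.occasion_days, n_occasions=config.n_occasions,
            )
    for method, hist in singles.items():
        hist.to_csv(out / f"history_{method}.csv")
        artifacts[f"history_{method}.csv"] = str(out / f"history_{method}.csv")

    fused: dict[str, DetectionHistory] = {}
    for r in (2, 3):
        for combo in combinations(sorted(singles), r):
            try:
                h = fuse_histories([singles[m] for m in combo])
            except ValidationError:
                continue
            fused[h.covariates["method"].iloc[0]] = h
    for label, hist in fused.items():
        fname = f"history_{label.replace('+', '_')}.csv"
        hist.to_csv(out / fname)
        artifacts[fname] = str(out / fname)

    summary = naive_summary(list(singles.values()))
    save_csv(summary.rates, "naive_rates.csv")
    save_csv(summary.latency, "naive_latency.csv")
    save_csv(summary.overlap, "naive_overlap.csv")
    profile = hourly_profile(events, sites)
    profile.to_csv(out / "hourly_profile.csv")
    artifacts["hourly_profile.csv"] = str(out / "hourly_profile.csv")

    # ---- stage 3: occupancy modelling --------------------------------------
    stacked = stack_histories(list(singles.values()) + list(fused.values()))
    stacked.to_csv(out / "history_stacked.csv")
    artifacts["history_stacked.csv"] = str(out / "history_stacked.csv")

    fits = [fit(stacked, spec) for spec in standard_model_set(config.psi_mode)]
    table = rank_models(fits)
    save_csv(table, "model_table.csv")
    top = next(f for f in fits if f.name == table["model"].iloc[0])
    log.info("top model: %s (AICc %.2f)", top.name, top.aicc)

    coefs = top.coef_table().reset_index().rename(columns={"index": "parameter"})
    save_csv(coefs, "coefficients.csv")

    levels = top.levels.get("method", ["PT"]) if top.spec.p_covariates else []
    if levels:
        newdata = pd.DataFrame({"method": levels, "habitat": "forest"})
        preds = predict_p(top, newdata)
        preds["n_min"] = [n_min(p) if 0 < p < 1 else np.nan for p in preds["p"]]
        save_csv(preds[["method", "p", "se", "n_min"]], "predictions.csv")
    else:
        preds = None

    log.info("goodness of fit: %d bootstrap replicates (seed=%d)",
             config.n_boot, config.seed)
    gof = gof_parboot(top, n_boot=config.n_boot, seed=config.seed)
    save_json(
        {"chisq": gof.chisq_obs, "p_value": gof.p_value, "n_boot": gof.n_boot,
         "n_failed": gof.n_failed, "seed": gof.seed},
        "gof.json",
    )

    # ---- stage 4: survey-time equalization ---------------------------------
    reference = None
    if preds is not None and "PT" in set(preds["method"]):
        row = preds.loc[preds["method"] == "PT"].iloc[0]
        lo, hi = _ci_logit(row["p"], row["se_eta"])
        reference = {"mean": float(row["p"]), "lo": lo, "hi": hi}
    crossings = {}
    if coverage is not None and reference is not None:
        start, stop, step = config.effort_grid_hours
        grid = np.arange(start, stop + step / 2, step)
        for method in ("CT", "PAM"):
            sids = sites.loc[sites["method"] == method, "site_id"]
            cov_m = coverage.loc[coverage["site_id"].isin(sids)].set_index("site_id")
            if not len(cov_m):
                continue
            ev_m = events.loc[(events["method"] == method) & events["detected"]]
            by_site, rec_hours = {}, {}
            for sid in cov_m.index:
                t0, t1 = cov_m.loc[sid, "start"], cov_m.loc[sid, "end"]
                rec_hours[sid] = (t1 - t0) / pd.Timedelta(hours=1)
                ts = ev_m.loc[ev_m["site_id"] == sid, "timestamp"]
                by_site[sid] = ((ts - t0) / pd.Timedelta(hours=1)).to_numpy()
            curve = effort_curve(
                by_site, rec_hours, grid, n_reps=config.effort_reps,
                seed=config.seed, reference=reference,
            )
            save_csv(curve.table, f"effort_curve_{method}.csv")
            crossings[method] = crossing_time(curve)
            groups = {w: r for w, r in curve.replicates.items() if np.isfinite(r).all()}
            if len(groups) >= 2:
                an = anova_windows(groups)
                save_csv(
                    pd.DataFrame(
                        [{"method": method, "F": an["F"], "df_between": an["df"][0],
                          "df_within": an["df"][1], "p_value": an["p_value"]}]
                    ),
                    f"anova_{method}.csv",
                )
        save_json(crossings, "crossings.json")

    # ---- stage 5: design economics -----------------------------------------
    save_csv(design_summary(), "design_summary.csv")

    save_json(
        {"seed": config.seed, "config_hash": config.config_hash(),
         "package_version": __version__, "n_sites_stacked": stacked.n_sites,
         "top_model": top.name},
        "manifest.json",
    )
    return artifacts
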