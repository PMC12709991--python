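"""End-to-end reproducible runs: simulate -> aggregate -> stage 1 -> PLSR -> traits.

A run is fully determined by a YAML config plus an integer seed; rerunning
the same config yields bit-identical outputs.  Every CSV written carries the
config hash in a leading comment line, and the machine-readable report
(JSON) repeats it, so every reported number is traceable to its run.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import fieldsim, plsr, stage1, traits
from .viewgeom import LINEARIZED_COVARIATE_NAMES, SunPosition

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "seed": 42,
    "output_dir": "runs/demo",
    "field": {
        "n_rows": 27,
        "n_cols": 10,
        "n_genotypes": 30,
        "n_treatments": 3,
        "n_reps": 3,
        "treatment_blocking": "nested",
    },
    "effects": {
        "sd_genotype": 0.3,
        "sd_treatment": 0.3,
        "sd_interaction": 0.0,
        "sd_replicate": 0.1,
        "sd_plot": 0.2,
        "sd_spatial": 1.0,
        "rho_row": 0.8,
        "rho_col": 0.8,
        "grand_mean": 298.0,
    },
    "flight": {
        "n_flights": 3,
        "flight_height": 40.0,
        "fov_half_angles": [22.5, 18.5],
        "front_overlap": 0.8,
        "side_overlap": 0.8,
        "speed": 3.0,
    },
    "sun": {"azimuth": 180.0, "elevation": 55.0},
    "drift": {"amplitude": 1.5},
    "geom": {
        "vignetting_amplitude": 0.3,
        "fcc_effect": 0.5,
        "sun_gradient": 0.005,
        "noise_sd": 0.3,
    },
    "percentile": {
        "enabled": True,
        "n_triggers": 8,
        "n_pixels": 50,
        "soil_fraction": 0.3,
        "soil_delta": 8.0,
        "pixel_sd": 0.5,
        "percentiles": [10, 25, 50, 75, 90],
    },
    "stage1": {
        "include_interaction": True,
        "include_treatment_by_replicate": False,
        "spline_knot_spacing": 10,
        "rho_init": 0.5,
        "max_iter": 100,
        "tol": 1.0e-6,
    },
    "plsr": {"n_components": 2, "stop": 9, "run_elimination": True},
    "traits": {
        "yield_base": 60.0,
        "yield_slope": -8.0,
        "yield_treatment_coupling": -2.0,
        "yield_noise": 0.5,
        "height_base": 90.0,
        "height_slope": -30.0,
        "height_noise": 2.0,
    },
}


def _deep_merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (extra or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


@dataclass
class RunConfig:
    """Fully serializable run configuration (defaults merged in)."""

    params: dict

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls(params=_deep_merge(DEFAULT_CONFIG, user))

    @classmethod
    def default(cls, **overrides) -> "RunConfig":
        return cls(params=_deep_merge(DEFAULT_CONFIG, overrides))

    def with_seed(self, seed: int | None) -> "RunConfig":
        if seed is None:
            return self
        return RunConfig(params=_deep_merge(self.params, {"seed": int(seed)}))

    @property
    def seed(self) -> int:
        return int(self.params["seed"])

    def hash(self) -> str:
        blob = json.dumps(self.params, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def __getitem__(self, key):
        return self.params[key]


@dataclass
class RunReport:
    """All headline tables of one run; every number also lands in a CSV."""

    config_hash: str
    seed: int
    variance_table: pd.DataFrame
    importance: pd.DataFrame
    elimination: plsr.EliminationTrace | None
    residual_report: pd.DataFrame
    correlations: pd.DataFrame
    recovery: dict
    percentile_curve: agg.PercentileCurve | None

    def to_json_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "variance_table": self.variance_table.to_dict(orient="records"),
            "importance": self.importance.reset_index()
            .rename(columns={"index": "covariate"})
            .to_dict(orient="records"),
            "elimination": None
            if self.elimination is None
            else {
                "removed": self.elimination.removed,
                "survivors": self.elimination.survivors,
            },
            "residual_report": self.residual_report.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
            "recovery": self.recovery,
            "chosen_percentile": None
            if self.percentile_curve is None
            else self.percentile_curve.chosen_percentile,
        }


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str, index=False):
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=index)


def simulate_campaign(cfg: RunConfig):
    """Layout, true effects, flight plan and pooled multi-flight measurements."""
    seed = cfg.seed
    f = cfg["field"]
    layout = fieldsim.make_field_layout(
        f["n_rows"], f["n_cols"], f["n_genotypes"], f["n_treatments"],
        f["n_reps"], f["treatment_blocking"], seed=seed,
    )
    eff_cfg = fieldsim.EffectConfig(**cfg["effects"])
    effects = fieldsim.simulate_true_surface(layout, eff_cfg, seed=seed + 1)
    fl = cfg["flight"]
    plan = fieldsim.plan_flight(
        layout,
        flight_height=fl["flight_height"],
        fov_half_angles=tuple(fl["fov_half_angles"]),
        front_overlap=fl["front_overlap"],
        side_overlap=fl["side_overlap"],
        speed=fl["speed"],
        seed=seed,
    )
    sun = SunPosition(**cfg["sun"])
    geom = fieldsim.GeometricEffectModel(**cfg["geom"])
    tables, drifts = [], {}
    for i in range(fl["n_flights"]):
        fid = f"F{i + 1}"
        drift = fieldsim.DriftModel(
            cfg["drift"]["amplitude"], plan.duration, seed=seed + 100 + i
        )
        drifts[fid] = drift
        tables.append(
            fieldsim.simulate_measurements(
                effects, layout, plan, sun=sun, drift=drift, geom=geom,
                seed=seed + 200 + i, flight_id=fid,
            )
        )
    measurements = pd.concat(tables, ignore_index=True)
    return layout, effects, plan, drifts, measurements


def _percentile_stage(cfg, layout, effects, measurements, seed):
    p = cfg["percentile"]
    if not p["enabled"]:
        return None
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA66]))
    totals = effects.plot_totals(layout)
    sub = measurements[measurements["flight_id"] == measurements["flight_id"].iloc[0]]
    trig_ids = sub["trigger_id"].drop_duplicates().iloc[:: max(1, len(sub["trigger_id"].unique()) // p["n_triggers"])]
    samples = []
    for _, rec in sub[sub["trigger_id"].isin(trig_ids)].iterrows():
        true_t = float(totals[rec["plot_id"]])
        n_soil = int(round(p["n_pixels"] * p["soil_fraction"]))
        canopy = rng.normal(true_t, p["pixel_sd"], p["n_pixels"] - n_soil)
        soil = rng.normal(true_t + p["soil_delta"], p["pixel_sd"], n_soil)
        samples.append(
            agg.PlotPixelSample(rec["plot_id"], rec["trigger_id"], np.concatenate([canopy, soil]))
        )
    return agg.percentile_repeatability_curve(samples, layout, percentiles=p["percentiles"])


def run(cfg: RunConfig, output_dir=None) -> RunReport:
    """Execute the full chain and write all intermediate CSVs plus the report."""
    cfg_hash = cfg.hash()
    seed = cfg.seed
    outdir = Path(output_dir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run %s (seed %d) -> %s", cfg_hash, seed, outdir)

    # --- simulate -----------------------------------------------------------
    layout, effects, plan, drifts, measurements = simulate_campaign(cfg)
    _write_csv(layout.plots, outdir / "layout.csv", cfg_hash)
    _write_csv(effects.to_frame(), outdir / "true_effects.csv", cfg_hash)
    _write_csv(measurements, outdir / "measurements.csv", cfg_hash)

    # --- aggregate (percentile selection demo) ------------------------------
    curve = _percentile_stage(cfg, layout, effects, measurements, seed)
    if curve is not None:
        _write_csv(
            pd.DataFrame(
                {"percentile": curve.percentiles, "repeatability": curve.repeatability}
            ),
            outdir / "percentile_curve.csv",
            cfg_hash,
        )

    # --- stage 1: per flight + pooled campaign ------------------------------
    s1cfg = stage1.Stage1Config(**cfg["stage1"])
    flights = list(measurements["flight_id"].unique())
    per_flight = {}
    est_rows = []
    for fid in flights:
        sub = measurements[measurements["flight_id"] == fid]
        res = stage1.CanopyTemperatureModel(sub, layout, s1cfg).fit()
        per_flight[fid] = res
        for level in stage1.PREDICTION_LEVELS:
            e = res.predict(level)
            e["flight_id"] = fid
            est_rows.append(e)
    estimates = pd.concat(est_rows, ignore_index=True)
    var_tab = stage1.variance_table(estimates)
    _write_csv(estimates, outdir / "plot_estimates.csv", cfg_hash)
    _write_csv(var_tab, outdir / "variance_table.csv", cfg_hash)

    campaign = stage1.CanopyTemperatureModel(measurements, layout, s1cfg).fit()
    trend = campaign.spatial_trend()
    _write_csv(trend, outdir / "spatial_trend.csv", cfg_hash)
    _write_csv(campaign.effects_frame(), outdir / "stage1_effects.csv", cfg_hash)

    # --- recovery metrics vs ground truth ------------------------------------
    exp_mask = ~layout.plots["is_border"]
    geno_truth = effects.genotype.drop(fieldsim.BORDER, errors="ignore")
    geno_est = campaign.effects["genotype"].reindex(geno_truth.index)
    spat_truth = effects.spatial[layout.plots.loc[exp_mask, "plot_id"]]
    trend_s = trend.set_index("plot_id")["trend_K"].reindex(spat_truth.index)
    spline_corrs = {}
    for fid, res in per_flight.items():
        sp = res.spline.xs(fid, level="flight_id")
        times = (
            measurements[measurements["flight_id"] == fid]
            .drop_duplicates("trigger_id").set_index("trigger_id")["time_s"]
            .reindex(sp.index)
        )
        truth = drifts[fid](times.to_numpy())
        spline_corrs[fid] = float(np.corrcoef(sp.to_numpy(), truth)[0, 1])
    recovery = {
        "genotype_correlation": float(np.corrcoef(geno_est, geno_truth)[0, 1]),
        "genotype_rmse_K": float(np.sqrt(np.mean((geno_est - geno_truth) ** 2))),
        "spatial_trend_correlation": float(np.corrcoef(trend_s, spat_truth)[0, 1]),
        "drift_spline_correlation": spline_corrs,
    }

    # --- stage 2: PLSR -------------------------------------------------------
    cov_names = list(LINEARIZED_COVARIATE_NAMES)
    pls_cfg = cfg["plsr"]
    models, raw_vars, rel_rows = {}, {}, {}
    flight_pairs = []
    for fid in flights:
        sub_idx = measurements.index[measurements["flight_id"] == fid]
        res = per_flight[fid]
        e = res.residuals.loc[sub_idx].to_numpy()
        cov = measurements.loc[sub_idx, cov_names]
        m = plsr.fit_plsr(e, cov, n_components=pls_cfg["n_components"])
        models[fid] = m
        raw_vars[fid] = float(measurements.loc[sub_idx, "value_K"].var(ddof=1))
        rel_rows[fid] = m.relative_magnitudes()
        flight_pairs.append((e, cov))
    importance = pd.DataFrame(rel_rows)  # index: covariate; columns: flight
    importance["beta_med"] = importance.median(axis=1)
    _write_csv(importance, outdir / "importance_table.csv", cfg_hash, index=True)

    elim = None
    if pls_cfg["run_elimination"]:
        elim = plsr.backward_eliminate(
            flight_pairs, stop=pls_cfg["stop"], n_components=pls_cfg["n_components"]
        )
        _write_csv(
            pd.DataFrame(elim.removed, columns=["covariate", "beta_med_at_removal"]),
            outdir / "elimination_trace.csv",
            cfg_hash,
        )
    resid_report = plsr.residual_variance_report(raw_vars, models)
    _write_csv(resid_report, outdir / "residual_variance.csv", cfg_hash)

    # --- traits --------------------------------------------------------------
    t = cfg["traits"]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A17]))
    plots = layout.plots[exp_mask]
    geno_eff = effects.genotype.reindex(plots["genotype"]).to_numpy()
    treat_eff = effects.treatment.reindex(plots["treatment"]).to_numpy()
    yield_vals = pd.Series(
        t["yield_base"]
        + t["yield_slope"] * geno_eff
        + t["yield_treatment_coupling"] * treat_eff
        + rng.normal(0, t["yield_noise"], len(plots)),
        index=plots["plot_id"].to_numpy(),
    )
    height_vals = pd.Series(
        t["height_base"]
        + t["height_slope"] * geno_eff
        + rng.normal(0, t["height_noise"], len(plots)),
        index=plots["plot_id"].to_numpy(),
    )
    corr_rows = []
    fid0 = flights[0]
    for name, vals in (("yield", yield_vals), ("plant_height", height_vals)):
        ref = traits.fit_reference_trait(vals, layout)
        for level in ("ts_c", "t_defl"):
            ct_est = per_flight[fid0].predict(level)
            corr_rows.append(
                traits.correlate(ct_est, ref, level, trait=name, flight_id=fid0)
            )
    correlations = pd.concat(corr_rows, ignore_index=True)
    _write_csv(correlations, outdir / "correlations.csv", cfg_hash)

    report = RunReport(
        config_hash=cfg_hash,
        seed=seed,
        variance_table=var_tab,
        importance=importance,
        elimination=elim,
        residual_report=resid_report,
        correlations=correlations,
        recovery=recovery,
        percentile_curve=curve,
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, default=str)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.params, fh, sort_keys=True)
    return report
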