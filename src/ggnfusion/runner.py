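"""End-to-end orchestration: simulate -> features -> fold-safe harmonise ->
train/calibrate/stack -> derive and lock thresholds -> evaluate externally ->
benchmark against guideline strategies -> report.

The report is a plain JSON document whose every number is recomputed from
the run's own predictions; with a fixed seed the report is byte-identical
across runs.  External evaluation only ever uses the locked thresholds and
frozen models: any attempt to refit or re-derive on external-flagged data
raises.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import cohortsim, comparators, evalmetrics, fitstack, stratify
from .cohortsim import SimConfig
from .evalmetrics import ConfusionCounts
from .fitstack import FusionStratifier, STREAM_ORDER

__all__ = ["RunConfig", "run_pipeline", "sensitivity_suite", "cli"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int = 0
    mode: str = "table"                   # "table" | "image"
    n_patients: int = 404
    external_centre: int = 3
    grid_step: float = 0.005
    pathology_only: bool = False
    ablation: bool = True
    ablation_boot: int = 400
    stability_threshold_bootstrap: bool = False
    stability_grid: tuple[float, ...] = (3.0, 4.5, 6.0, 7.5, 9.0)
    out_dir: str | None = None
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def _block_metrics(p, y, bands, thresholds, seed: int) -> dict:
    """Discrimination / calibration / band metrics for one cohort block."""
    y = np.asarray(y).astype(int)
    p = np.asarray(p, dtype=float)
    high = bands == "high"
    low = bands == "low"
    cal = evalmetrics.brier_and_calibration(p, y, n_bins=min(10, len(p)))
    counts_high = ConfusionCounts(
        tp=int(np.sum(high & (y == 1))), fp=int(np.sum(high & (y == 0))),
        tn=int(np.sum(~high & (y == 0))), fn=int(np.sum(~high & (y == 1))))
    pv = evalmetrics.predictive_values(counts_high)
    npv_low_k = int(np.sum(low & (y == 0)))
    npv_low_n = int(np.sum(low))
    if npv_low_n > 0:
        lo, hi = evalmetrics.clopper_pearson(npv_low_k, npv_low_n)
        npv_low = {"pct": round(100.0 * npv_low_k / npv_low_n, 1),
                   "ci": (round(100 * lo, 1), round(100 * hi, 1)),
                   "k": npv_low_k, "n": npv_low_n}
    else:
        npv_low = {"pct": float("nan"), "ci": (float("nan"), float("nan")),
                   "k": 0, "n": 0}
    band_tab = stratify.band_summary(bands, y)
    dl = evalmetrics.delong(p, p, y)
    return {
        "auc": evalmetrics.auc(p, y),
        "auc_ci": list(dl.ci_a),
        "brier": cal.brier, "ece": cal.ece, "mce": cal.mce,
        "band_summary": band_tab.to_dict(orient="records"),
        "predictive_values_high_band": pv,
        "npv_low_band": npv_low,
        "fp_per_100_negatives": evalmetrics.fp_per_100_negatives(high, y),
        "risk_score_mean_by_class": {
            "invasive": float(np.mean(stratify.risk_score(p[y == 1]))),
            "non_invasive": float(np.mean(stratify.risk_score(p[y == 0]))),
        },
    }


def run_pipeline(config: RunConfig):
    """Run the full pipeline; returns (report dict, model bundle dict).

    When ``config.out_dir`` is set, writes ``report.json``, the model bundle
    and tidy CSV tables there.
    """
    sim = SimConfig(n_patients=config.n_patients, seed=config.seed,
                    **config.sim_overrides)
    cohort = cohortsim.generate_cohort(sim)
    if config.pathology_only:
        cohort = cohort[cohort["label_source"] == "pathology"].reset_index(drop=True)
    if config.mode == "image":
        # renders a voxel phantom pair per lesion; practical at small n
        features = cohortsim.extract_image_feature_table(cohort, sim)
    else:
        features = cohortsim.simulate_feature_table(cohort, sim)

    internal = features["centre_id"] != config.external_centre
    feats_int = features[internal].reset_index(drop=True)
    feats_ext = features[~internal].reset_index(drop=True)
    y_int = feats_int["label"].to_numpy().astype(int)
    y_ext = feats_ext["label"].to_numpy().astype(int)

    model = FusionStratifier(seed=config.seed, grid_step=config.grid_step)
    model.fit(feats_int, y_int, groups=feats_int["centre_id"].to_numpy(),
              batch=feats_int["centre_id"].to_numpy())
    oof = model.oof_
    p_int = oof["p_fusion"].to_numpy()
    bands_int = stratify.assign_band(p_int, model.thresholds_)

    p_ext = model.predict_proba(feats_ext, batch=feats_ext["centre_id"].to_numpy())[:, 1]
    bands_ext = model.assign_bands(feats_ext, batch=feats_ext["centre_id"].to_numpy())

    report: dict = {
        "config": {**asdict(config), "stability_grid": list(config.stability_grid)},
        "n_internal": int(internal.sum()),
        "n_external": int((~internal).sum()),
        "thresholds": {"t1": model.thresholds_.t1, "t2": model.thresholds_.t2,
                       "derivation": model.thresholds_.derivation},
        "streams": {},
    }
    for s in STREAM_ORDER:
        report["streams"][s] = {
            "oof_auc": evalmetrics.auc(oof[f"p_{s}"], y_int),
            "external_auc": evalmetrics.auc(
                model.stream_models_[s].predict_proba(
                    feats_ext[[c for c in feats_ext.columns if c.startswith(s + ".")]],
                    batch=feats_ext["centre_id"].to_numpy()), y_ext),
            "n_selected_features": len(model.stream_models_[s].selected),
        }
    report["internal_oof"] = _block_metrics(p_int, y_int, bands_int,
                                            model.thresholds_, config.seed)
    report["external"] = _block_metrics(p_ext, y_ext, bands_ext,
                                        model.thresholds_, config.seed)

    # guideline and clinical comparators -----------------------------------
    cohort_int = cohort[internal.to_numpy()].reset_index(drop=True)
    cohort_ext = cohort[(~internal).to_numpy()].reset_index(drop=True)
    tiers_int = comparators.cohort_guideline_tiers(cohort_int)
    tiers_ext = comparators.cohort_guideline_tiers(cohort_ext)
    brock_int = comparators.cohort_brock_probs(cohort_int)
    brock_cal_int = comparators.recalibrate_comparator(brock_int, y_int, model.plan_)
    a_b = fitstack.platt_calibrate(brock_int, y_int)
    brock_cal_ext = fitstack.apply_platt(comparators.cohort_brock_probs(cohort_ext), *a_b)

    bench = {}
    for name, tiers, blk in (("internal", tiers_int, None), ("external", tiers_ext, None)):
        y = y_int if name == "internal" else y_ext
        p = p_int if name == "internal" else p_ext
        bands = bands_int if name == "internal" else bands_ext
        brock_p = brock_cal_int if name == "internal" else brock_cal_ext
        dca = evalmetrics.decision_curve(
            p, y, comparators={
                "lungrads_high": (tiers["lungrads_tier"] == "high").to_numpy(),
                "fleischner_high": (tiers["fleischner_tier"] == "high").to_numpy(),
            })
        entry = {
            "dca_mean_net_benefit": {
                c: float(dca[c].mean()) for c in dca.columns if c != "threshold"},
            "brock_recalibrated_auc": evalmetrics.auc(brock_p, y),
        }
        for gname, col in (("lungrads", "lungrads_tier"), ("fleischner", "fleischner_tier")):
            res = evalmetrics.nri(tiers[col].to_numpy(), bands, y,
                                  n_boot=500, seed=config.seed)
            entry[f"nri_vs_{gname}"] = {
                "categorical": res.nri, "ci": list(res.ci),
                "event_component": res.event_component,
                "nonevent_component": res.nonevent_component,
                "binary": res.nri_binary, "ci_binary": list(res.ci_binary)}
        bench[name] = entry
    report["benchmark"] = bench

    if config.ablation:
        abl = fitstack.fusion_ablate(oof, y_int, n_boot=config.ablation_boot,
                                     seed=config.seed)
        report["ablation"] = abl.to_dict(orient="records")

    # global fusion-layer attributions (mean |Shapley| over internal OOF)
    bg = oof[[f"p_{s}" for s in STREAM_ORDER]]
    attrib = np.zeros(len(STREAM_ORDER))
    for _, row in bg.iterrows():
        phi, _ = fitstack.shapley_fusion(model.fusion_, row.to_numpy(), bg)
        attrib += np.abs(phi)
    report["shap_global_mean_abs"] = {
        s: float(a / len(bg)) for s, a in zip(STREAM_ORDER, attrib)}

    report = _round_floats(report)
    bundle = {
        "streams": {
            s: {
                "selected_features": model.stream_models_[s].selected,
                "coefficients": model.stream_models_[s].classifier.coef_.ravel().tolist(),
                "platt": list(model.stream_models_[s].platt),
            } for s in STREAM_ORDER},
        "fusion": {"intercept": model.fusion_.intercept,
                   "weights": model.fusion_.weights.tolist(),
                   "streams": list(model.fusion_.streams)},
        "thresholds": {"t1": model.thresholds_.t1, "t2": model.thresholds_.t2,
                       "locked": model.thresholds_.locked,
                       "derivation": model.thresholds_.derivation},
        "seed": config.seed,
    }
    bundle = _round_floats(bundle)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "model_bundle.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
        cohortsim.save_cohort(cohort, out / "cohort.csv")
        oof.to_csv(out / "oof_predictions.csv", index=False)
    return report, bundle, model


def sensitivity_suite(config: RunConfig, base_model: FusionStratifier | None = None) -> dict:
    """Alternative stability-threshold analysis.

    Re-derives the surveillance-stable labelling across a grid of annualised
    thresholds, counting label-eligibility flips among surveillance rows and
    the fusion OOF AUC restricted to rows retained at each threshold.
    """
    sim = SimConfig(n_patients=config.n_patients, seed=config.seed,
                    **config.sim_overrides)
    cohort = cohortsim.generate_cohort(sim)
    if base_model is None:
        _, _, base_model = run_pipeline(config)
    internal = cohort["centre_id"] != config.external_centre
    cohort_int = cohort[internal].reset_index(drop=True)
    oof = base_model.oof_
    y = oof["label"].to_numpy()
    addendum = {}
    for thr in config.stability_grid:
        rule = stratify.StabilityRule(annualised_rate_threshold=thr)
        surveil = cohort_int["label_source"] == "surveillance_stable"
        still_ok = np.array([
            stratify.is_radiologically_stable(rec, rule)
            for _, rec in cohort_int[surveil].iterrows()])
        keep = np.ones(len(cohort_int), dtype=bool)
        keep[np.flatnonzero(surveil.to_numpy())[~still_ok]] = False
        p = oof["p_fusion"].to_numpy()[keep]
        yk = y[keep]
        auc_val = evalmetrics.auc(p, yk) if yk.min() != yk.max() else float("nan")
        addendum[f"{thr:g}"] = {
            "label_flips": int((~still_ok).sum()),
            "n_retained": int(keep.sum()),
            "stable_subgroup_size": int(still_ok.sum()),
            "fusion_oof_auc": auc_val,
        }
    return _round_floats(addendum)


# ---------------------------------------------------------------------------
# CLI


@click.group()
def cli():
    """Multi-time-point GGN invasiveness fusion pipeline."""


@cli.command()
@click.option("--seed", type=int, default=0)
@click.option("--n", "n_patients", type=int, default=404)
@click.option("--out", "out_path", type=click.Path(), required=True)
@click.option("--features/--no-features", default=False,
              help="also write the simulated feature table")
def simulate(seed, n_patients, out_path, features):
    """Generate a synthetic multi-centre cohort CSV."""
    cfg = SimConfig(n_patients=n_patients, seed=seed)
    cohort = cohortsim.generate_cohort(cfg)
    cohortsim.save_cohort(cohort, out_path)
    if features:
        table = cohortsim.simulate_feature_table(cohort, cfg)
        table.to_csv(Path(out_path).with_suffix(".features.csv"), index=False)
    click.echo(f"wrote {len(cohort)} lesions to {out_path}")


@cli.command()
@click.option("--scan", type=click.Path(exists=True), required=True)
@click.option("--mask", "mask_path", type=click.Path(exists=True), required=True)
@click.option("--out", "out_path", type=click.Path(), required=True)
def extract(scan, mask_path, out_path):
    """Extract radiomic features from one NIfTI scan/mask pair."""
    from . import radiomics

    s = radiomics.load_scan(scan, mask_path)
    feats = radiomics.extract_features(s)
    pd.DataFrame([feats]).to_csv(out_path, index=False)
    click.echo(f"wrote {len(feats)} features to {out_path}")


@cli.command()
@click.option("--fit-on", type=click.Path(exists=True), required=True)
@click.option("--apply-to", type=click.Path(exists=True), required=True)
@click.option("--batch-col", default="centre_id")
@click.option("--out", "out_path", type=click.Path(), required=True)
def harmonise(fit_on, apply_to, batch_col, out_path):
    """Fit ComBat on one table and apply it (fold-safe) to another."""
    from .harmonise import ComBatHarmonizer

    train = pd.read_csv(fit_on)
    valid = pd.read_csv(apply_to)
    feat_cols = [c for c in train.columns
                 if c not in (batch_col, "patient_id", "label", "label_source")]
    est = ComBatHarmonizer(protect_label=False).fit(
        train[feat_cols], batch=train[batch_col].to_numpy())
    out = est.transform(valid[feat_cols], batch=valid[batch_col].to_numpy())
    out[batch_col] = valid[batch_col]
    out["unharmonised"] = est.unharmonised_mask_
    out.to_csv(out_path, index=False)
    click.echo(f"harmonised {len(out)} rows "
               f"({int(est.unharmonised_mask_.sum())} passed through)")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def run(config_path, seed, out_dir):
    """Run the full pipeline end to end and write the report."""
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig(seed=seed)
    cfg.out_dir = out_dir
    report, _, _ = run_pipeline(cfg)
    click.echo(json.dumps({"external_auc": report["external"]["auc"],
                           "thresholds": report["thresholds"]}, indent=2))


@cli.command("stratify")
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--probs", "probs_path", type=click.Path(exists=True), required=True)
@click.option("--out", "out_path", type=click.Path(), required=True)
def stratify_cmd(model_path, probs_path, out_path):
    """Assign locked risk bands to a CSV of fusion probabilities."""
    bundle = json.loads(Path(model_path).read_text())
    thr = stratify.RiskThresholds(t1=bundle["thresholds"]["t1"],
                                  t2=bundle["thresholds"]["t2"]).lock()
    probs = pd.read_csv(probs_path)
    probs["risk_score"] = np.round(stratify.risk_score(probs["p_fusion"].to_numpy()), 1)
    probs["band"] = stratify.assign_band(probs["p_fusion"].to_numpy(), thr)
    probs.to_csv(out_path, index=False)
    click.echo(f"wrote bands for {len(probs)} rows")


@cli.command()
@click.option("--probs", "probs_path", type=click.Path(exists=True), required=True)
@click.option("--out", "out_path", type=click.Path(), required=True)
def evaluate(probs_path, out_path):
    """Discrimination/calibration metrics for a probs+label CSV."""
    df = pd.read_csv(probs_path)
    p, y = df["p_fusion"].to_numpy(), df["label"].to_numpy().astype(int)
    cal = evalmetrics.brier_and_calibration(p, y, n_bins=min(10, len(p)))
    out = {"auc": evalmetrics.auc(p, y), "brier": cal.brier,
           "ece": cal.ece, "mce": cal.mce}
    Path(out_path).write_text(json.dumps(_round_floats(out), indent=2, sort_keys=True))
    click.echo(json.dumps(_round_floats(out)))


@cli.command()
@click.option("--cohort", "cohort_path", type=click.Path(exists=True), required=True)
@click.option("--out", "out_path", type=click.Path(), required=True)
def benchmark(cohort_path, out_path):
    """Guideline tiers (Lung-RADS, Fleischner) for a cohort CSV."""
    cohort = pd.read_csv(cohort_path)
    tiers = comparators.cohort_guideline_tiers(cohort)
    tiers.to_csv(out_path, index=False)
    click.echo(f"wrote tiers for {len(tiers)} lesions")


@cli.command()
@click.option("--seed", type=int, default=0)
@click.option("--out", "out_path", type=click.Path(), required=True)
def report(seed, out_path):
    """Stability-threshold sensitivity addendum."""
    cfg = RunConfig(seed=seed, ablation=False)
    addendum = sensitivity_suite(cfg)
    Path(out_path).write_text(json.dumps(addendum, indent=2, sort_keys=True))
    click.echo(f"wrote sensitivity addendum to {out_path}")
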