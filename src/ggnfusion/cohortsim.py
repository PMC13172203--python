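"""Seeded synthetic multi-centre ground-glass nodule cohorts.

Generates per-lesion tables (and optional voxel image pairs) carrying the
statistical structure the invasiveness pipeline assumes: two classes
(invasive vs non-invasive) with class-dependent baseline size, attenuation
and semantic-feature prevalence; class-dependent exponential growth over
variable follow-up; a radiologically stable small-pGGN surveillance subgroup
constructed to satisfy the <= 6 mm / >= 3 yr / <= 6 %/yr stability rule; and
per-centre affine batch effects on radiomic features.

Default class parameters are moment-matched to the descriptive statistics of
a multi-centre GGN cohort (invasive baseline volume median ~400 mm^3 vs
~73 mm^3 non-invasive; follow-up medians ~413 vs ~1517 days) with log-normal
volume/interval and normal attenuation forms; the parametric forms are a
modelling choice, i.e. declared emulation rather than reproduction of any
real data-generating process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .radiomics import (
    NoduleScan,
    DAYS_PER_YEAR,
    esd,
    growth_metrics,
    delta_features,
    log1p_rates,
    save_scan,
)

__all__ = [
    "ClassParams",
    "SimConfig",
    "generate_cohort",
    "simulate_growth",
    "render_nodule",
    "inject_batch_effects",
    "simulate_feature_table",
    "save_cohort",
    "load_cohort",
    "META_COLUMNS",
    "RADIOMIC_PREFIXES",
]

SEMANTIC_FLAGS = (
    "spiculation",
    "lobulation",
    "vacuole",
    "air_bronchogram",
    "vascular_convergence",
    "pleural_indentation",
    "initial_solid_component",
    "solid_component_increase",
)

LOBES = ("right_upper", "right_middle", "right_lower", "left_upper", "left_lower")

META_COLUMNS = ("patient_id", "centre_id", "label", "label_source")
RADIOMIC_PREFIXES = ("t0.", "t1.", "delta.")

RECORD_COLUMNS = (
    "patient_id", "centre_id", "age", "sex", "smoker",
    *SEMANTIC_FLAGS, "lobe", "shape_regular",
    "v0", "v1", "hu0", "hu1", "long0", "short0", "long1", "short1",
    "dt_days", "label", "label_source",
)


@dataclass
class ClassParams:
    """Distributions for one invasiveness class.

    Volumes and follow-up intervals are log-normal (parameterised by the
    median and log-scale sigma), attenuation is normal, semantic flags are
    Bernoulli, and growth is exponential with a log-normal |VDT|.
    """

    volume_median_mm3: float
    volume_log_sigma: float
    hu_mean: float
    hu_sd: float
    age_mean: float
    age_sd: float
    female_prob: float
    flag_prevalence: dict[str, float]
    vdt_median_days: float
    vdt_log_sigma: float
    vdt_negative_prob: float
    dt_median_days: float
    dt_log_sigma: float
    delta_hu_per_day_mean: float
    delta_hu_per_day_sd: float
    lobe_probs: tuple[float, ...] = (0.42, 0.06, 0.16, 0.25, 0.11)
    shape_regular_prob: float = 0.46


def default_class_params() -> dict[str, ClassParams]:
    invasive = ClassParams(
        volume_median_mm3=400.0, volume_log_sigma=0.90,
        hu_mean=-632.0, hu_sd=66.0,
        age_mean=58.0, age_sd=10.0, female_prob=0.76,
        flag_prevalence={
            "spiculation": 0.39, "lobulation": 0.47, "vacuole": 0.40,
            "air_bronchogram": 0.52, "vascular_convergence": 0.84,
            "pleural_indentation": 0.29, "initial_solid_component": 0.32,
            "solid_component_increase": 0.32, "smoker": 0.14,
        },
        vdt_median_days=770.0, vdt_log_sigma=0.80, vdt_negative_prob=0.08,
        dt_median_days=413.0, dt_log_sigma=0.62,
        delta_hu_per_day_mean=0.01, delta_hu_per_day_sd=0.06,
        shape_regular_prob=0.45,
    )
    non_invasive = ClassParams(
        volume_median_mm3=73.0, volume_log_sigma=1.10,
        hu_mean=-706.0, hu_sd=51.0,
        age_mean=53.0, age_sd=12.0, female_prob=0.64,
        flag_prevalence={
            "spiculation": 0.088, "lobulation": 0.31, "vacuole": 0.15,
            "air_bronchogram": 0.20, "vascular_convergence": 0.30,
            "pleural_indentation": 0.10, "initial_solid_component": 0.022,
            "solid_component_increase": 0.022, "smoker": 0.14,
        },
        vdt_median_days=4000.0, vdt_log_sigma=1.00, vdt_negative_prob=0.40,
        dt_median_days=1450.0, dt_log_sigma=0.45,
        delta_hu_per_day_mean=0.003, delta_hu_per_day_sd=0.025,
        shape_regular_prob=0.47,
    )
    return {"invasive": invasive, "non_invasive": non_invasive}


def default_batch_params() -> dict[int, dict[str, float]]:
    # Per-centre affine distortion of radiomic feature columns. Shifts are
    # expressed in per-feature SD units (converted to literal offsets at
    # injection time) so that small-magnitude rate features and large
    # volumetric features are distorted comparably.
    return {
        1: {"shift": 0.0, "scale": 1.0},
        2: {"shift": 0.3, "scale": 1.08},
        3: {"shift": -0.2, "scale": 0.94},
    }


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort draw."""

    n_patients: int = 404
    centre_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.386, 3: 0.114})
    invasive_prevalence: float = 0.62
    stable_subgroup_fraction: float = 0.65
    class_params: dict[str, ClassParams] = field(default_factory=default_class_params)
    batch_params: dict[int, dict[str, float]] = field(default_factory=default_batch_params)
    volume_noise_cv: float = 0.05
    stability_threshold_pct_per_year: float = 6.0
    stable_max_diameter_mm: float = 6.0
    stable_min_followup_days: float = 3.0 * DAYS_PER_YEAR
    n_texture_features: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.invasive_prevalence <= 1.0:
            raise ValueError("invasive_prevalence must be in [0, 1]")
        if not 0.0 <= self.stable_subgroup_fraction <= 1.0:
            raise ValueError("stable_subgroup_fraction must be in [0, 1]")
        w = np.array(list(self.centre_weights.values()), dtype=float)
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("centre_weights must be non-negative and sum to 1")


def simulate_growth(v0: float, vdt: float, dt_days: float) -> float:
    """Exponential growth under a signed volume doubling time:
    v1 = v0 * 2^(dt/vdt). Negative VDT shrinks the lesion."""
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if dt_days < 1:
        raise ValueError("dt_days must be >= 1")
    if vdt == 0:
        raise ValueError("vdt must be non-zero")
    return float(v0 * 2.0 ** (dt_days / vdt))


def _lognormal(rng: np.random.Generator, median: float, sigma: float, size=None):
    return np.exp(rng.normal(math.log(median), sigma, size=size))


def _diameters(rng: np.random.Generator, volume: float) -> tuple[float, float, float]:
    """Long/short axial diameters from an assumed ellipsoid with the given
    volume and a sampled long:short axis ratio; keeps size variables
    internally consistent. Returns (long, short, ratio)."""
    ratio = max(1.0, rng.normal(1.30, 0.12))
    short = (6.0 * volume / (math.pi * ratio)) ** (1.0 / 3.0)
    return round(ratio * short, 2), round(short, 2), ratio


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw one synthetic cohort table (one lesion per row).

    Reproducible for a fixed seed; the surveillance-stable subgroup is
    constructed to satisfy the stability rule by construction (no extra
    volumetric noise is layered on those rows).
    """
    rng = np.random.default_rng(config.seed)
    centres = np.array(list(config.centre_weights.keys()))
    cw = np.array(list(config.centre_weights.values()), dtype=float)
    rows = []
    for i in range(config.n_patients):
        centre = int(rng.choice(centres, p=cw))
        invasive = bool(rng.random() < config.invasive_prevalence)
        label = "invasive" if invasive else "non_invasive"
        as_stable = (not invasive) and (rng.random() < config.stable_subgroup_fraction)
        cp = config.class_params[label]
        age = float(np.clip(rng.normal(cp.age_mean, cp.age_sd), 25, 90))
        sex = "female" if rng.random() < cp.female_prob else "male"
        flags = {f: bool(rng.random() < cp.flag_prevalence.get(f, 0.0)) for f in SEMANTIC_FLAGS}
        flags["smoker"] = bool(rng.random() < cp.flag_prevalence.get("smoker", 0.14))
        if as_stable:
            # small pure GGN, long surveillance, bounded annualised change
            flags.update({f: False for f in (
                "initial_solid_component", "solid_component_increase", "spiculation")})
            ratio_cap = config.stable_max_diameter_mm
            for _ in range(100):
                v0 = float(_lognormal(rng, 40.0, 0.45))
                long0, short0, ratio = _diameters(rng, v0)
                if long0 <= ratio_cap:
                    break
            else:  # force a compliant size
                v0 = 30.0
                long0, short0, ratio = _diameters(rng, v0)
            dt = float(rng.uniform(config.stable_min_followup_days + 1.0,
                                   config.stable_min_followup_days + 1100.0))
            ann = float(abs(rng.normal(0.0, 2.2)))
            # cap strictly inside the rule so table rounding cannot tip a
            # constructed-stable row over the threshold
            ann = min(ann, 0.98 * config.stability_threshold_pct_per_year)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            v1 = v0 * (1.0 + sign * ann * dt / (DAYS_PER_YEAR * 100.0))
            v1 = max(v1, 1e-3)
            label_source = "surveillance_stable"
        else:
            v0 = float(_lognormal(rng, cp.volume_median_mm3, cp.volume_log_sigma))
            long0, short0, ratio = _diameters(rng, v0)
            dt = float(max(30.0, _lognormal(rng, cp.dt_median_days, cp.dt_log_sigma)))
            vdt_mag = float(_lognormal(rng, cp.vdt_median_days, cp.vdt_log_sigma))
            vdt = -vdt_mag if rng.random() < cp.vdt_negative_prob else vdt_mag
            v1 = simulate_growth(v0, vdt, dt)
            if config.volume_noise_cv > 0:
                v1 *= float(np.exp(rng.normal(0.0, config.volume_noise_cv)))
                v0 *= float(np.exp(rng.normal(0.0, config.volume_noise_cv)))
            label_source = "pathology"
        hu0 = float(rng.normal(cp.hu_mean, cp.hu_sd))
        hu1 = hu0 + float(rng.normal(cp.delta_hu_per_day_mean, cp.delta_hu_per_day_sd)) * dt
        hu1 = float(np.clip(hu1, -1000.0, 150.0))
        long1 = round(long0 * (v1 / v0) ** (1.0 / 3.0), 2)
        short1 = round(short0 * (v1 / v0) ** (1.0 / 3.0), 2)
        lobe = LOBES[int(rng.choice(len(LOBES), p=np.array(cp.lobe_probs)))]
        rows.append({
            "patient_id": f"P{i:04d}", "centre_id": centre, "age": round(age, 1),
            "sex": sex, "smoker": flags["smoker"],
            **{f: flags[f] for f in SEMANTIC_FLAGS},
            "lobe": lobe, "shape_regular": bool(rng.random() < cp.shape_regular_prob),
            "v0": round(v0, 3), "v1": round(v1, 3),
            "hu0": round(hu0, 2), "hu1": round(hu1, 2),
            "long0": long0, "short0": short0, "long1": long1, "short1": short1,
            "dt_days": round(dt, 1), "label": label, "label_source": label_source,
        })
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


# ---------------------------------------------------------------------------
# voxel rendering (image-mode fixtures)


def render_nodule(record: pd.Series | dict, spacing=(1.0, 1.0, 1.0), seed: int = 0,
                  hu_sigma: float = 30.0, background_hu: float = -1000.0,
                  background_sigma: float = 40.0) -> tuple[NoduleScan, NoduleScan]:
    """Render a (T0, T1) pair of voxel scans for one lesion.

    The ROI is an ellipsoid whose voxelised volume matches v0/v1 (to within
    the voxelisation error of the grid), interior HU ~ N(hu, sigma), with a
    denser core (> -300 HU) when an initial solid component is flagged, on a
    noisy lung-attenuation background.
    """
    rec = dict(record)
    rng = np.random.default_rng(seed)
    scans = []
    for tp in (0, 1):
        v = float(rec[f"v{tp}"])
        hu = float(rec[f"hu{tp}"])
        ratio = float(rec["long0"]) / max(float(rec["short0"]), 1e-9)
        # semi-axes of an ellipsoid with volume v and axis ratio `ratio`
        b = (3.0 * v / (4.0 * math.pi * ratio)) ** (1.0 / 3.0)
        a = ratio * b
        spacing = tuple(float(s) for s in spacing)
        min_vox = v / np.prod(spacing)
        if min_vox < 30:
            raise ValueError("grid too small: target volume below ~30 voxels")
        half = np.array([a, b, b]) + 4.0
        shape = tuple(int(math.ceil(2 * h / s)) | 1 for h, s in zip(half, spacing))
        grid = rng.normal(background_hu, background_sigma, size=shape)
        centre = (np.array(shape) - 1) / 2.0
        idx = np.indices(shape).astype(float)
        phys = [(idx[k] - centre[k]) * spacing[k] for k in range(3)]
        r2 = (phys[0] / a) ** 2 + (phys[1] / b) ** 2 + (phys[2] / b) ** 2
        mask = r2 <= 1.0
        grid[mask] = hu + (rng.normal(0.0, hu_sigma, size=int(mask.sum())) if hu_sigma > 0 else 0.0)
        solid = rec.get("initial_solid_component", False) or (
            tp == 1 and rec.get("solid_component_increase", False))
        if solid and str(rec.get("label", "")) == "invasive":
            frac = 0.45 if tp == 0 else 0.60
            core = r2 <= frac**2
            grid[core] = np.maximum(
                rng.normal(-150.0, hu_sigma if hu_sigma > 0 else 1e-9, size=int(core.sum())),
                -290.0)
        scans.append(NoduleScan(grid, mask, spacing))
    return scans[0], scans[1]


# ---------------------------------------------------------------------------
# feature tables (table mode)


def inject_batch_effects(features: pd.DataFrame, batch_params: dict[int, dict[str, float]],
                         centre_col: str = "centre_id",
                         prefixes: tuple[str, ...] = RADIOMIC_PREFIXES) -> pd.DataFrame:
    """Apply per-centre affine distortion f -> scale_c * f + shift_c to every
    radiomic feature column. Labels and meta columns are untouched."""
    unknown = set(features[centre_col].unique()) - set(batch_params)
    if unknown:
        raise KeyError(f"no batch parameters for centre(s) {sorted(unknown)}")
    out = features.copy()
    cols = [c for c in out.columns if any(c.startswith(p) for p in prefixes)]

    def per_feature(value, col, default):
        return value.get(col, default) if isinstance(value, dict) else value

    for centre, params in batch_params.items():
        sel = out[centre_col] == centre
        if not sel.any():
            continue
        for col in cols:
            shift = per_feature(params.get("shift", 0.0), col, 0.0)
            scale = per_feature(params.get("scale", 1.0), col, 1.0)
            out.loc[sel, col] = out.loc[sel, col] * scale + shift
    return out


def _clinical_block(cohort: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "clinical.age": cohort["age"],
        "clinical.sex_female": (cohort["sex"] == "female").astype(float),
        "clinical.smoker": cohort["smoker"].astype(float),
        "clinical.long_diameter_mm": cohort["long0"],
        "clinical.shape_irregular": (~cohort["shape_regular"]).astype(float),
        **{f"clinical.{f}": cohort[f].astype(float) for f in SEMANTIC_FLAGS},
    })


def _inject_sd_scaled(table: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Translate the config's SD-unit batch shifts into literal per-feature
    offsets, then apply the affine injection to radiomic columns."""
    cols = [c for c in table.columns if any(c.startswith(p) for p in RADIOMIC_PREFIXES)]
    sds = table[cols].std(ddof=0)
    literal = {
        centre: {"shift": {c: params.get("shift", 0.0) * float(sds[c]) for c in cols},
                 "scale": params.get("scale", 1.0)}
        for centre, params in config.batch_params.items()}
    return inject_batch_effects(table, literal)


def _texture_block(rng: np.random.Generator, stream: str, n: int, latent: np.ndarray,
                   weights: np.ndarray, noise_sd: float) -> pd.DataFrame:
    cols = {}
    for j, w in enumerate(weights):
        cols[f"{stream}.glcm.sim_texture_{j}"] = w * latent + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame(cols)


def simulate_feature_table(cohort: pd.DataFrame, config: SimConfig,
                           apply_batch_effects: bool = True) -> pd.DataFrame:
    """Build the four-stream feature table for a cohort in table mode.

    Measured quantities (volume, ESD, attenuation, diameters, growth metrics)
    are deterministic functions of the cohort table; synthetic texture
    features add a class- and size-correlated latent with per-stream noise so
    that the relative informativeness of the streams mirrors the intended
    pattern (clinical strongest, follow-up/delta intermediate, baseline
    weakest). Per-centre batch effects are then applied to radiomic columns.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    n = len(cohort)
    y = (cohort["label"] == "invasive").astype(float).to_numpy()

    t0 = pd.DataFrame({
        "t0.derived.volume_mm3": cohort["v0"],
        "t0.derived.esd_mm": cohort["v0"].map(esd),
        "t0.derived.mean_hu": cohort["hu0"],
        "t0.shape.long_mm": cohort["long0"],
        "t0.shape.short_mm": cohort["short0"],
    })
    t1 = pd.DataFrame({
        "t1.derived.volume_mm3": cohort["v1"],
        "t1.derived.esd_mm": cohort["v1"].map(esd),
        "t1.derived.mean_hu": cohort["hu1"],
        "t1.shape.long_mm": cohort["long1"],
        "t1.shape.short_mm": cohort["short1"],
    })
    k = config.n_texture_features
    w_t0 = rng.uniform(0.15, 0.45, k)    # weak class signal at baseline
    w_t1 = rng.uniform(0.5, 1.0, k)
    latent0 = 0.6 * y + 0.25 * np.log(cohort["v0"].to_numpy()) + rng.normal(0, 0.3, n)
    latent1 = 1.0 * y + 0.25 * np.log(cohort["v1"].to_numpy()) + rng.normal(0, 0.3, n)
    t0 = pd.concat([t0, _texture_block(rng, "t0", n, latent0, w_t0, noise_sd=1.6)], axis=1)
    t1 = pd.concat([t1, _texture_block(rng, "t1", n, latent1, w_t1, noise_sd=0.9)], axis=1)

    delta_rows = []
    for i in range(n):
        rec = cohort.iloc[i]
        gm = growth_metrics(rec["v0"], rec["v1"], rec["dt_days"], rec["hu0"], rec["hu1"])
        f0 = {c[len("t0."):]: t0.iloc[i][c] for c in t0.columns}
        f1 = {c[len("t1."):]: t1.iloc[i][c] for c in t1.columns}
        d = {f"delta.{k_}": v for k_, v in delta_features(f0, f1, rec["dt_days"]).items()}
        d["delta.rate.daily_volume_rate"] = gm.daily_rate
        d["delta.rate.annualised_pct_per_year"] = gm.annualised_rate
        d["delta.rate.mean_hu_per_day"] = gm.delta_mean_hu_per_day
        delta_rows.append(log1p_rates(d))
    delta = pd.DataFrame(delta_rows, index=cohort.index)

    clinical = _clinical_block(cohort)

    table = pd.concat(
        [cohort[["patient_id", "centre_id"]].reset_index(drop=True),
         pd.Series(y, name="label"),
         cohort["label_source"].reset_index(drop=True),
         t0.reset_index(drop=True), t1.reset_index(drop=True),
         delta.reset_index(drop=True), clinical.reset_index(drop=True)],
        axis=1)
    if apply_batch_effects and config.batch_params:
        table = _inject_sd_scaled(table, config)
    return table


def extract_image_feature_table(cohort: pd.DataFrame, config: SimConfig,
                                apply_batch_effects: bool = True) -> pd.DataFrame:
    """Image-mode feature table: render voxel pairs for every lesion and run
    the radiomic feature engine on them.

    Far slower than table mode (one voxel phantom pair per lesion); intended
    for small cohorts and for validating the table-mode shortcut against the
    full extraction path.
    """
    from .radiomics import extract_features

    rows_t0, rows_t1, rows_d = [], [], []
    for i, (_, rec) in enumerate(cohort.iterrows()):
        # finer grid for small lesions so the phantom stays representable
        vmin = min(float(rec["v0"]), float(rec["v1"]))
        s = min(1.0, round((vmin / 40.0) ** (1.0 / 3.0), 2))
        # phantoms are rendered isotropic already; skip the resampling step
        # (nearest-neighbour down-zoom would erode sub-centimetre masks)
        s0, s1 = render_nodule(rec, spacing=(s, s, s), seed=config.seed + 7919 * i)
        f0 = extract_features(s0, resample=False)
        f1 = extract_features(s1, resample=False)
        gm = growth_metrics(rec["v0"], rec["v1"], rec["dt_days"], rec["hu0"], rec["hu1"])
        common = sorted(set(f0) & set(f1))
        d = {f"delta.{k}": v for k, v in delta_features(
            {k: f0[k] for k in common}, {k: f1[k] for k in common},
            rec["dt_days"]).items()}
        d["delta.rate.daily_volume_rate"] = gm.daily_rate
        d["delta.rate.annualised_pct_per_year"] = gm.annualised_rate
        d["delta.rate.mean_hu_per_day"] = gm.delta_mean_hu_per_day
        rows_t0.append({f"t0.{k}": v for k, v in f0.items()})
        rows_t1.append({f"t1.{k}": v for k, v in f1.items()})
        rows_d.append(log1p_rates(d))
    y = (cohort["label"] == "invasive").astype(float)
    table = pd.concat(
        [cohort[["patient_id", "centre_id"]].reset_index(drop=True),
         pd.Series(y.to_numpy(), name="label"),
         cohort["label_source"].reset_index(drop=True),
         pd.DataFrame(rows_t0), pd.DataFrame(rows_t1), pd.DataFrame(rows_d),
         _clinical_block(cohort).reset_index(drop=True)],
        axis=1)
    # texture features can be undefined on degenerate phantoms; drop those
    feat_cols = [c for c in table.columns if "." in c]
    bad = [c for c in feat_cols if not np.isfinite(table[c]).all()]
    table = table.drop(columns=bad)
    if apply_batch_effects and config.batch_params:
        table = _inject_sd_scaled(table, config)
    return table


# ---------------------------------------------------------------------------
# I/O


def save_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_image_pairs(cohort: pd.DataFrame, out_dir: str | Path, seed: int = 0,
                     spacing=(1.0, 1.0, 1.0)) -> None:
    """Render and save NIfTI pairs ``<id>_T0.nii.gz`` etc. for each lesion."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for _, rec in cohort.iterrows():
        s0, s1 = render_nodule(rec, spacing=spacing, seed=seed + hash(rec["patient_id"]) % 2**20)
        pid = rec["patient_id"]
        save_scan(s0, out / f"{pid}_T0.nii.gz", out / f"{pid}_mask_T0.nii.gz")
        save_scan(s1, out / f"{pid}_T1.nii.gz", out / f"{pid}_mask_T1.nii.gz")
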