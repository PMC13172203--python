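"""Guideline-based and clinical comparator strategies.

Lung-RADS v2022 and Fleischner 2017 tier mappers driven by human-readable
versioned YAML rule tables (shipped with the package, editable), and a
"Brock-lite" logistic risk model with published-style coefficients that is
recalibrated with cross-validated Platt scaling before comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitstack import FoldPlan, platt_calibrate, apply_platt

__all__ = [
    "GuidelineInput",
    "BrockLiteInput",
    "load_rules",
    "lung_rads_tier",
    "fleischner_tier",
    "brock_lite",
    "recalibrate_comparator",
    "cohort_guideline_tiers",
    "cohort_brock_probs",
]


@dataclass
class GuidelineInput:
    """Two-dimensional measurements a guideline reader would use."""

    nodule_type: str                  # "ggn" | "part_solid" | "solid"
    total_mm_t0: float
    total_mm_t1: float | None = None
    solid_mm_t0: float = 0.0
    solid_mm_t1: float | None = None
    dt_days: float | None = None
    growth: bool | None = None        # computed from diameters if None
    new_nodule: bool = False

    def __post_init__(self):
        if self.nodule_type not in ("ggn", "part_solid", "solid"):
            raise ValueError("unknown nodule type")
        if self.solid_mm_t0 > self.total_mm_t0 + 1e-9:
            raise ValueError("solid component exceeds total diameter")


@dataclass
class BrockLiteInput:
    age_years: float
    sex_female: bool
    diameter_mm: float
    spiculation: bool
    upper_lobe: bool
    nodule_type: str = "ggn"

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be positive")


def load_rules(name_or_path: str | Path) -> dict:
    """Load a rule table: a packaged name ('lungrads_v2022', 'fleischner_2017',
    'brock_lite') or a path to a YAML file."""
    p = Path(str(name_or_path))
    if p.suffix in (".yaml", ".yml") and p.exists():
        return yaml.safe_load(p.read_text())
    ref = resources.files("ggnfusion").joinpath(f"rules/{name_or_path}.yaml")
    return yaml.safe_load(ref.read_text())


def _is_growing(gi: GuidelineInput, growth_def: dict) -> bool:
    if gi.growth is not None:
        return bool(gi.growth)
    if gi.total_mm_t1 is None or gi.dt_days is None:
        return False
    if gi.dt_days > growth_def.get("max_interval_days", 365):
        # annualise the observed change to the growth window
        change = (gi.total_mm_t1 - gi.total_mm_t0) * growth_def.get(
            "max_interval_days", 365) / gi.dt_days
    else:
        change = gi.total_mm_t1 - gi.total_mm_t0
    return change > growth_def.get("diameter_increase_mm", 1.5)


def _match_rules(gi: GuidelineInput, rules: dict) -> dict:
    growing = _is_growing(gi, rules.get("growth_definition", {}))
    solid = max(gi.solid_mm_t0, gi.solid_mm_t1 or 0.0)
    total = max(gi.total_mm_t0, gi.total_mm_t1 or 0.0)
    for rule in rules["rules"][gi.nodule_type]:
        if "max_total_mm" in rule and not total < rule["max_total_mm"]:
            continue
        if "min_total_mm" in rule and not total >= rule["min_total_mm"]:
            continue
        if "max_solid_mm" in rule and not solid < rule["max_solid_mm"]:
            continue
        if "min_solid_mm" in rule and not solid >= rule["min_solid_mm"]:
            continue
        if "growing" in rule and growing != rule["growing"]:
            continue
        return rule
    raise RuntimeError("rule table is not total over valid inputs")


def lung_rads_tier(gi: GuidelineInput, rules: dict | None = None) -> tuple[str, str]:
    """Map one nodule to its Lung-RADS category and collapsed risk tier."""
    rules = rules or load_rules("lungrads_v2022")
    category = _match_rules(gi, rules)["category"]
    return category, rules["tier_map"][category]


def fleischner_tier(gi: GuidelineInput, rules: dict | None = None) -> str:
    """Map one nodule to the three-tier collapse of Fleischner 2017."""
    rules = rules or load_rules("fleischner_2017")
    return _match_rules(gi, rules)["tier"]


def brock_lite(inp: BrockLiteInput, coeffs: dict | None = None) -> tuple[float, float]:
    """Linear predictor and probability of the Brock-lite logistic model."""
    cfg = coeffs or load_rules("brock_lite")
    c = cfg["coefficients"]
    lp = float(cfg["intercept"])
    lp += c["age_per_year"] * (inp.age_years - cfg["age_centre_years"])
    lp += c["sex_female"] * float(inp.sex_female)
    lp += c["spiculation"] * float(inp.spiculation)
    lp += c["upper_lobe"] * float(inp.upper_lobe)
    if inp.nodule_type == "ggn":
        lp += c["nodule_type_ggn"]
    elif inp.nodule_type == "part_solid":
        lp += c["nodule_type_part_solid"]
    lp += cfg["size_beta"] * ((inp.diameter_mm / 10.0) ** -0.5 - cfg["size_offset"])
    return lp, 1.0 / (1.0 + math.exp(-lp))


def recalibrate_comparator(probs, labels, plan: FoldPlan) -> np.ndarray:
    """Cross-validated Platt recalibration: the sigmoid is fitted on each
    outer-training partition and applied out-of-fold. Rank order within each
    fold is preserved (monotone sigmoid)."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    out = np.full(len(probs), np.nan)
    for tr, va in plan.outer:
        a, b = platt_calibrate(probs[tr], y[tr])
        out[va] = apply_platt(probs[va], a, b)
    if np.isnan(out).any():
        raise RuntimeError("fold plan did not cover all rows")
    return out


# ---------------------------------------------------------------------------
# cohort-table adapters


def _guideline_input_from_record(rec) -> GuidelineInput:
    if bool(rec.get("initial_solid_component", False)):
        ntype = "part_solid"
        solid0 = 0.45 * float(rec["long0"])
        solid1 = (0.6 if bool(rec.get("solid_component_increase", False)) else 0.45) \
            * float(rec["long1"])
    else:
        ntype = "ggn"
        solid0, solid1 = 0.0, 0.0
        if bool(rec.get("solid_component_increase", False)):
            ntype = "part_solid"
            solid1 = 0.4 * float(rec["long1"])
    return GuidelineInput(
        nodule_type=ntype, total_mm_t0=float(rec["long0"]),
        total_mm_t1=float(rec["long1"]), solid_mm_t0=min(solid0, float(rec["long0"])),
        solid_mm_t1=min(solid1, float(rec["long1"])), dt_days=float(rec["dt_days"]))


def cohort_guideline_tiers(cohort: pd.DataFrame) -> pd.DataFrame:
    """Lung-RADS and Fleischner tiers for every lesion of a cohort table."""
    lr_rules = load_rules("lungrads_v2022")
    fl_rules = load_rules("fleischner_2017")
    rows = []
    for _, rec in cohort.iterrows():
        gi = _guideline_input_from_record(rec)
        cat, lr = lung_rads_tier(gi, lr_rules)
        rows.append({"patient_id": rec["patient_id"], "lungrads_category": cat,
                     "lungrads_tier": lr, "fleischner_tier": fleischner_tier(gi, fl_rules)})
    return pd.DataFrame(rows)


def cohort_brock_probs(cohort: pd.DataFrame) -> np.ndarray:
    """Raw Brock-lite probabilities for every lesion of a cohort table."""
    cfg = load_rules("brock_lite")
    out = []
    for _, rec in cohort.iterrows():
        inp = BrockLiteInput(
            age_years=float(rec["age"]), sex_female=rec["sex"] == "female",
            diameter_mm=float(rec["long0"]), spiculation=bool(rec["spiculation"]),
            upper_lobe=str(rec["lobe"]).endswith("upper"),
            nodule_type="part_solid" if bool(rec["initial_solid_component"]) else "ggn")
        out.append(brock_lite(inp, cfg)[1])
    return np.asarray(out)
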