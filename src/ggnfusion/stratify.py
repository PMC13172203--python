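"""Two-threshold three-tier risk stratification and the volumetric
stability rule.

The rule-out threshold t1 is the highest probability cut-point keeping
sensitivity >= 95 % on training out-of-fold predictions; the rule-in
threshold t2 first targets PPV >= 75 % and is then floored so that
t2 >= t1 + 0.05 and t2 >= 0.65, preserving a conservative rule-in boundary
and a meaningful intermediate band.  Once locked, thresholds are immutable
and applied unchanged to external data.  Classification convention:
p >= tau counts as positive; p = t1 falls in the intermediate band and
p = t2 in the high band.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .radiomics import DAYS_PER_YEAR, growth_metrics

__all__ = [
    "LockError",
    "RiskThresholds",
    "StabilityRule",
    "derive_t1",
    "derive_t2",
    "derive_thresholds",
    "risk_score",
    "assign_band",
    "band_summary",
    "is_radiologically_stable",
    "derive_stability_threshold",
    "BANDS",
]

BANDS = ("low", "intermediate", "high")


class LockError(RuntimeError):
    """Raised when locking discipline is violated."""


@dataclass
class RiskThresholds:
    """Locked pair of rule-out/rule-in probability thresholds."""

    t1: float
    t2: float
    grid_step: float = 0.005
    locked: bool = False
    derivation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.t1 <= 1.0 and 0.0 < self.t2 <= 1.0):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.t2 < self.t1:
            raise ValueError("t2 must be >= t1")

    def lock(self) -> "RiskThresholds":
        self.locked = True
        return self

    def __setattr__(self, name, value):
        if getattr(self, "locked", False) and name in ("t1", "t2", "grid_step"):
            raise LockError("locked thresholds are immutable")
        super().__setattr__(name, value)


@dataclass
class StabilityRule:
    """Radiological-stability criteria for the surveillance subgroup."""

    max_baseline_diameter_mm: float = 6.0
    min_followup_years: float = 3.0
    annualised_rate_threshold: float = 6.0   # %/year
    derivation_percentile: float | None = None
    bootstrap_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.annualised_rate_threshold < 0:
            raise ValueError("threshold must be non-negative")


def _grid(step: float) -> np.ndarray:
    n = int(round(1.0 / step))
    return np.round(np.arange(0, n + 1) * step, 10)


def _check_probs(p, y):
    p = np.asarray(p, dtype=float)
    y = np.asarray(y).astype(int)
    if p.shape != y.shape:
        raise ValueError("length mismatch")
    if y.min() == y.max():
        raise ValueError("both classes required")
    return p, y


def derive_t1(oof_probs, labels, grid_step: float = 0.005, target_sens: float = 0.95,
              external: bool = False) -> float:
    """Highest grid threshold with sensitivity >= target (positive = p >= tau)."""
    if external:
        raise LockError("threshold derivation is forbidden on external data")
    p, y = _check_probs(oof_probs, labels)
    pos = p[y == 1]
    best = 0.0
    for tau in _grid(grid_step):
        sens = float(np.mean(pos >= tau))
        if sens >= target_sens:
            best = float(tau)
    return best


def derive_t2(oof_probs, labels, t1: float, grid_step: float = 0.005,
              target_ppv: float = 0.75, min_gap: float = 0.05, floor: float = 0.65,
              external: bool = False) -> float:
    """Lowest grid threshold with PPV >= target, then floored by
    max(t1 + 0.05, 0.65)."""
    if external:
        raise LockError("threshold derivation is forbidden on external data")
    p, y = _check_probs(oof_probs, labels)
    tau_ppv = None
    for tau in _grid(grid_step):
        pred = p >= tau
        if pred.sum() == 0:
            continue  # PPV undefined at this threshold
        ppv = float(y[pred].mean())
        if ppv >= target_ppv:
            tau_ppv = float(tau)
            break
    if tau_ppv is None:
        warnings.warn("no threshold reaches the PPV target; using 0.95",
                      RuntimeWarning, stacklevel=2)
        tau_ppv = 0.95
    # the +0.05 gap can exceed the top of the grid on nearly separable sets
    return float(min(round(max(tau_ppv, t1 + min_gap, floor), 10), 1.0))


def derive_thresholds(oof_probs, labels, grid_step: float = 0.005,
                      lock: bool = True) -> RiskThresholds:
    """Derive, record provenance, and (by default) lock both thresholds."""
    p, y = _check_probs(oof_probs, labels)
    t1 = derive_t1(p, y, grid_step)
    t2 = derive_t2(p, y, t1, grid_step)
    sens = float(np.mean(p[y == 1] >= t1))
    pred = p >= t2
    ppv = float(y[pred].mean()) if pred.any() else float("nan")
    digest = hashlib.sha256(np.ascontiguousarray(np.round(p, 12)).tobytes()).hexdigest()[:16]
    thr = RiskThresholds(
        t1=t1, t2=t2, grid_step=grid_step,
        derivation={"oof_hash": digest, "sensitivity_at_t1": sens, "ppv_at_t2": ppv},
    )
    return thr.lock() if lock else thr


def risk_score(p):
    """Linear 0-100 risk score: score = 100 * p."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    out = 100.0 * arr
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def assign_band(p, thresholds: RiskThresholds):
    """Map probabilities to low / intermediate / high bands.

    Requires locked thresholds (the pipeline never stratifies external data
    with provisional cut-points)."""
    if not thresholds.locked:
        raise LockError("refusing to assign bands with unlocked thresholds")
    arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    bands = np.where(arr >= thresholds.t2, "high",
                     np.where(arr >= thresholds.t1, "intermediate", "low"))
    return bands[0] if np.isscalar(p) or np.asarray(p).ndim == 0 else bands


def band_summary(bands, labels) -> pd.DataFrame:
    """Counts, cohort percentages (1 decimal) and event incidence per band."""
    bands = np.asarray(bands)
    y = np.asarray(labels).astype(int)
    n = len(bands)
    if n < 1:
        raise ValueError("empty input")
    rows = []
    for band in BANDS:
        sel = bands == band
        count = int(sel.sum())
        pct = round(100.0 * count / n, 1)
        if count == 0:
            incidence = float("nan")
        else:
            incidence = round(100.0 * float(y[sel].mean()), 1)
        rows.append({"band": band, "count": count, "pct_of_cohort": pct,
                     "events": int(y[sel].sum()), "incidence_pct": incidence})
    return pd.DataFrame(rows)


def is_radiologically_stable(record, rule: StabilityRule | None = None) -> bool:
    """Stability = baseline max diameter <= 6 mm AND follow-up >= 3 years AND
    annualised absolute relative volume-change rate <= threshold (inclusive)."""
    rule = rule or StabilityRule()
    rec = dict(record)
    dt = rec.get("dt_days")
    if dt is None or (isinstance(dt, float) and math.isnan(dt)):
        raise ValueError("follow-up interval missing")
    gm = growth_metrics(rec["v0"], rec["v1"], dt)
    small = float(rec["long0"]) <= rule.max_baseline_diameter_mm
    long_followup = dt / DAYS_PER_YEAR >= rule.min_followup_years
    slow = gm.annualised_rate <= rule.annualised_rate_threshold
    return bool(small and long_followup and slow)


def derive_stability_threshold(volume_series, percentile: float = 95.0,
                               bootstrap_reps: int = 2000, seed: int = 0,
                               alternatives=(3.0, 4.5, 6.0, 7.5, 9.0)) -> dict:
    """Derive the annualised-variability threshold from longitudinal volume
    series of morphologically stable nodules.

    Each series is a sequence of (t_days, volume_mm3); its annualised
    absolute relative rate uses the first and last measurements. The
    threshold is the requested percentile of the per-nodule rates, with a
    bootstrap percentile CI and a count of nodules passing each alternative
    threshold (label-flip sensitivity).
    """
    series = list(volume_series)
    if len(series) < 20:
        raise ValueError("need at least 20 series")
    rates = []
    for s in series:
        pts = sorted(s)
        (t0, v0), (t1, v1) = pts[0], pts[-1]
        if t1 <= t0 or v0 <= 0:
            raise ValueError("invalid series")
        rates.append(abs(v1 - v0) / (v0 * (t1 - t0)) * DAYS_PER_YEAR * 100.0)
    rates = np.asarray(rates)
    point = float(np.percentile(rates, percentile))
    rng = np.random.default_rng(seed)
    boot = np.array([
        np.percentile(rng.choice(rates, size=len(rates), replace=True), percentile)
        for _ in range(bootstrap_reps)
    ])
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    flips = {float(t): int(np.sum(rates <= t)) for t in alternatives}
    return {
        "threshold_pct_per_year": point,
        "percentile": percentile,
        "bootstrap_ci": ci,
        "n_series": len(series),
        "stable_counts_by_threshold": flips,
    }
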