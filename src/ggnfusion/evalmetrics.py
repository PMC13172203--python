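"""Discrimination, calibration, predictive-value, agreement, decision-curve
and reclassification statistics.

Conventions: AUC is the Mann-Whitney statistic with half credit for ties;
confidence intervals on proportions are exact Clopper-Pearson (Beta quantile
form), which reproduces boundary cases such as 13/13 -> lower bound 75.3 %;
calibration bins are decile (quantile) bins by default; DCA uses
NB(tau) = TP/n - (FP/n) * tau/(1-tau) on a 0.10-0.80 grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConfusionCounts",
    "CalibrationReport",
    "auc",
    "delong",
    "brier_and_calibration",
    "predictive_values",
    "clopper_pearson",
    "fp_per_100_negatives",
    "mcnemar",
    "decision_curve",
    "nri",
    "icc",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("at least one observation required")


@dataclass
class CalibrationReport:
    brier: float
    ece: float
    mce: float
    bins: pd.DataFrame = field(repr=False)


def _split(probs, labels):
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.shape != y.shape:
        raise ValueError("length mismatch")
    if y.min() == y.max():
        raise ValueError("both classes required")
    return p, y


def auc(probs, labels) -> float:
    """Mann-Whitney AUC with 0.5 credit for tied scores."""
    p, y = _split(probs, labels)
    pos, neg = p[y == 1], p[y == 0]
    ranks = sps.rankdata(p)
    r_pos = ranks[y == 1].sum()
    n1, n0 = len(pos), len(neg)
    return float((r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_components(p, y):
    pos, neg = p[y == 1], p[y == 0]
    # placement values
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / len(neg) for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / len(pos) for x in neg])
    return v10, v01


@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    diff: float
    var_diff: float
    z: float
    p_value: float
    degenerate: bool = False


def delong(probs_a, probs_b, labels, alpha: float = 0.05) -> DelongResult:
    """DeLong structural-components comparison of two paired AUCs."""
    pa, y = _split(probs_a, labels)
    pb, _ = _split(probs_b, labels)
    v10a, v01a = _delong_components(pa, y)
    v10b, v01b = _delong_components(pb, y)
    m, n = len(v10a), len(v01a)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    S = s10 / m + s01 / n
    var_a, var_b = float(S[0, 0]), float(S[1, 1])
    var_diff = float(S[0, 0] + S[1, 1] - 2 * S[0, 1])
    z_crit = sps.norm.ppf(1 - alpha / 2)

    def ci(a, v):
        half = z_crit * math.sqrt(max(v, 0.0))
        return (max(0.0, a - half), min(1.0, a + half))

    diff = auc_a - auc_b
    if var_diff <= 0:
        if abs(diff) < 1e-15:
            return DelongResult(auc_a, auc_b, var_a, var_b, ci(auc_a, var_a),
                                ci(auc_b, var_b), 0.0, 0.0, 0.0, 1.0)
        return DelongResult(auc_a, auc_b, var_a, var_b, ci(auc_a, var_a),
                            ci(auc_b, var_b), diff, var_diff, float("nan"),
                            float("nan"), degenerate=True)
    z = diff / math.sqrt(var_diff)
    p = float(2 * sps.norm.sf(abs(z)))
    return DelongResult(auc_a, auc_b, var_a, var_b, ci(auc_a, var_a),
                        ci(auc_b, var_b), diff, var_diff, float(z), p)


def brier_and_calibration(probs, labels, n_bins: int = 10,
                          strategy: str = "quantile") -> CalibrationReport:
    """Brier score plus expected/maximum calibration error over probability
    bins (quantile deciles by default; equal-width behind the flag)."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(p) < n_bins:
        raise ValueError("need at least n_bins observations")
    brier = float(np.mean((p - y) ** 2))
    if strategy == "quantile":
        edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
        if len(edges) < 2:  # constant predictions -> one bin
            edges = np.array([edges[0] - 1e-12, edges[0] + 1e-12])
    elif strategy == "uniform":
        edges = np.linspace(0, 1, n_bins + 1)
    else:
        raise ValueError("strategy must be 'quantile' or 'uniform'")
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows, gaps, weights = [], [], []
    n = len(p)
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            continue
        mp, ob, cnt = float(p[sel].mean()), float(y[sel].mean()), int(sel.sum())
        rows.append({"bin": b, "mean_predicted": mp, "observed_rate": ob, "count": cnt})
        gaps.append(abs(mp - ob))
        weights.append(cnt / n)
    gaps = np.asarray(gaps)
    weights = np.asarray(weights)
    return CalibrationReport(
        brier=brier, ece=float(np.sum(weights * gaps)), mce=float(gaps.max()),
        bins=pd.DataFrame(rows))


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI via Beta quantiles."""
    if n <= 0:
        raise ValueError("n must be positive")
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def predictive_values(counts: ConfusionCounts, alpha: float = 0.05) -> dict:
    """Sensitivity/specificity/PPV/NPV as percentages (1 decimal) with exact
    Clopper-Pearson CIs; zero-denominator quantities are flagged undefined."""
    out = {}
    for name, k, n in (
        ("sensitivity", counts.tp, counts.tp + counts.fn),
        ("specificity", counts.tn, counts.tn + counts.fp),
        ("ppv", counts.tp, counts.tp + counts.fp),
        ("npv", counts.tn, counts.tn + counts.fn),
    ):
        if n == 0:
            out[name] = {"pct": float("nan"), "ci": (float("nan"), float("nan")),
                         "k": k, "n": n, "undefined": True}
            continue
        lo, hi = clopper_pearson(k, n, alpha)
        out[name] = {"pct": round(100.0 * k / n, 1),
                     "ci": (round(100.0 * lo, 1), round(100.0 * hi, 1)),
                     "k": k, "n": n, "undefined": False}
    return out


def fp_per_100_negatives(predicted_high, labels) -> float:
    """False-positive high-risk classifications per 100 non-events."""
    pred = np.asarray(predicted_high)
    if pred.dtype.kind in "US":
        pred = pred == "high"
    pred = pred.astype(bool)
    y = np.asarray(labels).astype(int)
    neg = y == 0
    if neg.sum() == 0:
        raise ValueError("no negatives")
    return round(100.0 * float(pred[neg].mean()), 1)


def mcnemar(x=None, y=None, *, b: int | None = None, c: int | None = None,
            exact_limit: int = 25) -> float:
    """McNemar p-value on paired binaries (or on discordant counts b, c).

    Exact binomial when b + c < exact_limit, otherwise chi-square with
    continuity correction."""
    if b is None or c is None:
        if x is None or y is None:
            raise ValueError("provide paired arrays or discordant counts")
        xa = np.asarray(x).astype(bool)
        ya = np.asarray(y).astype(bool)
        if xa.shape != ya.shape:
            raise ValueError("paired arrays must match")
        b = int(np.sum(xa & ~ya))
        c = int(np.sum(~xa & ya))
    nd = b + c
    if nd == 0:
        return 1.0
    if nd < exact_limit:
        k = min(b, c)
        p = 2.0 * float(sps.binom.cdf(k, nd, 0.5))
        if b == c:
            p -= float(sps.binom.pmf(k, nd, 0.5))  # central term counted twice
        return min(1.0, p)
    stat = (abs(b - c) - 1) ** 2 / nd
    return float(sps.chi2.sf(stat, 1))


def decision_curve(probs_or_pred, labels, grid=None,
                   comparators: dict | None = None) -> pd.DataFrame:
    """Net-benefit curve: NB(tau) = TP/n - (FP/n) * tau/(1-tau).

    ``probs_or_pred`` may be probabilities (thresholded at each tau) or a
    fixed binary rule (e.g. a guideline's high tier), applied at every tau.
    Comparator strategies are fixed binary rules. Treat-all and treat-none
    are always included; treat-none is identically zero.
    """
    if grid is None:
        grid = np.round(np.arange(0.10, 0.801, 0.01), 10)
    y = np.asarray(labels).astype(int)
    n = len(y)
    pi = y.mean()
    arr = np.asarray(probs_or_pred, dtype=float)

    def nb_of(pred, tau):
        tp = float(np.sum(pred & (y == 1))) / n
        fp = float(np.sum(pred & (y == 0))) / n
        return tp - fp * tau / (1 - tau)

    fixed = set(np.unique(arr)) <= {0.0, 1.0}
    rows = []
    for tau in grid:
        pred = arr.astype(bool) if fixed else arr >= tau
        row = {"threshold": float(tau),
               "model": nb_of(pred, tau),
               "treat_all": float(pi - (1 - pi) * tau / (1 - tau)),
               "treat_none": 0.0}
        for name, comp in (comparators or {}).items():
            row[name] = nb_of(np.asarray(comp).astype(bool), tau)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class NriResult:
    nri: float
    event_component: float
    nonevent_component: float
    ci: tuple[float, float]
    nri_binary: float
    ci_binary: tuple[float, float]


def _nri_components(old_rank, new_rank, y):
    ev, ne = y == 1, y == 0
    up, down = new_rank > old_rank, new_rank < old_rank
    evc = float(up[ev].mean() - down[ev].mean())
    nec = float(down[ne].mean() - up[ne].mean())
    return evc, nec


def nri(old_tiers, new_tiers, labels, tier_order=("low", "intermediate", "high"),
        n_boot: int = 2000, seed: int = 0, alpha: float = 0.05) -> NriResult:
    """Categorical (3-tier) and binary (high-vs-not) net reclassification
    improvement, with bootstrap percentile CIs."""
    order = {t: i for i, t in enumerate(tier_order)}
    old = np.asarray([order[t] for t in np.asarray(old_tiers)])
    new = np.asarray([order[t] for t in np.asarray(new_tiers)])
    y = np.asarray(labels).astype(int)
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError("need both events and non-events")
    evc, nec = _nri_components(old, new, y)
    hi = order[tier_order[-1]]
    evb, neb = _nri_components((old == hi).astype(int), (new == hi).astype(int), y)
    rng = np.random.default_rng(seed)
    cat_boot, bin_boot = [], []
    n = len(y)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.sum() == 0 or (1 - yb).sum() == 0:
            continue
        e, ne_ = _nri_components(old[idx], new[idx], yb)
        cat_boot.append(e + ne_)
        e2, ne2 = _nri_components((old[idx] == hi).astype(int),
                                  (new[idx] == hi).astype(int), yb)
        bin_boot.append(e2 + ne2)
    lo, hi_ = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return NriResult(
        nri=evc + nec, event_component=evc, nonevent_component=nec,
        ci=(float(np.percentile(cat_boot, lo)), float(np.percentile(cat_boot, hi_))),
        nri_binary=evb + neb,
        ci_binary=(float(np.percentile(bin_boot, lo)), float(np.percentile(bin_boot, hi_))),
    )


def icc(measurements) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``measurements`` is an (n_subjects, n_raters) array or DataFrame.
    """
    X = np.asarray(measurements, dtype=float)
    n, k = X.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 raters")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return float("nan")
    return float((msr - mse) / denom)
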