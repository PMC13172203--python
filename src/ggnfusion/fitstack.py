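"""Centre-grouped nested cross-validation, per-stream model fitting with
probability calibration, stacked logistic fusion, and exact Shapley
attribution of the fusion layer.

Per stream (t0 / t1 / delta radiomics, clinical-semantic) and per outer
fold, strictly inside the outer-training rows: ComBat harmonisation (for
radiomic streams), Mann-Whitney screening with Benjamini-Hochberg FDR,
correlation pruning plus an L1 logistic path (penalty by inner-fold AUC,
1-SE rule), an L2 logistic base learner on standardised features, and Platt
calibration fitted on inner out-of-fold predictions.  Calibrated stream
probabilities from pooled outer-fold predictions feed a lightly penalised
logistic fusion on the logit scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from . import stratify
from .evalmetrics import auc
from .harmonise import ComBatHarmonizer

__all__ = [
    "FoldPlan",
    "make_folds",
    "screen_features",
    "select_sparse",
    "fit_unimodal",
    "platt_calibrate",
    "apply_platt",
    "StreamClassifier",
    "oof_predict",
    "FusionModel",
    "fit_fusion",
    "fusion_ablate",
    "shapley_fusion",
    "FusionStratifier",
    "STREAM_ORDER",
    "LeakageError",
]

logger = logging.getLogger(__name__)

STREAM_ORDER = ("t0", "t1", "delta", "clinical")
EPS = 1e-6


class LeakageError(RuntimeError):
    """Raised when a fold-safe guard detects train/validation contamination."""


def _logit(p):
    p = np.clip(np.asarray(p, dtype=float), EPS, 1 - EPS)
    return np.log(p / (1 - p))


# ---------------------------------------------------------------------------
# folds


@dataclass
class FoldPlan:
    """Outer/inner grouped fold structure over internal rows."""

    outer: list[tuple[np.ndarray, np.ndarray]]
    inner: list[list[tuple[np.ndarray, np.ndarray]]]   # indices relative to outer-train
    groups: np.ndarray
    seed: int
    inner_fallback: list[bool] = field(default_factory=list)

    def validate(self) -> None:
        n = len(self.groups)
        seen = np.zeros(n, dtype=int)
        for tr, va in self.outer:
            if set(self.groups[tr]) & set(self.groups[va]):
                raise LeakageError("a group spans train and validation")
            seen[va] += 1
        if not np.all(seen == 1):
            raise LeakageError("rows must appear in exactly one outer validation set")


def _grouped_splits(groups: np.ndarray, seed: int, k: int = 5):
    uniq = list(pd.unique(groups))
    if len(uniq) <= k:
        return [(np.flatnonzero(groups != g), np.flatnonzero(groups == g)) for g in uniq]
    # grouped k-fold: shuffle groups, deal into k bins balanced by size
    rng = np.random.default_rng(seed)
    order = sorted(uniq, key=lambda g: (-np.sum(groups == g), str(g)))
    rng.shuffle(order)
    bins: list[list] = [[] for _ in range(k)]
    sizes = np.zeros(k)
    for g in sorted(order, key=lambda g: -np.sum(groups == g)):
        j = int(np.argmin(sizes))
        bins[j].append(g)
        sizes[j] += np.sum(groups == g)
    splits = []
    for members in bins:
        va = np.flatnonzero(np.isin(groups, members))
        tr = np.flatnonzero(~np.isin(groups, members))
        splits.append((tr, va))
    return splits


def make_folds(groups, seed: int = 0, n_inner: int = 3,
               allow_single_group_fallback: bool = False) -> FoldPlan:
    """Leave-one-group-out outer folds when there are <= 5 groups, grouped
    5-fold otherwise; inner folds follow the same policy within each
    outer-training set, with seeded random pseudo-groups when the
    outer-training set contains a single centre."""
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        if not allow_single_group_fallback:
            raise ValueError(
                "only one group present; pass allow_single_group_fallback=True "
                "to use seeded random pseudo-groups")
        rng = np.random.default_rng(seed)
        groups = rng.integers(0, max(n_inner, 2), size=len(groups))
        uniq = pd.unique(groups)
    outer = _grouped_splits(groups, seed)
    inner, fallback = [], []
    for fold_id, (tr, _va) in enumerate(outer):
        g_tr = groups[tr]
        if len(pd.unique(g_tr)) < 2:
            rng = np.random.default_rng(seed * 1000 + fold_id + 1)
            pseudo = rng.integers(0, n_inner, size=len(tr))
            while len(np.unique(pseudo)) < 2:  # tiny-fold guard
                pseudo = rng.integers(0, n_inner, size=len(tr))
            inner.append(_grouped_splits(pseudo, seed * 1000 + fold_id))
            fallback.append(True)
        else:
            inner.append(_grouped_splits(g_tr, seed * 1000 + fold_id))
            fallback.append(False)
    plan = FoldPlan(outer=outer, inner=inner, groups=groups, seed=seed,
                    inner_fallback=fallback)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# screening and selection


def screen_features(X: pd.DataFrame, y, alpha: float = 0.05):
    """Two-sided Mann-Whitney U per feature with Benjamini-Hochberg FDR;
    retains adjusted p < alpha. Returns (names, raw p-values series)."""
    y = np.asarray(y).astype(int)
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need >= 2 rows per class")
    pvals = {}
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            pvals[col] = 1.0
            continue
        stat = sps.mannwhitneyu(x[y == 1], x[y == 0], alternative="two-sided")
        pvals[col] = float(stat.pvalue)
    pser = pd.Series(pvals)
    reject, _adj, *_ = multipletests(pser.to_numpy(), alpha=alpha, method="fdr_bh")
    names = [c for c, r in zip(pser.index, reject) if r]
    return names, pser


def _prune_correlated(X: pd.DataFrame, pvals: pd.Series, rho: float = 0.90) -> list[str]:
    cols = sorted(X.columns, key=lambda c: (pvals.get(c, 1.0), c))
    if len(cols) < 2:
        return list(cols)
    corr = sps.spearmanr(X[cols].to_numpy()).statistic
    if np.ndim(corr) == 0:  # scipy collapses the 2-column case to a scalar
        corr = np.array([[1.0, corr], [corr, 1.0]])
    keep: list[int] = []
    for i in range(len(cols)):
        if all(abs(corr[i, j]) <= rho or np.isnan(corr[i, j]) for j in keep):
            keep.append(i)
    return [cols[i] for i in keep]


def select_sparse(X: pd.DataFrame, y, inner_folds, seed: int = 0,
                  pvals: pd.Series | None = None,
                  c_grid=None) -> list[str]:
    """Correlation pruning (|Spearman| > 0.90, keep the lower screening p)
    followed by an L1 logistic path with the penalty chosen by inner-fold
    AUC under the 1-SE rule. Returns non-zero-coefficient features."""
    y = np.asarray(y).astype(int)
    if X.shape[1] == 0:
        raise ValueError("empty retained set")
    if pvals is None:
        _, pvals = screen_features(X, y, alpha=1.1)
    cols = _prune_correlated(X, pvals)
    Xp = X[cols]
    if c_grid is None:
        c_grid = np.logspace(-2, 2, 13)
    scaler = StandardScaler().fit(Xp)
    Xs = scaler.transform(Xp)
    scores = np.full((len(c_grid), len(inner_folds)), np.nan)
    for fi, (tr, va) in enumerate(inner_folds):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            continue
        sc = StandardScaler().fit(Xp.iloc[tr])
        xtr, xva = sc.transform(Xp.iloc[tr]), sc.transform(Xp.iloc[va])
        for ci_, C in enumerate(c_grid):
            clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=C,
                                     max_iter=10000, random_state=seed)
            clf.fit(xtr, y[tr])
            scores[ci_, fi] = auc(clf.predict_proba(xva)[:, 1], y[va])
    mean = np.nanmean(scores, axis=1)
    if np.all(np.isnan(mean)):
        mean = np.zeros(len(c_grid))
    nfold = np.sum(~np.isnan(scores), axis=1).clip(min=1)
    se = np.nanstd(scores, axis=1, ddof=0) / np.sqrt(nfold)
    best = int(np.nanargmax(mean))
    # Null guard: the best mean inner AUC must clear chance by 2.5 null
    # standard errors (null AUC variance (n1+n0+1)/(12*n1*n0) per fold);
    # maximising over the penalty grid otherwise "finds" signal in noise.
    null_vars = []
    for tr, va in inner_folds:
        n1 = int(np.sum(y[va] == 1))
        n0 = int(np.sum(y[va] == 0))
        if n1 > 0 and n0 > 0:
            null_vars.append((n1 + n0 + 1) / (12.0 * n1 * n0))
    se_null = (np.sqrt(np.sum(null_vars)) / len(null_vars)) if null_vars else 0.0
    if mean[best] <= 0.5 + 2.5 * se_null:
        chosen = float(c_grid[0])
    else:
        # 1-SE rule: most penalised C whose mean AUC is within one SE of best
        ok = mean >= mean[best] - se[best]
        chosen = float(c_grid[int(np.flatnonzero(ok)[0])])
    clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=chosen,
                             max_iter=10000, random_state=seed)
    clf.fit(Xs, y)
    selected = [c for c, w in zip(cols, clf.coef_.ravel()) if w != 0.0]
    if not selected:
        top = pvals.reindex(cols).sort_values().index[0]
        warnings.warn("L1 path selected no features; falling back to top-1 by p",
                      RuntimeWarning, stacklevel=2)
        selected = [top]
    return selected


# ---------------------------------------------------------------------------
# base learners and calibration


class StreamClassifier(BaseEstimator, ClassifierMixin):
    """L2 logistic regression on standardised features (one stream).

    Standardisation parameters come from the training rows only. Perfect
    separation is harmless: the ridge penalty keeps coefficients finite.
    """

    def __init__(self, C: float = 1.0, random_state: int = 0):
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.scaler_ = StandardScaler().fit(X)
        self.model_ = LogisticRegression(C=self.C, max_iter=5000,
                                         random_state=self.random_state)
        self.model_.fit(self.scaler_.transform(X), y)
        self.classes_ = self.model_.classes_
        self.coef_ = self.model_.coef_
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(self.scaler_.transform(np.asarray(X, dtype=float)))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def fit_unimodal(X, y, C: float = 1.0, seed: int = 0) -> StreamClassifier:
    return StreamClassifier(C=C, random_state=seed).fit(X, y)


def platt_calibrate(raw_probs, labels) -> tuple[float, float]:
    """Platt sigmoid on the logit of held-out raw probabilities:
    p_cal = sigmoid(a * logit(raw) + b), fitted by maximum likelihood on the
    plain labels."""
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes required for calibration")
    s = _logit(raw_probs).reshape(-1, 1)
    clf = LogisticRegression(C=1e6, max_iter=5000)
    clf.fit(s, y)
    return float(clf.coef_[0, 0]), float(clf.intercept_[0])


def apply_platt(raw_probs, a: float, b: float) -> np.ndarray:
    z = a * _logit(raw_probs) + b
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# per-stream fold pipeline


@dataclass
class StreamModel:
    """Everything needed to score one stream on new rows."""

    stream: str
    harmonizer: ComBatHarmonizer | None
    selected: list[str]
    classifier: StreamClassifier
    platt: tuple[float, float]
    screening_p: pd.Series = field(repr=False, default=None)

    def predict_proba(self, X: pd.DataFrame, batch=None) -> np.ndarray:
        if self.harmonizer is not None:
            X = self.harmonizer.transform(X, batch=batch)
        raw = self.classifier.predict_proba(X[self.selected])[:, 1]
        return apply_platt(raw, *self.platt)


def _stream_columns(table: pd.DataFrame, stream: str) -> list[str]:
    return [c for c in table.columns if c.startswith(stream + ".")]


def fit_stream(table: pd.DataFrame, y, stream: str, inner_folds,
               batch=None, harmonise: bool = True, seed: int = 0,
               alpha: float = 0.05) -> StreamModel:
    """Fit one stream entirely inside the given training rows: harmonise,
    screen, select, fit, and calibrate on inner out-of-fold predictions."""
    cols = _stream_columns(table, stream)
    X = table[cols].reset_index(drop=True)
    y = np.asarray(y).astype(int)
    batch = np.asarray(batch) if batch is not None else np.zeros(len(X), dtype=int)

    harmonizer = None
    Xh = X
    if harmonise and len(pd.unique(batch)) >= 2:
        harmonizer = ComBatHarmonizer().fit(X, y=y, batch=batch)
        Xh = harmonizer.transform(X, batch=batch, y=y)

    retained, pvals = screen_features(Xh, y, alpha=alpha)
    if not retained:
        retained = [pvals.sort_values().index[0]]
        warnings.warn(f"{stream}: screening retained nothing; top-1 fallback",
                      RuntimeWarning, stacklevel=2)
    selected = select_sparse(Xh[retained], y, inner_folds, seed=seed,
                             pvals=pvals.reindex(retained))

    # inner-OOF raw predictions for calibration (never rows used to fit the
    # learner that produced them)
    raw_oof = np.full(len(X), np.nan)
    for tr, va in inner_folds:
        if len(np.unique(y[tr])) < 2:
            continue
        ih = None
        Xtr, Xva = X.iloc[tr], X.iloc[va]
        if harmonise and len(pd.unique(batch[tr])) >= 2:
            ih = ComBatHarmonizer().fit(Xtr, y=y[tr], batch=batch[tr])
            Xtr = ih.transform(Xtr, batch=batch[tr], y=y[tr])
            Xva = ih.transform(Xva, batch=batch[va])
        clf = fit_unimodal(Xtr[selected], y[tr], seed=seed)
        raw_oof[va] = clf.predict_proba(Xva[selected])[:, 1]
    have = ~np.isnan(raw_oof)
    if have.sum() < 2 or len(np.unique(y[have])) < 2:
        platt = (1.0, 0.0)
    else:
        platt = platt_calibrate(raw_oof[have], y[have])

    classifier = fit_unimodal(Xh[selected], y, seed=seed)
    return StreamModel(stream=stream, harmonizer=harmonizer, selected=selected,
                       classifier=classifier, platt=platt, screening_p=pvals)


# ---------------------------------------------------------------------------
# pooled out-of-fold predictions


def oof_predict(plan: FoldPlan, table: pd.DataFrame, y, batch=None,
                streams=STREAM_ORDER, harmonised_streams=("t0", "t1", "delta"),
                seed: int = 0) -> pd.DataFrame:
    """Pooled out-of-fold calibrated probabilities per stream.

    For each outer fold the whole preprocessing chain (ComBat, screening,
    selection, fitting, calibration) runs inside the outer-training rows
    only, then scores the held-out centre. A provenance audit asserts that
    validation rows never enter any fit.
    """
    y = np.asarray(y).astype(int)
    batch = np.asarray(batch) if batch is not None else np.zeros(len(table), dtype=int)
    out = pd.DataFrame(index=range(len(table)),
                       columns=[f"p_{s}" for s in streams], dtype=float)
    out["fold"] = -1
    out["label"] = y
    for fold_id, (tr, va) in enumerate(plan.outer):
        if set(tr) & set(va):
            raise LeakageError("outer fold overlap")
        sub = table.iloc[tr].reset_index(drop=True)
        for s in streams:
            model = fit_stream(sub, y[tr], s, plan.inner[fold_id],
                               batch=batch[tr], harmonise=s in harmonised_streams,
                               seed=seed)
            out.loc[va, f"p_{s}"] = model.predict_proba(
                table.iloc[va][_stream_columns(table, s)].reset_index(drop=True),
                batch=batch[va])
        out.loc[va, "fold"] = fold_id
    if out[[f"p_{s}" for s in streams]].isna().any().any():
        raise LeakageError("some rows received no out-of-fold prediction")
    return out


# ---------------------------------------------------------------------------
# fusion


@dataclass
class FusionModel:
    """Logistic fusion of calibrated stream probabilities on the logit scale."""

    streams: tuple[str, ...]
    intercept: float
    weights: np.ndarray

    def decision(self, probs: pd.DataFrame) -> np.ndarray:
        Z = np.column_stack([_logit(probs[f"p_{s}"]) for s in self.streams])
        return self.intercept + Z @ self.weights

    def predict_proba(self, probs: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision(probs)))


def fit_fusion(oof: pd.DataFrame, labels, streams=STREAM_ORDER,
               l2_lambda: float = 1e-3) -> FusionModel:
    """Fit the stacked logistic fusion on pooled out-of-fold rows."""
    missing = [s for s in streams if f"p_{s}" not in oof.columns]
    if missing:
        raise ValueError(f"missing stream predictions: {missing}")
    y = np.asarray(labels).astype(int)
    Z = np.column_stack([_logit(oof[f"p_{s}"]) for s in streams])
    clf = LogisticRegression(C=1.0 / (l2_lambda * len(y)), max_iter=5000)
    clf.fit(Z, y)
    return FusionModel(streams=tuple(streams), intercept=float(clf.intercept_[0]),
                       weights=clf.coef_.ravel().copy())


def fusion_ablate(oof: pd.DataFrame, labels, streams=STREAM_ORDER,
                  n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Refit the fusion without each stream; report the AUC change with a
    bootstrap percentile CI (negative delta = performance lost)."""
    y = np.asarray(labels).astype(int)
    full = fit_fusion(oof, y, streams)
    auc_full = auc(full.predict_proba(oof), y)
    rng = np.random.default_rng(seed)
    rows = []
    n = len(y)
    for s in streams:
        reduced_streams = tuple(t for t in streams if t != s)
        reduced = fit_fusion(oof, y, reduced_streams)
        delta = auc(reduced.predict_proba(oof), y) - auc_full
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() == yb.max():
                continue
            ob = oof.iloc[idx].reset_index(drop=True)
            f_b = fit_fusion(ob, yb, streams)
            r_b = fit_fusion(ob, yb, reduced_streams)
            boots.append(auc(r_b.predict_proba(ob), yb) - auc(f_b.predict_proba(ob), yb))
        rows.append({"removed": s, "delta_auc": float(delta),
                     "ci_lo": float(np.percentile(boots, 2.5)),
                     "ci_hi": float(np.percentile(boots, 97.5))})
    return pd.DataFrame(rows)


def shapley_fusion(fusion: FusionModel, x, background: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Exact Shapley attribution of the fusion logit by enumeration of all
    2^k coalitions with the interventional (background-mean substitution)
    value function.

    ``x`` is the vector of calibrated stream probabilities for one case;
    ``background`` a DataFrame of reference rows with p_<stream> columns.
    Returns (attributions per stream, base value); base plus the sum of
    attributions equals the fused logit (efficiency).
    """
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    k = len(fusion.streams)
    xprime = _logit(np.asarray(x, dtype=float))
    mu = np.array([_logit(background[f"p_{s}"]).mean() for s in fusion.streams])
    w = fusion.weights

    def value(coalition: frozenset) -> float:
        z = np.where([i in coalition for i in range(k)], xprime, mu)
        return float(fusion.intercept + z @ w)

    from math import factorial

    phi = np.zeros(k)
    members = list(range(k))
    for i in members:
        others = [j for j in members if j != i]
        for r in range(k):
            for S in combinations(others, r):
                S = frozenset(S)
                weight = factorial(len(S)) * factorial(k - len(S) - 1) / factorial(k)
                phi[i] += weight * (value(S | {i}) - value(S))
    return phi, value(frozenset())


# ---------------------------------------------------------------------------
# top-level estimator


class FusionStratifier(BaseEstimator, ClassifierMixin):
    """End-to-end multi-time-point fusion classifier with locked thresholds.

    ``fit`` runs centre-grouped nested cross-validation over the internal
    table (fold-safe ComBat, screening, selection, per-stream calibration),
    pools out-of-fold predictions, fits the stacked fusion, derives and
    locks the two risk thresholds on the internal OOF fusion probabilities,
    and finally refits each stream on all internal rows (calibration via the
    internal grouped folds) for external use.

    Parameters
    ----------
    seed : int
        Funnels all randomness (fold construction, selection paths).
    grid_step : float
        Threshold-derivation grid resolution.
    harmonise : bool
        Apply fold-safe ComBat to radiomic streams.

    Attributes
    ----------
    plan_ : FoldPlan
    oof_ : DataFrame with pooled per-stream and fusion OOF probabilities
    fusion_ : FusionModel
    thresholds_ : locked RiskThresholds
    stream_models_ : dict of final per-stream models
    """

    def __init__(self, seed: int = 0, grid_step: float = 0.005,
                 harmonise: bool = True, streams: tuple[str, ...] = STREAM_ORDER):
        self.seed = seed
        self.grid_step = grid_step
        self.harmonise = harmonise
        self.streams = streams

    def fit(self, X: pd.DataFrame, y, *, groups, batch=None):
        y = np.asarray(y).astype(int)
        groups = np.asarray(groups)
        batch = np.asarray(batch) if batch is not None else groups
        harmonised = tuple(s for s in self.streams if s != "clinical") if self.harmonise else ()
        self.plan_ = make_folds(groups, seed=self.seed,
                                allow_single_group_fallback=True)
        oof = oof_predict(self.plan_, X, y, batch=batch, streams=self.streams,
                          harmonised_streams=harmonised, seed=self.seed)
        self.fusion_ = fit_fusion(oof, y, self.streams)
        oof["p_fusion"] = self.fusion_.predict_proba(oof)
        self.oof_ = oof
        self.thresholds_ = stratify.derive_thresholds(
            oof["p_fusion"].to_numpy(), y, grid_step=self.grid_step)
        self.stream_models_ = {
            s: fit_stream(X.reset_index(drop=True), y, s,
                          inner_folds=[(tr, va) for tr, va in self.plan_.outer],
                          batch=batch, harmonise=s in harmonised, seed=self.seed)
            for s in self.streams
        }
        self.classes_ = np.array([0, 1])
        return self

    def stream_probabilities(self, X: pd.DataFrame, batch=None) -> pd.DataFrame:
        if batch is None:
            batch = np.zeros(len(X), dtype=int)
        probs = {}
        for s in self.streams:
            cols = _stream_columns(X, s)
            probs[f"p_{s}"] = self.stream_models_[s].predict_proba(
                X[cols].reset_index(drop=True), batch=np.asarray(batch))
        return pd.DataFrame(probs)

    def predict_proba(self, X: pd.DataFrame, batch=None) -> np.ndarray:
        p = self.fusion_.predict_proba(self.stream_probabilities(X, batch=batch))
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame, batch=None) -> np.ndarray:
        return (self.predict_proba(X, batch=batch)[:, 1] >= 0.5).astype(int)

    def assign_bands(self, X: pd.DataFrame, batch=None) -> np.ndarray:
        p = self.predict_proba(X, batch=batch)[:, 1]
        return stratify.assign_band(p, self.thresholds_)
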