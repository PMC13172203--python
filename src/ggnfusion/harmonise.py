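"""Parametric empirical-Bayes ComBat batch correction with a strictly
fold-safe fit/apply protocol.

The estimator follows the classical location/scale model: each feature is
standardised against a design of batch indicators plus optional protected
covariates (by default the outcome label, so harmonisation does not strip
class signal), per-batch location and scale are estimated on the
standardised residuals, and both are shrunk towards their across-feature
priors with the usual normal / inverse-gamma parametric EB iteration.

Rows from batches never seen at fit time are passed through unchanged and
flagged, so no extrapolative adjustment is ever applied to external data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["CombatParams", "ComBatHarmonizer", "fit_combat", "apply_combat"]

logger = logging.getLogger(__name__)


@dataclass
class CombatParams:
    """Fitted ComBat parameters (JSON-serialisable for audit)."""

    feature_names: list[str]
    batch_ids: list
    alpha: np.ndarray                 # per-feature grand mean
    beta: np.ndarray                  # covariate effects, shape (n_cov, n_feat)
    sigma2: np.ndarray                # pooled residual variance per feature
    gamma_star: dict = field(default_factory=dict)   # batch -> location (n_feat,)
    delta_star: dict = field(default_factory=dict)   # batch -> scale^2 (n_feat,)
    dropped_features: list[str] = field(default_factory=list)
    identity: bool = False

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "batch_ids": [str(b) for b in self.batch_ids],
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "sigma2": self.sigma2.tolist(),
            "gamma_star": {str(k): v.tolist() for k, v in self.gamma_star.items()},
            "delta_star": {str(k): v.tolist() for k, v in self.delta_star.items()},
            "dropped_features": self.dropped_features,
            "identity": self.identity,
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _eb_iterate(gamma_hat, delta_hat, n_b, tol=1e-6, max_iter=200):
    """Parametric EB shrinkage of one batch's location/scale estimates."""
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1) if gamma_hat.size > 1 else 1.0
    if tau2 <= 0:
        tau2 = 1e-12
    # inverse-gamma prior moments for delta^2
    m = delta_hat.mean()
    v = delta_hat.var(ddof=1) if delta_hat.size > 1 else 1.0
    lam = (m**2 + 2 * v) / v if v > 0 else 2.0 + 1e3
    theta = (m**3 + m * v) / v if v > 0 else m * (lam - 1.0)
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n_b * tau2 * gamma_hat + delta_star * gamma_bar) / (n_b * tau2 + delta_star)
        ssq = delta_hat * n_b + n_b * (gamma_hat - g_new) ** 2
        d_new = (theta + 0.5 * ssq) / (n_b / 2.0 + lam - 1.0)
        d_new = np.clip(d_new, 1e-12, None)
        change = max(np.abs(g_new - gamma_star).max(), np.abs(d_new - delta_star).max())
        gamma_star, delta_star = g_new, d_new
        if change < tol:
            break
    return gamma_star, delta_star


class ComBatHarmonizer(BaseEstimator, TransformerMixin):
    """Fold-safe parametric ComBat.

    Parameters
    ----------
    protect_label : bool
        Include the outcome as a protected covariate in the standardisation
        design (default True) so class-associated variation is preserved.
    parametric : bool
        Parametric EB shrinkage (the only implemented variant).

    Attributes
    ----------
    params_ : CombatParams
        Fitted standardisation and per-batch adjustment parameters.
    unharmonised_mask_ : ndarray of bool
        After :meth:`transform`, marks rows passed through because their
        batch was not seen at fit time.
    """

    def __init__(self, protect_label: bool = True, parametric: bool = True):
        self.protect_label = protect_label
        self.parametric = parametric

    def fit(self, X, y=None, *, batch):
        X = pd.DataFrame(X).copy()
        batch = np.asarray(batch)
        if len(batch) != len(X):
            raise ValueError("batch length mismatch")
        feature_names = list(X.columns)
        # drop zero-variance features from adjustment
        variances = X.var(axis=0, ddof=0).to_numpy()
        dropped = [f for f, v in zip(feature_names, variances) if not v > 0]
        if dropped:
            logger.info("ComBat: dropping zero-variance features: %s", dropped)
        keep = [f for f in feature_names if f not in set(dropped)]
        batches = list(pd.unique(batch))
        if len(batches) < 2:
            warnings.warn("single batch at fit time: ComBat is the identity",
                          RuntimeWarning, stacklevel=2)
            self.params_ = CombatParams(
                feature_names=feature_names, batch_ids=batches,
                alpha=np.zeros(0), beta=np.zeros((0, 0)), sigma2=np.zeros(0),
                dropped_features=dropped, identity=True)
            return self
        counts = pd.Series(batch).value_counts()
        if (counts < 3).any():
            raise ValueError("every batch needs >= 3 rows")

        Z = X[keep].to_numpy(dtype=float)
        n, p = Z.shape
        n_batches = len(batches)
        B = np.zeros((n, n_batches))
        for j, b in enumerate(batches):
            B[:, j] = batch == b
        covs = []
        if self.protect_label and y is not None:
            covs.append(np.asarray(y, dtype=float).reshape(-1, 1))
        C = np.hstack(covs) if covs else np.zeros((n, 0))
        design = np.hstack([B, C])
        # OLS per feature (shared design)
        coef, *_ = np.linalg.lstsq(design, Z, rcond=None)
        batch_effects = coef[:n_batches, :]
        beta = coef[n_batches:, :]
        weights = counts.reindex(batches).to_numpy(dtype=float) / n
        alpha = weights @ batch_effects
        stand_mean = alpha[None, :] + C @ beta
        resid = Z - design @ coef
        sigma2 = (resid**2).mean(axis=0)
        sigma2 = np.clip(sigma2, 1e-12, None)
        # per-batch naive estimates on standardised data, then EB shrinkage
        Zb = (Z - stand_mean) / np.sqrt(sigma2)
        gamma_star, delta_star = {}, {}
        for j, b in enumerate(batches):
            rows = batch == b
            gamma_hat = Zb[rows].mean(axis=0)
            delta_hat = Zb[rows].var(axis=0, ddof=1)
            delta_hat = np.clip(delta_hat, 1e-12, None)
            if self.parametric and p > 1:
                g, d = _eb_iterate(gamma_hat, delta_hat, float(rows.sum()))
            else:
                g, d = gamma_hat, delta_hat
            gamma_star[b] = g
            delta_star[b] = d
        self.params_ = CombatParams(
            feature_names=feature_names, batch_ids=batches,
            alpha=alpha, beta=beta, sigma2=sigma2,
            gamma_star=gamma_star, delta_star=delta_star,
            dropped_features=dropped, identity=False)
        self._kept = keep
        self._y_mean = float(np.mean(y)) if (self.protect_label and y is not None) else None
        return self

    def transform(self, X, *, batch, y=None):
        if not hasattr(self, "params_"):
            raise AttributeError("not fitted")
        X = pd.DataFrame(X).copy()
        batch = np.asarray(batch)
        if list(X.columns) != self.params_.feature_names:
            raise ValueError("feature columns differ from fit time")
        if self.params_.identity:
            self.unharmonised_mask_ = np.zeros(len(X), dtype=bool)
            return X
        keep = self._kept
        Z = X[keep].to_numpy(dtype=float)
        seen = np.isin(batch, self.params_.batch_ids)
        self.unharmonised_mask_ = ~seen
        if self.unharmonised_mask_.any():
            logger.info("ComBat: %d rows from unseen batches passed through "
                        "unharmonised", int(self.unharmonised_mask_.sum()))
        beta = self.params_.beta
        if beta.shape[0] > 0:
            # protected covariate unknown at apply time -> use fit-time mean
            c = (np.asarray(y, dtype=float).reshape(-1, 1) if y is not None
                 else np.full((len(X), 1), self._y_mean))
            cov_term = c @ beta
        else:
            cov_term = 0.0
        stand_mean = self.params_.alpha[None, :] + cov_term
        sd = np.sqrt(self.params_.sigma2)
        out = Z.copy()
        for b in self.params_.batch_ids:
            rows = batch == b
            if not rows.any():
                continue
            Zb = (Z[rows] - (stand_mean[rows] if beta.shape[0] > 0 else stand_mean[0])) / sd
            adj = (Zb - self.params_.gamma_star[b]) / np.sqrt(self.params_.delta_star[b])
            out[rows] = adj * sd + (stand_mean[rows] if beta.shape[0] > 0 else stand_mean[0])
        X.loc[:, keep] = out
        return X


def fit_combat(features: pd.DataFrame, batch, covariates=None,
               protect_label: bool = True) -> ComBatHarmonizer:
    """Fit ComBat on a feature table; ``covariates`` is the optional
    protected outcome indicator."""
    est = ComBatHarmonizer(protect_label=protect_label and covariates is not None)
    est.fit(features, y=covariates, batch=batch)
    return est


def apply_combat(harmonizer: ComBatHarmonizer, features: pd.DataFrame, batch,
                 covariates=None) -> tuple[pd.DataFrame, np.ndarray]:
    """Apply fitted params; returns (adjusted table, unharmonised row flags).

    Rows of batches unseen at fit time are bit-identical pass-throughs."""
    out = harmonizer.transform(features, batch=batch, y=covariates)
    return out, harmonizer.unharmonised_mask_.copy()
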