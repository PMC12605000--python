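"""Parametric empirical-Bayes ComBat harmonization of feature tables.

Removes per-batch (scanner) location and scale effects from radiomic
features under the standard location-scale model

    x_fg = alpha_f + X beta_f + gamma_fg + delta_fg * eps,

with empirical-Bayes shrinkage of the per-batch location gamma and scale
delta across features (normal prior for gamma, inverse-gamma for delta).
Biological covariates (e.g. the class label) supplied at fit time are
estimated jointly and preserved by the adjustment.  The model is fitted on
training rows only and can be applied to held-out rows, which keeps
validation data out of every harmonization estimate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class HarmonizationModel:
    """Fitted ComBat model (or an identity pass-through)."""

    features: list[str]
    batches: list[str]
    alpha: np.ndarray  # (p,) grand effects
    beta: np.ndarray  # (c, p) covariate effects
    covariates: list[str]
    cov_means: np.ndarray  # (c,) training means used to center covariates
    pooled_sd: np.ndarray  # (p,)
    gamma_star: np.ndarray  # (b, p)
    delta_star: np.ndarray  # (b, p), > 0
    identity: bool = False
    constant_features: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": self.features,
                "batches": self.batches,
                "alpha": self.alpha.tolist(),
                "beta": self.beta.tolist(),
                "covariates": self.covariates,
                "cov_means": self.cov_means.tolist(),
                "pooled_sd": self.pooled_sd.tolist(),
                "gamma_star": self.gamma_star.tolist(),
                "delta_star": self.delta_star.tolist(),
                "identity": self.identity,
                "constant_features": self.constant_features,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "HarmonizationModel":
        d = json.loads(s)
        return cls(
            features=d["features"],
            batches=d["batches"],
            alpha=np.asarray(d["alpha"]),
            beta=np.asarray(d["beta"]),
            covariates=d["covariates"],
            cov_means=np.asarray(d["cov_means"]),
            pooled_sd=np.asarray(d["pooled_sd"]),
            gamma_star=np.asarray(d["gamma_star"]),
            delta_star=np.asarray(d["delta_star"]),
            identity=d["identity"],
            constant_features=d.get("constant_features", []),
        )


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a_prior, b_prior):
    return (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)


def fit_combat(
    table: pd.DataFrame,
    batch_col: str = "batch",
    covariates: list[str] | None = None,
    feature_cols: list[str] | None = None,
) -> HarmonizationModel:
    """Fit parametric empirical-Bayes ComBat on a feature table.

    ``covariates`` are column names of numeric biological covariates whose
    effects must survive harmonization (the binary label is the typical
    one).  Zero-variance features are passed through untouched; a single
    batch yields an identity model with a warning.
    """
    covariates = list(covariates or [])
    if feature_cols is None:
        from habitatrad.texture_features import feature_columns

        feature_cols = feature_columns(table)
        feature_cols = [c for c in feature_cols if c not in covariates]
    batches = sorted(table[batch_col].astype(str).unique())
    X = table[feature_cols].to_numpy(dtype=float)
    n, p = X.shape

    const = [f for f, sd in zip(feature_cols, X.std(axis=0)) if sd == 0]
    if len(batches) < 2:
        warnings.warn("single batch: harmonization is the identity")
        return HarmonizationModel(
            features=feature_cols,
            batches=batches,
            alpha=np.zeros(p),
            beta=np.zeros((len(covariates), p)),
            covariates=covariates,
            cov_means=np.zeros(len(covariates)),
            pooled_sd=np.ones(p),
            gamma_star=np.zeros((1, p)),
            delta_star=np.ones((1, p)),
            identity=True,
            constant_features=const,
        )

    batch_idx = np.array([batches.index(str(b)) for b in table[batch_col]])
    counts = np.bincount(batch_idx, minlength=len(batches))
    if counts.min() < 3:
        raise ValueError("every batch needs >= 3 rows to fit ComBat")

    # design: batch one-hot + covariates (no global intercept; the grand
    # effect alpha is the sample-size-weighted mean of the batch effects)
    B = np.eye(len(batches))[batch_idx]
    C = table[covariates].to_numpy(dtype=float) if covariates else np.empty((n, 0))
    cov_means = C.mean(axis=0) if C.shape[1] else np.zeros(0)
    if C.shape[1]:
        C = C - cov_means  # centered so batch effects absorb the mean
    design = np.hstack([B, C])
    if C.shape[1] and np.linalg.matrix_rank(design) < design.shape[1]:
        # batch and covariates are confounded: the split is unidentifiable,
        # so attribute the shared component to the biology (covariates
        # first, batch on the residuals) rather than remove it
        warnings.warn(
            "covariates are confounded with batch; attributing the shared "
            "variation to the covariates to protect the biological effect"
        )
        beta, *_ = np.linalg.lstsq(C, X, rcond=None)
        batch_effects, *_ = np.linalg.lstsq(B, X - C @ beta, rcond=None)
        coef = np.vstack([batch_effects, beta])
    else:
        coef, *_ = np.linalg.lstsq(design, X, rcond=None)
        batch_effects = coef[: len(batches)]  # (b, p)
        beta = coef[len(batches):]  # (c, p)
    alpha = (counts / n) @ batch_effects

    resid = X - design @ coef
    pooled_var = (resid**2).sum(axis=0) / n
    pooled_sd = np.sqrt(pooled_var)
    ok = pooled_sd > 0
    safe_sd = np.where(ok, pooled_sd, 1.0)

    # standardized data: remove grand effect and covariates, keep batch shifts
    Z = (X - alpha - C @ beta) / safe_sd

    nb = len(batches)
    gamma_hat = np.zeros((nb, p))
    delta_hat = np.ones((nb, p))
    for b in range(nb):
        rows = Z[batch_idx == b]
        gamma_hat[b] = rows.mean(axis=0)
        delta_hat[b] = rows.var(axis=0, ddof=1)

    gamma_star = np.zeros((nb, p))
    delta_star = np.ones((nb, p))
    for b in range(nb):
        g = gamma_hat[b]
        d = delta_hat[b]
        g_bar, t2 = g.mean(), g.var()
        # inverse-gamma prior on delta^2 by method of moments
        v, s2 = d.mean(), d.var()
        a_prior = (2.0 * s2 + v**2) / s2 if s2 > 0 else 2.0
        b_prior = (v * s2 + v**3) / s2 if s2 > 0 else v
        nb_rows = counts[b]
        rows = Z[batch_idx == b]
        g_new, d_new = g.copy(), d.copy()
        if t2 > 0:
            for _ in range(100):  # iterative EB solution
                g_old, d_old = g_new.copy(), d_new.copy()
                g_new = _postmean(g, g_bar, nb_rows, d_new, t2)
                sum2 = ((rows - g_new) ** 2).sum(axis=0)
                d_new = _postvar(sum2, nb_rows, a_prior, b_prior)
                if (
                    np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)) < 1e-6
                    and np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)) < 1e-6
                ):
                    break
        gamma_star[b] = g_new
        delta_star[b] = np.maximum(d_new, 1e-12)

    # constant features: force identity adjustment
    gamma_star[:, ~ok] = 0.0
    delta_star[:, ~ok] = 1.0

    return HarmonizationModel(
        features=feature_cols,
        batches=batches,
        alpha=alpha,
        beta=beta,
        covariates=covariates,
        cov_means=cov_means,
        pooled_sd=safe_sd,
        gamma_star=gamma_star,
        delta_star=delta_star,
        constant_features=const,
        diagnostics={"batch_counts": {b: int(c) for b, c in zip(batches, counts)}},
    )


def apply_combat(model: HarmonizationModel, table: pd.DataFrame, batch_col: str = "batch") -> pd.DataFrame:
    """Apply a fitted model; unknown batch ids raise (no silent pass-through).

    Returns a table of identical shape with adjusted feature values; all
    non-feature columns and the row index are untouched.
    """
    if table.empty:
        return table.copy()
    missing = [f for f in model.features if f not in table.columns]
    if missing:
        raise ValueError(f"table lacks model features: {missing[:5]}...")
    out = table.copy()
    if model.identity:
        return out
    unknown = set(table[batch_col].astype(str)) - set(model.batches)
    if unknown:
        raise ValueError(f"unknown batch ids: {sorted(unknown)}")
    X = table[model.features].to_numpy(dtype=float)
    bidx = np.array([model.batches.index(str(b)) for b in table[batch_col]])
    C = table[model.covariates].to_numpy(dtype=float) if model.covariates else np.empty((len(table), 0))
    if C.shape[1]:
        C = C - model.cov_means
    bio = model.alpha + C @ model.beta
    Z = (X - bio) / model.pooled_sd
    Zadj = (Z - model.gamma_star[bidx]) / np.sqrt(model.delta_star[bidx])
    out.loc[:, model.features] = Zadj * model.pooled_sd + bio
    for f in model.constant_features:  # exact pass-through, no float churn
        out[f] = table[f]
    return out
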