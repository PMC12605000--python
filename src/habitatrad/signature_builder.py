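"""Leakage-safe signature construction: U-test screen -> LASSO -> fusion.

Feature selection runs strictly inside the training rows (and, in nested
cross-validation, inside each outer-training fold): a two-sided
Mann-Whitney U screen at alpha = 0.05 followed by L1-penalized logistic
regression whose penalty is chosen by inner five-fold cross-validated
binomial deviance ("lambda.min").  The radiomics signature (RS) is the
weighted linear combination of the selected standardized features; a
logistic layer maps RS to a probability and the training Youden cutoff is
stored with the model.  The multi-sequence regional fusion model is a
two-input logistic regression on the parent RS scores of the best
subregion in each sequence.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from habitatrad.model_evaluation import roc_auc, youden_cutoff

logger = logging.getLogger("habitatrad")

SCREEN_ALPHA = 0.05


@dataclass
class SelectionResult:
    """Screening statistics and the LASSO path outcome for one fit."""

    screen: pd.DataFrame  # feature, U, p, retained
    screened_features: list[str]
    lambda_grid: np.ndarray | None = None
    cv_deviance: np.ndarray | None = None
    chosen_lambda: float | None = None
    coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    fold: str | int | None = None

    @property
    def selected_features(self) -> list[str]:
        return [f for f, b in self.coefficients.items() if b != 0.0]


def mann_whitney_screen(
    table: pd.DataFrame,
    label_col: str = "label",
    feature_cols: list[str] | None = None,
    alpha: float = SCREEN_ALPHA,
    fdr: bool = False,
) -> SelectionResult:
    """Two-sided Mann-Whitney U test per feature; retain p < alpha.

    Constant features get p = 1 and are dropped.  An optional
    Benjamini-Hochberg switch exists (default off, matching the plain
    p < 0.05 screen).
    """
    if feature_cols is None:
        from habitatrad.texture_features import feature_columns

        feature_cols = feature_columns(table)
    y = table[label_col].astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    recs = []
    for f in feature_cols:
        x = table[f].to_numpy(dtype=float)
        if np.std(x) == 0:
            recs.append({"feature": f, "U": np.nan, "p": 1.0})
            continue
        res = stats.mannwhitneyu(x[y == 1], x[y == 0], alternative="two-sided")
        recs.append({"feature": f, "U": float(res.statistic), "p": float(res.pvalue)})
    screen = pd.DataFrame(recs)
    pvals = screen["p"].to_numpy()
    if fdr:
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        padj = np.empty_like(pvals)
        padj[order] = np.minimum(adj, 1.0)
        screen["p_adj"] = padj
        screen["retained"] = screen["p_adj"] < alpha
    else:
        screen["retained"] = screen["p"] < alpha
    retained = screen.loc[screen["retained"], "feature"].tolist()
    return SelectionResult(screen=screen, screened_features=retained)


@dataclass
class _Scaler:
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _fit_scaler(X: np.ndarray) -> _Scaler:
    sd = X.std(axis=0)
    return _Scaler(X.mean(axis=0), np.where(sd > 0, sd, 1.0))


def _lasso_path_fit(Xs: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # sklearn minimizes ||w||_1 / C + sum losses; lam is the per-sample
    # penalty, so C = 1 / (n * lam)
    C = 1.0 / (len(y) * lam)
    # liblinear penalizes the intercept; a large intercept_scaling makes
    # that negligible, matching the glmnet convention of an unpenalized
    # intercept (verified against a proximal-gradient solver in the tests)
    lr = LogisticRegression(
        C=C, solver="liblinear", l1_ratio=1.0, intercept_scaling=100.0,
        max_iter=5000, tol=1e-10, random_state=0,
    )
    lr.fit(Xs, y)
    return lr


def _deviance(model: LogisticRegression, Xs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(model.predict_proba(Xs)[:, 1], 1e-12, 1 - 1e-12)
    return float(-2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def lasso_select(
    table: pd.DataFrame,
    feature_cols: list[str],
    label_col: str = "label",
    lambda_grid: np.ndarray | None = None,
    inner_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """L1-penalized logistic selection with inner-CV choice of lambda.

    The grid spans [lambda_max * 1e-3, lambda_max] log-uniformly (50
    points), lambda_max being the smallest penalty that zeroes every
    coefficient.  lambda is chosen to minimize mean inner-fold binomial
    deviance; the model is refit on all supplied rows at that lambda.
    """
    if len(feature_cols) < 2:
        raise ValueError("need >= 2 screened features")
    if len(table) < 10:
        raise ValueError("need >= 10 rows")
    y = table[label_col].astype(int).to_numpy()
    X = table[feature_cols].to_numpy(dtype=float)
    scaler = _fit_scaler(X)
    Xs = scaler.transform(X)

    if lambda_grid is None:
        ybar = y.mean()
        lam_max = np.abs(Xs.T @ (y - ybar)).max() / len(y)
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-3, 50)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    dev = np.zeros((len(lambda_grid), inner_folds))
    for k, (tr, va) in enumerate(skf.split(Xs, y)):
        for i, lam in enumerate(lambda_grid):
            m = _lasso_path_fit(Xs[tr], y[tr], lam)
            dev[i, k] = _deviance(m, Xs[va], y[va])
    mean_dev = dev.mean(axis=1)
    best = int(np.argmin(mean_dev))
    lam_star = float(lambda_grid[best])

    final = _lasso_path_fit(Xs, y, lam_star)
    coefs = dict(zip(feature_cols, final.coef_[0]))
    nonzero = {f: float(b) for f, b in coefs.items() if b != 0.0}
    if not nonzero:
        raise ValueError(
            "empty signature: no feature survives at the chosen penalty "
            f"(lambda={lam_star:.4g}, min deviance {mean_dev[best]:.3f})"
        )
    return SelectionResult(
        screen=pd.DataFrame({"feature": feature_cols}),
        screened_features=list(feature_cols),
        lambda_grid=lambda_grid,
        cv_deviance=mean_dev,
        chosen_lambda=lam_star,
        coefficients={f: float(b) for f, b in coefs.items()},
        intercept=float(final.intercept_[0]),
    )


@dataclass
class SignatureModel:
    """Radiomics signature: RS(x) = sum_f w_f z_f + b on standardized
    features, plus a logistic layer mapping RS to probability."""

    region: str
    sequence: str
    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    logit_coef: float = 1.0
    logit_intercept: float = 0.0
    training_cutoff: float | None = None
    training_auc: float | None = None
    separation_flag: bool = False
    training_rows: list | None = None

    def score(self, table: pd.DataFrame) -> np.ndarray:
        """Deterministic RS per row."""
        X = table[self.feature_names].to_numpy(dtype=float)
        Z = (X - self.feature_means) / self.feature_sds
        return Z @ self.weights + self.intercept

    def margin(self, table: pd.DataFrame) -> np.ndarray:
        return self.logit_intercept + self.logit_coef * self.score(table)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.margin(table)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "region": self.region,
                "sequence": self.sequence,
                "feature_names": self.feature_names,
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "feature_means": self.feature_means.tolist(),
                "feature_sds": self.feature_sds.tolist(),
                "logit_coef": self.logit_coef,
                "logit_intercept": self.logit_intercept,
                "training_cutoff": self.training_cutoff,
                "training_auc": self.training_auc,
                "separation_flag": self.separation_flag,
                "training_rows": self.training_rows,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "SignatureModel":
        d = json.loads(s)
        d["weights"] = np.asarray(d["weights"], dtype=float)
        d["feature_means"] = np.asarray(d["feature_means"], dtype=float)
        d["feature_sds"] = np.asarray(d["feature_sds"], dtype=float)
        return cls(**d)


def build_signature(
    selection: SelectionResult,
    table: pd.DataFrame,
    region: str,
    sequence: str,
    label_col: str = "label",
) -> SignatureModel:
    """Turn a LASSO selection into a deployable signature on given rows.

    RS weights are the (nonzero) LASSO coefficients on train-standardized
    features; a 1-D unpenalized logistic layer maps RS to probability and
    the training Youden cutoff is stored.  Perfect separation is flagged
    but the model is still emitted.
    """
    feats = selection.selected_features
    if not feats:
        raise ValueError("empty selection")
    y = table[label_col].astype(int).to_numpy()
    X = table[feats].to_numpy(dtype=float)
    scaler = _fit_scaler(X)
    w = np.array([selection.coefficients[f] for f in feats])
    rs = scaler.transform(X) @ w + selection.intercept

    sep = False
    if len(np.unique(y)) == 2:
        lo1, hi0 = rs[y == 1].min(), rs[y == 0].max()
        sep = bool(lo1 > hi0 or rs[y == 0].min() > rs[y == 1].max())
    if sep:
        warnings.warn(f"perfect separation in {sequence}/{region} training RS")
    lr = LogisticRegression(penalty="l2", C=1e6, max_iter=5000)
    lr.fit(rs[:, None], y)
    probs = lr.predict_proba(rs[:, None])[:, 1]
    cut = youden_cutoff(probs, y)["cutoff"]
    return SignatureModel(
        region=region,
        sequence=sequence,
        feature_names=feats,
        weights=w,
        intercept=selection.intercept,
        feature_means=scaler.mean,
        feature_sds=scaler.sd,
        logit_coef=float(lr.coef_[0, 0]),
        logit_intercept=float(lr.intercept_[0]),
        training_cutoff=float(cut),
        training_auc=float(roc_auc(rs, y, ci=False)["auc"]),
        separation_flag=sep,
        training_rows=sorted(table["patient_id"].tolist()) if "patient_id" in table else None,
    )


@dataclass
class FusionModel:
    """Logistic model on two parent RS scores (2 inputs + intercept)."""

    parents: tuple[SignatureModel, SignatureModel]
    coef: np.ndarray  # (2,)
    intercept: float
    training_cutoff: float | None = None
    training_auc: float | None = None

    region: str = "fusion"
    sequence: str = "fusion"

    def parent_scores(self, table: pd.DataFrame) -> np.ndarray:
        return np.column_stack([p.score(table) for p in self.parents])

    def margin(self, table: pd.DataFrame) -> np.ndarray:
        return self.parent_scores(table) @ self.coef + self.intercept

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.margin(table)))

    @property
    def feature_names(self) -> list[str]:
        return sorted(set(self.parents[0].feature_names) | set(self.parents[1].feature_names))

    def flat_weights(self) -> tuple[dict[str, float], float]:
        """Fusion margin as an exactly linear function of the underlying
        standardized-feature values (chain rule through both parents)."""
        w: dict[str, float] = {}
        b = self.intercept
        for c, parent in zip(self.coef, self.parents):
            b += c * parent.intercept
            for f, pw, mu, sd in zip(
                parent.feature_names, parent.weights, parent.feature_means, parent.feature_sds
            ):
                key = f"{parent.sequence}|{parent.region}|{f}"
                w[key] = w.get(key, 0.0) + float(c * pw / sd)
                b -= float(c * pw * mu / sd)
        return w, float(b)


def build_fusion(
    sig_a: SignatureModel,
    sig_b: SignatureModel,
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    labels: np.ndarray,
) -> FusionModel:
    """Fuse two single-sequence signatures into one logistic model.

    Both parents must have been fitted on identical training rows; a tiny
    L2 penalty keeps the 2-input logistic solvable when the parent scores
    are collinear.
    """
    if sig_a.training_rows is not None and sig_b.training_rows is not None:
        if sig_a.training_rows != sig_b.training_rows:
            raise ValueError("fusion parents were fitted on different training rows")
    if len(table_a) != len(table_b):
        raise ValueError("parent feature tables have different row counts")
    y = np.asarray(labels).astype(int)
    S = np.column_stack([sig_a.score(table_a), sig_b.score(table_b)])
    lr = LogisticRegression(penalty="l2", C=1e6, max_iter=5000)
    lr.fit(S, y)
    probs = lr.predict_proba(S)[:, 1]
    cut = youden_cutoff(probs, y)["cutoff"]
    fm = FusionModel(
        parents=(sig_a, sig_b),
        coef=lr.coef_[0].astype(float),
        intercept=float(lr.intercept_[0]),
        training_cutoff=float(cut),
        training_auc=float(roc_auc(probs, y, ci=False)["auc"]),
    )
    return fm


@dataclass
class NestedCVResult:
    fold_selections: list[SelectionResult]
    fold_models: list[SignatureModel]
    outer_predictions: pd.DataFrame  # patient_id, fold, prob, label
    outer_auc: float
    final_selection: SelectionResult
    final_model: SignatureModel


def run_nested_cv(
    table: pd.DataFrame,
    region: str,
    sequence: str,
    label_col: str = "label",
    feature_cols: list[str] | None = None,
    outer_folds: int = 5,
    inner_folds: int = 5,
    alpha: float = SCREEN_ALPHA,
    seed: int = 0,
) -> NestedCVResult:
    """Nested stratified CV: screening + LASSO per outer-training fold.

    Outer-fold predictions are pooled for an honest performance estimate;
    the deployable model is refit on the full training table.  No held-out
    fold's rows enter screening, standardization, or the lambda choice.
    """
    if feature_cols is None:
        from habitatrad.texture_features import feature_columns

        feature_cols = feature_columns(table)
    y = table[label_col].astype(int).to_numpy()
    if y.sum() < outer_folds or (1 - y).sum() < outer_folds:
        raise ValueError("need >= outer_folds rows per class for stratification")
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    fold_sel, fold_models, preds = [], [], []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        sub = table.iloc[tr]
        screen = mann_whitney_screen(sub, label_col, feature_cols, alpha=alpha)
        if len(screen.screened_features) < 2:
            raise ValueError(f"fold {fold}: fewer than 2 features pass the U-test screen")
        sel = lasso_select(sub, screen.screened_features, label_col, inner_folds=inner_folds, seed=seed)
        sel.fold = fold
        sel.screen = screen.screen
        model = build_signature(sel, sub, region, sequence, label_col)
        fold_sel.append(sel)
        fold_models.append(model)
        te_rows = table.iloc[te]
        preds.append(
            pd.DataFrame(
                {
                    "patient_id": te_rows["patient_id"].to_numpy()
                    if "patient_id" in te_rows
                    else te,
                    "fold": fold,
                    "prob": model.predict_proba(te_rows),
                    "label": y[te],
                }
            )
        )
    outer = pd.concat(preds, ignore_index=True)
    outer_auc = roc_auc(outer["prob"], outer["label"], ci=False)["auc"]

    screen = mann_whitney_screen(table, label_col, feature_cols, alpha=alpha)
    final_sel = lasso_select(
        table, screen.screened_features, label_col, inner_folds=inner_folds, seed=seed
    )
    final_sel.screen = screen.screen
    final_model = build_signature(final_sel, table, region, sequence, label_col)
    return NestedCVResult(
        fold_selections=fold_sel,
        fold_models=fold_models,
        outer_predictions=outer,
        outer_auc=float(outer_auc),
        final_selection=final_sel,
        final_model=final_model,
    )
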