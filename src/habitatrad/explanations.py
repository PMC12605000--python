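"""Exact Shapley attributions for linear signature/fusion models.

For a model whose margin is linear in its features, the Shapley value of
feature f at input x with mean-imputed absent features is exactly

    phi_f(x) = w_f * (x_f - mean_background(x_f)),

with base value equal to the margin at the background means, so local
accuracy (sum phi + base = margin) holds to machine precision.
Attributions are reported on the margin (logit) scale with the training
split as background.  For the fusion model the margin is linear in the
underlying features as well (the chain rule through both linear parents is
exact), so a feature-level report needs no approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import spearmanr


@dataclass
class ShapReport:
    """Per-patient, per-feature attributions on the margin scale."""

    feature_names: list[str]
    phi: np.ndarray  # (n_patients, n_features)
    base_value: float
    margins: np.ndarray  # (n_patients,)
    feature_values: np.ndarray  # raw feature values, same shape as phi
    patient_ids: list = field(default_factory=list)

    @property
    def mean_abs_phi(self) -> pd.Series:
        return pd.Series(np.abs(self.phi).mean(axis=0), index=self.feature_names).sort_values(
            ascending=False
        )

    def local_accuracy_error(self) -> float:
        return float(np.abs(self.phi.sum(axis=1) + self.base_value - self.margins).max())


def linear_shap(
    weights: dict[str, float] | np.ndarray,
    intercept: float,
    table: pd.DataFrame,
    background: pd.DataFrame,
    feature_names: list[str] | None = None,
) -> ShapReport:
    """Exact Shapley attributions for a linear margin model.

    ``weights`` maps feature name -> weight (or an array aligned with
    ``feature_names``); ``background`` supplies the reference distribution
    (typically the training rows).  Every feature must be present in both
    tables.
    """
    if isinstance(weights, dict):
        feature_names = list(weights.keys())
        w = np.array([weights[f] for f in feature_names], dtype=float)
    else:
        if feature_names is None:
            raise ValueError("feature_names required with array weights")
        w = np.asarray(weights, dtype=float)
    missing = [f for f in feature_names if f not in table.columns]
    if missing:
        raise ValueError(f"features missing from table: {missing}")
    if background.empty:
        raise ValueError("background must be nonempty")
    X = table[feature_names].to_numpy(dtype=float)
    bg_mean = background[feature_names].to_numpy(dtype=float).mean(axis=0)
    phi = w * (X - bg_mean)
    base = float(w @ bg_mean + intercept)
    margins = X @ w + intercept
    pids = table["patient_id"].tolist() if "patient_id" in table else list(range(len(table)))
    return ShapReport(
        feature_names=feature_names,
        phi=phi,
        base_value=base,
        margins=margins,
        feature_values=X,
        patient_ids=pids,
    )


def signature_shap(model, table: pd.DataFrame, background: pd.DataFrame) -> ShapReport:
    """Attributions for a SignatureModel on the RS margin scale.

    Works on standardized features internally, so phi is expressed per raw
    feature (weight / sd folds the standardization into the weight).
    """
    w = {
        f: float(model.logit_coef * wt / sd)
        for f, wt, sd in zip(model.feature_names, model.weights, model.feature_sds)
    }
    b = float(
        model.logit_intercept
        + model.logit_coef
        * (model.intercept - np.sum(model.weights * model.feature_means / model.feature_sds))
    )
    return linear_shap(w, b, table, background)


def fusion_shap(fusion, table: pd.DataFrame, background: pd.DataFrame) -> dict:
    """Two-level fusion report: phi over the two parent RS inputs, and
    chain-ruled phi over the underlying features (exact for linear parents)."""
    S = pd.DataFrame(
        fusion.parent_scores(table),
        columns=[f"RS-{p.sequence}-{p.region}" for p in fusion.parents],
    )
    S_bg = pd.DataFrame(fusion.parent_scores(background), columns=S.columns)
    if "patient_id" in table:
        S["patient_id"] = table["patient_id"].to_numpy()
    parent_report = linear_shap(
        dict(zip(S.columns[:2], fusion.coef)), fusion.intercept, S, S_bg
    )

    flat_w, flat_b = fusion.flat_weights()
    renamed = table.copy()
    renamed_bg = background.copy()
    for key in flat_w:
        _, _, feat = key.split("|", 2)
        renamed[key] = table[feat].to_numpy(dtype=float)
        renamed_bg[key] = background[feat].to_numpy(dtype=float)
    feature_report = linear_shap(flat_w, flat_b, renamed, renamed_bg)
    return {"parents": parent_report, "features": feature_report}


def shap_summaries(report: ShapReport, out_dir: str | Path) -> dict[str, Path]:
    """Write a mean-|phi| bar chart and a beeswarm plot; returns file paths."""
    if report.phi.size == 0:
        raise ValueError("empty report")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rank = report.mean_abs_phi

    fig, ax = plt.subplots(figsize=(7, 0.5 * len(rank) + 1.5))
    ax.barh(rank.index[::-1], rank.values[::-1], color="#d62728")
    ax.set_xlabel("mean |SHAP value| (margin scale)")
    fig.tight_layout()
    bar_path = out_dir / "shap_bar.png"
    fig.savefig(bar_path, dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 0.5 * len(rank) + 1.5))
    rng = np.random.default_rng(0)
    for row, f in enumerate(rank.index[::-1]):
        j = report.feature_names.index(f)
        vals = report.feature_values[:, j]
        rng_v = vals.max() - vals.min()
        color = (vals - vals.min()) / rng_v if rng_v > 0 else np.full(len(vals), 0.5)
        ax.scatter(
            report.phi[:, j],
            row + rng.uniform(-0.25, 0.25, len(vals)),
            c=color,
            cmap="coolwarm",
            s=14,
        )
    ax.set_yticks(range(len(rank)))
    ax.set_yticklabels(rank.index[::-1])
    ax.axvline(0, color="gray", lw=0.7)
    ax.set_xlabel("SHAP value (margin scale)")
    fig.tight_layout()
    bee_path = out_dir / "shap_beeswarm.png"
    fig.savefig(bee_path, dpi=110)
    plt.close(fig)
    return {"bar": bar_path, "beeswarm": bee_path}


def feature_heatmaps(
    table: pd.DataFrame,
    feature_names: list[str],
    labels=None,
    out_dir: str | Path | None = None,
) -> dict:
    """Spearman correlation heatmap + Ward-ordered patient x feature heatmap.

    Constant features are excluded with a warning.  Returns the correlation
    matrix, the dendrogram leaf orders, and any written file paths.
    """
    import warnings as _warnings

    feats = []
    for f in feature_names:
        if table[f].nunique() <= 1:
            _warnings.warn(f"constant feature {f!r} excluded from heatmaps")
        else:
            feats.append(f)
    if len(feats) < 2:
        raise ValueError("need >= 2 non-constant features")
    X = table[feats].to_numpy(dtype=float)
    corr, _ = spearmanr(X)
    if np.ndim(corr) == 0:  # spearmanr returns a scalar for 2 columns
        corr = np.array([[1.0, float(corr)], [float(corr), 1.0]])

    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    feat_order = leaves_list(linkage(Z.T, method="ward"))
    pat_order = leaves_list(linkage(Z, method="ward"))

    out: dict = {
        "correlation": pd.DataFrame(corr, index=feats, columns=feats),
        "feature_order": [feats[i] for i in feat_order],
        "patient_order": pat_order.tolist(),
        "files": {},
    }
    if out_dir is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(corr, cmap="coolwarm", vmin=-1, vmax=1)
        ax.set_xticks(range(len(feats)))
        ax.set_xticklabels(feats, rotation=90, fontsize=7)
        ax.set_yticks(range(len(feats)))
        ax.set_yticklabels(feats, fontsize=7)
        fig.colorbar(im)
        fig.tight_layout()
        p1 = out_dir / "feature_correlation.png"
        fig.savefig(p1, dpi=110)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(6, 7))
        M = Z[np.ix_(pat_order, feat_order)]
        im = ax.imshow(M, aspect="auto", cmap="coolwarm", vmin=-3, vmax=3)
        ax.set_xticks(range(len(feats)))
        ax.set_xticklabels([feats[i] for i in feat_order], rotation=90, fontsize=7)
        ax.set_ylabel("patients (Ward order)")
        fig.colorbar(im)
        fig.tight_layout()
        p2 = out_dir / "feature_cluster_heatmap.png"
        fig.savefig(p2, dpi=110)
        plt.close(fig)
        out["files"] = {"correlation": p1, "cluster": p2}
    return out
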