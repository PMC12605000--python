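"""Discrimination, calibration, clinical-utility and cohort statistics.

AUC is computed by the Mann-Whitney pair-counting identity (ties count
one half) with a DeLong-variance confidence interval; correlated AUCs are
compared with the DeLong test via placement values.  The operating cutoff
maximizes the Youden index J = SEN + SPE - 1 on the training split and is
frozen for validation splits.  Clinical utility uses decision-curve
analysis, NB(pt) = TP/N - (FP/N) pt/(1-pt), against treat-all/treat-none;
calibration uses quantile-binned observed-vs-predicted points plus a
logistic recalibration intercept and slope.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return y


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong machinery
# ---------------------------------------------------------------------------


def _placements(scores: np.ndarray, y: np.ndarray):
    """DeLong placement values.

    V10[i] for positive i: fraction of negatives scored below (ties half);
    V01[j] for negative j: fraction of positives scored above (ties half).
    """
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, s in enumerate(pos):
        v10[i] = ((s > neg).sum() + 0.5 * (s == neg).sum()) / n
    for j, s in enumerate(neg):
        v01[j] = ((pos > s).sum() + 0.5 * (pos == s).sum()) / m
    return v10, v01


def roc_auc(scores, labels, ci: bool = True, alpha: float = 0.05) -> dict:
    """AUC via pair counting (Mann-Whitney identity), DeLong-variance CI.

    Returns ``{"auc", "ci", "var", "n_pos", "n_neg"}``; requires both
    classes present.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    v10, v01 = _placements(s, y)
    auc = float(v10.mean())
    out = {"auc": auc, "n_pos": int(y.sum()), "n_neg": int((1 - y).sum())}
    if ci:
        m, n = len(v10), len(v01)
        var = (v10.var(ddof=1) / m if m > 1 else 0.0) + (v01.var(ddof=1) / n if n > 1 else 0.0)
        z = stats.norm.ppf(1 - alpha / 2)
        h = z * np.sqrt(var)
        out["var"] = float(var)
        out["ci"] = (float(max(0.0, auc - h)), float(min(1.0, auc + h)))
    return out


def delong_test(scores_a, scores_b, labels) -> dict:
    """DeLong comparison of two correlated AUCs on the same patients.

    Returns AUC difference (a - b), its variance, z and two-sided p.
    Identical score vectors give p = 1 with a degeneracy flag.
    """
    y = _check_binary(labels)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape[0] != y.shape[0]:
        raise ValueError("scores must be paired on identical patients")
    va10, va01 = _placements(sa, y)
    vb10, vb01 = _placements(sb, y)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = len(va10), len(va01)
    s10 = np.cov(np.stack([va10, vb10])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([va01, vb01])) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    diff = float(auc_a - auc_b)
    if var <= 0:
        return {"auc_a": float(auc_a), "auc_b": float(auc_b), "diff": diff,
                "var": float(max(var, 0.0)), "z": 0.0, "p": 1.0, "degenerate": True}
    z = diff / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b), "diff": diff,
            "var": float(var), "z": float(z), "p": float(p), "degenerate": False}


# ---------------------------------------------------------------------------
# operating point
# ---------------------------------------------------------------------------


def confusion_metrics(scores, labels, cutoff: float) -> dict:
    """ACC/SEN/SPE/PPV/NPV/F1 for the rule score >= cutoff -> positive."""
    y = _check_binary(labels)
    pred = (np.asarray(scores, dtype=float) >= cutoff).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sen = tp / (tp + fn) if tp + fn else np.nan
    spe = tn / (tn + fp) if tn + fp else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else np.nan
    return {
        "cutoff": float(cutoff), "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "acc": (tp + tn) / len(y), "sen": sen, "spe": spe,
        "ppv": ppv, "npv": npv, "f1": f1,
    }


def youden_cutoff(scores, labels) -> dict:
    """Cutoff maximizing J = SEN + SPE - 1 over midpoints of adjacent
    distinct scores (plus the extremes); ties break toward higher SPE."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    candidates = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    best = None
    for c in candidates:
        m = confusion_metrics(s, y, c)
        j = m["sen"] + m["spe"] - 1.0
        key = (round(j, 12), round(m["spe"], 12))
        if best is None or key > best[0]:
            best = (key, c, m, j)
    _, cutoff, metrics, j = best
    metrics = dict(metrics)
    metrics["youden_j"] = float(j)
    return metrics


# ---------------------------------------------------------------------------
# precision-recall
# ---------------------------------------------------------------------------


def auprc(scores, labels, n_boot: int = 0, seed: int = 0, alpha: float = 0.05) -> dict:
    """Step-interpolated area under the precision-recall curve.

    AP = sum_k (R_k - R_{k-1}) P_k over descending distinct score groups;
    optional percentile-bootstrap CI with ``n_boot`` resamples.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0:
        raise ValueError("need at least one positive")

    def _ap(s, y):
        order = np.argsort(-s, kind="mergesort")
        ys = y[order]
        ss = s[order]
        # group ties: cumulative counts at each distinct-score boundary
        boundary = np.r_[np.flatnonzero(np.diff(ss)), len(ss) - 1]
        tp = np.cumsum(ys)[boundary]
        npred = boundary + 1
        precision = tp / npred
        recall = tp / y.sum()
        prev_r = np.r_[0.0, recall[:-1]]
        return float(((recall - prev_r) * precision).sum())

    out = {"auprc": _ap(s, y), "n_pos": int(y.sum())}
    if n_boot:
        rng = np.random.default_rng(seed)
        reps = []
        n = len(y)
        while len(reps) < n_boot:
            idx = rng.integers(0, n, n)
            if y[idx].sum() == 0:
                continue
            reps.append(_ap(s[idx], y[idx]))
        lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        out["ci"] = (float(lo), float(hi))
    return out


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def calibration_curve(probs, labels, bins: int = 5) -> dict:
    """Quantile-binned calibration points plus logistic recalibration.

    The recalibration fits observed outcomes on logit(p); a calibrated
    model has slope ~ 1 and intercept ~ 0.
    """
    y = _check_binary(labels)
    p = np.asarray(probs, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probs must lie in [0, 1]")
    if len(np.unique(p)) < 2:
        if len(np.unique(p)) == 1:
            return {
                "bin_pred": [float(p[0])], "bin_obs": [float(y.mean())],
                "bin_count": [len(y)], "intercept": np.nan, "slope": np.nan,
            }
        raise ValueError("need at least 1 probability")
    q = pd.qcut(p, q=min(bins, len(np.unique(p))), duplicates="drop")
    df = pd.DataFrame({"p": p, "y": y, "bin": q})
    g = df.groupby("bin", observed=True)
    pts = g.agg(pred=("p", "mean"), obs=("y", "mean"), n=("y", "size")).reset_index(drop=True)

    eps = 1e-10
    logit = np.log(np.clip(p, eps, 1 - eps) / np.clip(1 - p, eps, 1 - eps))
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(penalty=None, max_iter=1000)
    try:
        lr.fit(logit[:, None], y)
        slope = float(lr.coef_[0, 0])
        intercept = float(lr.intercept_[0])
    except Exception:  # perfect separation etc.
        slope = intercept = np.nan
    return {
        "bin_pred": pts["pred"].tolist(),
        "bin_obs": pts["obs"].tolist(),
        "bin_count": pts["n"].tolist(),
        "intercept": intercept,
        "slope": slope,
    }


# ---------------------------------------------------------------------------
# decision curve analysis
# ---------------------------------------------------------------------------


def decision_curve(probs, labels, thresholds=None) -> pd.DataFrame:
    """Net benefit of the model, treat-all and treat-none per threshold.

    NB(pt) = TP/N - (FP/N) * pt/(1-pt) with the rule p >= pt; the default
    grid is 0.01..0.60 step 0.01 (pt = 1 is excluded by construction).
    """
    y = _check_binary(labels)
    p = np.asarray(probs, dtype=float)
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.605, 0.01), 4)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    N = len(y)
    prev = y.mean()
    rows = []
    for pt in thresholds:
        pred = p >= pt
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        w = pt / (1 - pt)
        rows.append(
            {
                "threshold": pt,
                "net_benefit": tp / N - fp / N * w,
                "treat_all": prev - (1 - prev) * w,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# waterfall
# ---------------------------------------------------------------------------


def waterfall(probs, labels, cutoff: float, patient_ids=None) -> dict:
    """Patients sorted by predicted probability (centered at the cutoff)
    with label colors and high-confidence misclassification counts."""
    y = _check_binary(labels)
    p = np.asarray(probs, dtype=float)
    if patient_ids is None:
        patient_ids = [f"P{i}" for i in range(len(y))]
    order = np.argsort(p, kind="mergesort")
    df = pd.DataFrame(
        {
            "patient_id": np.asarray(patient_ids)[order],
            "prob": p[order],
            "bar": p[order] - cutoff,
            "label": y[order],
            "predicted": (p[order] >= cutoff).astype(int),
        }
    )
    df["misclassified"] = df["label"] != df["predicted"]
    # high confidence: misclassified with |p - cutoff| in the top half of bars
    half = np.median(np.abs(df["bar"])) if len(df) else 0.0
    counts = {
        "misclassified": int(df["misclassified"].sum()),
        "high_confidence_misclassified": int(
            (df["misclassified"] & (df["bar"].abs() > half)).sum()
        ),
        "fp": int(((df["predicted"] == 1) & (df["label"] == 0)).sum()),
        "fn": int(((df["predicted"] == 0) & (df["label"] == 1)).sum()),
    }
    return {"table": df, "counts": counts, "cutoff": float(cutoff)}


# ---------------------------------------------------------------------------
# cohort baseline characteristics ("Table 1"-style summary)
# ---------------------------------------------------------------------------

CONTINUOUS_DEFAULT = ("age", "cea", "cyfra", "nse")
CATEGORICAL_DEFAULT = ("gender", "smoking", "ps_score")


def cohort_characteristics(
    clinical: pd.DataFrame,
    continuous=CONTINUOUS_DEFAULT,
    categorical=CATEGORICAL_DEFAULT,
    label_col: str = "label",
    split_col: str = "split",
) -> dict:
    """Per-split class comparison of clinical covariates.

    Continuous columns: mean +- SD per class with a two-sided Mann-Whitney
    U p-value.  Categorical columns: counts (%) per class with a chi-square
    p-value (Yates continuity correction on 2x2 tables); when any expected
    cell is below 1 a Fisher exact fallback is used and flagged.  Constant
    columns are dropped with a warning.
    """
    out: dict[str, dict] = {}
    for split, sub in clinical.groupby(split_col):
        y = sub[label_col].astype(int)
        if y.sum() < 2 or (1 - y).sum() < 2:
            raise ValueError(f"split {split!r} needs >= 2 patients per class")
        entry: dict[str, dict] = {}
        for col in continuous:
            x = sub[col].astype(float)
            if x.nunique() <= 1:
                warnings.warn(f"constant column {col!r} dropped in split {split!r}")
                continue
            a, b = x[y == 1], x[y == 0]
            entry[col] = {
                "type": "continuous",
                "pos_mean": float(a.mean()), "pos_sd": float(a.std(ddof=1)),
                "neg_mean": float(b.mean()), "neg_sd": float(b.std(ddof=1)),
                "p": float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue),
            }
        for col in categorical:
            x = sub[col]
            if x.nunique() <= 1:
                warnings.warn(f"constant column {col!r} dropped in split {split!r}")
                continue
            tab = pd.crosstab(x, y)
            counts = {
                str(level): {
                    "pos": int(tab.loc[level, 1]) if 1 in tab.columns else 0,
                    "neg": int(tab.loc[level, 0]) if 0 in tab.columns else 0,
                }
                for level in tab.index
            }
            obs = tab.to_numpy()
            chi2 = stats.chi2_contingency(obs, correction=(obs.shape == (2, 2)))
            exact_fallback = False
            p = float(chi2.pvalue)
            if (chi2.expected_freq < 1).any():
                if obs.shape == (2, 2):
                    p = float(stats.fisher_exact(obs).pvalue)
                exact_fallback = True
            entry[col] = {
                "type": "categorical",
                "counts": counts,
                "p": p,
                "exact_fallback": exact_fallback,
                "correction": "yates" if obs.shape == (2, 2) else "none",
            }
        out[str(split)] = entry
    return out


# ---------------------------------------------------------------------------
# consolidated report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """All metrics for one model across splits.

    ``cutoff`` is learned once on the training split and frozen for every
    other split.
    """

    model_name: str
    cutoff: float
    per_split: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(o):
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="list")
            if isinstance(o, dict):
                return {k: conv(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [conv(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return o

        return {"model": self.model_name, "cutoff": self.cutoff, "per_split": conv(self.per_split)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), default=str)


def evaluate_model(
    model_name: str,
    probs_by_split: dict[str, np.ndarray],
    labels_by_split: dict[str, np.ndarray],
    train_split: str = "train",
    n_boot: int = 2000,
    seed: int = 0,
    calibration_bins: int = 5,
) -> EvaluationReport:
    """Full evaluation with the training-split Youden cutoff frozen."""
    train = youden_cutoff(probs_by_split[train_split], labels_by_split[train_split])
    cutoff = train["cutoff"]
    report = EvaluationReport(model_name=model_name, cutoff=cutoff)
    for split, p in probs_by_split.items():
        y = labels_by_split[split]
        entry = {
            "auc": roc_auc(p, y),
            "auprc": auprc(p, y, n_boot=n_boot, seed=seed),
            "metrics": confusion_metrics(p, y, cutoff),
            "calibration": calibration_curve(p, y, bins=calibration_bins),
            "decision_curve": decision_curve(p, y),
            "waterfall": waterfall(p, y, cutoff)["counts"],
            "n": int(len(y)),
        }
        report.per_split[split] = entry
    return report
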