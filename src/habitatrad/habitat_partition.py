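"""Entropy-based two-level intratumoral ("habitat") partitioning.

Three steps per sequence:

1. voxelwise local Shannon entropy of the intensity histogram in a small
   in-plane window (default 9x9, stride 1), with the window clipped to the
   lesion mask so background never contaminates the histogram; entropy and
   raw intensity are then Z-scored within each ROI;
2. per-patient superpixelization: k-means with k=30 on the 2-D (Z-intensity,
   Z-entropy) voxel vectors, summarising each superpixel by its member mean;
3. population-level agglomerative Ward clustering of all patients'
   superpixel summaries, with the number of habitats K chosen in [2, 10] by
   the mean Silhouette coefficient (ties broken by the Calinski-Harabasz
   index).

Habitats are renamed so that S2 is the cluster with the higher mean
Z-scored entropy (the "inner" habitat) and S1 the lower ("marginal").
Patients outside the fitting population receive labels by nearest population
centroid, which avoids refitting and leakage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from scipy.stats import ttest_rel
from sklearn.cluster import KMeans

from habitatrad.synthetic_cohort import Cohort, LesionVolume

logger = logging.getLogger("habitatrad")

DEFAULT_WINDOW = 9
DEFAULT_BINS = 32
DEFAULT_SUPERPIXELS = 30
DEFAULT_K_RANGE = tuple(range(2, 11))


@dataclass
class EntropyMap:
    """Per-voxel local entropy plus Z-scored entropy/intensity on the mask."""

    patient_id: str
    sequence_id: str
    entropy: np.ndarray  # (z,y,x) float, NaN off-mask; bits
    z_entropy: np.ndarray
    z_intensity: np.ndarray
    mask: np.ndarray
    window: int = DEFAULT_WINDOW
    bins: int = DEFAULT_BINS


@dataclass
class SuperpixelSet:
    """Per-voxel superpixel labels and per-superpixel summary vectors."""

    patient_id: str
    sequence_id: str
    labels: np.ndarray  # (z,y,x) int, 0 off-mask, 1..M on-mask
    summaries: np.ndarray  # (M, 2): mean (z-intensity, z-entropy)
    sizes: np.ndarray  # (M,) voxel counts

    @property
    def n_superpixels(self) -> int:
        return self.summaries.shape[0]


@dataclass
class PartitionModel:
    """Fitted population clustering over pooled superpixel summaries."""

    k_star: int
    centroids: np.ndarray  # (k_star, 2) ordered by ascending mean entropy
    scores: dict = field(default_factory=dict)  # K -> {"ch": ., "silhouette": .}
    linkage_method: str = "ward"
    k_range: tuple = DEFAULT_K_RANGE

    def to_dict(self) -> dict:
        return {
            "k_star": int(self.k_star),
            "centroids": self.centroids.tolist(),
            "scores": {str(k): v for k, v in self.scores.items()},
            "linkage_method": self.linkage_method,
            "k_range": list(self.k_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PartitionModel":
        return cls(
            k_star=int(d["k_star"]),
            centroids=np.asarray(d["centroids"], dtype=float),
            scores={int(k): v for k, v in d.get("scores", {}).items()},
            linkage_method=d.get("linkage_method", "ward"),
            k_range=tuple(d.get("k_range", DEFAULT_K_RANGE)),
        )


@dataclass
class SubregionPartition:
    """Per-voxel habitat labels (0 background, 1=S1 .. K=SK)."""

    patient_id: str
    sequence_id: str
    labels: np.ndarray
    k: int
    voxel_counts: np.ndarray  # (k,)
    mean_intensity: np.ndarray  # (k,) raw-intensity means, NaN when empty
    mean_entropy: np.ndarray  # (k,) entropy (bits) means, NaN when empty
    mean_z_entropy: np.ndarray

    def habitat_mask(self, habitat: int) -> np.ndarray:
        return self.labels == habitat


# ---------------------------------------------------------------------------
# step 1: local entropy
# ---------------------------------------------------------------------------


def _window_counts(values: np.ndarray, half: int) -> np.ndarray:
    """Sliding (2*half+1)^2 window sums of a 2-D integer array, via an
    integral image (exact)."""
    h, w = values.shape
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(values, axis=0), axis=1, out=ii[1:, 1:])
    y0 = np.clip(np.arange(h) - half, 0, h)
    y1 = np.clip(np.arange(h) + half + 1, 0, h)
    x0 = np.clip(np.arange(w) - half, 0, w)
    x1 = np.clip(np.arange(w) + half + 1, 0, w)
    return (
        ii[np.ix_(y1, x1)] - ii[np.ix_(y0, x1)] - ii[np.ix_(y1, x0)] + ii[np.ix_(y0, x0)]
    )


def local_entropy(
    volume: LesionVolume, w: int = DEFAULT_WINDOW, bins: int = DEFAULT_BINS
) -> EntropyMap:
    """Local Shannon entropy (bits) of the in-plane w-by-w neighborhood.

    The neighborhood is restricted to mask voxels; the histogram uses
    ``bins`` equal-width bins spanning the ROI's min-max intensity range.
    A constant neighborhood has H = 0 and H is bounded by log2(bins).
    """
    if w < 3 or w % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    img, mask = volume.image, volume.mask
    vals = img[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        idx = np.minimum((img - lo) / (hi - lo) * bins, bins - 1).astype(np.int32)
    else:
        idx = np.zeros(img.shape, dtype=np.int32)

    half = w // 2
    H = np.full(img.shape, np.nan)
    for z in range(img.shape[0]):
        m2 = mask[z]
        if not m2.any():
            continue
        counts = np.stack(
            [_window_counts(((idx[z] == b) & m2).astype(np.int64), half) for b in range(bins)]
        )  # (bins, h, w)
        totals = counts.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / totals
            logp = np.where(p > 0, p, 1.0)
            terms = -p * np.log2(logp)
        Hz = np.nan_to_num(terms).sum(axis=0)
        H[z][m2] = Hz[m2]

    hvals = H[mask]
    z_ent = np.full(img.shape, np.nan)
    z_int = np.full(img.shape, np.nan)
    z_ent[mask] = _zscore(hvals)
    z_int[mask] = _zscore(vals)
    return EntropyMap(volume.patient_id, volume.sequence_id, H, z_ent, z_int, mask, w, bins)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


# ---------------------------------------------------------------------------
# step 2: per-patient superpixels
# ---------------------------------------------------------------------------


def superpixelize(em: EntropyMap, M: int = DEFAULT_SUPERPIXELS, seed: int = 0) -> SuperpixelSet:
    """k-means (k=M) on per-voxel (Z-intensity, Z-entropy) vectors.

    Superpixel summaries are the member means in the same 2-D space.  When
    the ROI has fewer than M voxels, M is reduced to the voxel count with a
    logged warning.  Deterministic under a fixed seed.
    """
    mask = em.mask
    n_vox = int(mask.sum())
    if n_vox < M:
        logger.warning(
            "ROI %s/%s has %d voxels < M=%d superpixels; reducing M",
            em.patient_id,
            em.sequence_id,
            n_vox,
            M,
        )
        M = n_vox
    X = np.column_stack([em.z_intensity[mask], em.z_entropy[mask]])
    if M == n_vox:
        member = np.arange(n_vox)
        centers = X.copy()
    else:
        km = KMeans(n_clusters=M, n_init=10, random_state=seed)
        member = km.fit_predict(X)
        centers = np.stack([X[member == m].mean(axis=0) for m in range(M)])
    # deterministic ordering: sort superpixels by (entropy, intensity) mean
    order = np.lexsort((centers[:, 0], centers[:, 1]))
    rank = np.empty(M, dtype=int)
    rank[order] = np.arange(M)
    member = rank[member]
    summaries = centers[order]
    sizes = np.bincount(member, minlength=M)

    labels = np.zeros(mask.shape, dtype=np.int32)
    labels[mask] = member + 1
    return SuperpixelSet(em.patient_id, em.sequence_id, labels, summaries, sizes)


# ---------------------------------------------------------------------------
# clustering indices (own implementations, oracle-tested)
# ---------------------------------------------------------------------------


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """CH = [B/(K-1)] / [W/(N-K)] with B, W the between/within-cluster
    sums of squared Euclidean distances to the respective means."""
    X = np.asarray(X, dtype=float)
    uniq = np.unique(labels)
    K, N = len(uniq), X.shape[0]
    if K < 2 or N <= K:
        raise ValueError("need 2 <= K < N")
    grand = X.mean(axis=0)
    B = W = 0.0
    for u in uniq:
        pts = X[labels == u]
        c = pts.mean(axis=0)
        B += len(pts) * float(((c - grand) ** 2).sum())
        W += float(((pts - c) ** 2).sum())
    if W == 0:
        raise ValueError("degenerate dispersion: all within-cluster variance is zero")
    return (B / (K - 1)) / (W / (N - K))


def silhouette_mean(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean Silhouette s(i) = (b(i)-a(i))/max(a(i),b(i)); singleton
    clusters contribute s = 0 (standard convention)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    D = cdist(X, X)
    s = np.zeros(len(X))
    for i in range(len(X)):
        same = labels == labels[i]
        n_same = same.sum()
        if n_same == 1:
            s[i] = 0.0
            continue
        a = D[i][same].sum() / (n_same - 1)
        b = min(D[i][labels == u].mean() for u in uniq if u != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


# ---------------------------------------------------------------------------
# step 3: population clustering and assignment
# ---------------------------------------------------------------------------


def population_cluster(
    superpixel_sets: list[SuperpixelSet],
    k_range=DEFAULT_K_RANGE,
    seed: int = 0,
) -> PartitionModel:
    """Ward-linkage agglomerative clustering of pooled superpixel summaries.

    For every K in ``k_range`` the Calinski-Harabasz index and the mean
    Silhouette coefficient are evaluated; K* maximizes the mean Silhouette,
    with ties broken by the higher CH.  Cluster centroids (ordered by
    ascending mean entropy) are stored for nearest-centroid assignment of
    patients outside the fitting population.
    """
    if len(superpixel_sets) < 2:
        raise ValueError("population clustering needs >= 2 patients")
    X = np.vstack([s.summaries for s in superpixel_sets])
    if X.shape[0] < max(k_range):
        raise ValueError("fewer pooled superpixels than max(k_range)")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate dispersion: all pooled summaries identical")

    Z = linkage(X, method="ward")
    scores: dict[int, dict] = {}
    best = None
    for K in k_range:
        lab = fcluster(Z, t=K, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        ch = calinski_harabasz(X, lab)
        sil = silhouette_mean(X, lab)
        scores[K] = {"ch": ch, "silhouette": sil}
        key = (sil, ch)
        if best is None or key > best[0]:
            best = (key, K, lab)
    if best is None:
        raise ValueError("no valid clustering in k_range")
    _, k_star, lab = best
    centroids = np.stack([X[lab == u].mean(axis=0) for u in np.unique(lab)])
    centroids = centroids[np.argsort(centroids[:, 1])]  # ascending entropy: S1..SK
    return PartitionModel(k_star=k_star, centroids=centroids, scores=scores, k_range=tuple(k_range))


def assign_subregions(
    sp: SuperpixelSet, model: PartitionModel, em: EntropyMap | None = None
) -> SubregionPartition:
    """Assign each superpixel to its nearest population centroid.

    Voxels inherit their superpixel's habitat.  Habitats are numbered by the
    model's entropy ordering, so S2 (and higher) have higher mean Z-scored
    entropy than S1.  A patient may leave a habitat empty.
    """
    d = cdist(sp.summaries, model.centroids)
    sp_habitat = d.argmin(axis=1) + 1  # 1..K in entropy order
    labels = np.zeros(sp.labels.shape, dtype=np.int16)
    on = sp.labels > 0
    labels[on] = sp_habitat[sp.labels[on] - 1]

    k = model.k_star
    counts = np.array([(labels == h).sum() for h in range(1, k + 1)])
    mean_int = np.full(k, np.nan)
    mean_ent = np.full(k, np.nan)
    mean_zent = np.full(k, np.nan)
    if em is not None:
        for h in range(1, k + 1):
            hm = labels == h
            if hm.any():
                mean_ent[h - 1] = float(np.nanmean(em.entropy[hm]))
                mean_zent[h - 1] = float(np.nanmean(em.z_entropy[hm]))
    return SubregionPartition(
        sp.patient_id, sp.sequence_id, labels, k, counts, mean_int, mean_ent, mean_zent
    )


def partition_sequence(
    cohort: Cohort,
    sequence_id: str,
    w: int = DEFAULT_WINDOW,
    bins: int = DEFAULT_BINS,
    M: int = DEFAULT_SUPERPIXELS,
    k_range=DEFAULT_K_RANGE,
    seed: int = 0,
    fit_splits: tuple[str, ...] = ("train",),
) -> tuple[PartitionModel, dict[str, SubregionPartition], dict[str, EntropyMap]]:
    """Run the full partitioning of one sequence over a cohort.

    The population model is fitted on ``fit_splits`` patients only; all
    patients (including validation/external) are then assigned by nearest
    centroid.  Returns the model and per-patient partitions/entropy maps.
    """
    ems: dict[str, EntropyMap] = {}
    sps: dict[str, SuperpixelSet] = {}
    for pid in cohort.patient_ids:
        em = local_entropy(cohort.volume(pid, sequence_id), w=w, bins=bins)
        ems[pid] = em
        sps[pid] = superpixelize(em, M=M, seed=seed)
    fit_ids = [
        pid for pid in cohort.patient_ids if cohort.clinical.loc[pid, "split"] in fit_splits
    ]
    if len(fit_ids) < 2:
        raise ValueError("need >= 2 patients in the fitting splits")
    model = population_cluster([sps[p] for p in fit_ids], k_range=k_range, seed=seed)
    partitions = {pid: assign_subregions(sps[pid], model, ems[pid]) for pid in cohort.patient_ids}
    return model, partitions, ems


def partition_diagnostics(
    partitions: dict[str, SubregionPartition],
    cohort: Cohort,
    ems: dict[str, EntropyMap] | None = None,
    plot_dir=None,
) -> dict:
    """Per-split habitat intensity/entropy summaries with paired t-tests.

    For each split, patients with both S1 and S2 nonempty contribute their
    habitat mean intensity and entropy; a paired two-sided t-test compares
    S1 against S2.  Patients with an empty habitat are excluded with a
    warning.  Optionally writes boxplot figures to ``plot_dir``.
    """
    per_split: dict[str, dict] = {}
    splits = cohort.clinical["split"].unique()
    for split in splits:
        pids = [p for p in cohort.patient_ids if cohort.clinical.loc[p, "split"] == split]
        if len(pids) < 2:
            raise ValueError(f"split {split!r} has fewer than 2 patients")
        s1_int, s2_int, s1_ent, s2_ent = [], [], [], []
        for pid in pids:
            part = partitions.get(pid)
            if part is None:
                continue
            m1, m2 = part.habitat_mask(1), part.habitat_mask(part.k)
            if not (m1.any() and m2.any()):
                warnings.warn(f"patient {pid}: single-habitat partition excluded from diagnostics")
                continue
            seq = part.sequence_id
            img = cohort.volume(pid, seq).image
            s1_int.append(float(img[m1].mean()))
            s2_int.append(float(img[m2].mean()))
            if ems is not None and pid in ems:
                s1_ent.append(float(np.nanmean(ems[pid].entropy[m1])))
                s2_ent.append(float(np.nanmean(ems[pid].entropy[m2])))
        entry = {"n": len(s1_int), "s1_intensity": s1_int, "s2_intensity": s2_int}
        if len(s1_int) >= 2:
            entry["intensity_t_p"] = float(ttest_rel(s1_int, s2_int).pvalue)
        if len(s1_ent) >= 2:
            entry.update(
                s1_entropy=s1_ent,
                s2_entropy=s2_ent,
                entropy_t_p=float(ttest_rel(s1_ent, s2_ent).pvalue),
            )
        per_split[str(split)] = entry

    if plot_dir is not None:
        _diagnostic_boxplots(per_split, plot_dir)
    return per_split


def _diagnostic_boxplots(per_split: dict, plot_dir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    plot_dir = Path(plot_dir)
    plot_dir.mkdir(parents=True, exist_ok=True)
    for split, entry in per_split.items():
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        axes[0].boxplot(
            [entry["s1_intensity"], entry["s2_intensity"]], tick_labels=["S1", "S2"]
        )
        axes[0].set_title(f"{split}: intensity (p={entry.get('intensity_t_p', float('nan')):.3g})")
        if "s1_entropy" in entry:
            axes[1].boxplot(
                [entry["s1_entropy"], entry["s2_entropy"]], tick_labels=["S1", "S2"]
            )
            axes[1].set_title(f"{split}: entropy (p={entry.get('entropy_t_p', float('nan')):.3g})")
        fig.tight_layout()
        fig.savefig(plot_dir / f"habitat_boxplot_{split}.png", dpi=110)
        plt.close(fig)
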