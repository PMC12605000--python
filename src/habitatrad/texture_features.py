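"""Image preprocessing and radiomic feature extraction per habitat/region.

Features are computed on discretized gray levels (fixed bin count, default
32, levels 1..N_g over the region's min-max range).  Texture matrices are
computed in 3-D with 26-connectivity and distance-1 offsets and features are
averaged over angles where applicable; an in-plane 2-D mode (8-connectivity)
is available.  The module provides first-class implementations of:

* GLCM Inverse Variance and Maximal Correlation Coefficient (MCC),
* GLDM Dependence Non-Uniformity Normalized (alpha = 0),
* GLSZM Small Area Emphasis,
* first-order 90th percentile (linear / type-7 interpolation),

together with a representative first-order set and one representative each
of the GLRLM (Short Run Emphasis) and NGTDM (Coarseness) families, all
verified against brute-force enumeration oracles in the test suite.

The filter bank covers the eight classes used upstream of feature
extraction: wavelet, square, square root, 2-D local binary pattern,
Laplacian of Gaussian, logarithm, exponential, and gradient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from scipy.stats import kurtosis, skew
from skimage.feature import local_binary_pattern

from habitatrad.synthetic_cohort import Cohort, LesionVolume

logger = logging.getLogger("habitatrad")

DEFAULT_BINS = 32
REGION_VOXEL_FLOOR = 10

# 13 unique distance-1 3-D offsets (half of the 26-neighborhood)
_OFFSETS_3D = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]
# 4 unique in-plane offsets (half of the 8-neighborhood)
_OFFSETS_2D = [(0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1)]


@dataclass
class PreprocessSpec:
    """Preprocessing/extraction settings.

    ``filters`` lists derived-image classes; ``log_sigmas`` are the
    Laplacian-of-Gaussian scales in mm; ``bins`` the fixed gray-level bin
    count; ``mode`` '3d' (26-connectivity) or '2d' (in-plane).
    """

    normalize: bool = True
    bins: int = DEFAULT_BINS
    filters: tuple[str, ...] = (
        "log-sigma-3", "log-sigma-5", "wavelet-HHH", "square", "squareroot",
        "logarithm", "exponential", "gradient", "lbp-2D",
    )
    log_sigmas: tuple[float, ...] = (3.0, 5.0)
    mode: str = "3d"
    region_floor: int = REGION_VOXEL_FLOOR

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if any(s <= 0 for s in self.log_sigmas):
            raise ValueError("LoG sigma must be positive")
        if self.mode not in ("3d", "2d"):
            raise ValueError("mode must be '3d' or '2d'")

    def to_dict(self) -> dict:
        return {
            "normalize": self.normalize,
            "bins": self.bins,
            "filters": list(self.filters),
            "log_sigmas": list(self.log_sigmas),
            "mode": self.mode,
            "region_floor": self.region_floor,
        }


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


def discretize(values: np.ndarray, bins: int = DEFAULT_BINS) -> np.ndarray:
    """Fixed-bin-count discretization to integer levels 1..bins."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=np.int32)
    lev = np.floor((values - lo) / (hi - lo) * bins).astype(np.int32) + 1
    return np.minimum(lev, bins)


# ---------------------------------------------------------------------------
# image filters
# ---------------------------------------------------------------------------


def _filter_image(image: np.ndarray, name: str, spacing, mask: np.ndarray) -> np.ndarray | None:
    m = float(np.abs(image[mask]).max())
    if m == 0:
        m = 1.0
    if name == "original":
        return image
    if name == "square":
        # monotone on |x|, rescaled back to the original magnitude range
        return np.sign(image) * (image / m) ** 2 * m
    if name == "squareroot":
        return np.sign(image) * np.sqrt(np.abs(image) * m)
    if name == "logarithm":
        return np.sign(image) * np.log1p(np.abs(image) / m) * m / np.log(2.0)
    if name == "exponential":
        return np.exp(image / m)
    if name == "gradient":
        spacing = np.asarray(spacing, dtype=float)
        if image.shape[0] >= 2:
            g = np.gradient(image, *spacing)
        else:
            g = np.gradient(image[0], *spacing[1:])
            g = [np.zeros_like(image)] + [a[None] for a in g]
        return np.sqrt(sum(a**2 for a in g))
    if name.startswith("log-sigma"):
        sigma_mm = float(name.split("-")[2])
        ext = _lesion_extent_mm(mask, spacing)
        if sigma_mm > ext:
            warnings.warn(
                f"LoG sigma {sigma_mm} mm exceeds lesion extent {ext:.1f} mm; filter skipped"
            )
            return None
        sig_vox = [sigma_mm / s for s in spacing]
        if image.shape[0] < 3:
            sig_vox[0] = 0.0
        return ndimage.gaussian_laplace(image, sigma=sig_vox)
    if name.startswith("wavelet"):
        band = name.split("-")[1]
        return _wavelet_band(image, band)
    if name in ("lbp-2D", "lbp-3D-m2"):
        if name == "lbp-3D-m2":
            logger.info("lbp-3D-m2 honored as an alias of the 2-D rotation-invariant LBP")
        out = np.empty_like(image)
        for z in range(image.shape[0]):
            out[z] = local_binary_pattern(image[z], P=8, R=1.0, method="uniform")
        return out
    raise ValueError(f"unknown filter {name!r}")


def _lesion_extent_mm(mask: np.ndarray, spacing) -> float:
    idx = np.argwhere(mask)
    span = (idx.max(axis=0) - idx.min(axis=0) + 1) * np.asarray(spacing, dtype=float)
    return float(span.max())


def _wavelet_band(image: np.ndarray, band: str) -> np.ndarray:
    """Single-level stationary (undecimated) wavelet subband, coif1."""
    axes = tuple(i for i in range(image.ndim) if image.shape[i] >= 2)
    if len(band) != len(axes):
        band = band[-len(axes):]
    pad = [(0, image.shape[i] % 2 if i in axes else 0) for i in range(image.ndim)]
    padded = np.pad(image, pad, mode="symmetric")
    coeffs = pywt.swtn(padded, wavelet="coif1", level=1, axes=axes)[0]
    key = "".join("a" if c == "L" else "d" for c in band.upper())
    sub = coeffs[key]
    slicer = tuple(slice(0, image.shape[i]) for i in range(image.ndim))
    return sub[slicer]


def preprocess(volume: LesionVolume, spec: PreprocessSpec) -> dict[str, np.ndarray]:
    """Derived image stack: original plus each requested filter response.

    Images stay on the lesion grid; discretization happens at feature time.
    Z-score normalization (over mask voxels) is applied to the input image
    first when ``spec.normalize`` is set.  Filters whose scale exceeds the
    lesion extent are skipped with a warning.
    """
    img = volume.image
    if spec.normalize:
        vals = img[volume.mask]
        sd = vals.std()
        img = (img - vals.mean()) / (sd if sd > 0 else 1.0)
    stack: dict[str, np.ndarray] = {"original": img}
    for name in spec.filters:
        if name.startswith("log-sigma") and len(name.split("-")) == 3:
            names = [f"log-sigma-{s:g}" for s in spec.log_sigmas] if name == "log-sigma" else [name]
        else:
            names = [name]
        for nm in names:
            out = _filter_image(img, nm, volume.spacing, volume.mask)
            if out is not None:
                stack[nm] = out
    return stack


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def _glcm_matrices(levels: np.ndarray, mask: np.ndarray, n_levels: int, mode: str = "3d"):
    """Symmetric, normalized co-occurrence matrix per distance-1 offset."""
    offsets = _OFFSETS_3D if mode == "3d" else _OFFSETS_2D
    lev = np.where(mask, levels, 0)
    mats = []
    for dz, dy, dx in offsets:
        a, b = _shifted_pairs(lev, mask, dz, dy, dx)
        if a.size == 0:
            continue
        counts = np.bincount((a - 1) * n_levels + (b - 1), minlength=n_levels * n_levels)
        C = counts.reshape(n_levels, n_levels)
        C = C + C.T
        mats.append(C / C.sum())
    return mats


def _shifted_pairs(lev: np.ndarray, mask: np.ndarray, dz: int, dy: int, dx: int):
    """Pairs of levels (center, neighbor at offset) with both voxels in-mask."""
    nz, ny, nx = lev.shape

    def sl(d, n):
        return (slice(max(0, -d), min(n, n - d)), slice(max(0, d), min(n, n + d)))

    (za, zb), (ya, yb), (xa, xb) = sl(dz, nz), sl(dy, ny), sl(dx, nx)
    ma = mask[za, ya, xa] & mask[zb, yb, xb]
    return lev[za, ya, xa][ma], lev[zb, yb, xb][ma]


def glcm_inverse_variance(
    values: np.ndarray, mask: np.ndarray, bins: int = DEFAULT_BINS, mode: str = "3d"
) -> float:
    """IV = sum_{i != j} p(i,j) / (i-j)^2, averaged over angles."""
    if mask.sum() < 2:
        raise ValueError("need >= 2 voxels")
    lev = np.zeros(values.shape, dtype=np.int32)
    lev[mask] = discretize(values[mask], bins)
    mats = _glcm_matrices(lev, mask, bins, mode)
    if not mats:
        raise ValueError("no valid voxel pairs for GLCM")
    i, j = np.indices((bins, bins))
    off = i != j
    denom = (i - j).astype(float) ** 2
    vals = [float((P[off] / denom[off]).sum()) for P in mats]
    return float(np.mean(vals))


def glcm_mcc(
    values: np.ndarray, mask: np.ndarray, bins: int = DEFAULT_BINS, mode: str = "3d"
) -> float:
    """Maximal correlation coefficient: sqrt of the second-largest
    eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (p_x(i) p_y(k))."""
    if mask.sum() < 2:
        raise ValueError("need >= 2 voxels")
    lev = np.zeros(values.shape, dtype=np.int32)
    lev[mask] = discretize(values[mask], bins)
    if len(np.unique(lev[mask])) < 2:
        raise ValueError("MCC undefined for a single gray level")
    mats = _glcm_matrices(lev, mask, bins, mode)
    if not mats:
        raise ValueError("no valid voxel pairs for GLCM")
    vals = []
    for P in mats:
        px = P.sum(axis=1)
        keep = px > 0
        P = P[np.ix_(keep, keep)]
        px = px[keep]
        if P.shape[0] < 2:
            vals.append(0.0)
            continue
        # Q[i, j] = sum_k P[i, k] P[j, k] / (px[i] px[k])
        Q = (P / px[:, None]) @ (P / px[None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        second = max(ev[-2], 0.0)
        vals.append(float(np.sqrt(min(second, 1.0))))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------


def _dependence_sizes(
    levels: np.ndarray, mask: np.ndarray, alpha: float = 0.0, mode: str = "3d"
) -> np.ndarray:
    """Per-voxel dependence size: the voxel itself plus its distance-1
    neighbors (26- or 8-connectivity) whose level differs by <= alpha."""
    offsets = _OFFSETS_3D if mode == "3d" else _OFFSETS_2D
    lev = np.where(mask, levels, 0)
    nz, ny, nx = lev.shape
    dep_grid = np.zeros(lev.shape, dtype=np.int64)
    for dz, dy, dx in offsets:
        for sgn in (1, -1):
            oz, oy, ox = sgn * dz, sgn * dy, sgn * dx

            def sl(d, n):
                return (slice(max(0, -d), min(n, n - d)), slice(max(0, d), min(n, n + d)))

            (za, zb), (ya, yb), (xa, xb) = sl(oz, nz), sl(oy, ny), sl(ox, nx)
            hit = (
                mask[za, ya, xa]
                & mask[zb, yb, xb]
                & (np.abs(lev[za, ya, xa].astype(np.int64) - lev[zb, yb, xb]) <= alpha)
            )
            dep_grid[za, ya, xa] += hit
    return dep_grid[mask] + 1


def gldm_dnn(
    values: np.ndarray,
    mask: np.ndarray,
    bins: int = DEFAULT_BINS,
    alpha: float = 0.0,
    mode: str = "3d",
) -> float:
    """Dependence Non-Uniformity Normalized:
    DNN = sum_j (sum_i P(i,j))^2 / N_z^2 over the gray-level dependence
    matrix; invariant to how dependence sizes are indexed."""
    if not mask.any():
        raise ValueError("empty region")
    lev = np.zeros(values.shape, dtype=np.int32)
    lev[mask] = discretize(values[mask], bins)
    dep = _dependence_sizes(lev, mask, alpha, mode)
    counts = np.bincount(dep)
    nz = dep.size
    return float((counts.astype(float) ** 2).sum() / nz**2)


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------


def _zone_sizes(
    levels: np.ndarray, mask: np.ndarray, mode: str = "3d", full_connectivity: bool = True
) -> list[tuple[int, int]]:
    """(level, size) of each connected equal-level zone.

    ``full_connectivity`` gives 26-/8-connectivity (the standard for
    size-zone matrices); False gives face-only 6-/4-connectivity."""
    if full_connectivity:
        structure = np.ones((3, 3, 3), dtype=bool)
        if mode == "2d":
            structure = np.zeros((3, 3, 3), dtype=bool)
            structure[1] = True
    else:
        structure = ndimage.generate_binary_structure(3, 1)
        if mode == "2d":
            structure[0] = structure[2] = False
    zones = []
    for g in np.unique(levels[mask]):
        lab, nlab = ndimage.label((levels == g) & mask, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(g), int(s)) for s in sizes)
    return zones


def glszm_sae(
    values: np.ndarray,
    mask: np.ndarray,
    bins: int = DEFAULT_BINS,
    mode: str = "3d",
    full_connectivity: bool = True,
) -> float:
    """Small Area Emphasis: (1/N_z) sum_zones 1/size^2, zones being
    connected components of equal discretized level."""
    if not mask.any():
        raise ValueError("empty region")
    lev = np.zeros(values.shape, dtype=np.int32)
    lev[mask] = discretize(values[mask], bins)
    zones = _zone_sizes(lev, mask, mode, full_connectivity)
    sizes = np.array([s for _, s in zones], dtype=float)
    return float((1.0 / sizes**2).sum() / len(sizes))


# ---------------------------------------------------------------------------
# GLRLM / NGTDM representatives
# ---------------------------------------------------------------------------


def glrlm_sre(
    values: np.ndarray, mask: np.ndarray, bins: int = DEFAULT_BINS, mode: str = "3d"
) -> float:
    """Short Run Emphasis: (1/N_r) sum_runs 1/length^2 per direction,
    averaged over directions."""
    if not mask.any():
        raise ValueError("empty region")
    lev = np.zeros(values.shape, dtype=np.int64)
    lev[mask] = discretize(values[mask], bins)
    offsets = _OFFSETS_3D if mode == "3d" else _OFFSETS_2D
    vals = []
    for off in offsets:
        runs = _runs_along(lev, mask, off)
        if runs.size:
            r = runs.astype(float)
            vals.append(float((1.0 / r**2).sum() / len(r)))
    return float(np.mean(vals))


def _runs_along(lev: np.ndarray, mask: np.ndarray, offset) -> np.ndarray:
    """Lengths of maximal equal-level in-mask runs along one direction.

    Vectorized: ``cont`` marks voxels whose +offset neighbor continues the
    run; forward run lengths are propagated iteratively (converges after
    max-run-length steps)."""
    dz, dy, dx = offset
    nz, ny, nx = lev.shape

    def sl(d, n):
        return (slice(max(0, -d), min(n, n - d)), slice(max(0, d), min(n, n + d)))

    (za, zb), (ya, yb), (xa, xb) = sl(dz, nz), sl(dy, ny), sl(dx, nx)
    cont = np.zeros(lev.shape, dtype=bool)
    cont[za, ya, xa] = (
        mask[za, ya, xa] & mask[zb, yb, xb] & (lev[za, ya, xa] == lev[zb, yb, xb])
    )
    # L(v) = 1 + L(v + offset) when the run continues, else 1
    L = mask.astype(np.int64)
    while True:
        Lf = np.zeros_like(L)
        Lf[za, ya, xa] = L[zb, yb, xb]
        newL = np.where(cont, 1 + Lf, mask.astype(np.int64))
        if np.array_equal(newL, L):
            break
        L = newL
    # run starts: in-mask voxels whose -offset neighbor does not continue
    prev_cont = np.zeros(lev.shape, dtype=bool)
    prev_cont[zb, yb, xb] = cont[za, ya, xa]
    starts = mask & ~prev_cont
    return L[starts]


def ngtdm_coarseness(
    values: np.ndarray, mask: np.ndarray, bins: int = DEFAULT_BINS, mode: str = "3d"
) -> float:
    """Coarseness = 1 / sum_i p_i s_i, with s_i the summed absolute
    difference between voxels of level i and their neighborhood mean."""
    if not mask.any():
        raise ValueError("empty region")
    lev = np.zeros(values.shape, dtype=np.float64)
    lev[mask] = discretize(values[mask], bins)
    structure = np.ones((3, 3, 3)) if mode == "3d" else np.pad(
        np.ones((1, 3, 3)), ((1, 1), (0, 0), (0, 0))
    )
    structure[1, 1, 1] = 0
    nbr_sum = ndimage.convolve(np.where(mask, lev, 0.0), structure, mode="constant")
    nbr_cnt = ndimage.convolve(mask.astype(float), structure, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        nbr_mean = nbr_sum / nbr_cnt
    valid = mask & (nbr_cnt > 0)
    nvp = valid.sum()
    s = {}
    for g in np.unique(lev[valid]):
        sel = valid & (lev == g)
        s[g] = float(np.abs(g - nbr_mean[sel]).sum())
    total = sum((lev[valid] == g).sum() / nvp * s[g] for g in s)
    return float(1.0 / total) if total > 0 else 1e6


# ---------------------------------------------------------------------------
# first-order
# ---------------------------------------------------------------------------


def firstorder_p90(values: np.ndarray) -> float:
    """90th percentile with linear (type-7) interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty region")
    return float(np.percentile(values, 90))


def _firstorder_features(v: np.ndarray, bins: int) -> dict[str, float]:
    lev = discretize(v, bins)
    counts = np.bincount(lev)[1:]
    p = counts[counts > 0] / v.size
    return {
        "firstorder_Mean": float(v.mean()),
        "firstorder_Median": float(np.median(v)),
        "firstorder_StdDev": float(v.std()),
        "firstorder_10Percentile": float(np.percentile(v, 10)),
        "firstorder_90Percentile": firstorder_p90(v),
        "firstorder_Minimum": float(v.min()),
        "firstorder_Maximum": float(v.max()),
        "firstorder_Skewness": float(skew(v)) if v.std() > 0 else 0.0,
        "firstorder_Kurtosis": float(kurtosis(v, fisher=False)) if v.std() > 0 else 0.0,
        "firstorder_Energy": float((v**2).sum()),
        "firstorder_Entropy": float(-(p * np.log2(p)).sum()),
        "firstorder_InterquartileRange": float(np.percentile(v, 75) - np.percentile(v, 25)),
    }


# ---------------------------------------------------------------------------
# per-region extraction
# ---------------------------------------------------------------------------


def _texture_features(img: np.ndarray, mask: np.ndarray, bins: int, mode: str) -> dict[str, float]:
    out: dict[str, float] = {}
    try:
        out["glcm_InverseVariance"] = glcm_inverse_variance(img, mask, bins, mode)
    except ValueError:
        pass
    try:
        out["glcm_MCC"] = glcm_mcc(img, mask, bins, mode)
    except ValueError:
        pass
    out["gldm_DependenceNonUniformityNormalized"] = gldm_dnn(img, mask, bins, 0.0, mode)
    out["glszm_SmallAreaEmphasis"] = glszm_sae(img, mask, bins, mode)
    out["glrlm_ShortRunEmphasis"] = glrlm_sre(img, mask, bins, mode)
    out["ngtdm_Coarseness"] = ngtdm_coarseness(img, mask, bins, mode)
    return out


def extract_region_features(
    stack: dict[str, np.ndarray], mask: np.ndarray, spec: PreprocessSpec
) -> dict[str, float]:
    """All configured filter x feature combinations for one region mask."""
    feats: dict[str, float] = {}
    for fname, img in stack.items():
        v = img[mask]
        for k, val in _firstorder_features(v, spec.bins).items():
            feats[f"{fname}_{k}"] = val
        for k, val in _texture_features(img, mask, spec.bins, spec.mode).items():
            feats[f"{fname}_{k}"] = val
    return feats


def extract_features(
    cohort: Cohort,
    partitions: dict[str, dict[str, "object"]],
    spec: PreprocessSpec | None = None,
    regions: tuple[str, ...] = ("S1", "S2", "whole"),
) -> pd.DataFrame:
    """Feature table over patient x sequence x region rows.

    ``partitions`` maps sequence_id -> patient_id -> SubregionPartition.
    Regions smaller than ``spec.region_floor`` voxels are dropped with a
    logged reason.  Columns carry structured names
    ``<filter>_<class>_<name>`` plus label, batch and split metadata.
    """
    spec = spec or PreprocessSpec()
    rows = []
    for seq, parts in partitions.items():
        for pid, part in parts.items():
            vol = cohort.volume(pid, seq)
            stack = preprocess(vol, spec)
            k = getattr(part, "k", 2)
            masks = {"S1": part.habitat_mask(1), "S2": part.habitat_mask(k), "whole": vol.mask}
            for region in regions:
                rmask = masks[region]
                n = int(rmask.sum())
                if n < spec.region_floor:
                    logger.info(
                        "dropping %s/%s/%s: %d voxels < floor %d",
                        pid, seq, region, n, spec.region_floor,
                    )
                    continue
                feats = extract_region_features(stack, rmask, spec)
                meta = cohort.clinical.loc[pid]
                rows.append(
                    {
                        "patient_id": pid,
                        "sequence": seq,
                        "region": region,
                        "label": int(meta["label"]),
                        "batch": meta["batch"],
                        "split": meta["split"],
                        "n_voxels": n,
                        **feats,
                    }
                )
    table = pd.DataFrame(rows)
    if not table.empty:
        feat_cols = feature_columns(table)
        assert not table[feat_cols].isna().any().any(), "missing values after extraction"
    return table


META_COLUMNS = ("patient_id", "sequence", "region", "label", "batch", "split", "n_voxels")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# ICC reproducibility filtering
# ---------------------------------------------------------------------------


def icc_two_way(x1: np.ndarray, x2: np.ndarray) -> float:
    """ICC from a two-way mixed-effects, absolute-agreement, single-measures
    model (McGraw & Wong A-1) for two repeated ratings per subject."""
    Y = np.column_stack([x1, x2]).astype(float)
    n, k = Y.shape
    grand = Y.mean()
    row_m = Y.mean(axis=1)
    col_m = Y.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_tot = ((Y - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0:
        return np.nan
    return float((msr - mse) / denom)


def perturb_mask(mask: np.ndarray, seed: int = 0, flip_prob: float = 0.3) -> np.ndarray:
    """1-voxel morphological jitter of a mask: randomly add dilation-shell
    voxels and remove erosion-shell voxels.  Emulates a second reader's
    delineation for repeated-extraction ICC on synthetic data."""
    rng = np.random.default_rng(seed)
    structure = np.zeros((3, 3, 3), dtype=bool)
    structure[1] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    grow = ndimage.binary_dilation(mask, structure) & ~mask
    shrink = mask & ~ndimage.binary_erosion(mask, structure)
    out = mask.copy()
    out[grow] = rng.random(int(grow.sum())) < flip_prob
    drop = shrink & (rng.random(mask.shape) < flip_prob * 0.5)
    out[drop] = False
    if not out.any():
        return mask.copy()
    return out


def icc_filter(
    table_a: pd.DataFrame, table_b: pd.DataFrame, threshold: float = 0.80
) -> pd.DataFrame:
    """Per-feature ICC between two repeated extractions.

    Rows are aligned on (patient_id, sequence, region); both tables must
    cover the same keys and features.  Returns a report with the ICC
    estimate, the model form, and a retained flag (ICC > threshold).
    Zero-variance features are dropped (ICC undefined).
    """
    keys = ["patient_id", "sequence", "region"]
    feats = feature_columns(table_a)
    if set(feats) != set(feature_columns(table_b)):
        raise ValueError("feature columns differ between tables")
    a = table_a.set_index(keys).sort_index()
    b = table_b.set_index(keys).sort_index()
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValueError("need >= 2 aligned rows")
    if len(common) < len(a.index):
        logger.info("ICC computed on %d/%d aligned rows", len(common), len(a.index))
    recs = []
    for f in feats:
        x1 = a.loc[common, f].to_numpy(dtype=float)
        x2 = b.loc[common, f].to_numpy(dtype=float)
        if np.std(np.concatenate([x1, x2])) == 0:
            recs.append({"feature": f, "icc": np.nan, "retained": False, "dropped": True})
            continue
        icc = icc_two_way(x1, x2)
        recs.append(
            {"feature": f, "icc": icc, "retained": bool(icc > threshold), "dropped": False}
        )
    report = pd.DataFrame(recs)
    report.attrs["model"] = "two-way mixed effects, absolute agreement, single measures"
    report.attrs["threshold"] = threshold
    return report
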