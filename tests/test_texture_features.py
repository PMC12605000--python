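"""Texture features against brute-force enumeration oracles, filters, ICC."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from habitatrad import texture_features as tf
from habitatrad import synthetic_cohort as sc
from habitatrad import habitat_partition as hp

# ---------------------------------------------------------------------------
# brute-force oracles (pure loops, independent of the implementation)
# ---------------------------------------------------------------------------

OFFSETS_3D = tf._OFFSETS_3D
OFFSETS_2D = tf._OFFSETS_2D


def brute_glcm(lev, mask, offsets, n_levels):
    mats = []
    nz, ny, nx = lev.shape
    for dz, dy, dx in offsets:
        C = np.zeros((n_levels, n_levels))
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    z2, y2, x2 = z + dz, y + dy, x + dx
                    if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                        continue
                    if mask[z, y, x] and mask[z2, y2, x2]:
                        C[lev[z, y, x] - 1, lev[z2, y2, x2] - 1] += 1
        C = C + C.T
        if C.sum():
            mats.append(C / C.sum())
    return mats


def brute_iv(lev, mask, offsets, n_levels):
    vals = []
    for P in brute_glcm(lev, mask, offsets, n_levels):
        s = 0.0
        for i in range(n_levels):
            for j in range(n_levels):
                if i != j:
                    s += P[i, j] / (i - j) ** 2
        vals.append(s)
    return float(np.mean(vals))


def brute_mcc(lev, mask, offsets, n_levels):
    vals = []
    for P in brute_glcm(lev, mask, offsets, n_levels):
        px = P.sum(axis=1)
        keep = px > 0
        P = P[np.ix_(keep, keep)]
        px = px[keep]
        m = P.shape[0]
        if m < 2:
            vals.append(0.0)
            continue
        Q = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                Q[i, j] = sum(
                    P[i, k] * P[j, k] / (px[i] * px[k]) for k in range(m) if px[k] > 0
                )
        ev = sorted(np.real(np.linalg.eigvals(Q)))
        vals.append(np.sqrt(min(max(ev[-2], 0.0), 1.0)))
    return float(np.mean(vals))


def brute_dnn(lev, mask, offsets, alpha=0.0):
    nz, ny, nx = lev.shape
    deps = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                d = 1
                for dz, dy, dx in offsets:
                    for s in (1, -1):
                        z2, y2, x2 = z + s * dz, y + s * dy, x + s * dx
                        if (
                            0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx
                            and mask[z2, y2, x2]
                            and abs(int(lev[z2, y2, x2]) - int(lev[z, y, x])) <= alpha
                        ):
                            d += 1
                deps.append(d)
    counts = np.bincount(deps)
    return float((counts.astype(float) ** 2).sum() / len(deps) ** 2)


def brute_sae(lev, mask, structure):
    """Flood-fill zone enumeration."""
    sizes = []
    visited = np.zeros(lev.shape, bool)
    offs = np.argwhere(structure) - 1
    for start in np.argwhere(mask):
        if visited[tuple(start)]:
            continue
        g = lev[tuple(start)]
        stack = [tuple(start)]
        visited[tuple(start)] = True
        size = 0
        while stack:
            v = stack.pop()
            size += 1
            for o in offs:
                w = tuple(np.array(v) + o)
                if all(0 <= w[i] < lev.shape[i] for i in range(3)):
                    if mask[w] and not visited[w] and lev[w] == g:
                        visited[w] = True
                        stack.append(w)
        sizes.append(size)
    sizes = np.array(sizes, float)
    return float((1.0 / sizes**2).sum() / len(sizes))


def brute_sre(lev, mask, offsets):
    nz, ny, nx = lev.shape
    vals = []
    for dz, dy, dx in offsets:
        runs = []
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    if not mask[z, y, x]:
                        continue
                    pz, py, px = z - dz, y - dy, x - dx
                    if (
                        0 <= pz < nz and 0 <= py < ny and 0 <= px < nx
                        and mask[pz, py, px] and lev[pz, py, px] == lev[z, y, x]
                    ):
                        continue
                    n = 0
                    cz, cy, cx = z, y, x
                    while (
                        0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx
                        and mask[cz, cy, cx] and lev[cz, cy, cx] == lev[z, y, x]
                    ):
                        n += 1
                        cz, cy, cx = cz + dz, cy + dy, cx + dx
                    runs.append(n)
        if runs:
            r = np.array(runs, float)
            vals.append((1.0 / r**2).sum() / len(r))
    return float(np.mean(vals))


def brute_coarseness(lev, mask, offsets):
    nz, ny, nx = lev.shape
    s = {}
    nvp = 0
    counts = {}
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                nbrs = []
                for dz, dy, dx in offsets:
                    for sign in (1, -1):
                        z2, y2, x2 = z + sign * dz, y + sign * dy, x + sign * dx
                        if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx and mask[z2, y2, x2]:
                            nbrs.append(lev[z2, y2, x2])
                if not nbrs:
                    continue
                nvp += 1
                g = lev[z, y, x]
                s[g] = s.get(g, 0.0) + abs(g - np.mean(nbrs))
                counts[g] = counts.get(g, 0) + 1
    total = sum(counts[g] / nvp * s[g] for g in s)
    return float(1.0 / total) if total > 0 else 1e6


def _fixture(seed, shape=(3, 7, 7), bins=6):
    rng = np.random.default_rng(seed)
    vals = rng.random(shape) * 10
    mask = rng.random(shape) > 0.25
    mask[shape[0] // 2, shape[1] // 2, shape[2] // 2] = True
    lev = np.zeros(shape, dtype=np.int64)
    lev[mask] = tf.discretize(vals[mask], bins)
    return vals, mask, lev, bins


@pytest.mark.parametrize("seed", range(8))
def test_glcm_inverse_variance_matches_enumeration(seed):
    vals, mask, lev, bins = _fixture(seed)
    got = tf.glcm_inverse_variance(vals, mask, bins)
    want = brute_iv(lev, mask, OFFSETS_3D, bins)
    assert got == pytest.approx(want, rel=1e-9)


@pytest.mark.parametrize("seed", range(8))
def test_glcm_mcc_matches_enumeration(seed):
    vals, mask, lev, bins = _fixture(seed)
    got = tf.glcm_mcc(vals, mask, bins)
    want = brute_mcc(lev, mask, OFFSETS_3D, bins)
    assert got == pytest.approx(want, rel=1e-8)
    assert 0.0 <= got <= 1.0


@pytest.mark.parametrize("seed", range(8))
def test_gldm_dnn_matches_enumeration(seed):
    vals, mask, lev, bins = _fixture(seed)
    got = tf.gldm_dnn(vals, mask, bins)
    want = brute_dnn(lev, mask, OFFSETS_3D)
    assert got == pytest.approx(want, rel=1e-12)
    assert 0.0 < got <= 1.0


@pytest.mark.parametrize("seed", range(8))
def test_glszm_sae_matches_flood_fill(seed):
    vals, mask, lev, bins = _fixture(seed, shape=(2, 6, 6))
    got = tf.glszm_sae(vals, mask, bins)
    want = brute_sae(lev, mask, np.ones((3, 3, 3), bool))
    assert got == pytest.approx(want, rel=1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_glrlm_sre_matches_enumeration(seed):
    vals, mask, lev, bins = _fixture(seed, shape=(2, 6, 6))
    got = tf.glrlm_sre(vals, mask, bins)
    want = brute_sre(lev, mask, OFFSETS_3D)
    assert got == pytest.approx(want, rel=1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_ngtdm_coarseness_matches_enumeration(seed):
    vals, mask, lev, bins = _fixture(seed, shape=(2, 6, 6))
    got = tf.ngtdm_coarseness(vals, mask, bins)
    want = brute_coarseness(lev.astype(float), mask, OFFSETS_3D)
    assert got == pytest.approx(want, rel=1e-9)


# ---------------------------------------------------------------------------
# frozen small examples
# ---------------------------------------------------------------------------


def test_constant_region_examples():
    c = np.full((1, 4, 4), 3.0)
    m = np.ones((1, 4, 4), bool)
    assert tf.glcm_inverse_variance(c, m, 32) == 0.0  # all mass on the diagonal
    assert tf.glszm_sae(c, m, 32) == pytest.approx(1 / 256)  # one 16-voxel zone
    assert tf.firstorder_p90(c[m]) == 3.0
    with pytest.raises(ValueError, match="single gray level"):
        tf.glcm_mcc(c, m, 32)


def test_gldm_dnn_3x3_hand_value():
    # 8-connectivity in-plane: corners depend on 4, edges 6, center 9
    c = np.ones((1, 3, 3))
    m = np.ones((1, 3, 3), bool)
    assert tf.gldm_dnn(c, m, 32, 0, "2d") == pytest.approx((16 + 16 + 1) / 81)


def test_glcm_iv_2x2_hand_enumeration():
    img = np.array([[[1.0, 2.0], [1.0, 2.0]]])
    m = np.ones((1, 2, 2), bool)
    lev = np.zeros((1, 2, 2), np.int64)
    lev[m] = tf.discretize(img[m], 2)
    got = tf.glcm_inverse_variance(img, m, 2, "2d")
    want = brute_iv(lev, m, OFFSETS_2D, 2)
    assert got == pytest.approx(want, rel=1e-12)


def test_mcc_checkerboard_dependence():
    cb = (np.indices((1, 4, 4)).sum(axis=0) % 2).astype(float)
    m = np.ones((1, 4, 4), bool)
    assert tf.glcm_mcc(cb, m, 2, "2d") == pytest.approx(1.0)


def test_sae_checkerboard_isolated_voxels():
    cb = (np.indices((1, 4, 4)).sum(axis=0) % 2).astype(float)
    m = np.ones((1, 4, 4), bool)
    # face-connectivity: every voxel is its own zone
    assert tf.glszm_sae(cb, m, 2, "2d", full_connectivity=False) == pytest.approx(1.0)


def test_p90_conventions():
    assert tf.firstorder_p90(np.arange(1, 11)) == pytest.approx(9.1)
    rng = np.random.default_rng(0)
    v = rng.random(37)
    assert tf.firstorder_p90(v) >= np.median(v)


def test_discretize_levels_range():
    rng = np.random.default_rng(1)
    v = rng.normal(size=200)
    lev = tf.discretize(v, 32)
    assert lev.min() == 1 and lev.max() == 32
    assert set(np.unique(tf.discretize(np.ones(5), 32))) == {1}


# ---------------------------------------------------------------------------
# filters and extraction
# ---------------------------------------------------------------------------


def test_filters_basic_properties():
    rng = np.random.default_rng(0)
    img = rng.normal(size=(3, 16, 16))
    mask = np.ones((3, 16, 16), bool)
    vol = sc.LesionVolume("p", "T1W", img, mask, (4.0, 1.0, 1.0))
    spec = tf.PreprocessSpec(
        filters=("square", "squareroot", "logarithm", "exponential", "gradient",
                 "wavelet-HHH", "lbp-2D", "log-sigma-3"),
        normalize=False,
    )
    stack = tf.preprocess(vol, spec)
    for name, out in stack.items():
        assert out.shape == img.shape, name
        assert np.isfinite(out[mask]).all(), name
    # LoG of a constant image vanishes in the interior
    const = sc.LesionVolume("p", "T1W", np.full((3, 16, 16), 5.0), mask)
    log = tf._filter_image(const.image, "log-sigma-3", (4.0, 1.0, 1.0), mask)
    # the discrete LoG kernel is truncated, so a constant image maps to
    # a small constant offset rather than exact zero
    assert np.allclose(log[1, 6:10, 6:10], log[1, 6, 6], atol=1e-12)
    assert np.abs(log[1, 6:10, 6:10]).max() < 0.01 * 5.0
    # exponential of a constant stays constant
    e = tf._filter_image(const.image, "exponential", (4, 1, 1), mask)
    assert np.allclose(e, e[0, 0, 0])


def test_wavelet_hhh_energy_higher_on_white_noise():
    rng = np.random.default_rng(2)
    noise = rng.normal(size=(4, 16, 16))
    smooth = ndimage.gaussian_filter(noise, 2.0)
    e_noise = (tf._wavelet_band(noise, "HHH") ** 2).mean()
    e_smooth = (tf._wavelet_band(smooth, "HHH") ** 2).mean()
    assert e_noise > e_smooth


def test_log_sigma_larger_than_lesion_skipped():
    rng = np.random.default_rng(0)
    img = rng.normal(size=(1, 12, 12))
    mask = np.zeros((1, 12, 12), bool)
    mask[0, 5:8, 5:8] = True  # 3 mm extent at 1 mm spacing
    vol = sc.LesionVolume("p", "T1W", img, mask, (4.0, 1.0, 1.0))
    with pytest.warns(UserWarning, match="exceeds lesion extent"):
        stack = tf.preprocess(vol, tf.PreprocessSpec(filters=("log-sigma-5",)))
    assert "log-sigma-5" not in stack


def test_extraction_mask_faithful():
    rng = np.random.default_rng(3)
    img = rng.random((2, 10, 10))
    mask = np.zeros((2, 10, 10), bool)
    mask[:, 2:8, 2:8] = True
    spec = tf.PreprocessSpec(filters=(), normalize=False)
    base = tf.extract_region_features({"original": img}, mask, spec)
    img2 = img.copy()
    img2[0, 0, 0] += 100.0  # outside the region
    pert = tf.extract_region_features({"original": img2}, mask, spec)
    assert base == pert


def test_extract_features_counts_and_determinism(small_cohort, t1w_partition):
    _, parts, _ = t1w_partition
    three = {p: parts[p] for p in list(parts)[:3]}
    spec = tf.PreprocessSpec(filters=())
    a = tf.extract_features(small_cohort, {"T1W": three}, spec)
    b = tf.extract_features(small_cohort, {"T1W": three}, spec)
    assert len(a) <= 9  # 3 patients x 1 sequence x 3 regions
    assert a.equals(b)
    assert not a[tf.feature_columns(a)].isna().any().any()


def test_region_floor_drops_small_regions(small_cohort, t1w_partition):
    _, parts, _ = t1w_partition
    one = {p: parts[p] for p in list(parts)[:1]}
    spec = tf.PreprocessSpec(filters=(), region_floor=10**9)
    out = tf.extract_features(small_cohort, {"T1W": one}, spec)
    assert out.empty


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


def icc_closed_form(Y):
    """ANOVA-table hand computation for n subjects x k raters."""
    n, k = Y.shape
    grand = Y.mean()
    msr = k * ((Y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((Y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = (
        ((Y - grand) ** 2).sum()
        - k * ((Y.mean(axis=1) - grand) ** 2).sum()
        - n * ((Y.mean(axis=0) - grand) ** 2).sum()
    ) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def test_icc_hand_worked_table():
    Y = np.array([[9.0, 2.0], [4.0, 5.0], [7.0, 8.0], [1.0, 3.0]])
    assert tf.icc_two_way(Y[:, 0], Y[:, 1]) == pytest.approx(icc_closed_form(Y), rel=1e-12)


def test_icc_against_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    x1 = rng.normal(size=25)
    x2 = x1 + rng.normal(0, 0.3, size=25)
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(25), 2),
            "rater": np.tile([0, 1], 25),
            "y": np.column_stack([x1, x2]).ravel(),
        }
    )
    ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="y")
    icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    assert tf.icc_two_way(x1, x2) == pytest.approx(icc2, abs=1e-10)


def test_icc_filter_report(small_cohort, t1w_partition):
    _, parts, _ = t1w_partition
    sub = {p: parts[p] for p in list(parts)[:4]}
    spec = tf.PreprocessSpec(filters=())
    a = tf.extract_features(small_cohort, {"T1W": sub}, spec)
    # perfect agreement
    rep = tf.icc_filter(a, a.copy())
    assert (rep.loc[~rep["dropped"], "icc"] > 0.999).all()
    assert rep.attrs["model"].startswith("two-way mixed")
    # large independent noise destroys agreement
    rng = np.random.default_rng(0)
    b = a.copy()
    feats = tf.feature_columns(a)
    b[feats] = b[feats] + rng.normal(0, 100, size=b[feats].shape) * b[feats].std().to_numpy()
    rep2 = tf.icc_filter(a, b)
    assert (rep2.loc[~rep2["dropped"], "icc"].abs() < 0.5).all()
    assert not rep2["retained"].any()


def test_icc_repeat_extraction_via_mask_jitter(small_cohort, t1w_partition):
    """Mask perturbation emulates a second reader; most features stay reliable."""
    _, parts, _ = t1w_partition
    sub = {p: parts[p] for p in list(parts)[:6]}
    spec = tf.PreprocessSpec(filters=())
    a = tf.extract_features(small_cohort, {"T1W": sub}, spec)
    jittered = {}
    import dataclasses

    for i, (pid, part) in enumerate(sub.items()):
        vol = small_cohort.volume(pid, "T1W")
        newmask = tf.perturb_mask(vol.mask, seed=i)
        lab = part.labels.copy()
        lab[~newmask] = 0
        grown = newmask & (part.labels == 0)
        lab[grown] = 1  # grown voxels join the marginal habitat
        jittered[pid] = dataclasses.replace(part, labels=lab)
    b = tf.extract_features(small_cohort, {"T1W": jittered}, spec)
    rep = tf.icc_filter(a, b)
    ok = rep.loc[~rep["dropped"], "icc"]
    # the jitter emulation must produce informative reliability variation:
    # some features are robust to a 1-voxel contour change, others (e.g.
    # range-sensitive first-order features once background voxels slip in)
    # are not -- which is exactly what the ICC filter is for
    assert 0.1 < (ok > 0.8).mean() < 0.95
    assert rep["retained"].any() and not rep["retained"].all()
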