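"""Brute-force reference implementations used as independent oracles.

Everything here is deliberately written as plain loops / enumeration,
independent of the package's vectorized code paths.
"""

import itertools
import math

import numpy as np

OFFSETS_3D = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]


def brute_entropy(img, mask, w, bins):
    lo, hi = img[mask].min(), img[mask].max()
    if hi > lo:
        idx = np.minimum(((img - lo) / (hi - lo) * bins), bins - 1).astype(int)
    else:
        idx = np.zeros(img.shape, int)
    half = w // 2
    H = np.full(img.shape, np.nan)
    nz, ny, nx = img.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                ys = slice(max(0, y - half), min(ny, y + half + 1))
                xs = slice(max(0, x - half), min(nx, x + half + 1))
                vals = idx[z][ys, xs][mask[z][ys, xs]]
                counts = np.bincount(vals, minlength=bins).astype(float)
                p = counts[counts > 0] / counts.sum()
                H[z, y, x] = float(-(p * np.log2(p)).sum())
    return H


def brute_ch(X, labels):
    grand = X.mean(axis=0)
    B = W = 0.0
    for u in set(labels):
        pts = X[labels == u]
        c = pts.mean(axis=0)
        B += len(pts) * ((c - grand) ** 2).sum()
        W += ((pts - c) ** 2).sum()
    K, N = len(set(labels)), len(X)
    return (B / (K - 1)) / (W / (N - K))


def brute_silhouette(X, labels):
    vals = []
    for i in range(len(X)):
        d = np.sqrt(((X - X[i]) ** 2).sum(axis=1))
        same = labels == labels[i]
        if same.sum() == 1:
            vals.append(0.0)
            continue
        a = d[same].sum() / (same.sum() - 1)
        b = min(d[labels == u].mean() for u in set(labels) if u != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def _brute_glcm(lev, mask, n_levels):
    mats = []
    nz, ny, nx = lev.shape
    for dz, dy, dx in OFFSETS_3D:
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


def brute_iv(lev, mask, n_levels):
    vals = []
    for P in _brute_glcm(lev, mask, n_levels):
        s = 0.0
        for i in range(n_levels):
            for j in range(n_levels):
                if i != j:
                    s += P[i, j] / (i - j) ** 2
        vals.append(s)
    return float(np.mean(vals))


def brute_mcc(lev, mask, n_levels):
    vals = []
    for P in _brute_glcm(lev, mask, n_levels):
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
                Q[i, j] = sum(P[i, k] * P[j, k] / (px[i] * px[k]) for k in range(m))
        ev = sorted(np.real(np.linalg.eigvals(Q)))
        vals.append(math.sqrt(min(max(ev[-2], 0.0), 1.0)))
    return float(np.mean(vals))


def brute_dnn(lev, mask, alpha=0.0):
    nz, ny, nx = lev.shape
    deps = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                d = 1
                for dz, dy, dx in OFFSETS_3D:
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


def brute_sae(lev, mask):
    sizes = []
    visited = np.zeros(lev.shape, bool)
    offs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in map(tuple, np.argwhere(mask)):
        if visited[start]:
            continue
        g = lev[start]
        stack = [start]
        visited[start] = True
        size = 0
        while stack:
            v = stack.pop()
            size += 1
            for o in offs:
                w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= w[i] < lev.shape[i] for i in range(3)):
                    if mask[w] and not visited[w] and lev[w] == g:
                        visited[w] = True
                        stack.append(w)
        sizes.append(size)
    sizes = np.array(sizes, float)
    return float((1.0 / sizes**2).sum() / len(sizes))


def brute_sre(lev, mask):
    nz, ny, nx = lev.shape
    vals = []
    for dz, dy, dx in OFFSETS_3D:
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


def brute_p90(values):
    v = np.sort(np.asarray(values, float))
    h = 0.9 * (len(v) - 1)
    lo = int(np.floor(h))
    return float(v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo]))


def brute_icc(x1, x2):
    Y = np.column_stack([x1, x2]).astype(float)
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


def brute_u_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating label assignments."""
    from scipy.stats import mannwhitneyu

    u_obs = mannwhitneyu(x[y == 1], x[y == 0]).statistic
    n1 = int(y.sum())
    mu = n1 * (len(y) - n1) / 2
    us = []
    for pos in itertools.combinations(range(len(y)), n1):
        yy = np.zeros(len(y), int)
        yy[list(pos)] = 1
        us.append(mannwhitneyu(x[yy == 1], x[yy == 0]).statistic)
    us = np.array(us)
    return float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12))


def brute_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_youden_j(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    uniq = np.unique(s)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    best = -np.inf
    for c in cands:
        pred = s >= c
        sen = (pred & (y == 1)).sum() / (y == 1).sum()
        spe = (~pred & (y == 0)).sum() / (y == 0).sum()
        best = max(best, sen + spe - 1)
    return float(best)


def brute_auprc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    area = 0.0
    prev_recall = 0.0
    for thr in sorted(np.unique(s), reverse=True):
        pred = s >= thr
        tp = (pred & (y == 1)).sum()
        precision = tp / pred.sum()
        recall = tp / y.sum()
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return float(area)


def brute_nb(probs, labels, pt):
    p = np.asarray(probs, float)
    y = np.asarray(labels, int)
    pred = p >= pt
    tp = (pred & (y == 1)).sum()
    fp = (pred & (y == 0)).sum()
    n = len(y)
    return float(tp / n - fp / n * pt / (1 - pt))


def brute_shapley_linear(w, b, x, bg_mean):
    p = len(w)
    phi = np.zeros(p)
    for f in range(p):
        others = [j for j in range(p) if j != f]
        for r in range(len(others) + 1):
            for S in itertools.combinations(others, r):
                weight = (
                    math.factorial(len(S))
                    * math.factorial(p - len(S) - 1)
                    / math.factorial(p)
                )

                def val(coal):
                    z = np.array([x[j] if j in coal else bg_mean[j] for j in range(p)])
                    return float(np.dot(w, z) + b)

                phi[f] += weight * (val(set(S) | {f}) - val(set(S)))
    return phi
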