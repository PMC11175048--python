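"""Independent reference implementations used only to check the package.

Everything here is deliberately written the slow, obvious way (loops,
normal equations, exhaustive search) so that agreement with the package is
meaningful.
"""

import numpy as np


def pearson_r(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def sd_of_sds(values):
    """Two-pass sd-over-wavelengths of the per-wavelength replicate sd."""
    values = np.asarray(values, dtype=float)
    n_rep, n_wl = values.shape
    per_wl = np.empty(n_wl)
    for j in range(n_wl):
        col = values[:, j]
        m = col.mean()
        per_wl[j] = np.sqrt(np.sum((col - m) ** 2) / (n_rep - 1))
    m = per_wl.mean()
    return float(np.sqrt(np.sum((per_wl - m) ** 2) / (n_wl - 1)))


def natural_cubic_spline(x, y, xq):
    """Natural cubic spline by solving the tridiagonal second-derivative
    system with a dense solver."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    h = np.diff(x)
    A = np.zeros((n, n))
    b = np.zeros(n)
    A[0, 0] = A[-1, -1] = 1.0
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        b[i] = 3 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    c = np.linalg.solve(A, b)
    out = np.empty(len(xq))
    for k, q in enumerate(np.asarray(xq, dtype=float)):
        i = min(max(np.searchsorted(x, q) - 1, 0), n - 2)
        dx = q - x[i]
        bi = (y[i + 1] - y[i]) / h[i] - h[i] * (2 * c[i] + c[i + 1]) / 3
        di = (c[i + 1] - c[i]) / (3 * h[i])
        out[k] = y[i] + bi * dx + c[i] * dx**2 + di * dx**3
    return out


def sliding_polyfit(y, window, polyorder):
    """Savitzky-Golay by explicit local polynomial fits (interior points)."""
    y = np.asarray(y, dtype=float)
    half = window // 2
    out = y.copy()
    x_local = np.arange(-half, half + 1, dtype=float)
    for i in range(half, len(y) - half):
        coeffs = np.polyfit(x_local, y[i - half : i + half + 1], polyorder)
        out[i] = np.polyval(coeffs, 0.0)
    return out


def kennard_stone_bruteforce(X, ids, n_select):
    """O(n^2 k) max-min selection with explicit loops and id tie-breaks."""
    X = np.asarray(X, dtype=float)
    ids = list(ids)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(np.sum((X[i] - X[j]) ** 2))
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((i, j), key=lambda k: str(ids[k]))
            key = (-d[i, j], str(ids[a]), str(ids[b]))
            if best is None or key < best[0]:
                best = (key, [a, b])
    chosen = best[1][:n_select]
    while len(chosen) < n_select:
        cands = [i for i in range(n) if i not in chosen]
        keyed = sorted(
            cands, key=lambda i: (-min(d[i, j] for j in chosen), str(ids[i]))
        )
        chosen.append(keyed[0])
    return [ids[i] for i in chosen]


def ols_predict(X_train, y_train, X_test):
    """Least-squares (minimum-norm) linear fit on centred data."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    xm = X_train.mean(axis=0)
    ym = y_train.mean()
    beta, *_ = np.linalg.lstsq(X_train - xm, y_train - ym, rcond=None)
    return (np.asarray(X_test, dtype=float) - xm) @ beta + ym


def wilks_lambda_1d(scores_a, scores_b):
    """Closed-form one-dimensional Wilk's lambda: SSW / (SSW + SSB)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    grand = np.concatenate([a, b]).mean()
    ssw = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
    ssb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    return ssw / (ssw + ssb)
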