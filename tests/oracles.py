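"""Independent test oracles, kept free of the implementation paths they check."""

import numpy as np
from scipy import integrate, optimize

from mmscreen.doseresponse import ll4


def dss_quadrature_oracle(b, c, d, e, lo=1.0, hi=1e4, t=10.0):
    """Sensitivity score by adaptive quadrature with kink isolation.

    Integrates 100 - max(clip(v, 0, 100), t) over log10 dose, splitting the
    interval at every crossing of the threshold and the clipping bounds so
    each quad panel is smooth.
    """
    x_min, x_max = np.log10(lo), np.log10(hi)

    def integrand(x):
        v = np.clip(ll4(10.0**x, b, c, d, e), 0.0, 100.0)
        return 100.0 - np.maximum(v, t)

    pts = []
    for target in (t, 0.0, 100.0):
        def f(x, target=target):
            return ll4(10.0**x, b, c, d, e) - target

        xs = np.linspace(x_min, x_max, 2001)
        fs = f(xs)
        for i in range(2000):
            if fs[i] * fs[i + 1] < 0:
                pts.append(float(optimize.brentq(f, xs[i], xs[i + 1])))
    pts = sorted(set([x_min, x_max] + pts))
    area = 0.0
    for a, bnd in zip(pts[:-1], pts[1:]):
        val, _ = integrate.quad(integrand, a, bnd, epsabs=1e-13,
                                epsrel=1e-13, limit=200)
        area += val
    return 100.0 * area / ((100.0 - t) * (x_max - x_min))


def grid_oracle_2x2(X, Y, lam, leaf_w, group_w, lo=-2.0, hi=2.0, n=101):
    """Brute-force minimum of the 2-feature/2-drug tree-lasso objective.

    Scans the n^4 grid of coefficient matrices in memory-bounded slices
    (vectorized over the second feature row for each fixed first row) and
    returns the best objective found, on centered data, with penalty
    leaf_w * sum|B| + group_w * sum of per-feature row norms.
    """
    g = np.linspace(lo, hi, n)
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    tail = np.stack(np.meshgrid(g, g, indexing="ij"), -1).reshape(-1, 2)
    B = np.empty((tail.shape[0], 2, 2))
    B[:, 1, :] = tail
    best = np.inf
    for b11 in g:
        B[:, 0, 0] = b11
        for b12 in g:
            B[:, 0, 1] = b12
            resid = np.einsum("nf,kfd->knd", Xc, B) - Yc
            ls = 0.5 * np.sum(resid**2, axis=(1, 2))
            pen = leaf_w * np.abs(B).sum(axis=(1, 2)) + group_w * np.sqrt(
                (B**2).sum(axis=2)
            ).sum(axis=1)
            best = min(best, float(np.min(ls + lam * pen)))
    return best


def welch_oracle(a, b):
    """Welch statistic, Welch-Satterthwaite df, and two-sided p by formula."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va = np.sum((a - a.mean()) ** 2) / (a.size - 1)
    vb = np.sum((b - b.mean()) ** 2) / (b.size - 1)
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / a.size) ** 2 / (a.size - 1)
                   + (vb / b.size) ** 2 / (b.size - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, df, p


def pearson_p_oracle(x, y):
    """Two-sided p for Pearson r via the exact t transform with n-2 df."""
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    r = float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return r, float(2.0 * tdist.sf(abs(t), n - 2))
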