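"""Independent brute-force / closed-form oracles used to cross-check the
package's statistical routines.  These deliberately avoid the code paths
they validate."""

import math

import numpy as np
import scipy.stats as sstats


def bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg: sort, p*m/i, cumulative min from the
    largest rank."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def pooled_t_oracle(x, y):
    """Textbook pooled-variance two-sample t with the t CDF."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * sstats.t.sf(abs(t), nx + ny - 2)
    return t, p


def shapiro3_oracle(x):
    """Closed-form Shapiro-Wilk W at n=3:
    W = (a1*(x(3)-x(1)))^2 / sum((x-mean)^2) with a1 = 1/sqrt(2)."""
    x = np.asarray(x, float)
    s = np.sort(x)
    return ((s[2] - s[0]) / math.sqrt(2)) ** 2 / np.sum((x - x.mean()) ** 2)


def spearman_oracle(x, y):
    """Pearson correlation of midranks with the t-approximation p-value."""
    rx, ry = sstats.rankdata(x), sstats.rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    n = len(x)
    if abs(rho) >= 1:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    return rho, 2 * sstats.t.sf(abs(t), n - 2)


def ols_oracle(x, y):
    """Closed-form normal equations for slope and intercept."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    return slope, y.mean() - slope * x.mean()
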