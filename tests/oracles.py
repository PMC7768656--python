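"""Independent brute-force oracles used to validate the implementation.

These are deliberately naive (loops, scipy distribution objects, explicit
enumeration) and share no code with the package internals.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def logrank_brute_force(time, event, in_group1):
    """Two-group log-rank via explicit hypergeometric moments per event time.

    At each distinct time with d events, the number of group-1 events among d
    draws from a risk pool of n with n1 group-1 members is hypergeometric;
    sum observed-minus-mean and the variances, then chi-square(1).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    g1 = np.asarray(in_group1, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        h = stats.hypergeom(n, n1, d)
        o_minus_e += d1 - h.mean()
        v = h.var()
        var += 0.0 if np.isnan(v) else v  # risk set of 1: no variance
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return chi2, float(stats.chi2.sf(chi2, 1))


def fisher_exact_enumeration(table):
    """Two-sided Fisher p by enumerating all 2x2 tables with the same margins."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def gamma_loglik(x, shape, rate):
    return float(np.sum(stats.gamma.logpdf(x, a=shape, scale=1.0 / rate)))


def gamma_mle_grid(x, k_range, rate_range, n_grid=200):
    """Coarse grid maximization of the Gamma log-likelihood."""
    best = (None, None, -np.inf)
    for k in np.linspace(*k_range, n_grid):
        for r in np.linspace(*rate_range, n_grid):
            ll = gamma_loglik(x, k, r)
            if ll > best[2]:
                best = (k, r, ll)
    return best


def km_by_hand(time, event):
    """Product-limit estimator as an explicit loop; returns (times, S)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s = 1.0
    out_t, out_s = [], []
    for t in sorted(set(time[event == 1])):
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)
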