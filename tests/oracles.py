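"""Independent brute-force reference implementations used by the tests.

Everything here is written as plainly as possible (explicit loops, direct
formula transcription) and stays independent of the code paths it checks.
"""

import itertools
import math

import numpy as np
from scipy import stats

CLIP = 0.999999


def pcit_mask_bruteforce(R):
    """Trio-enumeration PCIT: eliminate (x,y) if some z dominates it."""
    n = R.shape[0]
    sig = np.ones((n, n), dtype=bool)
    np.fill_diagonal(sig, False)
    c = np.clip(R, -CLIP, CLIP)

    def pc(a, b, d):
        return (a - b * d) / math.sqrt((1 - b * b) * (1 - d * d))

    for x, y, z in itertools.combinations(range(n), 3):
        rxy, rxz, ryz = R[x, y], R[x, z], R[y, z]
        if rxy == 0 or rxz == 0 or ryz == 0:
            continue
        cxy, cxz, cyz = c[x, y], c[x, z], c[y, z]
        pxy = pc(cxy, cxz, cyz)
        pxz = pc(cxz, cxy, cyz)
        pyz = pc(cyz, cxy, cxz)
        eps = (pxy / cxy + pxz / cxz + pyz / cyz) / 3.0
        checks = [
            ((x, y), rxy, rxz, ryz),
            ((x, z), rxz, rxy, ryz),
            ((y, z), ryz, rxy, rxz),
        ]
        for (a, b), direct, r1, r2 in checks:
            if abs(direct) < abs(eps * r1) and abs(direct) < abs(eps * r2):
                sig[a, b] = sig[b, a] = False
    return sig


def nb_exact_pvalue_bruteforce(counts_a, counts_b, size_factors_a, size_factors_b, alpha):
    """Full enumeration of the conditioned NB exact test for one gene."""
    k_a, k_b = float(np.sum(counts_a)), float(np.sum(counts_b))
    k_s = int(round(k_a + k_b))
    if k_s == 0:
        return 1.0
    all_counts = np.concatenate([counts_a, counts_b]).astype(float)
    all_sf = np.concatenate([size_factors_a, size_factors_b]).astype(float)
    q0 = float(np.mean(all_counts / all_sf))

    def group_prob(k, sf):
        mean = q0 * np.sum(sf)
        var = q0 * np.sum(sf) + alpha * q0**2 * np.sum(np.asarray(sf) ** 2)
        if var > mean:
            size = mean**2 / (var - mean)
            return stats.nbinom.pmf(k, size, size / (size + mean))
        return stats.poisson.pmf(k, mean)

    probs = np.array([group_prob(a, size_factors_a) * group_prob(k_s - a, size_factors_b)
                      for a in range(k_s + 1)])
    observed = group_prob(k_a, size_factors_a) * group_prob(k_b, size_factors_b)
    return min(1.0, float(probs[probs <= observed * (1 + 1e-7)].sum() / probs.sum()))


def bh_stepup_bruteforce(pvalues):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adj[idx] = running_min
    return np.minimum(adj, 1.0)


def hypergeom_upper_tail_bruteforce(N, K, n, x):
    """P(X >= x) for X ~ Hypergeometric(N, K, n) by direct pmf summation."""
    total = math.comb(N, n)
    acc = 0
    for k in range(x, min(K, n) + 1):
        if n - k <= N - K:
            acc += math.comb(K, k) * math.comb(N - K, n - k)
    return acc / total


def welch_t_bruteforce(a, b):
    """Welch statistic, Welch-Satterthwaite df and two-sided p, by formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p
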