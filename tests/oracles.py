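"""Independent brute-force oracles for the summary statistics.

Everything here is written from the definitions by exhaustive enumeration
(pairs of haplotypes, sites, genotype tables) and stays independent of the
implementations in :mod:`sweepabc.sumstats`.
"""

import itertools

import numpy as np


def pi_bruteforce(hap):
    """Mean pairwise differences by enumerating all haplotype pairs."""
    n = hap.shape[0]
    tot = 0
    for i, j in itertools.combinations(range(n), 2):
        tot += int((hap[i] != hap[j]).sum())
    return tot / (n * (n - 1) / 2)


def watterson_bruteforce(hap):
    n, s = hap.shape
    S = sum(1 for j in range(s) if 0 < hap[:, j].sum() < n)
    return S / sum(1.0 / i for i in range(1, n))


def tajimas_d_bruteforce(hap):
    """Direct evaluation of the 1989 constants a1,a2,b1,b2,c1,c2,e1,e2."""
    n, s = hap.shape
    S = sum(1 for j in range(s) if 0 < hap[:, j].sum() < n)
    if S == 0:
        raise ZeroDivisionError("undefined for S = 0")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi_bruteforce(hap) - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def fay_wu_h_bruteforce(hap):
    """θ_π − θ_H summed site by site over segregating sites."""
    n, s = hap.shape
    h = 0.0
    for j in range(s):
        i = int(hap[:, j].sum())
        if 0 < i < n:
            h += 2.0 * i * (n - i) / (n * (n - 1))
            h -= 2.0 * i * i / (n * (n - 1))
    return h


def wc_theta_bruteforce(genotype_counts):
    """Weir & Cockerham (1984) θ̂ for two populations, straight from the
    published variance-component formulas."""
    (a0, b0, c0), (a1, b1, c1) = genotype_counts
    n1, n2 = a0 + b0 + c0, a1 + b1 + c1
    p1 = (b0 + 2 * c0) / (2 * n1)
    p2 = (b1 + 2 * c1) / (2 * n2)
    h1, h2 = b0 / n1, b1 / n2
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a / (a + b + c)


def reynolds_theta_bruteforce(n1, d1, n2, d2):
    """Reynolds-Weir-Cockerham (1983) haploid-sample θ̂."""
    p1, p2 = d1 / n1, d2 / n2
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
    return a / (a + b)


def ehh_bruteforce(carriers, cols):
    """EHH by enumerating all carrier pairs over the given columns."""
    k = carriers.shape[0]
    ident = 0
    for i, j in itertools.combinations(range(k), 2):
        if (carriers[i, cols] == carriers[j, cols]).all():
            ident += 1
    return ident / (k * (k - 1) / 2)


def ihh_bruteforce(sample, pop, core, allele, gmap, truncation=0.05):
    """Trapezoid iHH built from the pairwise EHH oracle, one site at a
    time, including the closing below-threshold trapezoid; extends to the
    region edge with the last EHH value when never truncated."""
    hap = sample.haplotypes_of(pop)
    car = hap if allele is None else hap[hap[:, core] == allele]
    g = np.atleast_1d(gmap.genetic_position(sample.positions))
    total = 0.0
    for direction in (+1, -1):
        cols = (range(core + 1, sample.n_sites) if direction > 0
                else range(core - 1, -1, -1))
        # EHH at the core includes the core column itself
        e_prev, g_prev = ehh_bruteforce(car, [core]), g[core]
        if e_prev < truncation:
            continue
        truncated = False
        for col in cols:
            span = list(range(min(core, col), max(core, col) + 1))
            e = ehh_bruteforce(car, span)
            total += 0.5 * (e_prev + e) * abs(g[col] - g_prev)
            e_prev, g_prev = e, g[col]
            if e < truncation:
                truncated = True
                break
        if not truncated:
            edge = sample.region_length if direction > 0 else 0.0
            total += e_prev * abs(float(gmap.genetic_position(edge)) - g_prev)
    return total


def pls_nipals_oracle(X, Y, n_components):
    """Textbook NIPALS PLS2: returns the X-score matrix T.

    Deflation of X only, scores normalised like scikit-learn's
    PLSRegression (unit-norm weights).
    """
    X = np.array(X, float)
    Y = np.array(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    T = np.zeros((X.shape[0], n_components))
    Xk = X - X.mean(axis=0)
    Yk = Y - Y.mean(axis=0)
    for k in range(n_components):
        u = Yk[:, np.argmax(Yk.var(axis=0))].copy()
        for _ in range(500):
            w = Xk.T @ u
            w /= np.linalg.norm(w)
            t = Xk @ w
            q = Yk.T @ t / (t @ t)
            u_new = Yk @ q / (q @ q)
            if np.linalg.norm(u_new - u) < 1e-12 * np.linalg.norm(u_new):
                u = u_new
                break
            u = u_new
        p = Xk.T @ t / (t @ t)
        Xk = Xk - np.outer(t, p)
        Yk = Yk - np.outer(t, q)
        T[:, k] = t
    return T
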