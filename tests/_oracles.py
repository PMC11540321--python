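"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (explicit
pair enumeration, raw indicator-variable ANOVA, exact Markov chains) and
never calls the package's own estimators.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse, stats
from scipy.sparse.linalg import LinearOperator, eigs


def pi_bruteforce(values) -> float:
    """Unbiased diversity: fraction of differing unordered pairs, times 1
    (states differ by one site) — enumerated explicitly."""
    v = list(values)
    n = len(v)
    diff = sum(
        1 for i in range(n) for j in range(i + 1, n) if v[i] != v[j]
    )
    # the mean over unordered pairs equals (1 - sum x^2) * n/(n-1)
    return diff / (n * (n - 1) / 2)


def dxy_bruteforce(a, b) -> float:
    a, b = list(a), list(b)
    return sum(1 for x in a for y in b if x != y) / (len(a) * len(b))


def fst_anova_bruteforce(counts) -> float:
    """Weir-Cockerham theta from raw 0/1 indicator vectors, per allele,
    combined ratio-of-sums over alleles."""
    counts = np.asarray(counts, dtype=int)
    r, n_all = counts.shape
    n_i = counts.sum(axis=1)
    n_tot = n_i.sum()
    n_c = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
    num = den = 0.0
    for a in range(n_all):
        pops = [
            np.concatenate([np.ones(counts[i, a]), np.zeros(n_i[i] - counts[i, a])])
            for i in range(r)
        ]
        ybar = np.concatenate(pops).mean()
        ssb = sum(len(y) * (y.mean() - ybar) ** 2 for y in pops)
        ssw = sum(((y - y.mean()) ** 2).sum() for y in pops)
        msp = ssb / (r - 1)
        msg = ssw / (n_tot - r)
        num += msp - msg
        den += msp + (n_c - 1) * msg
    return num / den if den != 0 else float("nan")


def r2_bruteforce(x, y) -> float:
    """Squared Pearson correlation from raw sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx, syy = (x**2).sum(), (y**2).sum()
    num = n * sxy - sx * sy
    den = np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
    return (num / den) ** 2


# ---------------------------------------------------------------------------
# exact single-locus Markov chains for the neutral island model


def _post_mutation_freq(p: np.ndarray, mu: float) -> np.ndarray:
    return p * (1 - mu) + (1 - p) * mu


def single_deme_equilibrium_H(N: int, mu: float) -> float:
    """Expected census heterozygosity 2p(1-p)*2N/(2N-1) at the stationary
    distribution of a diallelic Wright-Fisher deme with symmetric flip
    mutation, by direct eigenvector computation."""
    K = 2 * N + 1
    p = np.arange(K) / (2 * N)
    x = _post_mutation_freq(p, mu)
    T = np.empty((K, K))
    for i in range(K):
        T[i] = stats.binom.pmf(np.arange(K), 2 * N, x[i])
    w, v = np.linalg.eig(T.T)
    k = np.argmin(np.abs(w - 1.0))
    statd = np.real(v[:, k])
    statd = np.abs(statd) / np.abs(statd).sum()
    H = 2 * p * (1 - p) * (2 * N) / (2 * N - 1)
    return float(statd @ H)


def two_deme_equilibrium_H(N: int, m: float, mu: float) -> float:
    """Expected within-deme census heterozygosity at stationarity for two
    demes of N diploids exchanging migrants at backward rate m, with
    symmetric flip mutation at rate mu.

    State = allele-1 counts (i, j) in the two demes; one generation mixes
    frequencies by migration, mutates, and resamples each deme
    Binomial(2N, .). The stationary distribution is found with an Arnoldi
    eigensolver on the transition operator.
    """
    n2 = 2 * N
    K = n2 + 1
    S = K * K
    p = np.arange(K) / n2
    P1, P2 = np.meshgrid(p, p, indexing="ij")
    x1 = _post_mutation_freq((1 - m) * P1 + m * P2, mu).ravel()
    x2 = _post_mutation_freq((1 - m) * P2 + m * P1, mu).ravel()
    kk = np.arange(K)
    A = stats.binom.pmf(kk[None, :], n2, x1[:, None])  # (S, K)
    B = stats.binom.pmf(kk[None, :], n2, x2[:, None])

    def step(v):
        v = np.asarray(v).ravel()
        out = A.T @ (v[:, None] * B)  # (K, K): out[i', j']
        return out.ravel()

    op = LinearOperator((S, S), matvec=step, dtype=float)
    v0 = np.full(S, 1.0 / S)
    w, vec = eigs(op, k=1, which="LM", v0=v0, maxiter=5000, tol=1e-10)
    statd = np.abs(np.real(vec[:, 0]))
    statd /= statd.sum()
    H = (2 * P1 * (1 - P1) * n2 / (n2 - 1)).ravel()  # deme 1; symmetric
    return float(statd @ H)
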