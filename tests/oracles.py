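"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from first principles (explicit
2x2 matrix inverses, log-gamma densities, batched label permutations)
rather than calling the code under test.
"""

import numpy as np
from math import exp, lgamma, log


def hotelling_brute(xa, xb):
    """Direct evaluation of the two-sample T^2 matrix formula with an
    explicit adjugate/determinant 2x2 inverse."""
    xa = np.asarray(xa, float)
    xb = np.asarray(xb, float)
    n1, n2 = len(xa), len(xb)
    p = xa.shape[1]
    d = xa.mean(0) - xb.mean(0)
    ca = xa - xa.mean(0)
    cb = xb - xb.mean(0)
    S = (ca.T @ ca + cb.T @ cb) / (n1 + n2 - 2)
    if p == 2:
        det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
        Sinv = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det
    else:
        Sinv = np.linalg.inv(S)
    t2 = n1 * n2 / (n1 + n2) * d @ Sinv @ d
    df1, df2 = p, n1 + n2 - p - 1
    f = t2 * df2 / (df1 * (n1 + n2 - 2))
    return t2, f, df1, df2


def f_density(x, d1, d2):
    """F density from the log-gamma form (no scipy.stats)."""
    if x <= 0:
        return 0.0
    lb = lgamma((d1 + d2) / 2) - lgamma(d1 / 2) - lgamma(d2 / 2)
    return exp(
        lb + (d1 / 2) * log(d1 / d2) + (d1 / 2 - 1) * log(x)
        - ((d1 + d2) / 2) * log(1 + d1 * x / d2)
    )


def _batch_t2(X1, X2):
    """T^2 for a batch of bivariate two-group datasets.

    ``X1``: (B, n1, 2), ``X2``: (B, n2, 2).  Returns (B,) statistics.
    """
    n1, n2 = X1.shape[1], X2.shape[1]
    m1 = X1.mean(axis=1)
    m2 = X2.mean(axis=1)
    c1 = X1 - m1[:, None, :]
    c2 = X2 - m2[:, None, :]
    S = (
        np.einsum("bij,bik->bjk", c1, c1) + np.einsum("bij,bik->bjk", c2, c2)
    ) / (n1 + n2 - 2)
    d = m1 - m2
    det = S[:, 0, 0] * S[:, 1, 1] - S[:, 0, 1] * S[:, 1, 0]
    quad = (
        S[:, 1, 1] * d[:, 0] ** 2
        - 2.0 * S[:, 0, 1] * d[:, 0] * d[:, 1]
        + S[:, 0, 0] * d[:, 1] ** 2
    ) / det
    return n1 * n2 / (n1 + n2) * quad


def null_sampling_p(t2_obs, n1, n2, n_rep, rng, chunk=20000):
    """Monte-Carlo estimate of P(T^2 >= t2_obs) under the bivariate
    Gaussian null, by simulating ``n_rep`` fresh two-group datasets.

    Under the null the sampling distribution of T^2 is exact (scaled F),
    so this estimator converges to the parametric p-value and its only
    error is binomial Monte-Carlo noise.
    """
    hits = 0
    done = 0
    while done < n_rep:
        b = min(chunk, n_rep - done)
        X1 = rng.standard_normal((b, n1, 2))
        X2 = rng.standard_normal((b, n2, 2))
        hits += int(np.count_nonzero(_batch_t2(X1, X2) >= t2_obs))
        done += b
    return hits / n_rep


def permutation_p(xa, xb, n_perm, rng, chunk=20000):
    """Label-permutation p-value for the two-sample T^2 (conditional on
    the observed data), estimated from ``n_perm`` random relabelings."""
    X = np.vstack([np.asarray(xa, float), np.asarray(xb, float)])
    n1 = len(xa)
    n = len(X)
    t2_obs = _batch_t2(X[None, :n1, :], X[None, n1:, :])[0]
    hits = 0
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        Xp = X[idx]
        t2 = _batch_t2(Xp[:, :n1, :], Xp[:, n1:, :])
        hits += int(np.count_nonzero(t2 >= t2_obs - 1e-12))
        done += b
    return (hits + 1) / (n_perm + 1)
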