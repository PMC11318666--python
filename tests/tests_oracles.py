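"""Naive reference implementations used as independent oracles in tests.

Deliberately literal (sets and explicit loops) so they share no code path
with the vectorized package internals they validate.
"""
import numpy as np


def cocc_brute_matrix(A):
    """All-pairs co-clustering coefficients by literal set enumeration."""
    n = len(A)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = {a for a in range(n) if A[i][a]} | {a for a in range(n) if A[j][a]}
            k = len(union)
            if k <= 1:
                continue
            e = sum(1 for a in union for b in union if a < b and A[a][b])
            V[i, j] = V[j, i] = 2.0 * e / (k * (k - 1))
    return V


def resultant_brute(P, D, W, beta, j):
    """Term-by-term weighted-average resultant of one bin."""
    N = len(P)
    total = np.zeros(3)
    wsum = 0.0
    for i in range(N):
        if i == j or not np.isfinite(D[j][i]):
            continue
        diff = np.asarray(P[i]) - np.asarray(P[j])
        d = float(np.sqrt(sum(diff**2)))
        total = total + W[j][i] * (diff / d) * (d - D[j][i])
        wsum += W[j][i]
    if wsum == 0.0:
        return np.zeros(3)
    return total / (wsum * (N - 1) ** beta)


def objective_brute(P, D, W, beta):
    """Sum of brute-force resultant norms over all bins."""
    return sum(
        float(np.sqrt(sum(resultant_brute(P, D, W, beta, j) ** 2)))
        for j in range(len(P))
    )
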