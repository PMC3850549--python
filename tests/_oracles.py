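"""Independent brute-force oracles for the split statistics.

Deliberately naive O(n^2 K) double-loop implementations of the class-vector
variance and the Geary-style autocorrelation statistic, kept free of any
package internals beyond plain numpy, so they can certify the incremental
implementations.
"""

import numpy as np


def dist2(weights, a, b):
    return sum(w * (x - y) ** 2 for w, x, y in zip(weights, a, b))


def brute_variance(weights, Y):
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    mean = Y.mean(axis=0)
    return sum(dist2(weights, Y[i], mean) for i in range(n)) / n


def brute_ssd(weights, Y):
    Y = np.asarray(Y, dtype=float)
    mean = Y.mean(axis=0)
    return sum(dist2(weights, row, mean) for row in Y)


def brute_autocorrelation(weights, Y, W):
    """A_Y via the literal double sums; W is a full symmetric weight matrix
    with zero diagonal."""
    Y = np.asarray(Y, dtype=float)
    W = np.asarray(W, dtype=float)
    n = Y.shape[0]
    ssd = brute_ssd(weights, Y)
    w_sum = W.sum()
    if n < 2 or w_sum <= 0 or ssd <= 1e-12:
        return 0.5
    wd = 0.0
    for i in range(n):
        for j in range(n):
            if W[i, j]:
                wd += W[i, j] * dist2(weights, Y[i], Y[j])
    a = 1.0 - (n - 1) * wd / (4.0 * w_sum * ssd)
    return min(1.0, max(0.0, a))


def random_instance(rng, n_max=30, k_max=10, edge_prob=0.3):
    """A random labelled-network instance: weights, closed-ish bit matrix, W."""
    n = int(rng.integers(2, n_max + 1))
    k = int(rng.integers(1, k_max + 1))
    weights = rng.uniform(0.1, 1.0, size=k)
    Y = (rng.random((n, k)) < rng.uniform(0.2, 0.8)).astype(float)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                w = float(rng.uniform(0.5, 3.0))
                W[i, j] = W[j, i] = w
    return weights, Y, W
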