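"""Shared brute-force oracles, independent of the library implementations."""

import numpy as np


def brute_delong_variance(scores, labels):
    """Structural-component AUC variance by explicit pairwise placement."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    v10 = np.array([np.mean([1.0 if p > q else 0.5 if p == q else 0.0
                             for q in neg]) for p in pos])
    v01 = np.array([np.mean([1.0 if p > q else 0.5 if p == q else 0.0
                             for p in pos]) for q in neg])
    return v10.var(ddof=1) / m + v01.var(ddof=1) / n


def grid_logistic_mle(values, labels, span=6.0):
    """Coarse-to-fine grid maximization of the Bernoulli log-likelihood."""
    values = np.asarray(values, float)
    y = np.asarray(labels, float)

    def ll(b0, b1):
        z = np.clip(b0 + b1 * values, -30, 30)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

    c0, c1, width = 0.0, 0.0, span
    for _ in range(12):
        b0s = np.linspace(c0 - width, c0 + width, 21)
        b1s = np.linspace(c1 - width, c1 + width, 21)
        vals = np.array([[ll(a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        c0, c1 = b0s[i], b1s[j]
        width /= 5.0
    return c0, c1
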