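"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's computational paths:
the exact-test oracle enumerates hypergeometric masses one scipy call at a
time, the HMM oracle sums over all 2^N state paths, and the AUC oracle
compares every positive/negative pair.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy.special import logsumexp
from scipy.stats import hypergeom

from fethmm import LibrarySizes

settings.register_profile(
    "fethmm",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fethmm")


@pytest.fixture
def balanced_sizes() -> LibrarySizes:
    return LibrarySizes(1e8, 1e8, 1e8, 1e8)


def make_table(site_counts: dict[str, tuple]) -> pd.DataFrame:
    """Build a bin-count table from {site_id: (x0, y0, x1, y1) arrays}."""
    frames = []
    for site_id, (x0, y0, x1, y1) in site_counts.items():
        n = len(x0)
        frames.append(
            pd.DataFrame(
                {
                    "site_id": site_id,
                    "bin_index": np.arange(n),
                    "x0": np.asarray(x0, dtype=np.int64),
                    "y0": np.asarray(y0, dtype=np.int64),
                    "x1": np.asarray(x1, dtype=np.int64),
                    "y1": np.asarray(y1, dtype=np.int64),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def fisher_two_tailed_oracle(x0: int, y0: int, x1: int, y1: int) -> float:
    """Minimum-likelihood two-sided exact p by direct enumeration."""
    N = x0 + y0 + x1 + y1
    if N == 0:
        return 1.0
    n = x0 + y0
    K = x0 + x1
    kmin = max(0, n + K - N)
    kmax = min(n, K)
    masses = [float(hypergeom.pmf(k, N, K, n)) for k in range(kmin, kmax + 1)]
    p_obs = masses[x0 - kmin]
    total = sum(m for m in masses if m <= p_obs * (1.0 + 1e-7))
    return min(1.0, total)


def enum_posterior(pi, A, E):
    """gamma, summed xi and log-likelihood by summing all 2^N paths."""
    pi = np.asarray(pi, float)
    A = np.asarray(A, float)
    E = np.asarray(E, float)
    N = E.shape[0]
    gamma = np.zeros((N, 2))
    xi = np.zeros((2, 2))
    total = 0.0
    for path in itertools.product((0, 1), repeat=N):
        p = pi[path[0]] * E[0, path[0]]
        for t in range(1, N):
            p *= A[path[t - 1], path[t]] * E[t, path[t]]
        total += p
        for t, s in enumerate(path):
            gamma[t, s] += p
        for t in range(N - 1):
            xi[path[t], path[t + 1]] += p
    return gamma / total, xi / total, math.log(total)


def logspace_forward_backward(pi, A, E):
    """Log-domain forward-backward: independent of the scaled recursion."""
    pi = np.asarray(pi, float)
    A = np.asarray(A, float)
    logE = np.log(np.asarray(E, float))
    logA = np.log(A, out=np.full_like(A, -np.inf), where=A > 0)
    logpi = np.log(pi, out=np.full_like(pi, -np.inf), where=pi > 0)
    N = logE.shape[0]
    la = np.empty((N, 2))
    la[0] = logpi + logE[0]
    for t in range(1, N):
        la[t] = logE[t] + logsumexp(la[t - 1][:, None] + logA, axis=0)
    lb = np.zeros((N, 2))
    for t in range(N - 2, -1, -1):
        lb[t] = logsumexp(logA + (logE[t + 1] + lb[t + 1])[None, :], axis=1)
    ll = logsumexp(la[-1])
    lg = la + lb - ll
    return np.exp(lg), ll


def auc_pairwise_oracle(scores, labels) -> float:
    """AUC as the fraction of correctly ordered pos/neg pairs, ties 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_hmm_draw(rng):
    """A random valid 2-state parameter set (pi, A, Bernoulli p)."""
    pi1 = rng.uniform(0.05, 0.95)
    d0 = rng.uniform(0.05, 0.95)
    d1 = rng.uniform(0.05, 0.95)
    A = np.array([[d0, 1 - d0], [1 - d1, d1]])
    p = rng.uniform(0.5, 0.99)
    return np.array([1 - pi1, pi1]), A, p


def sample_hmm_chain(rng, n, A, p, pi):
    """Draw hidden states and noisy binary observations."""
    s = np.empty(n, dtype=np.int64)
    s[0] = rng.random() < pi[1]
    for t in range(1, n):
        s[t] = rng.random() < A[s[t - 1], 1]
    flips = rng.random(n) >= p
    obs = np.where(flips, 1 - s, s)
    return s, obs
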