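"""Shared fixtures and independent oracles.

The joint-Gaussian oracle here computes smoother moments and the data
log-likelihood by explicit conditioning of the full 2N-dimensional
Gaussian — brute force, deliberately independent of the recursive
filter/smoother implementation it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from trackem.model import MotionParameters


def joint_gaussian_oracle(y, params: MotionParameters, dt, prior_mean, prior_var):
    """Exact posterior moments of x | y and log p(y) for the linear model.

    Builds the joint covariance of (x_1..x_N) by direct recursion, adds
    measurement noise for y, and conditions.  Returns (posterior mean,
    posterior covariance matrix, log-likelihood).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    a, b = params.a, params.b
    q = max(params.q(dt), 1e-12)
    r = max(params.r, 1e-12)

    mean_x = np.empty(n)
    mean_x[0] = prior_mean
    for k in range(1, n):
        mean_x[k] = a * mean_x[k - 1] + b

    C = np.zeros((n, n))
    C[0, 0] = prior_var
    for k in range(1, n):
        for j in range(k):
            C[k, j] = C[j, k] = a * C[k - 1, j]
        C[k, k] = a * a * C[k - 1, k - 1] + q

    Cyy = C + r * np.eye(n)
    post_mean = mean_x + C @ np.linalg.solve(Cyy, y - mean_x)
    post_cov = C - C @ np.linalg.solve(Cyy, C)
    loglik = float(multivariate_normal(mean_x, Cyy).logpdf(y))
    return post_mean, post_cov, loglik


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
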