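"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (explicit loops, dense joint
covariances, normal equations) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import multivariate_normal


def brute_mvn_loglik(obs, T, s2p, s2s, s2o, x0_var):
    """Log density of the observations under the hierarchical random-walk model,
    evaluated from the explicit dense joint covariance."""
    K = np.array([[x0_var + s2p * min(i, j) for j in range(T)] for i in range(T)])
    sizes = [len(idx) for idx, _ in obs]
    starts = np.concatenate([[0], np.cumsum(sizes)])
    N = starts[-1]
    C = np.zeros((N, N))
    for si, (idx_i, _) in enumerate(obs):
        for sj, (idx_j, _) in enumerate(obs):
            blk = K[np.ix_(idx_i, idx_j)].astype(float).copy()
            if si == sj:
                blk += s2s * np.ones((len(idx_i), len(idx_j))) + s2o * np.eye(len(idx_i))
            C[starts[si]:starts[si + 1], starts[sj]:starts[sj + 1]] = blk
    y = np.concatenate([y for _, y in obs])
    return float(multivariate_normal.logpdf(y, np.zeros(N), C))


def brute_mvn_loglik_mp(obs, T, s2p, s2s, s2o, x0_var, dps=50):
    """Same density evaluated in 50-digit arithmetic (mpmath); immune to the
    conditioning loss of the dense float64 covariance under a diffuse prior."""
    import mpmath as mp

    mp.mp.dps = dps
    K = [[mp.mpf(x0_var) + mp.mpf(s2p) * min(i, j) for j in range(T)] for i in range(T)]
    sizes = [len(idx) for idx, _ in obs]
    starts = np.concatenate([[0], np.cumsum(sizes)])
    N = int(starts[-1])
    C = mp.zeros(N)
    for si, (idx_i, _) in enumerate(obs):
        for sj, (idx_j, _) in enumerate(obs):
            for a, i in enumerate(idx_i):
                for b, j in enumerate(idx_j):
                    v = K[i][j]
                    if si == sj:
                        v = v + mp.mpf(s2s) + (mp.mpf(s2o) if i == j else 0)
                    C[int(starts[si] + a), int(starts[sj] + b)] = v
    y = mp.matrix([float(v) for _, yy in obs for v in yy])
    L = mp.cholesky(C)
    quad = (y.T * mp.lu_solve(C, y))[0]
    logdet = 2 * sum(mp.log(L[i, i]) for i in range(N))
    return float(-mp.mpf(N) / 2 * mp.log(2 * mp.pi) - logdet / 2 - quad / 2)


def brute_posterior(obs, T, s2p, s2s, s2o, x0_var):
    """Smoothing posterior of the latent trajectory by explicit Gaussian conditioning."""
    Kx = np.array([[x0_var + s2p * min(i, j) for j in range(T)] for i in range(T)])
    sizes = [len(idx) for idx, _ in obs]
    starts = np.concatenate([[0], np.cumsum(sizes)])
    N = starts[-1]
    C = np.zeros((N, N))
    cross = np.zeros((T, N))
    for si, (idx_i, _) in enumerate(obs):
        cross[:, starts[si]:starts[si + 1]] = Kx[:, idx_i]
        for sj, (idx_j, _) in enumerate(obs):
            blk = Kx[np.ix_(idx_i, idx_j)].astype(float).copy()
            if si == sj:
                blk += s2s * np.ones((len(idx_i), len(idx_j))) + s2o * np.eye(len(idx_i))
            C[starts[si]:starts[si + 1], starts[sj]:starts[sj + 1]] = blk
    y = np.concatenate([v for _, v in obs])
    sol = np.linalg.solve(C, y)
    mean = cross @ sol
    cov = Kx - cross @ np.linalg.solve(C, cross.T)
    return mean, np.diag(cov)


def kalman_local_level(y, q, r, x0_var):
    """Univariate random-walk-plus-noise Kalman filter + RTS smoother.

    Complete data only. Returns (loglik, smoothed means, smoothed variances).
    """
    T = len(y)
    m_f = np.zeros(T)
    P_f = np.zeros(T)
    m_pred, P_pred = 0.0, x0_var
    ll = 0.0
    for t in range(T):
        S = P_pred + r
        ll += -0.5 * (math.log(2 * math.pi * S) + (y[t] - m_pred) ** 2 / S)
        gain = P_pred / S
        m_f[t] = m_pred + gain * (y[t] - m_pred)
        P_f[t] = (1 - gain) * P_pred
        m_pred, P_pred = m_f[t], P_f[t] + q
    m_s = m_f.copy()
    P_s = P_f.copy()
    for t in range(T - 2, -1, -1):
        A = P_f[t] / (P_f[t] + q)
        m_s[t] = m_f[t] + A * (m_s[t + 1] - m_f[t])
        P_s[t] = P_f[t] + A**2 * (P_s[t + 1] - (P_f[t] + q))
    return ll, m_s, P_s


def loop_weighted_mean_se(values, weights):
    """Weighted mean and SE by explicit summation loops."""
    sw = swx = 0.0
    for x, w in zip(values, weights):
        sw += w
        swx += w * x
    mean = swx / sw
    s = 0.0
    for x, w in zip(values, weights):
        s += (w * (x - mean)) ** 2
    return mean, math.sqrt(s) / sw


def loop_ols_slope(years, values):
    """OLS slope from the normal equations, written out by hand."""
    n = len(years)
    sx = sum(years)
    sy = sum(values)
    sxx = sum(x * x for x in years)
    sxy = sum(x * y for x, y in zip(years, values))
    return (n * sxy - sx * sy) / (n * sxx - sx * sx)
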