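"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's fitting/statistics code paths: the
Weibull likelihood is maximized by iterated grid refinement, the logrank
statistic is recomputed from the hypergeometric definition in a plain loop,
and genotype-class moments come from enumerating the breeding cross.
"""

from __future__ import annotations

import numpy as np


def weibull_loglik_grid(time, event, dose, logk, loglam, beta):
    """Full Weibull PH log-likelihood on a parameter grid (vectorized over
    the grid, looped over mice)."""
    k = np.exp(logk)
    lam = np.exp(loglam)
    ll = np.zeros(np.broadcast_shapes(k.shape, lam.shape, beta.shape))
    for t, d, x in zip(time, event, dose):
        h = np.exp(beta * x) * (t / lam) ** k
        if d:
            ll = ll + np.log(k) - np.log(lam) + (k - 1.0) * (np.log(t) - np.log(lam)) + beta * x
        ll = ll - h
    return ll


def grid_ml(time, event, dose, with_beta, rounds=10, n_grid=25):
    """Iterated grid-search maximum likelihood; returns the maximum
    log-likelihood. Ranges expand if the optimum touches a grid edge."""
    lo = np.array([-2.5, 0.0, -9.0])
    hi = np.array([2.5, 6.0, 9.0])
    best = -np.inf
    for _ in range(rounds):
        gk = np.linspace(lo[0], hi[0], n_grid)
        gl = np.linspace(lo[1], hi[1], n_grid)
        gb = np.linspace(lo[2], hi[2], n_grid) if with_beta else np.array([0.0])
        K, L, B = np.meshgrid(gk, gl, gb, indexing="ij")
        ll = weibull_loglik_grid(time, event, dose, K, L, B)
        idx = np.unravel_index(np.argmax(ll), ll.shape)
        best = max(best, float(ll[idx]))
        centre = np.array([gk[idx[0]], gl[idx[1]], gb[idx[2]] if with_beta else 0.0])
        span = hi - lo
        widths = span / (n_grid - 1)
        edge = (
            idx[0] in (0, n_grid - 1)
            or idx[1] in (0, n_grid - 1)
            or (with_beta and idx[2] in (0, n_grid - 1))
        )
        if edge:
            lo = centre - span * 0.75
            hi = centre + span * 0.75
        else:
            lo = centre - 2.0 * widths
            hi = centre + 2.0 * widths
    return best


def grid_lrt(time, event, dose):
    """LRT statistic from two independent grid-search fits."""
    ll1 = grid_ml(time, event, dose, with_beta=True)
    ll0 = grid_ml(time, event, dose, with_beta=False)
    return max(0.0, 2.0 * (ll1 - ll0))


def logrank_chi2_oracle(time, event, group):
    """Hand-coded Mantel-Cox chi-square (tied-data hypergeometric form)."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event])):
        at = time >= t
        n = at.sum()
        n1 = (at & group).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o_minus_e**2 / var) if var > 0 else 0.0


def logrank_permutation_p(time, event, n_a, n_shuffles, seed):
    """Permutation p of the logrank statistic: first ``n_a`` mice form group
    A; group labels are reshuffled ``n_shuffles`` times."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.zeros(time.size, bool)
    group[:n_a] = True
    obs = logrank_chi2_oracle(time, event, group)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_shuffles):
        g = rng.permutation(group)
        if logrank_chi2_oracle(time, event, g) >= obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_shuffles)


def g3_var_count_moments(n_dams, g3_per_dam, n_loci):
    """Mean and variance of the total VAR-call count over all (G3 mouse,
    locus) cells, from enumerating the backcross: per dam and locus the VAR
    count is Bernoulli(1/2, dam HET) times Binomial(g, 1/4), so per-locus
    counts are overdispersed relative to a plain binomial."""
    g = g3_per_dam
    mean_per_dam = g / 8.0
    var_per_dam = 3.0 * g / 32.0 + g * g / 64.0
    mean = n_dams * n_loci * mean_per_dam
    var = n_dams * n_loci * var_per_dam
    return mean, var
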