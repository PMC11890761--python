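"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from math import sqrt

import numpy as np
import pytest

from rdeep.gaussfit import X_GRID
from rdeep.profiles import MeanProfile, NORM_TOTAL


def gaussian_mixture(peaks, x=X_GRID):
    """Evaluate a sum of (center, amplitude, width) Gaussians."""
    y = np.zeros_like(x, dtype=float)
    for c, a, w in peaks:
        y = y + a * np.exp(-((x - c) ** 2) / (2.0 * w * w))
    return y


def make_mean_profile(peaks, protein_id="P", condition="control", n_replicates=3):
    """Noiseless normalized MeanProfile generated from Gaussian peaks."""
    y = gaussian_mixture(peaks)
    y = y * (NORM_TOTAL / y.sum())
    reps = np.tile(y, (n_replicates, 1))
    return MeanProfile(
        protein_id=protein_id, condition=condition, values=y, replicate_values=reps
    )


def grid_search_gauss_oracle(y, k, center_step=0.5, width_step=0.5):
    """Brute-force sum-of-Gaussians fit: exhaustive (center, width) grid with
    amplitudes solved in closed form by linear least squares.

    Independent of the package's optimizer; used to bound the fit RSS.
    """
    centers = np.arange(1.0, 25.0 + 1e-9, center_step)
    widths = np.arange(0.5, 5.0 + 1e-9, width_step)
    basis = []
    params = []
    for c in centers:
        for w in widths:
            basis.append(np.exp(-((X_GRID - c) ** 2) / (2.0 * w * w)))
            params.append((c, w))
    basis = np.asarray(basis)
    gram = basis @ basis.T
    proj = basis @ y
    yy = float(y @ y)
    best_rss, best = np.inf, None
    if k == 1:
        rss = yy - proj**2 / np.diag(gram)
        i = int(np.argmin(rss))
        return float(rss[i]), [params[i]]
    assert k == 2
    n = len(basis)
    for i in range(n):
        gii, bi = gram[i, i], proj[i]
        for j in range(i + 1, n):
            gjj, gij, bj = gram[j, j], gram[i, j], proj[j]
            det = gii * gjj - gij * gij
            if det <= 1e-12:
                continue
            a1 = (gjj * bi - gij * bj) / det
            a2 = (gii * bj - gij * bi) / det
            if a1 <= 0 or a2 <= 0:
                continue
            rss = yy - (a1 * bi + a2 * bj)
            if rss < best_rss:
                best_rss, best = rss, [params[i], params[j]]
    return float(best_rss), best


def bh_adjust_oracle(pvals):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        val = min(prev, p[idx] * n / rank)
        adj[idx] = val
        prev = val
    return adj


def welch_t_oracle(a, b):
    """Closed-form Welch t statistic, degrees of freedom and two-sided p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2.0 * tdist.sf(abs(t), df)


def best_assignment_oracle(control_centers, rnase_centers):
    """Exhaustive peak assignment minimizing total |distance|."""
    best_cost, best = np.inf, None
    k = min(len(control_centers), len(rnase_centers))
    for c_idx in itertools.permutations(range(len(control_centers)), k):
        for r_idx in itertools.permutations(range(len(rnase_centers)), k):
            cost = sum(
                abs(rnase_centers[r] - control_centers[c])
                for c, r in zip(c_idx, r_idx)
            )
            if cost < best_cost:
                best_cost = cost
                best = dict(zip(c_idx, r_idx))
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(42)
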