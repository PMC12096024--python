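"""Brute-force oracles shared across test modules."""
import itertools

import numpy as np
import scipy.stats as sps


def brute_force_wilcoxon(d) -> float:
    """Exact two-sided signed-rank p-value by enumerating all 2^n sign
    assignments (zeros dropped, midranks for ties)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = np.array([
        np.dot(ranks, signs)
        for signs in itertools.product((0.0, 1.0), repeat=d.size)
    ])
    p_le = np.mean(sums <= w_obs + 1e-9)
    p_ge = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))
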