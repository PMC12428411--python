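"""Independent brute-force oracles used to check the statistical wrappers."""

import itertools

import numpy as np


def mann_whitney_exact_oracle(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration (tie-free samples).

    Enumerates every way of assigning the pooled observations to the two
    groups; U counts (a > b) pairs.  p = 2 * min(P(U' <= u), P(U' >= u)),
    capped at 1.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    u_obs = sum(x > y for x in a for y in b)
    n1 = len(a)
    vals = np.asarray(pooled)
    all_idx = frozenset(range(len(pooled)))
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = vals[list(idx)]
        gb = vals[sorted(all_idx - set(idx))]
        us.append(int((ga[:, None] > gb[None, :]).sum()))
    us = np.array(us)
    cnt_le = (us <= u_obs).sum()
    cnt_ge = (us >= u_obs).sum()
    p = min(1.0, 2.0 * min(cnt_le, cnt_ge) / len(us))
    return float(u_obs), float(p)


def mann_whitney_permutation_oracle(a, b, n_resample=100_000, seed=0) -> float:
    """Monte-Carlo permutation two-sided p for the rank-sum statistic."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = len(a)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(b) / 2
    rng = np.random.default_rng(seed)
    # vectorised resampling of the rank sum
    idx = np.argsort(rng.random((n_resample, len(pooled))), axis=1)[:, :n1]
    u_null = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2
    return float(np.mean(np.abs(u_null - mu) >= abs(u_obs - mu) - 1e-12))
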