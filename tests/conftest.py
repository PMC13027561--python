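import warnings

import numpy as np
import pytest

from triplehit import synthdata


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # generator QC flags and small-regulon warnings are part of normal runs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def pathway_table():
    return synthdata.gen_pathway_table(planted=synthdata.default_lipid_shifts(), seed=11)


@pytest.fixture(scope="session")
def null_pathway_table():
    return synthdata.gen_pathway_table(planted=None, seed=12)


@pytest.fixture(scope="session")
def methylation_planted():
    return synthdata.gen_methylation(
        n_cpg=800, planted_dmrs=[synthdata.DmrSpec()], seed=13
    )


@pytest.fixture(scope="session")
def regulome():
    return synthdata.gen_paired_regulome(seed=14)


def exact_mwu_oracle(x, y):
    """Independent brute-force two-sided Mann-Whitney p: enumerate every
    assignment of the pooled values to the two groups and compare pairwise
    win counts (ties count one half)."""
    from itertools import combinations

    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(group1):
        rest = list(pooled)
        g1 = []
        for i in sorted(group1, reverse=True):
            g1.append(rest.pop(i))
        u = 0.0
        for a in g1:
            for b in rest:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    mid = n1 * (len(pooled) - n1) / 2.0
    u_obs = u_of(tuple(range(n1)))
    dev = abs(u_obs - mid)
    hits = total = 0
    for comb in combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(comb) - mid) >= dev - 1e-12:
            hits += 1
    return hits / total


@pytest.fixture(scope="session")
def mwu_oracle():
    return exact_mwu_oracle


def brute_force_es(scores, hit_positions, p=1.0):
    """O(n) reference enrichment score: walk the full ranking accumulating
    the running sum and return the value of maximum absolute deviation."""
    n = len(scores)
    hits = set(int(h) for h in hit_positions)
    w = np.array([abs(scores[i]) ** p for i in sorted(hits)])
    wsum = w.sum() if w.sum() > 0 else len(hits)
    miss = 1.0 / (n - len(hits))
    running = 0.0
    best = 0.0
    widx = 0
    ordered_w = {h: abs(scores[h]) ** p for h in hits}
    for i in range(n):
        if i in hits:
            running += (ordered_w[i] if wsum > 0 else 1.0) / wsum
        else:
            running -= miss
        if abs(running) > abs(best):
            best = running
    return best


@pytest.fixture(scope="session")
def es_oracle():
    return brute_force_es
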