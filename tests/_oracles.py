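"""Independent brute-force oracles used to validate the dynamic programs
and statistics.  These enumerate configurations directly and must stay
free of the implementation code paths they check."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from mirabind._kernels import BIG
from mirabind.duplex_energy import EnergyParams, encode, loop_cost


def brute_duplex_mfe(mirna: str, window: str, params: EnergyParams) -> float | None:
    """Minimum energy over every legal >= 2-pair antiparallel duplex
    configuration, by direct recursion; None when no configuration is
    negative."""
    pm = params.pair_matrix()
    m = encode(mirna)
    t = encode(window)[::-1]
    nt, nm = len(t), len(m)
    best = [math.inf]

    def rec(i0, j0, last_i, last_j, e, npairs):
        for i in range(i0, nt):
            for j in range(j0, nm):
                pe = pm[t[i], m[j]]
                if pe >= BIG:
                    continue
                if npairs == 0:
                    e2 = pe
                else:
                    e2 = e + pe + loop_cost(i - last_i - 1, j - last_j - 1, params)
                if npairs + 1 >= 2 and e2 < best[0]:
                    best[0] = e2
                rec(i + 1, j + 1, i, j, e2, npairs + 1)

    rec(0, 0, -1, -1, 0.0, 0)
    return None if (best[0] is math.inf or best[0] >= 0) else best[0]


def enumerate_structures(s, allowed, pm, min_hairpin):
    """Yield every nested pair set over encoded sequence ``s``."""

    def rec(i, j):  # interval [i, j)
        if j - i <= 0:
            yield []
            return
        yield from rec(i + 1, j)
        for k in range(i + 1, j):
            if (
                allowed[i]
                and allowed[k]
                and pm[s[i], s[k]] < BIG
                and k - i - 1 >= min_hairpin
            ):
                for inner in rec(i + 1, k):
                    for outer in rec(k + 1, j):
                        yield [(i, k)] + inner + outer

    return rec(0, len(s))


def brute_free_energy(
    seq: str, params: EnergyParams, site: tuple[int, int] | None = None
) -> float:
    """-RT ln Z by exhaustive structure enumeration.

    Structure energy = sum of pair energies + stack bonus per directly
    stacked pair + helix-initiation penalty per maximal helix.
    """
    s = encode(seq)
    allowed = [True] * len(s)
    if site is not None:
        for p in range(*site):
            allowed[p] = False
    pm = params.pair_matrix()
    z = 0.0
    for pairs in enumerate_structures(s, allowed, pm, params.min_hairpin):
        pairset = set(pairs)
        n_stacked = sum(1 for (i, j) in pairs if (i + 1, j - 1) in pairset)
        e = sum(pm[s[i], s[j]] for i, j in pairs)
        e += params.e_stack * n_stacked
        e += params.helix_init * (len(pairs) - n_stacked)  # one per maximal helix
        z += math.exp(-e / params.rt)
    return -params.rt * math.log(z)


def brute_opening_energy(seq: str, site: tuple[int, int], params: EnergyParams) -> float:
    return brute_free_energy(seq, params, site) - brute_free_energy(seq, params)


def brute_wilcoxon_two_sided(x, y) -> float:
    """Exact two-sided rank-sum p-value by enumerating all C(n+m, n)
    group labelings (tie-free data only)."""
    x, y = list(x), list(y)
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    n = len(x)
    w_obs = sum(ranks[v] for v in x)
    mean_w = n * (len(combined) + 1) / 2
    dev = abs(w_obs - mean_w)
    count = 0
    total = 0
    all_ranks = list(ranks.values())
    for combo in combinations(all_ranks, n):
        total += 1
        if abs(sum(combo) - mean_w) >= dev - 1e-12:
            count += 1
    return count / total


def brute_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up by its textbook definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        running = min(running, p[idx] * m / (rank_from_top + 1))
        adj[idx] = running
    return adj


def brute_venn_regions(sets: dict[str, set]) -> dict[frozenset, set]:
    """Region decomposition by per-element membership lookup."""
    regions: dict[frozenset, set] = {}
    labels = list(sets)
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            regions[frozenset(combo)] = set()
    universe = set().union(*sets.values())
    for el in universe:
        membership = frozenset(g for g in labels if el in sets[g])
        regions[membership].add(el)
    return regions
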