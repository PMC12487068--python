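"""Numerical kernels for duplex and single-strand folding dynamic programs.

Both kernels operate on integer-encoded sequences (A=0, C=1, G=2, T/U=3)
and are compiled with numba when available; the pure-Python definitions are
the reference semantics and are used unchanged as a fallback.
"""

from __future__ import annotations

import numpy as np

BIG = 1.0e9  # sentinel for "no pairing possible"
NEG = -1.0e30  # log-space sentinel for an empty structure ensemble

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _loop_cost(gt, gm, e_stack, bulge_open, bulge_ext, loop_open, loop_ext):
    """Cost of the interior region between two consecutive duplex pairs.

    gt/gm are the number of unpaired bases skipped on the target and the
    miRNA side.  Zero on both sides is a helix stack (bonus); one side only
    is a bulge; both sides is an internal loop.
    """
    if gt == 0 and gm == 0:
        return e_stack
    if gt == 0:
        return bulge_open + bulge_ext * (gm - 1)
    if gm == 0:
        return bulge_open + bulge_ext * (gt - 1)
    return loop_open + loop_ext * (gt + gm - 2)


@njit(cache=True)
def duplex_fill(t, m, pairmat, e_stack, bulge_open, bulge_ext, loop_open, loop_ext):
    """Fill intermolecular hybridization DP tables.

    ``t`` is the target window *reversed* (so both strands advance 5'->3'
    antiparallel as indices grow) and ``m`` is the miRNA.  Returns
    ``(best1, best2, p2i, p2j, p1i, p1j)`` where ``best1[i, j]`` is the
    minimum energy of a duplex whose 3'-most pair is (t_i, m_j) with >= 1
    pair, ``best2`` the same restricted to >= 2 pairs, and the p-arrays
    give the chosen predecessor pair for traceback (-1 when the pair
    starts a duplex).
    """
    nt = t.shape[0]
    nm = m.shape[0]
    best1 = np.full((nt, nm), BIG)
    best2 = np.full((nt, nm), BIG)
    p1i = np.full((nt, nm), -1, dtype=np.int32)
    p1j = np.full((nt, nm), -1, dtype=np.int32)
    p2i = np.full((nt, nm), -1, dtype=np.int32)
    p2j = np.full((nt, nm), -1, dtype=np.int32)
    for i in range(nt):
        for j in range(nm):
            e = pairmat[t[i], m[j]]
            if e >= BIG:
                continue
            b1 = e
            bi = -1
            bj = -1
            b2 = BIG
            ci = -1
            cj = -1
            # iterate predecessors nearest-first so equal-energy ties
            # resolve to the most compact (stacked) continuation
            for i2 in range(i - 1, -1, -1):
                for j2 in range(j - 1, -1, -1):
                    prev = best1[i2, j2]
                    if prev >= BIG:
                        continue
                    cost = _loop_cost(
                        i - i2 - 1,
                        j - j2 - 1,
                        e_stack,
                        bulge_open,
                        bulge_ext,
                        loop_open,
                        loop_ext,
                    )
                    cand = e + prev + cost
                    if cand < b1:
                        b1 = cand
                        bi = i2
                        bj = j2
                    if cand < b2:
                        b2 = cand
                        ci = i2
                        cj = j2
            best1[i, j] = b1
            p1i[i, j] = bi
            p1j[i, j] = bj
            best2[i, j] = b2
            p2i[i, j] = ci
            p2j[i, j] = cj
    return best1, best2, p2i, p2j, p1i, p1j


@njit(cache=True)
def partition_logz(s, allowed, pairmat, e_stack, rt, min_hairpin):
    """log partition function over nested secondary structures.

    Structure energy = sum of pair energies + e_stack per directly
    stacked pair (i, j)/(i+1, j-1).  ``allowed`` masks positions that may
    pair (the accessibility constraint sets the binding site to 0).  The
    open chain contributes weight 1, so the result is always >= 0.
    """
    n = s.shape[0]
    if n == 0:
        return 0.0
    lz = np.zeros((n + 1, n + 1))  # lz[i, j]: interval [i, j) ; empty -> 0
    lzb = np.full((n, n), NEG)  # lzb[i, j]: i paired with j (inclusive)
    sigma = np.exp(-e_stack / rt)
    log_sm1 = NEG
    if sigma > 1.0:
        log_sm1 = np.log(sigma - 1.0)
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1  # inclusive right end
            # pair (i, j)
            if (
                allowed[i] == 1
                and allowed[j] == 1
                and pairmat[s[i], s[j]] < BIG
                and j - i - 1 >= min_hairpin
            ):
                inner = lz[i + 1, j]  # interval [i+1, j)
                if log_sm1 > NEG and i + 1 < j - 1 and lzb[i + 1, j - 1] > NEG:
                    inner = np.logaddexp(inner, log_sm1 + lzb[i + 1, j - 1])
                lzb[i, j] = -pairmat[s[i], s[j]] / rt + inner
            # interval [i, j]  (stored as lz[i, j+1])
            acc = lz[i + 1, j + 1]  # i unpaired
            for k in range(i + 1, j + 1):
                if lzb[i, k] > NEG:
                    acc = np.logaddexp(acc, lzb[i, k] + lz[k + 1, j + 1])
            lz[i, j + 1] = acc
    return lz[0, n]
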