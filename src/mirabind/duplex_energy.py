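"""Intermolecular miRNA-target hybridization scoring.

A duplex is a single antiparallel helix between the full mature miRNA
and a candidate window, optionally interrupted by bulges and internal
loops; intramolecular pairs are not allowed at this stage.  The energy
model is a deliberately simple nearest-neighbour-style table (per-pair
energies plus a stacking bonus for directly adjacent pairs and affine
loop penalties); all terms live in :class:`EnergyParams` so a richer
table can be swapped in.  Significance is assessed against a
dinucleotide-shuffle null with a Gumbel (extreme-value) fit, mirroring
the classical treatment of best-in-sequence alignment scores.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from ._kernels import BIG, _loop_cost, duplex_fill

log = logging.getLogger(__name__)

EULER_GAMMA = 0.5772156649015329

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENCODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"illegal character {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class EnergyParams:
    """Simplified pairing energy table (kcal/mol).

    Stability is deliberately concentrated in helix stacking, and loop
    penalties are stiff: the optimal duplex is then dominated by
    near-contiguous helices, so a full-length complementary site scores
    far below anything a random window can produce, and the default
    -20 kcal/mol screen is meaningful at the packaged 35-nt window size.
    T and U are the same pairing partner, so DNA windows hybridize
    against RNA miRNAs without conversion.  ``min_hairpin`` and ``rt``
    belong to the intramolecular (accessibility) model.
    """

    e_gc: float = -2.0
    e_au: float = -1.5
    e_gu: float = -0.5
    e_stack: float = -1.0
    bulge_open: float = 10.0
    bulge_ext: float = 4.0
    loop_open: float = 10.0
    loop_ext: float = 4.0
    helix_init: float = 10.0  # intramolecular helix-initiation penalty
    min_hairpin: int = 3
    rt: float = 0.6163  # kcal/mol at 310.15 K

    def __post_init__(self):
        if not (self.e_gc < 0 and self.e_au < 0 and self.e_gu < 0):
            raise ValueError("pair energies must be negative")
        if min(self.bulge_open, self.bulge_ext, self.loop_open, self.loop_ext) < 0:
            raise ValueError("loop penalties must be >= 0")

    def pair_matrix(self) -> np.ndarray:
        m = np.full((4, 4), BIG)
        m[0, 3] = m[3, 0] = self.e_au  # A:U/T
        m[1, 2] = m[2, 1] = self.e_gc  # C:G
        m[2, 3] = m[3, 2] = self.e_gu  # G:U/T wobble
        return m

    def intra_pair_matrix(self) -> np.ndarray:
        """Pair matrix for the intramolecular (folding) model.

        Each maximal helix pays ``helix_init`` once; since the number of
        helices equals pairs minus stacks, this is equivalent to adding
        the penalty to every pair and subtracting it from every stack,
        which keeps the folding partition function in the same DP family
        as the unpenalized model.
        """
        m = self.pair_matrix()
        m[m < BIG] += self.helix_init
        return m

    @property
    def intra_stack(self) -> float:
        return self.e_stack - self.helix_init


DEFAULT_PARAMS = EnergyParams()


@dataclass(frozen=True)
class DuplexHit:
    """Best hybridization of one miRNA against one window."""

    target_start: int  # within the window, 0-based half-open
    target_end: int
    mirna_start: int
    mirna_end: int
    structure: str  # "target(5'->3') & mirna(5'->3')" dot-bracket
    dG_duplex: float
    n_pairs: int
    mirna_paired: tuple[int, ...] = ()  # 0-based miRNA positions paired
    mirna_id: str = ""
    pvalue: float | None = None
    pvalue_empirical: float | None = None


def loop_cost(gap_target: int, gap_mirna: int, params: EnergyParams) -> float:
    return _loop_cost(
        gap_target,
        gap_mirna,
        params.e_stack,
        params.bulge_open,
        params.bulge_ext,
        params.loop_open,
        params.loop_ext,
    )


def duplex_mfe(
    mirna_seq: str, window_seq: str, params: EnergyParams = DEFAULT_PARAMS
) -> DuplexHit | None:
    """Minimum-free-energy duplex of a miRNA against a target window.

    Returns the globally optimal configuration with >= 2 base pairs, or
    None when no such configuration has negative energy.  Ties resolve
    to the smallest target start, then the configuration with the most
    pairs, then the smallest miRNA start.
    """
    if not mirna_seq or not window_seq:
        raise ValueError("sequences must be non-empty")
    m = encode(mirna_seq)
    t = encode(window_seq)[::-1].copy()  # reversed: both indices advance antiparallel
    pm = params.pair_matrix()
    best1, best2, p2i, p2j, p1i, p1j = duplex_fill(
        t,
        m,
        pm,
        params.e_stack,
        params.bulge_open,
        params.bulge_ext,
        params.loop_open,
        params.loop_ext,
    )
    mfe = float(best2.min())
    if mfe >= 0.0 or mfe >= BIG:
        return None
    L = len(window_seq)
    candidates = []
    for i, j in zip(*np.nonzero(best2 <= mfe + 1e-9)):
        pairs_rev = [(int(i), int(j))]
        ci, cj = int(p2i[i, j]), int(p2j[i, j])
        while ci >= 0:
            pairs_rev.append((ci, cj))
            ci, cj = int(p1i[ci, cj]), int(p1j[ci, cj])
        # pairs_rev holds (reversed-target idx, mirna idx), 3'-most first
        tpos = [L - 1 - a for a, _ in pairs_rev]  # original target coords
        mpos = [b for _, b in pairs_rev]
        candidates.append((min(tpos), -len(pairs_rev), min(mpos), tpos, mpos))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    _, _, _, tpos, mpos = candidates[0]
    ts, te = min(tpos), max(tpos) + 1
    ms, me = min(mpos), max(mpos) + 1
    tset, mset = set(tpos), set(mpos)
    tstruct = "".join("(" if p in tset else "." for p in range(ts, te))
    mstruct = "".join(")" if p in mset else "." for p in range(ms, me))
    return DuplexHit(
        target_start=ts,
        target_end=te,
        mirna_start=ms,
        mirna_end=me,
        structure=f"{tstruct}&{mstruct}",
        dG_duplex=round(mfe, 9),
        n_pairs=len(tpos),
        mirna_paired=tuple(sorted(mset)),
    )


def seed_constraint_ok(
    hit: DuplexHit, seed_start: int | None, seed_end: int | None, mirna_len: int
) -> bool:
    """True iff every miRNA position in [seed_start, seed_end] (1-based,
    5'->3') is paired in the hit.  Unset bounds disable the constraint
    (the default: the entire mature sequence is searched, no positional
    requirement)."""
    if seed_start is None or seed_end is None:
        return True
    if not (1 <= seed_start <= seed_end <= mirna_len):
        raise ValueError(
            f"seed range [{seed_start}, {seed_end}] outside miRNA of length {mirna_len}"
        )
    paired = set(hit.mirna_paired)
    return all(p - 1 in paired for p in range(seed_start, seed_end + 1))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide composition.

    Altschul-Erickson Eulerian-walk shuffle: the sequence is a walk on
    the digraph whose edges are its dinucleotides; a random arborescence
    toward the terminal vertex fixes each vertex's final departure and
    the remaining out-edges are permuted.
    """
    if len(seq) < 3:
        raise ValueError("dinucleotide shuffle requires length >= 3")
    letters = sorted(set(seq))
    if len(letters) == 1:
        return seq
    edges: dict[str, list[str]] = {c: [] for c in letters}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    non_terminal = [c for c in letters if c != last and edges[c]]
    for _ in range(10_000):
        # sample a candidate last-edge per vertex, then check that every
        # vertex reaches the terminal through the chosen last edges
        last_edge = {c: edges[c][rng.integers(len(edges[c]))] for c in non_terminal}
        ok = True
        for c in non_terminal:
            seen = {c}
            cur = c
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to sample a connected Eulerian arborescence")
    shuffled_edges: dict[str, list[str]] = {}
    for c in letters:
        rest = list(edges[c])
        if c in last_edge:
            rest.remove(last_edge[c])
        rng.shuffle(rest)
        if c in last_edge:
            rest.append(last_edge[c])
        shuffled_edges[c] = rest
    out = [seq[0]]
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur].pop(0)
        out.append(nxt)
        cur = nxt
    return "".join(out)


@dataclass(frozen=True)
class GumbelNull:
    """Extreme-value null for best-duplex scores (x = -dG_duplex)."""

    mu: float
    beta: float
    n_shuffles: int
    scores: tuple[float, ...] = field(repr=False, default=())

    def __post_init__(self):
        if self.n_shuffles < 100:
            raise ValueError("n_shuffles must be >= 100")


def calibrate_null(
    mirna_seq: str,
    window_seq: str,
    n_shuffles: int,
    rng: np.random.Generator,
    params: EnergyParams = DEFAULT_PARAMS,
) -> GumbelNull:
    """Fit a Gumbel null from the miRNA's best-duplex scores against
    dinucleotide shuffles of the window.

    Method-of-moments fit: beta = s * sqrt(6)/pi, mu = mean - gamma*beta.
    A window with no reportable duplex scores 0.
    """
    scores = []
    for _ in range(n_shuffles):
        shuf = dinucleotide_shuffle(window_seq, rng)
        hit = duplex_mfe(mirna_seq, shuf, params)
        scores.append(-hit.dG_duplex if hit is not None else 0.0)
    mu, beta = fit_gumbel(scores)
    if beta == 0.0:
        log.warning("degenerate null (all scores identical); p-values forced to 1")
    return GumbelNull(mu=mu, beta=beta, n_shuffles=n_shuffles, scores=tuple(scores))


def fit_gumbel(scores) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: beta = s*sqrt(6)/pi,
    mu = mean - gamma*beta (gamma: Euler-Mascheroni)."""
    x = np.asarray(scores, dtype=float)
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return float(x.mean()), 0.0
    beta = sd * math.sqrt(6.0) / math.pi
    return float(x.mean()) - EULER_GAMMA * beta, beta


def hybrid_pvalue(dG_duplex: float, null: GumbelNull) -> tuple[float, float]:
    """(Gumbel p, empirical p) for an observed duplex energy.

    p = 1 - exp(-exp(-(x - mu)/beta)) with x = -dG_duplex; the empirical
    fallback is the add-one rank (r+1)/(n+1).
    """
    x = -dG_duplex
    r = sum(1 for s in null.scores if s >= x)
    p_emp = (r + 1) / (null.n_shuffles + 1)
    if null.beta == 0.0:
        return 1.0, p_emp
    z = (x - null.mu) / null.beta
    # guard exp overflow for scores far below the null location
    p_gum = 1.0 if z < -30 else -math.expm1(-math.exp(-z))
    p_gum = min(max(p_gum, 5e-324), 1.0)
    return p_gum, p_emp


def pair_rng(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic per-(miRNA, window) substream independent of
    iteration order: the stream key mixes the run seed with a CRC of the
    identifying labels."""
    key = zlib.crc32("|".join(labels).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))
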