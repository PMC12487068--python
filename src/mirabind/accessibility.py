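"""Structural accessibility of predicted binding sites.

A stable hairpin covering the target site competes with miRNA binding:
before the duplex can form, the site must be melted out of the mRNA's
own secondary structure.  The cost of doing so is the opening energy

    dG_open = G_constrained - G_ensemble = RT * ln(Z / Z_unpaired) >= 0,

where Z is the partition function over all nested structures of the
extended window and Z_unpaired sums only structures leaving every site
base unpaired.  The final score is dG_total = dG_duplex + dG_open.  The
intramolecular model uses the same pair energies and stacking bonus as
the duplex stage plus a per-helix initiation penalty (suppressing
isolated pairs), so the two energy scales are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import partition_logz
from .duplex_energy import DEFAULT_PARAMS, EnergyParams, encode

log = logging.getLogger(__name__)

MAX_FOLD_LEN = 400  # bound on the O(n^3) fold; longer windows are trimmed


@dataclass(frozen=True)
class AccessibilityScore:
    dG_open: float  # >= 0 by construction
    dG_duplex: float
    dG_total: float


def _logz(seq: str, allowed: np.ndarray, params: EnergyParams) -> float:
    s = encode(seq)
    return float(
        partition_logz(
            s,
            allowed,
            params.intra_pair_matrix(),
            params.intra_stack,
            params.rt,
            params.min_hairpin,
        )
    )


def ensemble_free_energy(seq: str, params: EnergyParams = DEFAULT_PARAMS) -> float:
    """G_ens = -RT ln Z over all nested structures (open chain included,
    so Z >= 1 and the result is <= 0)."""
    if not seq:
        raise ValueError("empty sequence")
    if "N" in seq:
        raise ValueError("sequence contains N")
    allowed = np.ones(len(seq), dtype=np.uint8)
    return -params.rt * _logz(seq, allowed, params)


def opening_energy(
    seq: str, site: tuple[int, int], params: EnergyParams = DEFAULT_PARAMS
) -> float:
    """Free-energy cost of forcing ``site`` (half-open interval) to be
    single-stranded within ``seq``."""
    start, end = site
    if not (0 <= start < end <= len(seq)):
        raise ValueError(f"site [{start}, {end}) outside sequence of length {len(seq)}")
    if "N" in seq:
        raise ValueError("sequence contains N")
    allowed = np.ones(len(seq), dtype=np.uint8)
    lz = _logz(seq, allowed, params)
    allowed[start:end] = 0
    lz_u = _logz(seq, allowed, params)
    return max(0.0, params.rt * (lz - lz_u))


def total_energy(dG_duplex: float, dG_open: float) -> AccessibilityScore:
    if dG_open < 0:
        raise ValueError(f"dG_open must be >= 0, got {dG_open}")
    return AccessibilityScore(
        dG_open=dG_open, dG_duplex=dG_duplex, dG_total=dG_duplex + dG_open
    )


def trim_around_site(
    seq: str, site: tuple[int, int], max_len: int = MAX_FOLD_LEN
) -> tuple[str, tuple[int, int]]:
    """Symmetrically trim a sequence around ``site`` to at most
    ``max_len`` bases, returning the trimmed sequence and remapped site."""
    start, end = site
    if len(seq) <= max_len:
        return seq, site
    log.warning("folding window of %d nt trimmed to %d nt around site", len(seq), max_len)
    spare = max_len - (end - start)
    if spare <= 0:
        return seq[start:end][:max_len], (0, min(end - start, max_len))
    left = start - spare // 2
    right = left + max_len
    if left < 0:
        left, right = 0, max_len
    if right > len(seq):
        right = len(seq)
        left = right - max_len
    return seq[left:right], (start - left, end - left)


def score_site(
    ext_seq: str,
    site: tuple[int, int],
    dG_duplex: float,
    params: EnergyParams = DEFAULT_PARAMS,
) -> AccessibilityScore:
    """Opening-energy re-score of one duplex hit inside its extended
    window (site = duplex footprint in extended-window coordinates)."""
    seq, site = trim_around_site(ext_seq, site)
    return total_energy(dG_duplex, opening_energy(seq, site, params))
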