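"""Candidate-region extraction around CDS starts.

In prokaryotic mRNAs the ribosome binding (Shine-Dalgarno) site sits just
upstream of the start codon, and trans-acting small RNAs typically act by
occluding it.  Screening is therefore restricted to a short window
anchored at the translational start: by default 15 nt upstream through
20 nt downstream (the downstream stretch includes the first base of the
start codon), giving a 35 nt candidate sequence.  Only CDSs strictly
longer than ``min_cds_len`` (default 150 nt) are considered, and each
candidate window later gets an extended context (default 150 nt on each
flank) on which structural accessibility is evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .sequence_io import CdsFeature, reverse_complement

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowParams:
    upstream: int = 15
    downstream: int = 20
    min_cds_len: int = 150
    extension: int = 150

    def __post_init__(self):
        if min(self.upstream, self.downstream, self.min_cds_len, self.extension) < 0:
            raise ValueError("window parameters must be >= 0")
        if self.upstream + self.downstream < 1:
            raise ValueError("window must span at least one base")


@dataclass(frozen=True)
class CandidateWindow:
    cds_id: str
    genome_id: str
    contig: str
    win_start: int  # genome coordinates, 0-based half-open
    win_end: int
    strand: str
    seq: str  # transcript orientation (reverse-complemented for '-')
    clipped: bool = False
    gene_name: str = ""
    product: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return (self.genome_id, self.cds_id)


@dataclass(frozen=True)
class ExtendedWindow:
    parent: CandidateWindow
    ext_start: int
    ext_end: int
    seq: str  # transcript orientation
    site_offset: int  # offset of parent.seq within seq
    clipped: bool = False


def extract_window(
    cds: CdsFeature, contig_seq: str, params: WindowParams = WindowParams()
) -> CandidateWindow | None:
    """Extract the RBS-anchored candidate window for one CDS.

    Returns None for CDSs not longer than ``min_cds_len`` and for windows
    containing N (pairing with N is undefined).  Windows running off the
    contig edge are clipped and flagged, not dropped: fragmented contigs
    are the norm in metagenome-assembled genomes and dropping them would
    bias counts.
    """
    n = len(contig_seq)
    if cds.end > n:
        raise ValueError(
            f"CDS {cds.cds_id!r} [{cds.start}, {cds.end}) outside contig of length {n}"
        )
    if cds.length <= params.min_cds_len:
        return None
    if cds.strand == "+":
        a = cds.start - params.upstream
        b = cds.start + params.downstream
    else:
        # biological start is the last genomic base; mirror the offsets
        a = cds.end - params.downstream
        b = cds.end + params.upstream
    ca, cb = max(0, a), min(n, b)
    clipped = (ca != a) or (cb != b)
    seq = contig_seq[ca:cb]
    if cds.strand == "-":
        seq = reverse_complement(seq)
    if "N" in seq:
        log.info("window for CDS %s dropped: contains N", cds.cds_id)
        return None
    return CandidateWindow(
        cds_id=cds.cds_id,
        genome_id=cds.genome_id,
        contig=cds.contig,
        win_start=ca,
        win_end=cb,
        strand=cds.strand,
        seq=seq,
        clipped=clipped,
        gene_name=cds.gene_name,
        product=cds.product,
    )


def extend_window(
    win: CandidateWindow, contig_seq: str, extension: int = 150
) -> ExtendedWindow:
    """Add ``extension`` nt of genomic context on each flank of a window.

    The extended sequence is reported in transcript orientation and
    ``site_offset`` locates the parent window within it.
    """
    n = len(contig_seq)
    a = max(0, win.win_start - extension)
    b = min(n, win.win_end + extension)
    clipped = a != win.win_start - extension or b != win.win_end + extension
    seq = contig_seq[a:b]
    if win.strand == "-":
        seq = reverse_complement(seq)
        site_offset = b - win.win_end
    else:
        site_offset = win.win_start - a
    ext = ExtendedWindow(
        parent=win, ext_start=a, ext_end=b, seq=seq, site_offset=site_offset, clipped=clipped
    )
    sub = ext.seq[site_offset : site_offset + len(win.seq)]
    if sub != win.seq:
        raise AssertionError("extended window does not embed its parent window")
    return ext


def windows_for_genome(
    cds_list, contigs: dict[str, str], params: WindowParams = WindowParams()
) -> list[CandidateWindow]:
    """Extract windows for all CDSs of one genome, skipping flagged rows."""
    out = []
    for cds in cds_list:
        if not cds.on_known_contig or cds.contig not in contigs:
            continue
        win = extract_window(cds, contigs[cds.contig], params)
        if win is not None:
            out.append(win)
    return out


def window_fasta_header(win: CandidateWindow) -> str:
    return f"{win.genome_id}|{win.cds_id}|{win.contig}:{win.win_start}-{win.win_end}|{win.strand}"
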