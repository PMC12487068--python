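"""Self-contained synthetic datasets with planted miRNA binding sites.

The generator emulates the pipeline's real inputs - multi-CDS microbial
contigs, mature miRNA FASTA, sample list, metadata with >= 2 groups and
a gene->function map - and writes a machine-readable truth table.  Sites
are planted as the reverse complement of a miRNA inside (or outside) the
RBS-anchored candidate window of a chosen CDS; decoy classes each defeat
exactly one stage of the pipeline:

* ``cds_interior``  - perfect site, but 200+ nt into the CDS (outside
  any candidate window);
* ``intergenic``    - perfect site, far from every window;
* ``mismatched_k``  - in-window site with k positions mutated to
  non-complementary bases (duplex energy above the MFE cutoff);
* ``hairpin``       - in-window site (lightly mismatched to the miRNA)
  whose exact complement is planted as an arm in the extended context;
  the perfect intramolecular stem outcompetes the interrupted duplex
  and the opening energy pushes dG_total above its cutoff.

Generation is constructive: after assembly the generator re-scores the
dataset with the package's own energy engine and verifies that every
planted truth holds with margin under the default thresholds, resampling
contig backgrounds (bounded, seeded) when a spurious background duplex
crosses the MFE cutoff.  Datasets are byte-identical under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .accessibility import score_site
from .duplex_energy import DEFAULT_PARAMS, EnergyParams, duplex_mfe
from .sequence_io import (
    CdsFeature,
    SeqRecord,
    STOP_CODONS,
    reverse_complement,
    write_fasta,
    write_gff_cds,
)
from .target_windows import WindowParams, extend_window, extract_window

log = logging.getLogger(__name__)

BASES = "ACGT"
START_LIKE = {"ATG", "GTG", "TTG"}
# pairing partners (DNA alphabet) of each miRNA base, wobble included
_PARTNERS = {"A": {"T"}, "C": {"G"}, "G": {"C", "T"}, "U": {"A", "G"}}


@dataclass(frozen=True)
class PlantedSite:
    mirna_index: int
    genome_id: str
    cds_index: int  # ignored for intergenic placements
    placement: str  # rbs_window | cds_interior | intergenic | hairpin
    complementarity: str = "perfect"  # or "mismatched_<k>"

    @property
    def k_mismatch(self) -> int:
        if self.complementarity.startswith("mismatched_"):
            return int(self.complementarity.split("_")[1])
        return 0

    @property
    def expected_detected(self) -> bool:
        return self.placement == "rbs_window" and self.complementarity == "perfect"


@dataclass
class FixtureSpec:
    groups: tuple[str, ...] = ("feces", "rumen")
    n_genomes_per_group: int = 3
    contig_len: int = 4000
    n_cds: int = 4
    cds_len: int = 300
    minus_strand_cds: tuple[int, ...] = (2,)  # CDS indices on the minus strand
    n_mirnas: int = 5
    mirna_len: int = 22
    mirna_gc: float = 0.55
    planted: tuple[PlantedSite, ...] = ()
    rng_seed: int = 7
    window: WindowParams = field(default_factory=WindowParams)

    def genome_ids(self) -> list[str]:
        return [
            f"{g[0]}{i + 1}" for g in self.groups for i in range(self.n_genomes_per_group)
        ]

    def group_of(self) -> dict[str, str]:
        return {
            f"{g[0]}{i + 1}": g
            for g in self.groups
            for i in range(self.n_genomes_per_group)
        }


def default_demo_spec() -> FixtureSpec:
    """The packaged demo: 2 groups x 3 genomes, 5 miRNAs, 6 true sites
    (both strands, both groups) and one decoy of each class."""
    planted = (
        PlantedSite(0, "f1", 0, "rbs_window"),
        PlantedSite(1, "f1", 2, "rbs_window"),  # minus-strand CDS
        PlantedSite(2, "f2", 1, "rbs_window"),
        PlantedSite(0, "r1", 0, "rbs_window"),
        PlantedSite(3, "r2", 3, "rbs_window"),
        PlantedSite(4, "r3", 2, "rbs_window"),  # minus-strand CDS
        PlantedSite(1, "f3", 1, "cds_interior"),
        PlantedSite(2, "r1", 1, "intergenic"),
        PlantedSite(3, "f2", 3, "rbs_window", "mismatched_10"),
        # two mismatches to the miRNA, but the planted arm complements the
        # mutated site exactly: the intramolecular stem outcompetes the
        # interrupted duplex and the opening energy rejects the site
        PlantedSite(4, "r2", 0, "hairpin", "mismatched_2"),
    )
    return FixtureSpec(planted=planted)


def _random_seq(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))


def make_mirnas(spec: FixtureSpec, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Random mature miRNAs (RNA alphabet), distinct, with GC content
    such that a perfect full-length helix clears the MFE cutoff by a wide
    margin (verified downstream)."""
    out = []
    seen = set()
    while len(out) < spec.n_mirnas:
        seq = _random_seq(spec.mirna_len, rng, spec.mirna_gc).replace("T", "U")
        if seq in seen:
            continue
        seen.add(seq)
        out.append((f"mir-{len(out) + 1:02d}", seq))
    return out


def _cds_layout(spec: FixtureSpec) -> list[tuple[int, int, str]]:
    """Deterministic, evenly spaced CDS coordinates on one contig."""
    gap = (spec.contig_len - spec.n_cds * spec.cds_len) // (spec.n_cds + 1)
    if gap < spec.window.upstream + 60:
        raise ValueError("CDSs do not fit the contig with workable spacing")
    coords = []
    pos = gap
    for i in range(spec.n_cds):
        strand = "-" if i in spec.minus_strand_cds else "+"
        coords.append((pos, pos + spec.cds_len, strand))
        pos += spec.cds_len + gap
    return coords


def _write(contig: list[str], start: int, seq: str) -> None:
    contig[start : start + len(seq)] = list(seq)


def make_genome(
    genome_id: str, spec: FixtureSpec, rng: np.random.Generator
) -> tuple[SeqRecord, list[CdsFeature]]:
    """One contig with valid, rediscoverable CDSs on both strands.

    Every CDS gets a proper start codon, stop codon, a stop-free reading
    frame, an in-frame stop just upstream of its candidate window (so the
    naive ORF caller does not extend the start leftward) and an upstream
    region free of in-frame start codons.
    """
    contig = list(_random_seq(spec.contig_len, rng))
    features = []
    for i, (start, end, strand) in enumerate(_cds_layout(spec)):
        n_codons = spec.cds_len // 3
        body = ["ATG"]
        for _ in range(n_codons - 2):
            while True:
                codon = _random_seq(3, rng)
                if codon not in STOP_CODONS:
                    break
            body.append(codon)
        body.append("TAA")
        cds_seq = "".join(body)
        # upstream region (transcript orientation): in-frame stop guard,
        # then 15 nt with no in-frame start codon
        upstream = list(_random_seq(15, rng))
        for off in range(0, 15, 3):
            while "".join(upstream[off : off + 3]) in START_LIKE:
                upstream[off : off + 3] = list(_random_seq(3, rng))
        guard_and_up = "TAA" + "".join(upstream)
        if strand == "+":
            _write(contig, start, cds_seq)
            _write(contig, start - 18, guard_and_up)
        else:
            _write(contig, start, reverse_complement(cds_seq))
            _write(contig, end, reverse_complement(guard_and_up))
        features.append(
            CdsFeature(
                contig=f"{genome_id}_c1",
                start=start,
                end=end,
                strand=strand,
                cds_id=f"{genome_id}_cds{i + 1:02d}",
                gene_name=f"gene{chr(ord('A') + i)}",
                product=f"synthetic protein {chr(ord('A') + i)}",
                genome_id=genome_id,
            )
        )
    return SeqRecord(id=f"{genome_id}_c1", seq="".join(contig)), features


def _transcript_write(contig: list[str], cds: CdsFeature, t_start: int, seq: str) -> None:
    """Write ``seq`` so it reads 5'->3' in transcript orientation starting
    at transcript coordinate ``t_start`` (0 = first base of the start
    codon; negative = upstream)."""
    if cds.strand == "+":
        _write(contig, cds.start + t_start, seq)
    else:
        g_end = cds.end - t_start  # genomic position just past the written block
        _write(contig, g_end - len(seq), reverse_complement(seq))


def plant_site(
    contig: list[str],
    cds: CdsFeature,
    mirna_seq: str,
    placement: str,
    k_mismatch: int = 0,
    rng: np.random.Generator | None = None,
    window: WindowParams = WindowParams(),
    intergenic_pos: int | None = None,
) -> None:
    """Write a (possibly degraded) binding site for ``mirna_seq`` into a
    mutable contig at the requested placement.

    The site sequence is the reverse complement of the miRNA (DNA
    alphabet) in transcript orientation, so the extracted candidate
    window hybridizes with the full mature sequence.  ``mismatched_k``
    mutates k evenly spaced positions to bases that can neither
    Watson-Crick nor wobble pair with their miRNA partner.
    """
    mirna_dna = mirna_seq.replace("U", "T")
    site = reverse_complement(mirna_dna)
    L = len(site)
    if k_mismatch:
        if rng is None:
            raise ValueError("mismatched planting needs an rng")
        idx = np.round(np.linspace(0, L - 1, k_mismatch)).astype(int)
        site_l = list(site)
        for p in sorted(set(int(i) for i in idx)):
            partner = mirna_seq[L - 1 - p]  # antiparallel partner position
            forbidden = _PARTNERS[partner] | {site_l[p]}
            choices = [b for b in BASES if b not in forbidden]
            site_l[p] = choices[int(rng.integers(len(choices)))]
        site = "".join(site_l)
    site_offset_in_window = (window.upstream + window.downstream - L) // 2
    if placement in ("rbs_window", "hairpin"):
        t_start = -window.upstream + site_offset_in_window
        _transcript_write(contig, cds, t_start, site)
        if placement == "hairpin":
            # complementary arm upstream in the extended context; the
            # arm/site helix makes the site costly to open
            arm = reverse_complement(site)
            _transcript_write(contig, cds, t_start - 8 - L, arm)
    elif placement == "cds_interior":
        _transcript_write(contig, cds, 200, site)
    elif placement == "intergenic":
        if intergenic_pos is None:
            raise ValueError("intergenic placement needs an explicit position")
        _write(contig, intergenic_pos, site)
    else:
        raise ValueError(f"unknown placement {placement!r}")


def _intergenic_position(spec: FixtureSpec, site_len: int) -> int:
    """A fixed position at least ``extension`` nt clear of every window."""
    layout = _cds_layout(spec)
    windows = []
    for start, end, strand in layout:
        if strand == "+":
            windows.append((start - spec.window.upstream, start + spec.window.downstream))
        else:
            windows.append((end - spec.window.downstream, end + spec.window.upstream))
    clearance = spec.window.extension
    for pos in range(0, spec.contig_len - site_len):
        if all(
            pos + site_len + clearance <= a or pos >= b + clearance for a, b in windows
        ):
            # also keep clear of CDS bodies so the ORF annotation is untouched
            if all(pos + site_len <= s or pos >= e for s, e, _ in layout):
                return pos
    raise ValueError("no intergenic slot with the required clearance")


@dataclass
class FixtureBundle:
    dir: Path
    truth: pd.DataFrame
    mirnas: list[tuple[str, str]]
    config_path: Path


def make_dataset(
    spec: FixtureSpec,
    out_dir,
    params: EnergyParams = DEFAULT_PARAMS,
    mfe_cutoff: float = -20.0,
    dg_total_cutoff: float = -15.0,
    verify: bool = True,
    max_attempts: int = 20,
) -> FixtureBundle:
    """Generate and write a complete fixture bundle.

    When ``verify`` is on (the default), each genome background is
    re-scored against every miRNA and resampled (deterministically)
    until no non-planted pair crosses the MFE cutoff, and the planted
    truths are asserted with the real engine.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)
    mirnas = make_mirnas(spec, rng)
    by_genome: dict[str, list[PlantedSite]] = {g: [] for g in spec.genome_ids()}
    for site in spec.planted:
        if site.genome_id not in by_genome:
            raise ValueError(f"planted site references unknown genome {site.genome_id!r}")
        by_genome[site.genome_id].append(site)

    genomes: dict[str, SeqRecord] = {}
    features: dict[str, list[CdsFeature]] = {}
    truth_rows = []
    for gid in spec.genome_ids():
        for attempt in range(max_attempts):
            g_rng = np.random.default_rng([spec.rng_seed, _stable_key(gid), attempt])
            record, cds_list = make_genome(gid, spec, g_rng)
            contig = list(record.seq)
            for site in by_genome[gid]:
                mirna_seq = mirnas[site.mirna_index][1]
                cds = cds_list[site.cds_index]
                pos = (
                    _intergenic_position(spec, spec.mirna_len)
                    if site.placement == "intergenic"
                    else None
                )
                plant_site(
                    contig,
                    cds,
                    mirna_seq,
                    site.placement,
                    k_mismatch=site.k_mismatch,
                    rng=g_rng,
                    window=spec.window,
                    intergenic_pos=pos,
                )
            record = SeqRecord(id=record.id, seq="".join(contig))
            if not verify or _background_clean(
                record, cds_list, by_genome[gid], mirnas, spec, params, mfe_cutoff
            ):
                break
        else:
            raise RuntimeError(f"could not generate a clean background for {gid}")
        genomes[gid] = record
        features[gid] = cds_list
        for site in by_genome[gid]:
            cds = cds_list[site.cds_index]
            truth_rows.append(
                {
                    "mirna_id": mirnas[site.mirna_index][0],
                    "genome_id": gid,
                    "cds_id": "" if site.placement == "intergenic" else cds.cds_id,
                    "placement": site.placement,
                    "complementarity": site.complementarity,
                    "expected_detected": site.expected_detected,
                }
            )

    if verify:
        _verify_planted_truths(
            genomes, features, by_genome, mirnas, spec, params, mfe_cutoff, dg_total_cutoff
        )

    # --- write the bundle -------------------------------------------------
    group_of = spec.group_of()
    for gid in spec.genome_ids():
        write_fasta([genomes[gid]], out_dir / f"{gid}.fa")
        write_gff_cds(features[gid], out_dir / f"{gid}.gff")
    write_fasta(
        [SeqRecord(id=mid, seq=seq) for mid, seq in mirnas], out_dir / "mirnas.fa"
    )
    with open(out_dir / "samples.txt", "w") as fh:
        fh.write("\n".join(spec.genome_ids()) + "\n")
    meta = pd.DataFrame(
        {
            "genome_id": spec.genome_ids(),
            "group": [group_of[g] for g in spec.genome_ids()],
            "taxonomy": [_taxonomy_for(g, group_of[g]) for g in spec.genome_ids()],
        }
    )
    meta.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    _write_function_map(spec, out_dir / "function_map.tsv")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    config_path = out_dir / "config.yaml"
    _write_config(spec, out_dir, config_path)
    return FixtureBundle(dir=out_dir, truth=truth, mirnas=mirnas, config_path=config_path)


def _stable_key(label: str) -> int:
    import zlib

    return zlib.crc32(label.encode()) & 0x7FFFFFFF


def _taxonomy_for(genome_id: str, group: str) -> str:
    return (
        "d__Bacteria;p__Synthetica;c__Fixturia;o__Fixturales;"
        f"f__Fixturaceae;g__{group.capitalize()}bacter;s__{group.capitalize()}bacter {genome_id}"
    )


def _write_function_map(spec: FixtureSpec, path) -> None:
    """Deterministic gene->function map over a small vocabulary; gene
    labels match the generator's gene names so every genome shares them."""
    rows = []
    vocab = [f"F{j + 1:02d}" for j in range(2 * spec.n_cds)]
    for i in range(spec.n_cds):
        gene = f"gene{chr(ord('A') + i)}"
        rows.append({"gene_label": gene, "function_id": vocab[i], "function_name": f"function {vocab[i]}", "level": 1})
        rows.append({"gene_label": gene, "function_id": vocab[spec.n_cds + i], "function_name": f"function {vocab[spec.n_cds + i]}", "level": 3})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_config(spec: FixtureSpec, out_dir: Path, path: Path) -> None:
    import yaml

    cfg = {
        "genome_dir": str(out_dir),
        "mirna_fasta": str(out_dir / "mirnas.fa"),
        "sample_list": str(out_dir / "samples.txt"),
        "metadata": str(out_dir / "metadata.tsv"),
        "function_map": str(out_dir / "function_map.tsv"),
        "out_dir": str(out_dir / "results"),
        "rng_seed": int(spec.rng_seed),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _windows_of(record, cds_list, spec):
    wins = {}
    for cds in cds_list:
        w = extract_window(cds, record.seq, spec.window)
        if w is not None:
            wins[cds.cds_id] = w
    return wins


def _background_clean(
    record, cds_list, planted, mirnas, spec, params, mfe_cutoff
) -> bool:
    """True iff no non-planted (miRNA, window) pair crosses the MFE
    cutoff; spurious background duplexes trigger a resample."""
    wins = _windows_of(record, cds_list, spec)
    special = {
        (mirnas[s.mirna_index][0], cds_list[s.cds_index].cds_id)
        for s in planted
        if s.placement in ("rbs_window", "hairpin")
    }
    for mid, mseq in mirnas:
        for cds_id, win in wins.items():
            if (mid, cds_id) in special:
                continue
            hit = duplex_mfe(mseq, win.seq, params)
            if hit is not None and hit.dG_duplex < mfe_cutoff:
                log.info(
                    "background duplex %s vs %s at %.1f kcal/mol; resampling contig",
                    mid,
                    cds_id,
                    hit.dG_duplex,
                )
                return False
    return True


def _verify_planted_truths(
    genomes, features, by_genome, mirnas, spec, params, mfe_cutoff, dg_total_cutoff
) -> None:
    margin = 2.0
    for gid, planted in by_genome.items():
        record = genomes[gid]
        wins = _windows_of(record, features[gid], spec)
        for site in planted:
            if site.placement == "intergenic":
                continue
            mid, mseq = mirnas[site.mirna_index]
            cds = features[gid][site.cds_index]
            win = wins[cds.cds_id]
            hit = duplex_mfe(mseq, win.seq, params)
            if site.expected_detected or site.placement == "hairpin":
                if hit is None or hit.dG_duplex >= mfe_cutoff - margin:
                    raise RuntimeError(
                        f"planted site {mid}/{cds.cds_id} does not clear the MFE cutoff"
                    )
            if (
                site.placement == "rbs_window"
                and site.k_mismatch
                and hit is not None
                and hit.dG_duplex < mfe_cutoff + margin
            ):
                raise RuntimeError(
                    f"mismatched decoy {mid}/{cds.cds_id} is too stable ({hit.dG_duplex})"
                )
            if site.placement == "hairpin":
                ext = extend_window(win, record.seq, spec.window.extension)
                sitespan = (
                    ext.site_offset + hit.target_start,
                    ext.site_offset + hit.target_end,
                )
                score = score_site(ext.seq, sitespan, hit.dG_duplex, params)
                if score.dG_total < dg_total_cutoff + margin:
                    raise RuntimeError(
                        f"hairpin decoy {mid}/{cds.cds_id} still passes dG_total "
                        f"({score.dG_total:.1f})"
                    )


def simulate_function_counts(
    n_per_group: int,
    n_functions: int,
    rng: np.random.Generator,
    shifted: tuple[int, ...] = (),
    shift_factor: float = 4.0,
    base_mean: float = 100.0,
    shifted_base: float = 20.0,
    groups: tuple[str, str] = ("A", "B"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Poisson count matrix for the differential-abundance simulations.

    Functions listed in ``shifted`` start from a smaller baseline (so a
    fold change in counts survives the within-sample renormalization)
    and are multiplied by ``shift_factor`` in the first group.
    """
    means = np.full(n_functions, base_mean)
    means[list(shifted)] = shifted_base
    rows, labels, names = [], [], []
    for g_i, g in enumerate(groups):
        for s in range(n_per_group):
            mu = means.copy()
            if g_i == 0 and shifted:
                mu[list(shifted)] *= shift_factor
            rows.append(rng.poisson(mu))
            labels.append(g)
            names.append(f"{g}{s + 1}")
    counts = pd.DataFrame(
        rows, index=names, columns=[f"F{j + 1:02d}" for j in range(n_functions)]
    ).astype(float)
    return counts, pd.Series(labels, index=names)
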