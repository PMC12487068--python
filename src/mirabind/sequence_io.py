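"""Input/output for the pipeline's standard formats.

Genomic FASTA, mature-miRNA FASTA, GFF3 CDS annotations, the sample list
and metadata tables, and the YAML run configuration.  Also houses the
naive six-frame ORF caller used when no external annotation is supplied.

Coordinates are 0-based half-open everywhere inside the package; GFF3's
1-based inclusive convention is converted at the boundary.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import pandas as pd
import yaml
from Bio import SeqIO

log = logging.getLogger(__name__)

GENOME_ALPHABET = set("ACGTUN")
RNA_ALPHABET = set("ACGU")

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """One nucleotide record: id is the first header token."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MirnaRecord:
    """A mature miRNA; sequence is RNA (T normalized to U on read)."""

    mirna_id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CdsFeature:
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    cds_id: str
    gene_name: str = ""
    product: str = ""
    genome_id: str = ""
    on_known_contig: bool = True

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid CDS coordinates [{self.start}, {self.end}) for {self.cds_id!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    group: str
    taxonomy: str = ""


def _validate_seq(seq: str, rec_id: str, alphabet: set[str], path) -> None:
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(
                f"illegal character {ch!r} at position {pos + 1} of record "
                f"{rec_id!r} in {path}"
            )


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into normalized (upper-case) records.

    Raises on an empty file, duplicate ids, or characters outside
    {A, C, G, T, U, N}.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        _validate_seq(seq, rec.id, GENOME_ALPHABET, path)
        records.append(SeqRecord(id=rec.id, seq=seq, description=rec.description))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            desc = getattr(rec, "description", "")
            if desc and desc != rec.id and not desc.startswith(rec.id + " "):
                header = f"{rec.id} {desc}"
            elif desc and desc.startswith(rec.id + " "):
                header = desc
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_mirna_fasta(path, min_len: int = 15, max_len: int = 40) -> list[MirnaRecord]:
    """Read mature miRNAs; DNA input is converted to RNA (T -> U).

    Length bounds are sanity checks for mature miRNAs; N is rejected
    because base pairing with N is undefined.
    """
    out: list[MirnaRecord] = []
    for rec in read_fasta(path):
        seq = rec.seq.replace("T", "U")
        if "N" in seq:
            raise ValueError(f"miRNA {rec.id!r} contains N")
        _validate_seq(seq, rec.id, RNA_ALPHABET, path)
        if not (min_len <= len(seq) <= max_len):
            raise ValueError(
                f"miRNA {rec.id!r} has length {len(seq)}, outside [{min_len}, {max_len}]"
            )
        out.append(MirnaRecord(mirna_id=rec.id, seq=seq))
    return out


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff_cds(path, genome_id: str, known_contigs=None) -> list[CdsFeature]:
    """Extract CDS features from a GFF3 file.

    1-based inclusive coordinates are converted to 0-based half-open.
    Rows on contigs not in ``known_contigs`` are retained but flagged.
    Line-level diagnostics (column counts, inverted coordinates) are part
    of the contract, so rows are parsed directly rather than through a
    database layer.
    """
    features: list[CdsFeature] = []
    auto_id = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):  # optional embedded FASTA section
                break
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            contig, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = cols
            if ftype != "CDS":
                continue
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end {end1} < start {start1}")
            attrs = _parse_gff_attributes(attr_s)
            cds_id = attrs.get("ID") or attrs.get("locus_tag")
            if not cds_id:
                auto_id += 1
                cds_id = f"{genome_id}_cds{auto_id:05d}"
            known = True
            if known_contigs is not None and contig not in known_contigs:
                known = False
                log.warning("%s:%d: CDS %s on unknown contig %s", path, lineno, cds_id, contig)
            features.append(
                CdsFeature(
                    contig=contig,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    cds_id=cds_id,
                    gene_name=attrs.get("gene", ""),
                    product=attrs.get("product", ""),
                    genome_id=genome_id,
                    on_known_contig=known,
                )
            )
    return features


def write_gff_cds(features, path) -> None:
    """Write CDS features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.cds_id}"]
            if f.gene_name:
                attrs.append(f"gene={f.gene_name}")
            if f.product:
                attrs.append(f"product={f.product}")
            fh.write(
                "\t".join(
                    [
                        f.contig,
                        "mirabind",
                        "CDS",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def call_orfs(record: SeqRecord, min_len: int = 150, genome_id: str = "") -> list[CdsFeature]:
    """Naive six-frame ORF caller (fixture-scale annotation fallback).

    An ORF runs from a start codon (ATG/GTG/TTG) to the first in-frame
    stop (TAA/TAG/TGA), stop included; only ORFs of total length >=
    ``min_len`` are reported.  Within a frame, overlapping ORFs sharing a
    stop resolve to the leftmost (longest) start.  Minus-strand ORFs are
    reported in genome coordinates.
    """
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    n = len(record.seq)
    found: list[tuple[str, int, int, str]] = []

    def scan(seq: str, minus: bool) -> None:
        for frame in range(3):
            start: int | None = None
            for p in range(frame, len(seq) - 2, 3):
                codon = seq[p : p + 3]
                if start is None and codon in START_CODONS:
                    start = p
                elif start is not None and codon in STOP_CODONS:
                    end = p + 3
                    if end - start >= min_len:
                        if minus:
                            found.append((record.id, n - end, n - start, "-"))
                        else:
                            found.append((record.id, start, end, "+"))
                    start = None

    scan(record.seq, minus=False)
    scan(reverse_complement(record.seq), minus=True)
    found.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    return [
        CdsFeature(
            contig=contig,
            start=s,
            end=e,
            strand=strand,
            cds_id=f"{contig}_orf{i + 1:04d}",
            genome_id=genome_id,
        )
        for i, (contig, s, e, strand) in enumerate(found)
    ]


def read_metadata(path) -> pd.DataFrame:
    """Read the genome metadata TSV (genome_id, group, taxonomy)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"genome_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns: {sorted(missing)}")
    if "taxonomy" not in df.columns:
        df["taxonomy"] = ""
    dupes = df["genome_id"][df["genome_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate genome_id in metadata: {sorted(set(dupes))}")
    if (df["group"] == "").any():
        bad = df.loc[df["group"] == "", "genome_id"].tolist()
        raise ValueError(f"empty group for genomes: {bad}")
    return df[["genome_id", "group", "taxonomy"]]


def read_samples(path) -> list[str]:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    if not ids:
        raise ValueError(f"no sample ids in {path}")
    return ids


def check_samples_in_metadata(samples, metadata: pd.DataFrame) -> None:
    known = set(metadata["genome_id"])
    missing = [s for s in samples if s not in known]
    if missing:
        raise ValueError(f"sample ids missing from metadata: {missing}")
    extra = known - set(samples)
    if extra:
        log.warning("metadata contains %d genomes not in the sample list", len(extra))


def species_from_taxonomy(taxonomy: str) -> str:
    """Species label: the GTDB ``s__`` field when prefixed, else the last
    semicolon-separated field."""
    return _rank_from_taxonomy(taxonomy, "s__")


def genus_from_taxonomy(taxonomy: str) -> str:
    return _rank_from_taxonomy(taxonomy, "g__")


def _rank_from_taxonomy(taxonomy: str, prefix: str) -> str:
    fields = [f.strip() for f in taxonomy.split(";") if f.strip()]
    for f in fields:
        if f.startswith(prefix):
            return f[len(prefix) :].strip()
    if prefix == "s__" and fields and not any("__" in f for f in fields):
        return fields[-1]
    return ""


@dataclass
class PipelineConfig:
    """All run parameters; mirrors the YAML configuration file."""

    genome_dir: str = "."
    mirna_fasta: str = "mirnas.fa"
    sample_list: str = "samples.txt"
    metadata: str = "metadata.tsv"
    out_dir: str = "results"
    function_map: str = ""  # optional gene -> function TSV
    upstream: int = 15
    downstream: int = 20
    min_cds_len: int = 150
    extension: int = 150
    seed_start: int | None = None
    seed_end: int | None = None
    mfe_cutoff: float = -20.0
    pval_cutoff: float = 0.01
    dg_total_cutoff: float = -15.0
    null_shuffles: int = 200
    min_rel_abundance: float = 0.01
    min_prevalence: float = 0.20
    alpha: float = 0.05
    lfc_min: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.pval_cutoff < 1.0):
            raise ValueError("pval_cutoff must lie in (0, 1)")
        if self.mfe_cutoff >= 0 or self.dg_total_cutoff >= 0:
            raise ValueError("energy cutoffs must be negative")
        for name in ("upstream", "downstream", "min_cds_len", "extension"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.upstream + self.downstream < 1:
            raise ValueError("window must span at least one base")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(vars(config), fh, sort_keys=True)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
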