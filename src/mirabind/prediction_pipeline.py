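"""End-to-end orchestration: windows -> hybridization -> accessibility ->
filter cascade -> result and summary tables.

The filter cascade keeps a (miRNA, window) hit iff

    p < pval_cutoff  AND  dG_duplex < mfe_cutoff  AND  dG_total < dg_total_cutoff

with strict inequalities (defaults 0.01, -20 kcal/mol, -15 kcal/mol).
The Gumbel p-value gates the cascade; the empirical rank p is reported
alongside.  Accessibility is only computed for hits surviving the first
two tests - the opening-energy fold is the expensive stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accessibility import score_site
from .duplex_energy import (
    DEFAULT_PARAMS,
    EnergyParams,
    calibrate_null,
    duplex_mfe,
    hybrid_pvalue,
    pair_rng,
    seed_constraint_ok,
)
from .sequence_io import (
    PipelineConfig,
    SeqRecord,
    check_samples_in_metadata,
    call_orfs,
    file_sha256,
    read_fasta,
    read_gff_cds,
    read_metadata,
    read_mirna_fasta,
    read_samples,
    write_fasta,
)
from .target_windows import WindowParams, extend_window, window_fasta_header, windows_for_genome

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "genome_id",
    "contig",
    "cds_id",
    "gene_name",
    "product",
    "mirna_id",
    "win_start",
    "win_end",
    "strand",
    "target_start",
    "target_end",
    "structure",
    "dG_duplex",
    "pvalue",
    "pvalue_empirical",
    "dG_open",
    "dG_total",
]


@dataclass(frozen=True)
class FilterThresholds:
    pval_cutoff: float = 0.01
    mfe_cutoff: float = -20.0
    dg_total_cutoff: float = -15.0

    def __post_init__(self):
        if not (0.0 < self.pval_cutoff < 1.0):
            raise ValueError("pval_cutoff must lie in (0, 1)")
        if self.mfe_cutoff >= 0 or self.dg_total_cutoff >= 0:
            raise ValueError("energy cutoffs must be negative")


def apply_filters(hits: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()) -> pd.DataFrame:
    """Apply the three-way cascade to a joined hit/accessibility table.

    A row passing the p-value and MFE screens must carry an
    accessibility score; a missing one indicates a broken join upstream.
    """
    if hits.empty:
        return hits.copy()
    pass_p = hits["pvalue"] < thresholds.pval_cutoff
    pass_mfe = hits["dG_duplex"] < thresholds.mfe_cutoff
    needs_access = pass_p & pass_mfe
    if hits.loc[needs_access, "dG_total"].isna().any():
        bad = hits.loc[needs_access & hits["dG_total"].isna(), ["cds_id", "mirna_id"]]
        raise ValueError(
            f"missing accessibility scores for surviving hits: {bad.to_dict('records')}"
        )
    pass_dg = hits["dG_total"] < thresholds.dg_total_cutoff
    keep = pass_p & pass_mfe & pass_dg
    log.info(
        "filter cascade: %d hits -> %d kept (p removed %d, MFE removed %d, dG_total removed %d)",
        len(hits),
        int(keep.sum()),
        int((~pass_p).sum()),
        int((~pass_mfe).sum()),
        int((needs_access & ~pass_dg.fillna(False)).sum()),
    )
    return hits.loc[keep].reset_index(drop=True)


def summarize(records: pd.DataFrame, by: str) -> pd.DataFrame:
    """Distinct-count summary grouped by miRNA or by genome.

    ``n_sites`` counts table rows; genome and gene counts are distinct.
    """
    if by == "mirna":
        key, other = "mirna_id", "genome_id"
    elif by == "genome":
        key, other = "genome_id", "mirna_id"
    else:
        raise ValueError(f"unknown grouping {by!r}; use 'mirna' or 'genome'")
    if records.empty:
        log.info("no records to summarize by %s", by)
        return pd.DataFrame(columns=[key, f"n_{other[:-3]}s", "n_genes", "n_sites"])
    grouped = records.groupby(key)
    out = pd.DataFrame(
        {
            f"n_{other[:-3]}s": grouped[other].nunique(),
            "n_genes": grouped["cds_id"].nunique(),
            "n_sites": grouped.size(),
        }
    ).reset_index()
    return out.sort_values(key, kind="stable").reset_index(drop=True)


def rank_top(table: pd.DataFrame, n: int = 20, metric: str = "n_sites") -> pd.DataFrame:
    """Top-n rows by ``metric``; ties broken lexicographically by id."""
    if n <= 0:
        raise ValueError("n must be positive")
    if table.empty:
        return table.copy()
    id_col = table.columns[0]
    ranked = table.sort_values([metric, id_col], ascending=[False, True], kind="stable")
    return ranked.head(n).reset_index(drop=True)


def hybridize_windows(
    windows,
    mirnas,
    config: PipelineConfig,
    params: EnergyParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Best duplex + Gumbel significance for every (miRNA, window) pair."""
    rows = []
    for win in windows:
        for mir in mirnas:
            hit = duplex_mfe(mir.seq, win.seq, params)
            if hit is None:
                continue
            if not seed_constraint_ok(hit, config.seed_start, config.seed_end, mir.length):
                continue
            rng = pair_rng(config.rng_seed, mir.mirna_id, win.genome_id, win.cds_id)
            null = calibrate_null(mir.seq, win.seq, config.null_shuffles, rng, params)
            p_gum, p_emp = hybrid_pvalue(hit.dG_duplex, null)
            rows.append(
                {
                    "genome_id": win.genome_id,
                    "contig": win.contig,
                    "cds_id": win.cds_id,
                    "gene_name": win.gene_name,
                    "product": win.product,
                    "mirna_id": mir.mirna_id,
                    "win_start": win.win_start,
                    "win_end": win.win_end,
                    "strand": win.strand,
                    "target_start": hit.target_start,
                    "target_end": hit.target_end,
                    "structure": hit.structure,
                    "dG_duplex": hit.dG_duplex,
                    "pvalue": p_gum,
                    "pvalue_empirical": p_emp,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS[:15])


def add_accessibility(
    hits: pd.DataFrame,
    windows,
    contigs_by_genome: dict[str, dict[str, str]],
    config: PipelineConfig,
    params: EnergyParams = DEFAULT_PARAMS,
    thresholds: FilterThresholds | None = None,
) -> pd.DataFrame:
    """Opening-energy re-score for hits passing the first screen."""
    if thresholds is None:
        thresholds = FilterThresholds(
            pval_cutoff=config.pval_cutoff,
            mfe_cutoff=config.mfe_cutoff,
            dg_total_cutoff=config.dg_total_cutoff,
        )
    win_by_key = {(w.genome_id, w.cds_id): w for w in windows}
    hits = hits.copy()
    hits["dG_open"] = np.nan
    hits["dG_total"] = np.nan
    screen = (hits["pvalue"] < thresholds.pval_cutoff) & (
        hits["dG_duplex"] < thresholds.mfe_cutoff
    )
    for idx in hits.index[screen]:
        row = hits.loc[idx]
        win = win_by_key[(row["genome_id"], row["cds_id"])]
        contig_seq = contigs_by_genome[row["genome_id"]][win.contig]
        ext = extend_window(win, contig_seq, config.extension)
        site = (
            ext.site_offset + int(row["target_start"]),
            ext.site_offset + int(row["target_end"]),
        )
        score = score_site(ext.seq, site, float(row["dG_duplex"]), params)
        hits.loc[idx, "dG_open"] = round(score.dG_open, 6)
        hits.loc[idx, "dG_total"] = round(score.dG_total, 6)
    return hits


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_prediction(
    config: PipelineConfig, params: EnergyParams = DEFAULT_PARAMS
) -> dict[str, pd.DataFrame]:
    """Run the whole prediction pipeline and write the output bundle.

    Deterministic for a fixed config and rng_seed (null calibration is
    the only stochastic stage, and its streams are keyed per pair).
    Writes results.tsv, summary_by_mirna.tsv, summary_by_genome.tsv,
    four top-20 ranking tables, a candidate-window FASTA, and a run
    manifest with parameter values and input checksums.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = read_samples(config.sample_list)
    metadata = read_metadata(config.metadata)
    check_samples_in_metadata(samples, metadata)
    mirnas = read_mirna_fasta(config.mirna_fasta)
    wp = WindowParams(
        upstream=config.upstream,
        downstream=config.downstream,
        min_cds_len=config.min_cds_len,
        extension=config.extension,
    )

    genome_dir = Path(config.genome_dir)
    all_windows = []
    contigs_by_genome: dict[str, dict[str, str]] = {}
    checksums = {}
    for gid in samples:
        fasta = _find_genome_fasta(genome_dir, gid)
        recs = read_fasta(fasta)
        contigs = {r.id: r.seq for r in recs}
        contigs_by_genome[gid] = contigs
        checksums[fasta.name] = file_sha256(fasta)
        gff = genome_dir / f"{gid}.gff"
        if gff.exists():
            cds = read_gff_cds(gff, gid, known_contigs=set(contigs))
            checksums[gff.name] = file_sha256(gff)
        else:
            log.info("no GFF for %s; falling back to the naive ORF caller", gid)
            cds = [f for r in recs for f in call_orfs(r, config.min_cds_len, genome_id=gid)]
        all_windows.extend(windows_for_genome(cds, contigs, wp))
    for p in (config.mirna_fasta, config.sample_list, config.metadata):
        checksums[Path(p).name] = file_sha256(p)

    if not all_windows:
        log.warning("zero candidate windows extracted; writing empty outputs")
    if all_windows:
        write_fasta(
            [SeqRecord(id=window_fasta_header(w), seq=w.seq) for w in all_windows],
            out_dir / "candidate_windows.fa",
        )

    thresholds = FilterThresholds(
        pval_cutoff=config.pval_cutoff,
        mfe_cutoff=config.mfe_cutoff,
        dg_total_cutoff=config.dg_total_cutoff,
    )
    hits = hybridize_windows(all_windows, mirnas, config, params)
    hits = add_accessibility(hits, all_windows, contigs_by_genome, config, params, thresholds)
    if hits.empty:
        hits = pd.DataFrame(columns=RESULT_COLUMNS)
    results = apply_filters(hits, thresholds)

    by_mirna = summarize(results, "mirna")
    by_genome = summarize(results, "genome")
    bundle = {
        "hits": hits,
        "results": results,
        "summary_by_mirna": by_mirna,
        "summary_by_genome": by_genome,
        "top20_mirna_by_genomes": rank_top(by_mirna, 20, "n_genomes") if not by_mirna.empty else by_mirna,
        "top20_mirna_by_genes": rank_top(by_mirna, 20, "n_genes") if not by_mirna.empty else by_mirna,
        "top20_genome_by_mirnas": rank_top(by_genome, 20, "n_mirnas") if not by_genome.empty else by_genome,
        "top20_genome_by_genes": rank_top(by_genome, 20, "n_genes") if not by_genome.empty else by_genome,
    }
    _write_tsv(hits, out_dir / "hits.tsv")
    _write_tsv(results, out_dir / "results.tsv")
    _write_tsv(by_mirna, out_dir / "summary_by_mirna.tsv")
    _write_tsv(by_genome, out_dir / "summary_by_genome.tsv")
    for name in (
        "top20_mirna_by_genomes",
        "top20_mirna_by_genes",
        "top20_genome_by_mirnas",
        "top20_genome_by_genes",
    ):
        _write_tsv(bundle[name], out_dir / f"{name}.tsv")
    manifest = {
        "tool": "mirabind",
        "version": __version__,
        "parameters": dict(vars(config)),
        "energy_params": dict(vars(params)),
        "input_checksums": checksums,
        "n_windows": len(all_windows),
        "n_hits": int(len(hits)),
        "n_predictions": int(len(results)),
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return bundle


def _find_genome_fasta(genome_dir: Path, gid: str) -> Path:
    for ext in (".fa", ".fasta", ".fna"):
        p = genome_dir / f"{gid}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(f"no FASTA for genome {gid!r} in {genome_dir}")
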