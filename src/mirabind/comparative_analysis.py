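"""Shared/unique element analysis across sample groups.

Given final predictions and genome metadata, partitions records by group
and computes exact set overlaps (Venn regions) of miRNAs, genes, and
species-level taxa, plus per-group distinct-count summaries.  Executed
only when the metadata defines more than one group.

Cross-genome gene identity is not well defined for metagenome-assembled
genomes; the convention here is gene_name when present, else the
lower-cased product string, else the (genome-local, hence never shared)
cds_id.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .sequence_io import species_from_taxonomy

log = logging.getLogger(__name__)

ELEMENT_KINDS = ("mirna", "gene", "taxon")


def gene_label(row) -> str:
    if row.get("gene_name"):
        return str(row["gene_name"])
    if row.get("product"):
        return str(row["product"]).lower()
    return str(row["cds_id"])


@dataclass
class OverlapResult:
    element_kind: str
    group_sets: dict[str, set[str]]
    # region key: frozenset of group labels; value: elements exclusive to
    # exactly that combination of groups
    regions: dict[frozenset, set[str]] = field(default_factory=dict)

    @property
    def region_counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def union_size(self) -> int:
        return len(set().union(*self.group_sets.values())) if self.group_sets else 0


def split_groups(records: pd.DataFrame, metadata: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition prediction records by metadata group."""
    group_of = dict(zip(metadata["genome_id"], metadata["group"]))
    unknown = sorted(set(records["genome_id"]) - set(group_of))
    if unknown:
        raise ValueError(f"records reference genomes with no metadata group: {unknown}")
    groups = records["genome_id"].map(group_of)
    parts = {g: records.loc[groups == g].reset_index(drop=True) for g in sorted(groups.unique())}
    if len(parts) < 2:
        log.info("only one sample group present; comparative analysis will be skipped")
    return parts


def _element_set(records: pd.DataFrame, element_kind: str, metadata: pd.DataFrame | None) -> set[str]:
    if element_kind not in ELEMENT_KINDS:
        raise ValueError(f"unknown element_kind {element_kind!r}")
    if records.empty:
        return set()
    if element_kind == "mirna":
        return set(records["mirna_id"])
    if element_kind == "gene":
        return {gene_label(row) for _, row in records.iterrows()}
    if element_kind == "taxon":
        if metadata is None:
            raise ValueError("taxon overlaps require metadata")
        tax_of = dict(zip(metadata["genome_id"], metadata["taxonomy"]))
        out = set()
        for gid in records["genome_id"].unique():
            sp = species_from_taxonomy(tax_of.get(gid, ""))
            if sp:
                out.add(sp)
            else:
                log.warning("genome %s has no species-level taxonomy; excluded from overlaps", gid)
        return out
    raise ValueError(f"unknown element_kind {element_kind!r}")


def overlap_sets(
    partitions: dict[str, pd.DataFrame],
    element_kind: str,
    metadata: pd.DataFrame | None = None,
) -> OverlapResult:
    """Exact Venn-region decomposition of per-group element sets.

    For every non-empty subset S of groups, the region holds elements in
    all groups of S and in no other group; region counts therefore sum
    to the union size.
    """
    if len(partitions) < 2:
        raise ValueError("overlap analysis requires >= 2 groups")
    sets = {g: _element_set(df, element_kind, metadata) for g, df in partitions.items()}
    labels = sorted(sets)
    regions: dict[frozenset, set[str]] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(sets[g] for g in combo))
            outside = set().union(*(sets[g] for g in labels if g not in combo)) if len(combo) < len(labels) else set()
            regions[frozenset(combo)] = inside - outside
    return OverlapResult(element_kind=element_kind, group_sets=sets, regions=regions)


def unique_counts(
    partitions: dict[str, pd.DataFrame], metadata: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-group distinct counts of miRNAs, genes, genomes and species."""
    rows = []
    for g in sorted(partitions):
        df = partitions[g]
        rows.append(
            {
                "group": g,
                "n_mirnas": df["mirna_id"].nunique() if not df.empty else 0,
                "n_genes": len(_element_set(df, "gene", metadata)),
                "n_genomes": df["genome_id"].nunique() if not df.empty else 0,
                "n_taxa": len(_element_set(df, "taxon", metadata)) if metadata is not None else 0,
            }
        )
    return pd.DataFrame(rows)


def region_label(region: frozenset) -> str:
    return "&".join(sorted(region))


def overlap_tables(result: OverlapResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(counts table, element list table) backing Venn output."""
    counts = pd.DataFrame(
        [
            {"element_kind": result.element_kind, "region": region_label(k), "count": len(v)}
            for k, v in sorted(result.regions.items(), key=lambda kv: region_label(kv[0]))
        ]
    )
    lists = pd.DataFrame(
        [
            {"element_kind": result.element_kind, "region": region_label(k), "element": e}
            for k, v in sorted(result.regions.items(), key=lambda kv: region_label(kv[0]))
            for e in sorted(v)
        ],
        columns=["element_kind", "region", "element"],
    )
    return counts, lists


def write_comparative_outputs(partitions, metadata, out_dir) -> None:
    """Emit overlap count/list TSVs and the unique-count histogram data."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_counts, all_lists = [], []
    for kind in ELEMENT_KINDS:
        res = overlap_sets(partitions, kind, metadata)
        counts, lists = overlap_tables(res)
        all_counts.append(counts)
        all_lists.append(lists)
    pd.concat(all_counts, ignore_index=True).to_csv(
        out_dir / "overlap_counts.tsv", sep="\t", index=False
    )
    pd.concat(all_lists, ignore_index=True).to_csv(
        out_dir / "overlap_elements.tsv", sep="\t", index=False
    )
    unique_counts(partitions, metadata).to_csv(
        out_dir / "unique_counts.tsv", sep="\t", index=False
    )
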