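"""Differential abundance of functional categories between two groups.

Each genome (sample) contributes the set of its predicted target genes;
a user-supplied gene->function table maps those genes onto a functional
hierarchy.  Per sample, function counts are normalized to within-sample
relative abundances, functions are filtered on mean abundance (default
>= 0.01), prevalence (present in >= 20% of samples) and on being shared
by both groups, and surviving functions are tested with the two-sided
Wilcoxon rank-sum test with Benjamini-Hochberg FDR control.  A function
is called significant when adjusted p <= alpha and |log2FC| > lfc_min.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatsParams:
    min_rel_abundance: float = 0.01
    min_prevalence: float = 0.20
    alpha: float = 0.05
    lfc_min: float = 1.0
    pseudocount: float = 1e-6

    def __post_init__(self):
        for name in ("min_rel_abundance", "min_prevalence", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.lfc_min <= 0 or self.pseudocount <= 0:
            raise ValueError("lfc_min and pseudocount must be positive")


# profile matching the published real-data run (looser prevalence/FDR)
REAL_DATA_PROFILE = StatsParams(min_prevalence=0.05, alpha=0.1)


@dataclass(frozen=True)
class DiffAbundanceResult:
    function_id: str
    mean_a: float
    mean_b: float
    p_raw: float
    p_adj: float
    log2fc: float
    significant: bool
    test_branch: str = ""


def read_function_map(path, level: int | None = None) -> pd.DataFrame:
    """Read the gene->function TSV (gene_label, function_id,
    function_name, level), optionally restricted to one hierarchy level."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_label": str, "function_id": str})
    required = {"gene_label", "function_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"function map {path} missing columns: {sorted(missing)}")
    if "function_name" not in df.columns:
        df["function_name"] = df["function_id"]
    if "level" not in df.columns:
        df["level"] = 1
    if level is not None:
        df = df[df["level"] == level].reset_index(drop=True)
    return df


def function_counts(records: pd.DataFrame, function_map: pd.DataFrame) -> pd.DataFrame:
    """Samples x functions count matrix from prediction records.

    A gene predicted as a target in a genome contributes one count to
    each function it is annotated with (genes may carry several).
    """
    from .comparative_analysis import gene_label

    rows = []
    fmap = function_map.groupby("gene_label")["function_id"].apply(list).to_dict()
    for gid, sub in records.groupby("genome_id"):
        genes = {gene_label(row) for _, row in sub.iterrows()}
        counts: dict[str, int] = {}
        for g in genes:
            for fn in fmap.get(g, []):
                counts[fn] = counts.get(fn, 0) + 1
        rows.append(pd.Series(counts, name=gid))
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows).fillna(0.0).sort_index()


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a samples x functions count matrix.

    Samples with zero annotated genes are dropped with a warning.
    """
    if counts.empty:
        return counts.copy()
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        log.warning("dropping %d sample(s) with no annotated target genes", int(empty.sum()))
    kept = counts.loc[~empty]
    return kept.div(kept.sum(axis=1), axis=0)


def filter_functions(
    rel: pd.DataFrame, groups: pd.Series, params: StatsParams = StatsParams()
) -> pd.DataFrame:
    """Abundance / prevalence / shared-between-groups filter.

    Keeps functions whose mean relative abundance over all samples is >=
    ``min_rel_abundance``, that are present (abundance > 0) in >=
    ``min_prevalence`` of all samples, and that are present in every
    group being compared.
    """
    if rel.empty:
        return rel.copy()
    groups = groups.reindex(rel.index)
    if groups.isna().any():
        raise ValueError(f"samples missing a group: {list(rel.index[groups.isna()])}")
    for g, n in groups.value_counts().items():
        if n < 2:
            log.warning("group %r has only %d sample(s); tests will be underpowered", g, n)
    mean_ok = rel.mean(axis=0) >= params.min_rel_abundance
    prev_ok = (rel > 0).mean(axis=0) >= params.min_prevalence
    shared_ok = pd.Series(True, index=rel.columns)
    for g in groups.unique():
        shared_ok &= (rel.loc[groups == g] > 0).any(axis=0)
    keep = mean_ok & prev_ok & shared_ok
    return rel.loc[:, keep]


def wilcoxon_rank_sum(x, y) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration when the combined sample is small (n <= 12)
    and tie-free; otherwise the normal approximation with tie and
    continuity corrections.  Returns (p, branch used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups need at least one observation")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0, "degenerate"
    no_ties = len(np.unique(combined)) == len(combined)
    if len(combined) <= 12 and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.pvalue), "exact"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue), "normal"


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(mean_a: float, mean_b: float, pseudocount: float = 1e-6) -> float:
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be >= 0")
    return math.log2((mean_a + pseudocount) / (mean_b + pseudocount))


def diff_abundance(
    rel: pd.DataFrame,
    groups: pd.Series,
    params: StatsParams = StatsParams(),
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Full two-group differential-abundance analysis.

    ``rel`` is a samples x functions relative-abundance matrix (already
    or not yet filtered; the filter is applied here).  log2FC is
    log2((mean of first group + pc) / (mean of second group + pc));
    groups are ordered alphabetically unless ``group_order`` is given.
    """
    groups = groups.reindex(rel.index)
    labels = sorted(groups.dropna().unique()) if group_order is None else list(group_order)
    if len(labels) != 2:
        raise ValueError(f"differential abundance requires exactly 2 groups, got {labels}")
    ga, gb = labels
    filtered = filter_functions(rel, groups, params)
    rows = []
    for fn in filtered.columns:
        xa = filtered.loc[groups == ga, fn].to_numpy()
        xb = filtered.loc[groups == gb, fn].to_numpy()
        p, branch = wilcoxon_rank_sum(xa, xb)
        rows.append(
            {
                "function_id": fn,
                f"mean_{ga}": float(xa.mean()),
                f"mean_{gb}": float(xb.mean()),
                "p_raw": p,
                "log2fc": log2_fold_change(float(xa.mean()), float(xb.mean()), params.pseudocount),
                "test_branch": branch,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["function_id", f"mean_{ga}", f"mean_{gb}", "p_raw", "p_adj", "log2fc", "significant", "test_branch"]
        )
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = (out["p_adj"] <= params.alpha) & (out["log2fc"].abs() > params.lfc_min)
    return out[
        ["function_id", f"mean_{ga}", f"mean_{gb}", "p_raw", "p_adj", "log2fc", "significant", "test_branch"]
    ]
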