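"""Cross-sample statistics and report tables.

Per-gene medians by sample group, two-sample Wilcoxon rank-sum comparisons
(with optional Benjamini-Hochberg adjustment), pathway-level aggregation of
gene depths, and ranked top-taxa tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import Catalog, PROCESSES
from .errors import ValidationError
from .io import Sample


@dataclass(frozen=True)
class GroupComparison:
    gene_symbol: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float  # Mann-Whitney U for group_a
    p_value: float
    method: str


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    gene_symbol: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

    Uses the exact null distribution for small untied samples and the normal
    approximation with continuity correction otherwise (the wilcox.test
    convention).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("compare_groups: both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    exact = (not has_ties) and min(a.size, b.size) <= 25
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        gene_symbol=gene_symbol,
        group_a=group_a,
        group_b=group_b,
        n_a=int(a.size),
        n_b=int(b.size),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
    )


def _grouping_map(samples: Mapping[str, Sample], grouping: str) -> pd.Series:
    if grouping == "all":
        return pd.Series({s: "all" for s in samples})
    if grouping == "lake":
        return pd.Series({s: samples[s].lake for s in samples})
    if grouping == "month":
        return pd.Series({s: samples[s].month for s in samples})
    raise ValidationError(
        f"unknown grouping {grouping!r}; valid: all, lake, month"
    )


def gene_medians_by_group(
    gene_depths: pd.DataFrame,
    samples: Mapping[str, Sample],
    grouping: str = "all",
) -> pd.DataFrame:
    """Median gene depth per (gene, group); grouping in {all, lake, month}."""
    groups = _grouping_map(samples, grouping)
    df = gene_depths.copy()
    df["group"] = df["sample_id"].map(groups)
    out = (
        df.groupby(["gene_symbol", "group"])["gene_depth"]
        .median()
        .rename("median_gene_depth")
        .reset_index()
    )
    out["grouping"] = grouping
    return out


def compare_gene_across_groups(
    gene_depths: pd.DataFrame,
    samples: Mapping[str, Sample],
    grouping: str = "lake",
    adjust: bool = True,
) -> pd.DataFrame:
    """All pairwise group comparisons per gene, optionally BH-adjusted.

    The adjusted column is a convenience (the primary report is raw p-values);
    adjustment is across all (gene, pair) tests.
    """
    groups = _grouping_map(samples, grouping)
    df = gene_depths.copy()
    df["group"] = df["sample_id"].map(groups)
    labels = sorted(df["group"].unique())
    rows = []
    for gene, gdf in df.groupby("gene_symbol"):
        for i, ga in enumerate(labels):
            for gb in labels[i + 1:]:
                va = gdf.loc[gdf["group"] == ga, "gene_depth"].to_numpy()
                vb = gdf.loc[gdf["group"] == gb, "gene_depth"].to_numpy()
                if va.size == 0 or vb.size == 0:
                    continue
                c = compare_groups(va, vb, gene, ga, gb)
                rows.append(c.__dict__)
    out = pd.DataFrame(rows)
    if adjust and not out.empty:
        out["p_adjusted"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def pathway_abundance(
    gene_depths: pd.DataFrame,
    catalog: Catalog,
    aggregation: str = "sum",
) -> pd.DataFrame:
    """Aggregate member-gene depths to the seven nitrogen-cycle processes.

    Default aggregation is the sum over member genes (preserves the
    copy-number reading when member genes sit on distinct loci); 'max' and
    'mean' are alternatives. Processes whose member genes were all absent get
    0.0 with not_found=True — the 'dashed arrow' cases.
    """
    if aggregation not in ("sum", "max", "mean"):
        raise ValidationError(
            f"unknown aggregation {aggregation!r}; valid: sum, max, mean"
        )
    df = gene_depths.copy()
    df["process"] = df["gene_symbol"].map(
        lambda g: catalog.entry(g).process if g in catalog else None
    )
    df = df[df["process"].isin(PROCESSES)]
    agg_fn = {"sum": "sum", "max": "max", "mean": "mean"}[aggregation]
    rows = []
    for sample_id, sdf in df.groupby("sample_id"):
        for process in PROCESSES:
            pdf = sdf[sdf["process"] == process]
            if pdf.empty:
                value, found = 0.0, False
            else:
                value = float(pdf["gene_depth"].agg(agg_fn))
                found = bool((pdf["gene_depth"] > 0).any())
            rows.append(
                {"sample_id": sample_id, "process": process,
                 "abundance": value, "not_found": not found,
                 "aggregation": aggregation}
            )
    return pd.DataFrame(rows)


def top_taxa_report(
    metrics: Mapping[str, Mapping[str, float]],
    k: int,
    rank: str = "",
) -> pd.DataFrame:
    """Top-k taxa per metric (e.g. {'mag_count': ..., 'depth': ...}).

    Ties break deterministically by taxon name; k beyond the number of taxa
    returns the full ranking.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    rows = []
    for metric, values in metrics.items():
        ranked = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        for pos, (taxon, value) in enumerate(ranked, start=1):
            rows.append(
                {"metric": metric, "rank_position": pos, "taxon": taxon,
                 "value": value, "rank": rank}
            )
    return pd.DataFrame(rows)
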