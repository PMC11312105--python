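"""MAG-level logic.

Quality filtering at the MIMAG and tree-inclusion thresholds, the
taxon-level gene-presence rule (>25% of MAGs or any >90%-complete carrier),
multi-enzyme-type co-occurrence counting, taxonomy-novelty summaries, and
ANI-threshold species clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import ComplexRule, TypeGroupScheme, complex_present
from .errors import ValidationError
from .io import (
    MAG,
    MIMAG_THRESHOLDS,
    QualityThresholds,
    TREE_THRESHOLDS,
    TaxonomyString,
)


def percent_half_up(count: float, denominator: float, decimals: int = 1) -> float:
    """100*count/denominator rounded half-up at ``decimals`` (as printed in
    report tables; banker's rounding would flip boundary cases)."""
    if denominator == 0:
        raise ValidationError("percentage denominator is zero")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) / Decimal(denominator) * 100).quantize(q, ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class PresenceRule:
    """Taxon-level gene presence: strict >min_fraction of MAGs, or a carrier
    MAG with completeness strictly > hq_completeness."""

    min_fraction: float = 0.25
    hq_completeness: float = 90.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_fraction <= 1:
            raise ValidationError("min_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PresenceEvidence:
    gene_symbol: str
    present: bool
    n_mags: int
    n_with_gene: int
    fraction: float
    fraction_clause: bool
    hq_clause: bool
    hq_carriers: tuple[str, ...]


def _passes(mag: MAG, thresholds: QualityThresholds) -> bool:
    if np.isnan(mag.completeness) or np.isnan(mag.contamination):
        raise ValidationError(
            f"MAG {mag.mag_id}: missing completeness/contamination"
        )
    return (
        mag.completeness >= thresholds.min_completeness
        and mag.contamination < thresholds.max_contamination
    )


def filter_mags(
    mags: Iterable[MAG], thresholds: QualityThresholds = MIMAG_THRESHOLDS
) -> list[MAG]:
    """Retain MAGs with completeness >= floor AND contamination < ceiling.

    The boundary semantics are deliberate: completeness inclusive,
    contamination exclusive.
    """
    return [m for m in mags if _passes(m, thresholds)]


def tree_filter(mags: Iterable[MAG]) -> list[MAG]:
    """Stricter retention for phylogenetic-tree construction (>=70%, <7%)."""
    return filter_mags(mags, TREE_THRESHOLDS)


def taxon_gene_presence(
    taxon_mags: Sequence[MAG],
    gene_symbol: str,
    mag_gene_sets: Mapping[str, set[str]],
    rule: PresenceRule = PresenceRule(),
) -> PresenceEvidence:
    """Decide whether a gene is 'present in the taxon'.

    True iff strictly more than ``min_fraction`` of the taxon's MAGs carry it,
    or any carrier has completeness strictly above ``hq_completeness`` (the
    carrier must also satisfy the MIMAG contamination ceiling — only retained
    MAGs exist downstream).
    """
    if not taxon_mags:
        raise ValidationError("taxon has no MAGs; presence undefined")
    carriers = [
        m for m in taxon_mags
        if gene_symbol in mag_gene_sets.get(m.mag_id, set())
    ]
    fraction = len(carriers) / len(taxon_mags)
    fraction_clause = fraction > rule.min_fraction
    hq = tuple(
        m.mag_id for m in carriers
        if m.completeness > rule.hq_completeness
        and m.contamination < MIMAG_THRESHOLDS.max_contamination
    )
    hq_clause = bool(hq)
    return PresenceEvidence(
        gene_symbol=gene_symbol,
        present=fraction_clause or hq_clause,
        n_mags=len(taxon_mags),
        n_with_gene=len(carriers),
        fraction=fraction,
        fraction_clause=fraction_clause,
        hq_clause=hq_clause,
        hq_carriers=hq,
    )


@dataclass(frozen=True)
class MultiTypeSummary:
    """Co-occurrence of enzyme type groups across MAGs."""

    scheme_id: str
    per_mag_types: Mapping[str, frozenset[str]]
    n_mags: int
    n_with_any: int
    n_multi: int
    denominator: int

    @property
    def n_single(self) -> int:
        return self.n_with_any - self.n_multi

    def pct_with_any(self, decimals: int = 1) -> float:
        """Percent of the stated denominator with >=1 type."""
        return percent_half_up(self.n_with_any, self.denominator, decimals)

    def pct_multi(self, decimals: int = 2) -> float:
        """Percent of type-bearing MAGs with >1 type."""
        return percent_half_up(self.n_multi, self.n_with_any, decimals)

    def pct_single(self, decimals: int = 1) -> float:
        """Percent of type-bearing MAGs with exactly one type."""
        return percent_half_up(self.n_single, self.n_with_any, decimals)


def count_multitype(
    mag_gene_sets: Mapping[str, set[str]],
    scheme: TypeGroupScheme,
    complex_rules: Mapping[str, ComplexRule],
    denominator: int | None = None,
) -> MultiTypeSummary:
    """Count MAGs encoding one vs more than one enzyme type of a scheme.

    A type counts as encoded when any of its complexes satisfies its
    ComplexRule (so NarGHI needs all three subunits, NapAB any). The
    percentage denominator defaults to the number of MAGs given but can be
    stated explicitly (e.g. the full MAG count of the study).
    """
    if not scheme.groups:
        raise ValidationError(f"scheme {scheme.scheme_id}: no type groups")
    per_mag: dict[str, frozenset[str]] = {}
    for mag_id, genes in mag_gene_sets.items():
        types = frozenset(
            label
            for label, complexes in scheme.groups.items()
            if any(
                complex_present(genes, complex_rules[cid]) for cid in complexes
            )
        )
        per_mag[mag_id] = types
    n_any = sum(1 for t in per_mag.values() if t)
    n_multi = sum(1 for t in per_mag.values() if len(t) > 1)
    return MultiTypeSummary(
        scheme_id=scheme.scheme_id,
        per_mag_types=per_mag,
        n_mags=len(per_mag),
        n_with_any=n_any,
        n_multi=n_multi,
        denominator=denominator if denominator is not None else len(per_mag),
    )


def novelty_summary(
    taxonomies: Iterable[TaxonomyString],
    rank: str,
    denominator: int | None = None,
    decimals: int = 1,
) -> tuple[int, float]:
    """(count, percent) of taxonomies unassigned at ``rank``.

    Assigned-but-unnamed GTDB placeholders (alphanumeric species epithets)
    count as known; only empty suffixes are novel.
    """
    taxa = list(taxonomies)
    denom = denominator if denominator is not None else len(taxa)
    if denom == 0:
        raise ValidationError("novelty denominator is zero")
    n_unknown = sum(1 for t in taxa if t.is_unknown(rank))
    return n_unknown, percent_half_up(n_unknown, denom, decimals)


def _check_symmetric(ani: pd.DataFrame) -> None:
    if list(ani.index) != list(ani.columns):
        raise ValidationError("ANI matrix index and columns differ")
    if not np.allclose(ani.values, ani.values.T, atol=1e-9):
        raise ValidationError("ANI matrix is not symmetric")


def quality_score(completeness: float, contamination: float) -> float:
    """Dereplication quality score: completeness - 5 x contamination."""
    return completeness - 5.0 * contamination


def cluster_species_from_ani(
    ani: pd.DataFrame,
    quality: pd.DataFrame | None = None,
    threshold: float = 95.0,
    method: str = "greedy",
) -> pd.Series:
    """Group MAGs into species clusters at an ANI threshold (default 95%).

    method="greedy": deterministic best-quality-first representative
    clustering — seeds ordered by descending completeness - 5*contamination
    (ties by mag_id); each MAG joins the first representative with
    ANI >= threshold, else founds a new cluster. method="single":
    single-linkage connected components of the >=threshold graph.

    Returns mag_id -> cluster representative id.
    """
    _check_symmetric(ani)
    ids = list(ani.index)
    if method == "single":
        import networkx as nx  # stdlib-adjacent; in the scientific stack

        g = nx.Graph()
        g.add_nodes_from(ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if ani.at[a, b] >= threshold:
                    g.add_edge(a, b)
        assignment = {}
        for comp in nx.connected_components(g):
            rep = min(comp)
            for m in comp:
                assignment[m] = rep
        return pd.Series(assignment).sort_index()
    if method != "greedy":
        raise ValidationError(f"unknown clustering method {method!r}")

    def sort_key(mag_id: str):
        if quality is not None and mag_id in quality.index:
            row = quality.loc[mag_id]
            return (-quality_score(row["completeness"], row["contamination"]),
                    mag_id)
        return (0.0, mag_id)

    order = sorted(ids, key=sort_key)
    reps: list[str] = []
    assignment: dict[str, str] = {}
    for mag_id in order:
        for rep in reps:
            if ani.at[mag_id, rep] >= threshold:
                assignment[mag_id] = rep
                break
        else:
            reps.append(mag_id)
            assignment[mag_id] = mag_id
    return pd.Series(assignment).sort_index()
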