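"""Gene and MAG abundance statistics.

Two estimators drive the whole analysis:

* **Gene depth** (average copy number per genome): for a gene of interest,
  the sum of RPKM over the contigs carrying it (set Q), divided by the sum of
  RPKM over the contigs carrying the universal single-copy marker *rpsB*
  (set C). Because every genome carries exactly one marker copy, the ratio
  estimates the abundance-weighted mean copy number of the gene per genome.

* **MAG depth**: the sum of member-contig mean depths ("MAG raw depth"),
  normalized by MAG size (bp) and by the sample's sequencing effort
  (millions of read pairs), comparable across MAGs and samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .catalog import Catalog, DEFAULT_MARKER
from .errors import ValidationError
from .io import DEFAULT_READ_LENGTH, DepthTable, MAG, Sample, TaxonomyString


@dataclass(frozen=True)
class GeneDepthResult:
    """Marker-normalized gene abundance for one (gene, sample)."""

    gene_symbol: str
    sample_id: str
    gene_depth: float
    numerator_rpkm: float
    denominator_rpkm: float
    n_contigs_Q: int
    n_contigs_C: int


@dataclass(frozen=True)
class MAGDepthResult:
    """Raw and normalized MAG abundance for one (MAG, sample)."""

    mag_id: str
    sample_id: str
    raw_depth: float
    mag_depth: float
    relative_abundance: float = float("nan")


def rpkm(read_count: float, length_bp: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of contig per million mapped reads.

    rpkm = read_count * 1e9 / (length_bp * total_mapped_reads).
    """
    if length_bp <= 0:
        raise ValidationError(f"length_bp must be > 0, got {length_bp}")
    if total_mapped_reads <= 0:
        raise ValidationError(
            f"total_mapped_reads must be > 0, got {total_mapped_reads}"
        )
    return read_count * 1e9 / (length_bp * total_mapped_reads)


def _contig_rpkm(
    table: DepthTable, sample: Sample, read_length: int
) -> pd.Series:
    counts = table.counts(read_length)[sample.sample_id]
    return counts * 1e9 / (table.lengths * sample.total_mapped_reads)


def _gene_contigs(annotations: pd.DataFrame, gene_symbol: str) -> set[str]:
    return set(
        annotations.loc[annotations["gene_symbol"] == gene_symbol, "contig_id"]
    )


def gene_depth(
    gene_symbol: str,
    sample: Sample,
    table: DepthTable,
    annotations: pd.DataFrame,
    marker: str = DEFAULT_MARKER,
    read_length: int = DEFAULT_READ_LENGTH,
) -> GeneDepthResult:
    """Average copy number of ``gene_symbol`` per genome in ``sample``.

    Q and C are *sets* of contigs: a contig carrying both the gene and the
    marker contributes to both sums; multiple copies on one contig count once.
    An absent gene (empty Q) yields 0.0; an absent marker is an error, since
    the statistic is undefined without its denominator.
    """
    q_ids = _gene_contigs(annotations, gene_symbol)
    c_ids = _gene_contigs(annotations, marker)
    if not c_ids:
        raise ValidationError(
            f"no contigs carry the marker gene {marker!r}; "
            "gene depth is undefined without the marker denominator"
        )
    missing = (q_ids | c_ids) - set(table.contig_ids)
    if missing:
        raise ValidationError(
            f"annotated contigs missing from depth table: {sorted(missing)[:5]}"
        )
    contig_rpkm = _contig_rpkm(table, sample, read_length)
    denom = float(contig_rpkm.loc[sorted(c_ids)].sum())
    if denom <= 0:
        raise ValidationError(
            f"marker {marker!r} contigs have zero total RPKM in sample "
            f"{sample.sample_id}; gene depth undefined"
        )
    numer = float(contig_rpkm.loc[sorted(q_ids)].sum()) if q_ids else 0.0
    return GeneDepthResult(
        gene_symbol=gene_symbol,
        sample_id=sample.sample_id,
        gene_depth=numer / denom,
        numerator_rpkm=numer,
        denominator_rpkm=denom,
        n_contigs_Q=len(q_ids),
        n_contigs_C=len(c_ids),
    )


def gene_depth_profile(
    samples: Mapping[str, Sample],
    table: DepthTable,
    annotations: pd.DataFrame,
    catalog: Catalog,
    marker: str = DEFAULT_MARKER,
    read_length: int = DEFAULT_READ_LENGTH,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Gene-depth table over every catalog gene and sample.

    Genes never seen by annotation get explicit 0.0 rows so 'not found'
    genes stay reportable.
    """
    gene_list = sorted(genes) if genes is not None else sorted(catalog.gene_symbols)
    contigs_of = {
        g: sorted(_gene_contigs(annotations, g)) for g in gene_list
    }
    c_ids = sorted(_gene_contigs(annotations, marker))
    if not c_ids:
        raise ValidationError(
            f"no contigs carry the marker gene {marker!r}; "
            "gene depth is undefined without the marker denominator"
        )
    all_ids = set().union(*contigs_of.values(), c_ids)
    missing = all_ids - set(table.contig_ids)
    if missing:
        raise ValidationError(
            f"annotated contigs missing from depth table: {sorted(missing)[:5]}"
        )
    rows = []
    for sample_id in sorted(samples):
        sample = samples[sample_id]
        contig_rpkm = _contig_rpkm(table, sample, read_length)
        denom = float(contig_rpkm.loc[c_ids].sum())
        if denom <= 0:
            raise ValidationError(
                f"marker {marker!r} contigs have zero total RPKM in sample "
                f"{sample_id}; gene depth undefined"
            )
        for g in gene_list:
            q = contigs_of[g]
            numer = float(contig_rpkm.loc[q].sum()) if q else 0.0
            rows.append(GeneDepthResult(
                gene_symbol=g, sample_id=sample_id,
                gene_depth=numer / denom,
                numerator_rpkm=numer, denominator_rpkm=denom,
                n_contigs_Q=len(q), n_contigs_C=len(c_ids),
            ).__dict__)
    return pd.DataFrame(rows)


def mag_raw_depth(mag: MAG, sample_id: str, table: DepthTable) -> float:
    """Sum of member-contig mean depths (not length-weighted — the literal
    'sum the depths of individual contigs' convention; see mag_depth for the
    length-weighted alternative)."""
    missing = sorted(mag.contig_ids - set(table.contig_ids))
    if missing:
        raise ValidationError(
            f"MAG {mag.mag_id}: contigs missing from depth table: {missing[:5]}"
        )
    return float(table.depths.loc[sorted(mag.contig_ids), sample_id].sum())


def mag_depth(
    mag: MAG,
    sample: Sample,
    table: DepthTable,
    length_weighted: bool = False,
) -> MAGDepthResult:
    """Normalized MAG depth: (raw depth / MAG size bp) / million read pairs.

    ``length_weighted=True`` replaces the raw sum with the length-weighted
    mean member depth — less sensitive to how finely the MAG is fragmented.
    """
    if mag.size_bp <= 0:
        raise ValidationError(f"MAG {mag.mag_id}: size_bp must be > 0")
    if sample.raw_reads_size <= 0:
        raise ValidationError(
            f"sample {sample.sample_id}: raw_reads_size must be > 0"
        )
    if length_weighted:
        ids = sorted(mag.contig_ids)
        missing = sorted(mag.contig_ids - set(table.contig_ids))
        if missing:
            raise ValidationError(
                f"MAG {mag.mag_id}: contigs missing from depth table: {missing[:5]}"
            )
        w = table.lengths.loc[ids]
        raw = float((table.depths.loc[ids, sample.sample_id] * w).sum() / w.sum())
    else:
        raw = mag_raw_depth(mag, sample.sample_id, table)
    value = (raw / mag.size_bp) / sample.raw_reads_size
    return MAGDepthResult(mag.mag_id, sample.sample_id, raw, value)


def mag_depth_table(
    mags: Mapping[str, MAG],
    samples: Mapping[str, Sample],
    table: DepthTable,
    length_weighted: bool = False,
) -> pd.DataFrame:
    """MAG depths with within-sample relative abundances (shares sum to 1)."""
    rows = []
    for sample_id in sorted(samples):
        sample = samples[sample_id]
        results = [
            mag_depth(mags[m], sample, table, length_weighted)
            for m in sorted(mags)
        ]
        total = sum(r.mag_depth for r in results)
        for r in results:
            rel = r.mag_depth / total if total > 0 else np.nan
            rows.append({**r.__dict__, "relative_abundance": rel})
    return pd.DataFrame(rows)


def community_composition(
    mag_depths: pd.DataFrame,
    taxonomies: Mapping[str, TaxonomyString],
    rank: str,
) -> pd.DataFrame:
    """Per-sample relative abundance of taxa at ``rank`` from MAG depths.

    Unassigned ranks aggregate under 'unknown'. Shares sum to 1 per sample;
    rows are ordered by descending share then taxon name (stable ties).
    """
    rows = []
    for sample_id, grp in mag_depths.groupby("sample_id"):
        total = grp["mag_depth"].sum()
        if total <= 0:
            raise ValidationError(
                f"sample {sample_id}: all MAG depths are zero; "
                "composition undefined"
            )
        shares: dict[str, float] = {}
        for r in grp.itertuples():
            tax = taxonomies[r.mag_id]
            name = tax.rank(rank) if not tax.is_unknown(rank) else "unknown"
            shares[name] = shares.get(name, 0.0) + r.mag_depth / total
        for taxon in sorted(shares, key=lambda t: (-shares[t], t)):
            rows.append(
                {"sample_id": sample_id, "rank": rank, "taxon": taxon,
                 "share": shares[taxon]}
            )
    return pd.DataFrame(rows)


def taxon_gene_contribution(
    gene_symbol: str,
    sample: Sample,
    rank: str,
    table: DepthTable,
    annotations: pd.DataFrame,
    membership: pd.Series,
    taxonomies: Mapping[str, TaxonomyString],
    read_length: int = DEFAULT_READ_LENGTH,
) -> pd.Series:
    """Fraction of a gene's summed RPKM attributable to each taxon.

    Gene-bearing contigs outside any MAG pool under 'unassigned'. Fractions
    (including 'unassigned') sum to 1.
    """
    q_ids = _gene_contigs(annotations, gene_symbol)
    if not q_ids:
        raise ValidationError(
            f"gene {gene_symbol!r} absent from annotations (Q empty)"
        )
    contig_rpkm = _contig_rpkm(table, sample, read_length)
    total = float(contig_rpkm.loc[sorted(q_ids)].sum())
    if total <= 0:
        raise ValidationError(
            f"gene {gene_symbol!r}: zero total RPKM in sample {sample.sample_id}"
        )
    fractions: dict[str, float] = {}
    for cid in sorted(q_ids):
        if cid in membership.index:
            mag_id = membership.loc[cid]
            tax = taxonomies[mag_id]
            name = tax.rank(rank) if not tax.is_unknown(rank) else "unknown"
        else:
            name = "unassigned"
        fractions[name] = fractions.get(name, 0.0) + float(contig_rpkm.loc[cid]) / total
    out = pd.Series(fractions, name=f"{gene_symbol}_fraction")
    return out.sort_values(ascending=False)
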