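"""Domain types and table readers/writers.

All pipeline inputs are plain TSVs mirroring the outputs of the standard
metagenomics toolchain: jgi_summarize_bam_contig_depths depth tables,
gene-annotation tables, bin membership, CheckM-style MAG quality with
GTDB taxonomy strings, FastANI pairwise triples and sample metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .catalog import Catalog
from .errors import FormatError, ValidationError

#: Minimum contig length retained by the assembly filter (2 kb floor).
MIN_CONTIG_LENGTH = 2000

#: Default read length (PE150 sequencing), used to convert mean depth to counts.
DEFAULT_READ_LENGTH = 150

RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass(frozen=True)
class Sample:
    """One metagenome sample with its normalization constants.

    raw_reads_size: cleaned read-pair count in millions (MAG-depth scaler).
    total_mapped_reads: mapped read count (RPKM 'per million' scaler).
    """

    sample_id: str
    lake: str
    month: str
    raw_reads_size: float
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.raw_reads_size <= 0:
            raise ValidationError(
                f"sample {self.sample_id}: raw_reads_size must be > 0"
            )
        if self.total_mapped_reads < 0:
            raise ValidationError(
                f"sample {self.sample_id}: total_mapped_reads must be >= 0"
            )


@dataclass
class DepthTable:
    """Per-contig lengths and per-sample mean depths (reads per base)."""

    lengths: pd.Series                 # contig_id -> length_bp
    depths: pd.DataFrame               # contig_id x sample_id, mean depth
    read_counts: pd.DataFrame | None = None  # optional explicit counts

    @property
    def contig_ids(self) -> pd.Index:
        return self.lengths.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.depths.columns)

    def counts(self, read_length: int = DEFAULT_READ_LENGTH) -> pd.DataFrame:
        """Per-contig read counts.

        An explicit read-count table takes precedence; otherwise counts are
        reconstructed as round(mean_depth * length / read_length).
        """
        if self.read_counts is not None:
            return self.read_counts
        est = self.depths.mul(self.lengths, axis=0) / read_length
        return est.round().astype(np.int64)


@dataclass(frozen=True)
class TaxonomyString:
    """GTDB seven-rank taxonomy, each rank possibly empty (unassigned)."""

    domain: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def rank(self, rank: str) -> str:
        key = "class_" if rank == "class" else rank
        return getattr(self, key)

    def is_unknown(self, rank: str) -> bool:
        """Unassigned at ``rank``: empty GTDB suffix.

        Assigned-but-unnamed placeholders (e.g. species 'sp018402175') count
        as known: they carry a database assignment, just not a Latin name.
        """
        return not any(ch.isalnum() for ch in self.rank(rank))

    def __str__(self) -> str:
        values = (self.domain, self.phylum, self.class_, self.order,
                  self.family, self.genus, self.species)
        return ";".join(p + v for p, v in zip(_RANK_PREFIXES, values))


@dataclass
class MAG:
    """A metagenome-assembled genome: a bin of contigs with quality metadata."""

    mag_id: str
    contig_ids: set[str]
    size_bp: int
    completeness: float
    contamination: float
    taxonomy: TaxonomyString = field(default_factory=TaxonomyString)


@dataclass(frozen=True)
class QualityThresholds:
    """Completeness/contamination retention thresholds (percent)."""

    min_completeness: float
    max_contamination: float

    def __post_init__(self) -> None:
        for name, v in (("min_completeness", self.min_completeness),
                        ("max_contamination", self.max_contamination)):
            if not 0 <= v <= 100:
                raise ValidationError(f"{name} must be in [0, 100], got {v}")


#: MIMAG medium-quality retention: completeness >= 50 and contamination < 10.
MIMAG_THRESHOLDS = QualityThresholds(50.0, 10.0)
#: Stricter phylogenetic-tree inclusion: completeness >= 70, contamination < 7.
TREE_THRESHOLDS = QualityThresholds(70.0, 7.0)


def parse_taxonomy(gtdb_string: str) -> TaxonomyString:
    """Parse a 'd__...;p__...;...;s__...' GTDB string (trailing ranks may be absent)."""
    parts = [p.strip() for p in gtdb_string.strip().split(";")] if gtdb_string.strip() else []
    if len(parts) > 7:
        raise FormatError(f"taxonomy has {len(parts)} ranks (max 7): {gtdb_string!r}")
    values = []
    for i, part in enumerate(parts):
        prefix = _RANK_PREFIXES[i]
        if not part.startswith(prefix):
            raise FormatError(
                f"taxonomy rank {i + 1} should start with {prefix!r}: {part!r} "
                f"(full string {gtdb_string!r})"
            )
        values.append(part[len(prefix):])
    values += [""] * (7 - len(values))
    return TaxonomyString(*values)


# ---------------------------------------------------------------------------
# depth table (jgi_summarize_bam_contig_depths dialect)

_JGI_FIXED = ("contigName", "contigLen", "totalAvgDepth")


def read_depth_table(
    path: str | Path,
    strict_min_length: bool = True,
    min_length: int = MIN_CONTIG_LENGTH,
) -> DepthTable:
    """Read a jgi-dialect depth TSV.

    Columns: contigName, contigLen, totalAvgDepth, then one mean-depth column
    per sample (named '<sample>.bam' or bare '<sample>'); '-var' variance
    columns are ignored. With ``strict_min_length`` (default), contigs under
    the 2 kb assembly floor are rejected rather than silently dropped.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _JGI_FIXED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    if df["contigName"].duplicated().any():
        dupes = df.loc[df["contigName"].duplicated(), "contigName"].tolist()
        raise ValidationError(f"{path}: duplicate contig ids {dupes[:5]}")

    depth_cols = [
        c for c in df.columns if c not in _JGI_FIXED and not c.endswith("-var")
    ]
    sample_ids = [c[:-4] if c.endswith(".bam") else c for c in depth_cols]

    lengths = df.set_index("contigName")["contigLen"].astype(np.int64)
    lengths = lengths.rename("length_bp")
    lengths.index.name = "contig_id"
    if strict_min_length:
        short = lengths[lengths < min_length]
        if not short.empty:
            raise ValidationError(
                f"{path}: {len(short)} contig(s) below the {min_length} bp "
                f"(2 kb) assembly floor, e.g. {short.index[0]!r} "
                f"({int(short.iloc[0])} bp); contigs shorter than 2 kb are "
                "removed upstream"
            )
    depths = df.set_index("contigName")[depth_cols].astype(float)
    depths.columns = sample_ids
    depths.index.name = "contig_id"
    if (depths < 0).any().any():
        raise ValidationError(f"{path}: negative depth values")
    return DepthTable(lengths=lengths, depths=depths)


def write_depth_table(table: DepthTable, path: str | Path) -> None:
    """Write a DepthTable in the jgi dialect (per-sample '<id>.bam' columns)."""
    out = pd.DataFrame({"contigName": table.lengths.index})
    out["contigLen"] = table.lengths.values
    out["totalAvgDepth"] = table.depths.sum(axis=1).values
    for s in table.sample_ids:
        out[f"{s}.bam"] = table.depths[s].values
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation table

def read_annotation_table(
    path: str | Path, catalog: Catalog | None = None
) -> pd.DataFrame:
    """Read (contig_id, gene_symbol, ko_id) annotations.

    Duplicate (contig, gene) rows collapse to one — the gene-depth statistic
    is a set statistic over contigs. Symbols missing from ``catalog`` are kept
    but flagged (in_catalog=False) with a warning.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str,
        names=["contig_id", "gene_symbol", "ko_id"], header=0,
    )
    if df.empty:
        df = pd.DataFrame(columns=["contig_id", "gene_symbol", "ko_id"])
    df = df.drop_duplicates(subset=["contig_id", "gene_symbol"]).reset_index(drop=True)
    if catalog is not None:
        df["in_catalog"] = df["gene_symbol"].isin(catalog.gene_symbols)
        n_bad = int((~df["in_catalog"]).sum())
        if n_bad:
            bad = sorted(df.loc[~df["in_catalog"], "gene_symbol"].unique())
            warnings.warn(
                f"{path}: {n_bad} annotation row(s) with gene symbols not in "
                f"catalog: {bad[:10]}", stacklevel=2,
            )
    return df


def write_annotation_table(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations[["contig_id", "gene_symbol", "ko_id"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# bin membership / MAG quality

def read_bin_membership(path: str | Path) -> pd.Series:
    """Read (contig_id, mag_id); raises if a contig is claimed by two MAGs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"contig_id", "mag_id"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns contig_id, mag_id")
    df = df.drop_duplicates()
    clashes = df[df["contig_id"].duplicated(keep=False)]
    if not clashes.empty:
        raise ValidationError(
            f"{path}: contigs assigned to more than one MAG: "
            f"{sorted(clashes['contig_id'].unique())[:5]}"
        )
    return df.set_index("contig_id")["mag_id"]


def write_bin_membership(membership: pd.Series, path: str | Path) -> None:
    membership.rename("mag_id").rename_axis("contig_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_quality_table(path: str | Path) -> pd.DataFrame:
    """Read MAG quality: mag_id, completeness, contamination, taxonomy."""
    df = pd.read_csv(path, sep="\t", dtype={"mag_id": str, "taxonomy": str})
    required = {"mag_id", "completeness", "contamination"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    if "taxonomy" not in df.columns:
        df["taxonomy"] = ""
    df["taxonomy"] = df["taxonomy"].fillna("")
    out = df.set_index("mag_id")
    for col in ("completeness", "contamination"):
        bad = out[(out[col] < 0) | (out[col] > 100)]
        if not bad.empty:
            raise ValidationError(
                f"{path}: {col} outside [0,100] for {list(bad.index)[:5]}"
            )
    return out


def write_quality_table(quality: pd.DataFrame, path: str | Path) -> None:
    quality.rename_axis("mag_id").reset_index().to_csv(path, sep="\t", index=False)


def build_mags(
    membership: pd.Series,
    lengths: pd.Series,
    quality: pd.DataFrame,
) -> dict[str, MAG]:
    """Assemble MAG objects from membership, contig lengths and quality."""
    mags: dict[str, MAG] = {}
    missing = membership.index.difference(lengths.index)
    if not missing.empty:
        raise ValidationError(
            f"binned contigs missing from depth table: {list(missing[:5])}"
        )
    for mag_id, contigs in membership.groupby(membership).groups.items():
        contig_ids = set(membership.index[membership == mag_id])
        size = int(lengths.loc[sorted(contig_ids)].sum())
        if mag_id in quality.index:
            row = quality.loc[mag_id]
            tax = parse_taxonomy(str(row.get("taxonomy", "") or ""))
            mags[str(mag_id)] = MAG(
                str(mag_id), contig_ids, size,
                float(row["completeness"]), float(row["contamination"]), tax,
            )
        else:
            mags[str(mag_id)] = MAG(str(mag_id), contig_ids, size, np.nan, np.nan)
    return mags


# ---------------------------------------------------------------------------
# ANI matrix

def read_ani_matrix(path: str | Path) -> pd.DataFrame:
    """Read FastANI-style (mag_a, mag_b, ani) triples into a symmetric matrix.

    Directed asymmetry is resolved by the maximum of the two directions
    (conservative toward merging at a fixed threshold); the diagonal is 100.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, header=0,
                     names=["mag_a", "mag_b", "ani"])
    if ((df["ani"] < 0) | (df["ani"] > 100)).any():
        raise ValidationError(f"{path}: ANI values outside [0, 100]")
    ids = sorted(set(df["mag_a"]) | set(df["mag_b"]))
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for _, row in df.iterrows():
        a, b, v = row["mag_a"], row["mag_b"], float(row["ani"])
        best = max(v, mat.at[a, b])
        mat.at[a, b] = best
        mat.at[b, a] = best
    np.fill_diagonal(mat.values, 100.0)
    return mat


def write_ani_triples(matrix: pd.DataFrame, path: str | Path) -> None:
    rows = []
    ids = list(matrix.index)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            rows.append((a, b, matrix.at[a, b]))
    pd.DataFrame(rows, columns=["mag_a", "mag_b", "ani"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# sample metadata

def read_sample_metadata(path: str | Path) -> dict[str, Sample]:
    """Read sample_id, lake, month, raw_reads_size_millions, total_mapped_reads."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "lake", "month",
                "raw_reads_size_millions", "total_mapped_reads"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    return {
        str(r.sample_id): Sample(
            str(r.sample_id), str(r.lake), str(r.month),
            float(r.raw_reads_size_millions), int(r.total_mapped_reads),
        )
        for r in df.itertuples()
    }


def write_sample_metadata(samples: Mapping[str, Sample], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id, "lake": s.lake, "month": s.month,
            "raw_reads_size_millions": s.raw_reads_size,
            "total_mapped_reads": s.total_mapped_reads,
        }
        for s in samples.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def mag_gene_sets(
    annotations: pd.DataFrame, membership: pd.Series
) -> dict[str, set[str]]:
    """Per-MAG sets of annotated gene symbols (via contig membership)."""
    ann = annotations.merge(
        membership.rename("mag_id"), left_on="contig_id", right_index=True,
    )
    out: dict[str, set[str]] = {}
    for mag_id, grp in ann.groupby("mag_id"):
        out[str(mag_id)] = set(grp["gene_symbol"])
    return out
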