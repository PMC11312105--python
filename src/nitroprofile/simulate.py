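"""Ground-truth community simulator.

Emulates the statistical structure the profiling pipeline assumes: a
community of genomes with lognormal relative abundances (optionally with one
dominant genus), per-genome nitrogen-gene copy numbers drawn from a
per-complex prevalence table, exactly one *rpsB* marker copy per genome,
contig fragmentation with the 2 kb retention floor, Poisson read counts
proportional to abundance x contig length, and noisy binning. Every table
the pipeline consumes is emitted, together with a truth set used as the
recovery oracle:

    expected gene depth(gene, sample)
        = sum_g a_gs * contigs_g(gene) / sum_g a_gs * contigs_g(marker)

i.e. the abundance-weighted mean copy number under the contig-set semantics
of the statistic (two copies on one contig count once).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as nio
from .catalog import Catalog, DEFAULT_MARKER, load_catalog
from .errors import ValidationError
from .io import DepthTable, Sample

LAKES = ("AQK", "AYK", "JYH", "WSX")
MONTHS = ("April", "July", "October", "November")

#: Per-complex carriage probabilities, qualitatively mirroring an
#: oligotrophic saline-lake community: nitrite reduction, nitrogen fixation
#: and assimilatory nitrate reduction common; nitrification and anammox rare.
DEFAULT_COMPLEX_PREVALENCE: dict[str, float] = {
    "RpsB": 1.0,
    "Nif": 0.45, "Vnf": 0.0, "Anf": 0.0,
    "Amo": 0.05, "Hao": 0.05,
    "NarGHI": 0.20, "NapAB": 0.15,
    "NirK": 0.30, "NirS": 0.20, "NorBC": 0.10, "NosZ": 0.25,
    "NirBD": 0.60, "Nrf": 0.15,
    "Nas": 0.50, "NirA": 0.30,
    "Hzs": 0.03, "Hdh": 0.03,
    "Ure": 0.40, "CynS": 0.30, "NIT1": 0.30,
    "GlnA": 0.90, "GltBD": 0.70, "GdhA": 0.50,
}


@dataclass
class SimConfig:
    """Simulation parameters.

    mean_coverage is the average per-genome coverage (a genome at community
    share 1/n_genomes sees exactly this coverage). dominance_boost, when
    > 0, fixes the community share of the designated dominant genus at that
    value in every sample (the study-style 17-80% dominance regime is
    exercised by setting it inside that range).
    """

    n_genomes: int = 20
    n_samples: int = 5
    genome_size_bp: int = 1_000_000
    contig_length: int = 10_000
    variable_contig_lengths: bool = False
    min_contig_length: int = nio.MIN_CONTIG_LENGTH
    lognormal_sigma: float = 1.0
    dominance_boost: float = 0.0
    dominant_genus: str = "g__SimDominant"
    read_length: int = nio.DEFAULT_READ_LENGTH
    mean_coverage: float = 20.0
    nb_dispersion: float | None = None
    frac_unbinned: float = 0.0
    frac_misbinned: float = 0.0
    completeness_sim: float = 1.0
    complex_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPLEX_PREVALENCE)
    )
    extra_copy_rate: float = 0.2
    n_species_pairs: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.min_contig_length < nio.MIN_CONTIG_LENGTH:
            raise ValidationError("min_contig_length below the 2 kb floor")
        if self.contig_length < self.min_contig_length:
            raise ValidationError("contig_length below min_contig_length")
        if self.genome_size_bp < self.contig_length:
            raise ValidationError("genome smaller than one contig")
        for name in ("frac_unbinned", "frac_misbinned", "completeness_sim",
                     "dominance_boost"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_genomes < 1 or self.n_samples < 1:
            raise ValidationError("need at least one genome and one sample")


@dataclass
class SimGenome:
    genome_id: str
    size_bp: int
    taxonomy: str
    abundances: dict[str, float]          # sample_id -> share
    gene_copy_numbers: dict[str, int]     # gene_symbol -> copies (rpsB = 1)
    completeness_sim: float


@dataclass
class TruthSet:
    """Simulator ground truth plus every emitted pipeline input."""

    config: SimConfig
    genomes: list[SimGenome]
    contig_lengths: dict[str, int]
    contig_genome: dict[str, str]
    depth_table: DepthTable
    annotations: pd.DataFrame
    samples: dict[str, Sample]
    membership: pd.Series
    quality: pd.DataFrame
    ani: pd.DataFrame
    expected_gene_depth: pd.DataFrame     # gene_symbol, sample_id, expected
    gene_contig_counts: dict[str, dict[str, int]]  # genome -> gene -> contigs

    def expected_ranking(self, sample_id: str) -> list[str]:
        """Genome ids by descending true abundance (ties by id)."""
        return [
            g.genome_id
            for g in sorted(
                self.genomes,
                key=lambda g: (-g.abundances[sample_id], g.genome_id),
            )
        ]


def _simulate_taxonomies(config: SimConfig, rng: np.random.Generator) -> list[str]:
    taxa = []
    n_genera = max(4, config.n_genomes // 4)
    for i in range(config.n_genomes):
        genus = (
            config.dominant_genus
            if config.dominance_boost > 0 and i == 0
            else f"g__SimGenus{i % n_genera}"
        )
        taxa.append(
            f"d__Bacteria;p__SimPhylum{i % 3};c__SimClass{i % 3};"
            f"o__SimOrder{i % 4};f__SimFamily{i % 5};{genus};s__"
        )
    return taxa


def _simulate_abundances(
    config: SimConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-sample normalized lognormal abundances; genome 0 pinned to the
    dominance share when the boost is on."""
    out = {}
    for s in range(config.n_samples):
        w = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma,
                          size=config.n_genomes)
        a = w / w.sum()
        if config.dominance_boost > 0 and config.n_genomes > 1:
            rest = a[1:] / a[1:].sum() * (1.0 - config.dominance_boost)
            a = np.concatenate([[config.dominance_boost], rest])
        out[f"S{s + 1:02d}"] = a
    return out


def _assign_gene_copies(
    config: SimConfig, catalog: Catalog, rng: np.random.Generator
) -> dict[str, int]:
    """One genome's gene copy numbers, drawn per enzyme complex so subunits
    co-occur; the marker is fixed at exactly one copy."""
    copies: dict[str, int] = {}
    complexes = catalog.complexes()
    for cid, genes in sorted(complexes.items()):
        prev = config.complex_prevalence.get(cid, 0.2)
        carried = rng.random() < prev
        for g in sorted(genes):
            if g == DEFAULT_MARKER:
                copies[g] = 1
            elif carried:
                copies[g] = 1 + int(rng.poisson(config.extra_copy_rate))
            else:
                copies[g] = 0
    copies[DEFAULT_MARKER] = 1
    return copies


def fragment_genomes(
    genomes: list[SimGenome],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, int], dict[str, str], dict[str, dict[str, int]], pd.DataFrame]:
    """Cut genomes into contigs and place gene copies on them.

    Contigs are contiguous non-overlapping fragments; a trailing fragment
    below the 2 kb floor is dropped together with any gene copies on it.
    Returns (contig lengths, contig->genome, per-genome per-gene retained
    contig counts, annotation table).
    """
    contig_lengths: dict[str, int] = {}
    contig_genome: dict[str, str] = {}
    gene_contig_counts: dict[str, dict[str, int]] = {}
    ann_rows: list[tuple[str, str]] = []

    for genome in genomes:
        # fragment boundaries
        bounds = [0]
        while bounds[-1] < genome.size_bp:
            if config.variable_contig_lengths:
                step = int(rng.integers(config.min_contig_length,
                                        2 * config.contig_length + 1))
            else:
                step = config.contig_length
            bounds.append(min(bounds[-1] + step, genome.size_bp))
        starts, ends = np.array(bounds[:-1]), np.array(bounds[1:])
        keep = (ends - starts) >= config.min_contig_length
        kept_starts, kept_ends = starts[keep], ends[keep]
        ids = [
            f"{genome.genome_id}_c{i + 1:04d}" for i in range(len(kept_starts))
        ]
        for cid, s, e in zip(ids, kept_starts, kept_ends):
            contig_lengths[cid] = int(e - s)
            contig_genome[cid] = genome.genome_id

        # place each gene copy at a uniform offset; copies on dropped
        # fragments are lost (documented), copies sharing a contig count once
        per_gene: dict[str, set[str]] = {}
        for gene, n_copies in sorted(genome.gene_copy_numbers.items()):
            for _ in range(n_copies):
                offset = int(rng.integers(0, genome.size_bp))
                idx = int(np.searchsorted(ends, offset, side="right"))
                if idx < len(starts) and keep[idx]:
                    kept_idx = int(keep[:idx].sum())
                    per_gene.setdefault(gene, set()).add(ids[kept_idx])
        gene_contig_counts[genome.genome_id] = {
            g: len(cs) for g, cs in per_gene.items()
        }
        for gene, cids in sorted(per_gene.items()):
            for cid in sorted(cids):
                ann_rows.append((cid, gene))
    annotations = pd.DataFrame(ann_rows, columns=["contig_id", "gene_symbol"])
    return contig_lengths, contig_genome, gene_contig_counts, annotations


def simulate_depths(
    contig_lengths: dict[str, int],
    contig_genome: dict[str, str],
    genomes: list[SimGenome],
    config: SimConfig,
    rng: np.random.Generator,
) -> DepthTable:
    """Draw per-sample read counts: reads_c ~ Poisson(cov_g * len_c / L_read)
    with cov_g = a_g * n_genomes * mean_coverage (optionally negative
    binomial via a gamma-mixed rate)."""
    abundance = {g.genome_id: g.abundances for g in genomes}
    cids = sorted(contig_lengths)
    lengths = pd.Series({c: contig_lengths[c] for c in cids}, name="length_bp")
    lengths.index.name = "contig_id"
    sample_ids = sorted(next(iter(abundance.values())))
    counts = {}
    for s in sample_ids:
        lam = np.array([
            abundance[contig_genome[c]][s]
            * config.n_genomes * config.mean_coverage
            * contig_lengths[c] / config.read_length
            for c in cids
        ])
        if config.nb_dispersion:
            lam = rng.gamma(
                shape=1.0 / config.nb_dispersion,
                scale=np.where(lam > 0, lam * config.nb_dispersion, 1.0),
            ) * (lam > 0)
        counts[s] = rng.poisson(lam)
    count_df = pd.DataFrame(counts, index=pd.Index(cids, name="contig_id"))
    depths = count_df.mul(config.read_length).div(lengths, axis=0)
    return DepthTable(lengths=lengths, depths=depths, read_counts=count_df)


def _expected_gene_depth(
    genomes: list[SimGenome],
    gene_contig_counts: dict[str, dict[str, int]],
    catalog: Catalog,
) -> pd.DataFrame:
    sample_ids = sorted(genomes[0].abundances)
    rows = []
    for s in sample_ids:
        denom = sum(
            g.abundances[s]
            * gene_contig_counts[g.genome_id].get(DEFAULT_MARKER, 0)
            for g in genomes
        )
        for gene in sorted(catalog.gene_symbols):
            numer = sum(
                g.abundances[s]
                * gene_contig_counts[g.genome_id].get(gene, 0)
                for g in genomes
            )
            rows.append({
                "gene_symbol": gene, "sample_id": s,
                "expected_gene_depth": numer / denom if denom > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def _simulate_binning(
    genomes: list[SimGenome],
    contig_lengths: dict[str, int],
    contig_genome: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.Series, pd.DataFrame]:
    """Bin contigs back to per-genome MAGs with configurable noise.

    Completeness is the emitted fraction of the genome; contamination the
    misbinned-in fraction of the bin — crude, but it exercises the
    threshold logic with the right monotonicity.
    """
    mag_of = {g.genome_id: f"MAG_{g.genome_id}" for g in genomes}
    mag_ids = [mag_of[g.genome_id] for g in genomes]
    assignment: dict[str, str] = {}
    for g in genomes:
        cids = sorted(c for c, gen in contig_genome.items()
                      if gen == g.genome_id)
        n_emit = int(round(g.completeness_sim * len(cids)))
        for i, cid in enumerate(cids):
            if i >= n_emit:
                continue
            if config.frac_unbinned > 0 and rng.random() < config.frac_unbinned:
                continue
            if config.frac_misbinned > 0 and rng.random() < config.frac_misbinned:
                others = [m for m in mag_ids if m != mag_of[g.genome_id]]
                assignment[cid] = str(others[int(rng.integers(len(others)))]) \
                    if others else mag_of[g.genome_id]
            else:
                assignment[cid] = mag_of[g.genome_id]
    membership = pd.Series(assignment, name="mag_id").sort_index()
    membership.index.name = "contig_id"

    rows = []
    for g in genomes:
        mag_id = mag_of[g.genome_id]
        in_bin = membership.index[membership == mag_id]
        own = sum(contig_lengths[c] for c in in_bin
                  if contig_genome[c] == g.genome_id)
        foreign = sum(contig_lengths[c] for c in in_bin
                      if contig_genome[c] != g.genome_id)
        bin_size = own + foreign
        completeness = 100.0 * own / g.size_bp
        contamination = 100.0 * foreign / bin_size if bin_size else 0.0
        rows.append({
            "mag_id": mag_id,
            "completeness": round(min(completeness, 100.0), 2),
            "contamination": round(contamination, 2),
            "taxonomy": g.taxonomy,
        })
    quality = pd.DataFrame(rows).set_index("mag_id")
    return membership, quality


def _simulate_ani(
    genomes: list[SimGenome], config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Pairwise ANI: ~97% for designated same-species pairs, ~85% within a
    genus, ~77% otherwise."""
    ids = [f"MAG_{g.genome_id}" for g in genomes]
    genus = {f"MAG_{g.genome_id}": g.taxonomy.split(";")[5] for g in genomes}
    mat = pd.DataFrame(77.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            base = 85.0 if genus[a] == genus[b] else 77.0
            v = float(np.clip(base + rng.normal(0, 1.5), 70.0, 92.0))
            mat.at[a, b] = mat.at[b, a] = v
    for p in range(min(config.n_species_pairs, len(ids) // 2)):
        a, b = ids[2 * p], ids[2 * p + 1]
        v = float(rng.uniform(96.0, 99.0))
        mat.at[a, b] = mat.at[b, a] = v
    np.fill_diagonal(mat.values, 100.0)
    return mat


def simulate_community(
    config: SimConfig, catalog: Catalog | None = None
) -> TruthSet:
    """Run the full simulation; deterministic under a fixed seed."""
    config.validate()
    if catalog is None:
        catalog = load_catalog()
    rng = np.random.default_rng(config.seed)

    taxonomies = _simulate_taxonomies(config, rng)
    abundances = _simulate_abundances(config, rng)
    sample_ids = sorted(abundances)
    genomes = [
        SimGenome(
            genome_id=f"G{i + 1:03d}",
            size_bp=config.genome_size_bp,
            taxonomy=taxonomies[i],
            abundances={s: float(abundances[s][i]) for s in sample_ids},
            gene_copy_numbers=_assign_gene_copies(config, catalog, rng),
            completeness_sim=config.completeness_sim,
        )
        for i in range(config.n_genomes)
    ]

    contig_lengths, contig_genome, gene_contig_counts, annotations = (
        fragment_genomes(genomes, config, rng)
    )
    ko_of = {g: e.ko_id for g, e in
             ((s, catalog.entry(s)) for s in catalog.gene_symbols)}
    annotations["ko_id"] = annotations["gene_symbol"].map(ko_of)

    depth_table = simulate_depths(
        contig_lengths, contig_genome, genomes, config, rng
    )
    counts = depth_table.read_counts
    samples = {}
    for i, s in enumerate(sample_ids):
        total = int(counts[s].sum())
        samples[s] = Sample(
            sample_id=s,
            lake=LAKES[i % len(LAKES)],
            month=MONTHS[(i // len(LAKES)) % len(MONTHS)],
            raw_reads_size=max(total, 1) / 1e6,
            total_mapped_reads=max(total, 1),
        )

    membership, quality = _simulate_binning(
        genomes, contig_lengths, contig_genome, config, rng
    )
    ani = _simulate_ani(genomes, config, rng)
    expected = _expected_gene_depth(genomes, gene_contig_counts, catalog)

    return TruthSet(
        config=config,
        genomes=genomes,
        contig_lengths=contig_lengths,
        contig_genome=contig_genome,
        depth_table=depth_table,
        annotations=annotations,
        samples=samples,
        membership=membership,
        quality=quality,
        ani=ani,
        expected_gene_depth=expected,
        gene_contig_counts=gene_contig_counts,
    )


def emit_tables(truth: TruthSet, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input table plus the truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "depths": out / "depths.tsv",
        "annotations": out / "annotations.tsv",
        "bins": out / "bins.tsv",
        "quality": out / "quality.tsv",
        "samples": out / "samples.tsv",
        "ani": out / "ani.tsv",
        "truth": out / "truth.json",
    }
    nio.write_depth_table(truth.depth_table, paths["depths"])
    nio.write_annotation_table(truth.annotations, paths["annotations"])
    nio.write_bin_membership(truth.membership, paths["bins"])
    nio.write_quality_table(truth.quality, paths["quality"])
    nio.write_sample_metadata(truth.samples, paths["samples"])
    nio.write_ani_triples(truth.ani, paths["ani"])

    truth_json = {
        "seed": truth.config.seed,
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in asdict(truth.config).items()
        },
        "genomes": [
            {
                "genome_id": g.genome_id,
                "size_bp": g.size_bp,
                "taxonomy": g.taxonomy,
                "abundances": g.abundances,
                "gene_copy_numbers": g.gene_copy_numbers,
                "completeness_sim": g.completeness_sim,
            }
            for g in truth.genomes
        ],
        "contig_genome": truth.contig_genome,
        "expected_gene_depth": truth.expected_gene_depth.to_dict("records"),
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    return paths
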