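"""Simulator: determinism, fragmentation floor, coverage model, truth oracle,
binning noise, and round-trips through every reader."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from nitroprofile import io as nio
from nitroprofile.abundance import gene_depth_profile, mag_depth_table
from nitroprofile.catalog import load_catalog
from nitroprofile.errors import ValidationError
from nitroprofile.genome_profiles import taxon_gene_presence
from nitroprofile.simulate import (
    SimConfig,
    SimGenome,
    emit_tables,
    fragment_genomes,
    simulate_community,
    simulate_depths,
)


def small_cfg(**kw):
    base = dict(n_genomes=6, n_samples=3, genome_size_bp=100_000,
                contig_length=10_000, seed=7)
    base.update(kw)
    return SimConfig(**base)


def test_fixed_seed_is_byte_identical(tmp_path):
    a = emit_tables(simulate_community(small_cfg()), tmp_path / "a")
    b = emit_tables(simulate_community(small_cfg()), tmp_path / "b")
    for key in a:
        assert filecmp.cmp(a[key], b[key], shallow=False), key


def test_different_seed_differs():
    t1 = simulate_community(small_cfg(seed=1))
    t2 = simulate_community(small_cfg(seed=2))
    assert not np.array_equal(
        t1.depth_table.read_counts.values, t2.depth_table.read_counts.values
    )


def test_config_validation():
    with pytest.raises(ValidationError):
        SimConfig(genome_size_bp=1000, contig_length=5000).validate()
    with pytest.raises(ValidationError):
        SimConfig(min_contig_length=500).validate()
    with pytest.raises(ValidationError):
        SimConfig(frac_unbinned=1.5).validate()


def test_dominance_boost_makes_genus_top_everywhere():
    truth = simulate_community(small_cfg(dominance_boost=0.5))
    for s in truth.samples:
        ranking = truth.expected_ranking(s)
        assert ranking[0] == truth.genomes[0].genome_id
        assert truth.genomes[0].abundances[s] == pytest.approx(0.5)
        assert truth.genomes[0].taxonomy.split(";")[5] == "g__SimDominant"


def test_abundances_normalized_and_marker_single_copy():
    truth = simulate_community(small_cfg())
    for s in truth.samples:
        total = sum(g.abundances[s] for g in truth.genomes)
        assert total == pytest.approx(1.0, abs=1e-9)
    for g in truth.genomes:
        assert g.gene_copy_numbers["rpsB"] == 1


def _plain_genome(genome_id, size, copies):
    return SimGenome(genome_id, size, "d__B;p__P;c__C;o__O;f__F;g__G;s__",
                     {"S01": 0.5}, copies, 1.0)


def test_fragmentation_exact_division_and_floor():
    rng = np.random.default_rng(0)
    cfg = SimConfig(n_genomes=1, n_samples=1, genome_size_bp=10_000,
                    contig_length=5_000)
    g = _plain_genome("G1", 10_000, {"rpsB": 1})
    lengths, owner, counts, ann = fragment_genomes([g], cfg, rng)
    assert len(lengths) == 2 and all(v == 5000 for v in lengths.values())

    # 11 kb genome: 5k + 5k + 1k trailing remnant below the 2 kb floor
    g11 = _plain_genome("G1", 11_000, {"rpsB": 1})
    cfg11 = SimConfig(n_genomes=1, n_samples=1, genome_size_bp=11_000,
                      contig_length=5_000)
    lengths11, _, _, _ = fragment_genomes([g11], cfg11, rng)
    assert sorted(lengths11.values()) == [5000, 5000]


def test_gene_copies_land_on_exactly_one_contig():
    rng = np.random.default_rng(3)
    cfg = SimConfig(n_genomes=1, n_samples=1, genome_size_bp=50_000,
                    contig_length=10_000)
    g = _plain_genome("G1", 50_000, {"rpsB": 1, "nirB": 1})
    _, _, counts, ann = fragment_genomes([g], cfg, rng)
    assert counts["G1"]["nirB"] == 1
    assert (ann["gene_symbol"] == "nirB").sum() == 1


def test_expected_gene_depth_is_abundance_weighted_copy_number():
    """Two genomes at 50/50, copies 2 and 0 -> expected depth 1.0 (copies on
    distinct contigs for this seed)."""
    rng = np.random.default_rng(5)
    g1 = SimGenome("G1", 100_000, "d__B;p__1;c__;o__;f__;g__A;s__",
                   {"S01": 0.5}, {"rpsB": 1, "nifH": 2}, 1.0)
    g2 = SimGenome("G2", 100_000, "d__B;p__2;c__;o__;f__;g__B;s__",
                   {"S01": 0.5}, {"rpsB": 1, "nifH": 0}, 1.0)
    cfg = SimConfig(n_genomes=2, n_samples=1, genome_size_bp=100_000,
                    contig_length=10_000)
    _, _, counts, _ = fragment_genomes([g1, g2], cfg, rng)
    assert counts["G1"]["nifH"] == 2, "copies collided for this seed"

    from nitroprofile.simulate import _expected_gene_depth

    exp = _expected_gene_depth([g1, g2], counts, load_catalog())
    got = exp.query("gene_symbol == 'nifH'")["expected_gene_depth"].iloc[0]
    assert got == pytest.approx(1.0, abs=1e-12)


def test_poisson_mean_matches_rate():
    """Mean read count over many replicate samples within 3 SE of lambda."""
    n_rep = 400
    g = SimGenome("G1", 10_000, "d__B;p__;c__;o__;f__;g__;s__",
                  {f"S{i:04d}": 1.0 for i in range(n_rep)},
                  {"rpsB": 1}, 1.0)
    cfg = SimConfig(n_genomes=1, n_samples=n_rep, genome_size_bp=10_000,
                    contig_length=10_000, mean_coverage=20.0)
    rng = np.random.default_rng(9)
    table = simulate_depths({"G1_c0001": 10_000}, {"G1_c0001": "G1"}, [g],
                            cfg, rng)
    lam = 1.0 * 1 * 20.0 * 10_000 / 150
    counts = table.read_counts.loc["G1_c0001"].to_numpy()
    se = np.sqrt(lam / n_rep)
    assert abs(counts.mean() - lam) < 3 * se


def test_doubling_coverage_preserves_gene_depth_expectation():
    catalog = load_catalog()
    lo = simulate_community(small_cfg(mean_coverage=20.0))
    hi = simulate_community(small_cfg(mean_coverage=40.0))
    # expected truth identical (same seed, same genomes/abundances)
    pd.testing.assert_frame_equal(lo.expected_gene_depth,
                                  hi.expected_gene_depth)
    # depths double in expectation
    assert hi.depth_table.depths.values.sum() == pytest.approx(
        2 * lo.depth_table.depths.values.sum(), rel=0.05
    )
    # the ratio statistic stays put
    for truth in (lo, hi):
        prof = gene_depth_profile(truth.samples, truth.depth_table,
                                  truth.annotations, catalog)
        merged = prof.merge(truth.expected_gene_depth,
                            on=["gene_symbol", "sample_id"])
        # loose band: this fixture is tiny (10 contigs/genome), so counting
        # noise is a few percent; the acceptance suite checks the tight bound
        busy = merged[merged["expected_gene_depth"] >= 0.2]
        err = (busy["gene_depth"] - busy["expected_gene_depth"]).abs() \
            / busy["expected_gene_depth"]
        assert err.max() < 0.15


def test_zero_abundance_means_zero_reads():
    g1 = SimGenome("G1", 10_000, "d__B;p__;c__;o__;f__;g__;s__",
                   {"S01": 0.0}, {"rpsB": 1}, 1.0)
    g2 = SimGenome("G2", 10_000, "d__B;p__;c__;o__;f__;g__;s__",
                   {"S01": 1.0}, {"rpsB": 1}, 1.0)
    cfg = SimConfig(n_genomes=2, n_samples=1, genome_size_bp=10_000,
                    contig_length=10_000)
    table = simulate_depths(
        {"G1_c0001": 10_000, "G2_c0001": 10_000},
        {"G1_c0001": "G1", "G2_c0001": "G2"}, [g1, g2], cfg,
        np.random.default_rng(1),
    )
    assert table.read_counts.loc["G1_c0001", "S01"] == 0
    assert table.read_counts.loc["G2_c0001", "S01"] > 0


def test_emitted_tables_load_through_every_reader(tmp_path, small_truth,
                                                  catalog):
    paths = emit_tables(small_truth, tmp_path)
    table = nio.read_depth_table(paths["depths"])
    ann = nio.read_annotation_table(paths["annotations"], catalog)
    membership = nio.read_bin_membership(paths["bins"])
    quality = nio.read_quality_table(paths["quality"])
    samples = nio.read_sample_metadata(paths["samples"])
    ani = nio.read_ani_matrix(paths["ani"])
    assert len(table.contig_ids) == len(small_truth.contig_lengths)
    assert ann["in_catalog"].all()
    assert len(samples) == small_truth.config.n_samples
    assert ani.shape[0] == small_truth.config.n_genomes
    # zero binning noise: every contig binned to its true genome
    for contig, mag in membership.items():
        assert mag == f"MAG_{small_truth.contig_genome[contig]}"
    assert (quality["completeness"] == 100.0).all()
    assert (quality["contamination"] == 0.0).all()


def test_misbinning_noise_shows_up_as_contamination():
    truth = simulate_community(small_cfg(frac_misbinned=0.2, seed=21))
    assert (truth.quality["contamination"] > 0).any()
    wrong = sum(
        1 for contig, mag in truth.membership.items()
        if mag != f"MAG_{truth.contig_genome[contig]}"
    )
    assert wrong > 0


def test_unbinned_noise_reduces_completeness():
    truth = simulate_community(small_cfg(frac_unbinned=0.3, seed=22))
    assert (truth.quality["completeness"] < 100.0).any()
    assert len(truth.membership) < len(truth.contig_lengths)


def test_mag_depth_ranking_recovers_truth_ordering(small_truth):
    """Equal contigs + zero binning noise: normalized MAG depth orders every
    resolvable genome pair (true abundances >= 5% apart) like the truth."""
    mags = nio.build_mags(small_truth.membership,
                          small_truth.depth_table.lengths,
                          small_truth.quality)
    md = mag_depth_table(mags, small_truth.samples, small_truth.depth_table)
    ab = {(g.genome_id, s): g.abundances[s]
          for g in small_truth.genomes for s in small_truth.samples}
    for s in small_truth.samples:
        depth = (md.query("sample_id == @s")
                 .set_index("mag_id")["mag_depth"])
        ids = [g.genome_id for g in small_truth.genomes]
        for i, gi in enumerate(ids):
            for gj in ids[i + 1:]:
                ai, aj = ab[(gi, s)], ab[(gj, s)]
                if ai > 1.05 * aj:
                    assert depth[f"MAG_{gi}"] > depth[f"MAG_{gj}"], (gi, gj, s)
                elif aj > 1.05 * ai:
                    assert depth[f"MAG_{gj}"] > depth[f"MAG_{gi}"], (gi, gj, s)


def test_presence_rule_recovers_truth_copy_numbers(small_truth, catalog):
    """No binning noise, fully complete bins: the presence call per genus
    equals 'some member genome carries the gene' for every catalog gene."""
    mags = nio.build_mags(small_truth.membership,
                          small_truth.depth_table.lengths,
                          small_truth.quality)
    gene_sets = nio.mag_gene_sets(small_truth.annotations,
                                  small_truth.membership)
    genus_of = {f"MAG_{g.genome_id}": g.taxonomy.split(";")[5]
                for g in small_truth.genomes}
    copies = {f"MAG_{g.genome_id}": g.gene_copy_numbers
              for g in small_truth.genomes}
    by_genus: dict[str, list] = {}
    for mag_id, mag in mags.items():
        by_genus.setdefault(genus_of[mag_id], []).append(mag)
    for genus, members in by_genus.items():
        for gene in catalog.gene_symbols:
            ev = taxon_gene_presence(members, gene, gene_sets)
            truth_present = any(
                copies[m.mag_id].get(gene, 0) > 0 for m in members
            )
            assert ev.present == truth_present, (genus, gene)
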