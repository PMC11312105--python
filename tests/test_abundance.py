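"""Gene depth and MAG depth: hand-computed values, invariants, oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nitroprofile import abundance as ab
from nitroprofile.errors import ValidationError
from nitroprofile.io import MAG, parse_taxonomy

from conftest import make_depth_table, make_sample


def ann(*pairs):
    return pd.DataFrame(
        [{"contig_id": c, "gene_symbol": g, "ko_id": ""} for c, g in pairs]
    )


@pytest.mark.parametrize(
    "reads, length, total, expected",
    [(100, 2000, 1_000_000, 50.0), (0, 500, 10, 0.0), (10, 1000, 10**9, 0.01)],
)
def test_rpkm_hand_values(reads, length, total, expected):
    assert ab.rpkm(reads, length, total) == pytest.approx(expected, rel=1e-12)


def test_rpkm_rejects_degenerate_inputs():
    with pytest.raises(ValidationError):
        ab.rpkm(10, 0, 100)
    with pytest.raises(ValidationError):
        ab.rpkm(10, 100, 0)


def _two_set_fixture():
    # Q = {q1, q2} with RPKM 10 and 5; C = {c1, c2} with RPKM 5 each.
    # With equal lengths (2 kb) and 1e6 total reads, rpkm = count / 2,
    # so counts 20, 10 / 10, 10 give the target RPKMs.
    table = make_depth_table(
        {"q1": 2000, "q2": 2000, "c1": 2000, "c2": 2000},
        {"S1": {"q1": 20, "q2": 10, "c1": 10, "c2": 10}},
    )
    annotations = ann(("q1", "nirB"), ("q2", "nirB"),
                      ("c1", "rpsB"), ("c2", "rpsB"))
    return table, annotations, make_sample()


def test_gene_depth_ratio_of_rpkm_sums():
    table, annotations, sample = _two_set_fixture()
    r = ab.gene_depth("nirB", sample, table, annotations)
    assert r.gene_depth == pytest.approx(1.5, rel=1e-12)
    assert r.n_contigs_Q == 2 and r.n_contigs_C == 2


def test_gene_depth_marker_self_normalizes_exactly():
    table, annotations, sample = _two_set_fixture()
    assert ab.gene_depth("rpsB", sample, table, annotations).gene_depth == 1.0


def test_gene_depth_absent_gene_is_zero_not_error():
    table, annotations, sample = _two_set_fixture()
    r = ab.gene_depth("nosZ", sample, table, annotations)
    assert r.gene_depth == 0.0 and r.n_contigs_Q == 0


def test_gene_depth_missing_marker_is_explicit_error():
    table, _, sample = _two_set_fixture()
    with pytest.raises(ValidationError, match="rpsB"):
        ab.gene_depth("nirB", sample, table, ann(("q1", "nirB")))


def test_contig_with_gene_and_marker_counts_in_both_sets():
    table = make_depth_table(
        {"c1": 2000, "c2": 2000}, {"S1": {"c1": 10, "c2": 10}}
    )
    annotations = ann(("c1", "nirB"), ("c1", "rpsB"), ("c2", "rpsB"))
    r = ab.gene_depth("nirB", make_sample(), table, annotations)
    assert r.gene_depth == pytest.approx(0.5)
    assert r.n_contigs_Q == 1 and r.n_contigs_C == 2


@settings(max_examples=30, derandomize=True)
@given(k=st.integers(min_value=1, max_value=1000))
def test_gene_depth_scale_invariance(k):
    """Multiplying every read count by k leaves the ratio unchanged."""
    base = {"S1": {"q1": 20, "q2": 10, "c1": 10, "c2": 10}}
    scaled = {"S1": {c: n * k for c, n in base["S1"].items()}}
    lengths = {"q1": 2000, "q2": 3000, "c1": 2500, "c2": 2000}
    annotations = ann(("q1", "nirB"), ("q2", "nirB"),
                      ("c1", "rpsB"), ("c2", "rpsB"))
    sample = make_sample()
    r0 = ab.gene_depth("nirB", sample, make_depth_table(lengths, base),
                       annotations)
    rk = ab.gene_depth("nirB", sample, make_depth_table(lengths, scaled),
                       annotations)
    assert rk.gene_depth == pytest.approx(r0.gene_depth, rel=1e-12)


def test_profile_agrees_with_single_gene_calls(small_truth, catalog):
    prof = ab.gene_depth_profile(
        small_truth.samples, small_truth.depth_table,
        small_truth.annotations, catalog,
    )
    s = small_truth.samples["S01"]
    for gene in ("nirB", "nasA", "rpsB", "vnf"):
        single = ab.gene_depth(gene, s, small_truth.depth_table,
                               small_truth.annotations)
        row = prof.query("gene_symbol == @gene and sample_id == 'S01'")
        assert row["gene_depth"].iloc[0] == pytest.approx(
            single.gene_depth, rel=1e-12
        )


def test_profile_reports_unannotated_genes_as_zero(small_truth, catalog):
    """Genes the simulator never placed (vnf, anf) stay reportable at 0."""
    prof = ab.gene_depth_profile(
        small_truth.samples, small_truth.depth_table,
        small_truth.annotations, catalog,
    )
    for gene in ("vnf", "anf"):
        rows = prof[prof["gene_symbol"] == gene]
        assert len(rows) == len(small_truth.samples)
        assert (rows["gene_depth"] == 0.0).all()


def _mag(mag_id, contigs, size, completeness=90.0, contamination=1.0):
    return MAG(mag_id, set(contigs), size, completeness, contamination)


def test_mag_raw_depth_is_plain_sum():
    table = make_depth_table(
        {"c1": 2000, "c2": 4000},
        {"S1": {"c1": 0, "c2": 0}},
    )
    table.depths.loc["c1", "S1"] = 10.0
    table.depths.loc["c2", "S1"] = 20.0
    mag = _mag("M1", ["c1", "c2"], 6000)
    assert ab.mag_raw_depth(mag, "S1", table) == pytest.approx(30.0)
    single = _mag("M2", ["c2"], 4000)
    assert ab.mag_raw_depth(single, "S1", table) == pytest.approx(20.0)


def test_mag_raw_depth_missing_contig():
    table = make_depth_table({"c1": 2000}, {"S1": {"c1": 5}})
    with pytest.raises(ValidationError, match="ghost"):
        ab.mag_raw_depth(_mag("M1", ["c1", "ghost"], 4000), "S1", table)


def test_mag_depth_normalization_and_read_scaling():
    table = make_depth_table({"c1": 2000}, {"S1": {"c1": 0}})
    table.depths.loc["c1", "S1"] = 30.0
    mag = _mag("M1", ["c1"], 3_000_000)
    s10 = ab.mag_depth(mag, make_sample("S1", 10_000_000), table)
    s20 = ab.mag_depth(mag, make_sample("S1", 20_000_000), table)
    assert s10.mag_depth == pytest.approx(1.0e-6, rel=1e-12)
    assert s20.mag_depth == pytest.approx(0.5e-6, rel=1e-12)
    # zero depth -> zero, not an error
    table.depths.loc["c1", "S1"] = 0.0
    assert ab.mag_depth(mag, make_sample("S1"), table).mag_depth == 0.0


def test_community_composition_shares():
    table = make_depth_table(
        {"c1": 2000, "c2": 2000}, {"S1": {"c1": 0, "c2": 0}}
    )
    table.depths.loc["c1", "S1"] = 1.0
    table.depths.loc["c2", "S1"] = 3.0
    mags = {"M1": _mag("M1", ["c1"], 1_000_000),
            "M2": _mag("M2", ["c2"], 1_000_000)}
    md = ab.mag_depth_table(mags, {"S1": make_sample("S1")}, table)
    assert md["relative_abundance"].sum() == pytest.approx(1.0, abs=1e-9)
    tax = {
        "M1": parse_taxonomy("d__Bacteria;p__Bacteroidota;c__;o__;f__;g__;s__"),
        "M2": parse_taxonomy("d__Bacteria;p__Proteobacteria;c__;o__;f__;g__;s__"),
    }
    comp = ab.community_composition(md, tax, "phylum")
    shares = comp.set_index("taxon")["share"]
    assert shares["Bacteroidota"] == pytest.approx(0.25)
    assert shares["Proteobacteria"] == pytest.approx(0.75)


def test_community_composition_all_zero_sample_errors():
    md = pd.DataFrame(
        [{"mag_id": "M1", "sample_id": "S1", "raw_depth": 0.0,
          "mag_depth": 0.0, "relative_abundance": np.nan}]
    )
    tax = {"M1": parse_taxonomy("d__Bacteria;p__X;c__;o__;f__;g__;s__")}
    with pytest.raises(ValidationError, match="S1"):
        ab.community_composition(md, tax, "phylum")


def test_taxon_gene_contribution_fractions():
    table = make_depth_table(
        {"q1": 2000, "q2": 2000, "q3": 2000, "m": 2000},
        {"S1": {"q1": 30, "q2": 10, "q3": 20, "m": 10}},
    )
    annotations = ann(("q1", "nasA"), ("q2", "nasA"), ("q3", "nasA"),
                      ("m", "rpsB"))
    membership = pd.Series({"q1": "M1", "q2": "M2"})
    tax = {
        "M1": parse_taxonomy("d__B;p__P;c__C;o__O;f__F;g__Yoonia;s__"),
        "M2": parse_taxonomy("d__B;p__P;c__C;o__O;f__F;g__Other;s__"),
    }
    frac = ab.taxon_gene_contribution(
        "nasA", make_sample(), "genus", table, annotations, membership, tax
    )
    assert frac["Yoonia"] == pytest.approx(0.5)
    assert frac["Other"] == pytest.approx(1 / 6)
    assert frac["unassigned"] == pytest.approx(1 / 3)
    assert frac.sum() == pytest.approx(1.0, abs=1e-12)


def test_taxon_gene_contribution_absent_gene_errors():
    table = make_depth_table({"m": 2000}, {"S1": {"m": 10}})
    with pytest.raises(ValidationError, match="absent"):
        ab.taxon_gene_contribution(
            "nasA", make_sample(), "genus", table, ann(("m", "rpsB")),
            pd.Series(dtype=object), {},
        )
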