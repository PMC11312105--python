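#!/usr/bin/env python
"""Taxon-level gene presence, multi-enzyme co-occurrence, novelty, species.

Runs the >25%-of-MAGs / >90%-complete-carrier presence rule per genus,
counts MAGs carrying more than one nitrate-reductase type, summarizes
taxonomy novelty, and clusters MAGs into species at the 95% ANI threshold.
"""

from pathlib import Path

import pandas as pd

from nitroprofile import io as nio
from nitroprofile.catalog import NITRATE_REDUCTASE_TYPES, load_catalog
from nitroprofile.genome_profiles import (
    cluster_species_from_ani,
    count_multitype,
    filter_mags,
    novelty_summary,
    taxon_gene_presence,
)

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"
SIM = BASE / "sim"

if __name__ == "__main__":
    catalog = load_catalog()
    table = nio.read_depth_table(SIM / "depths.tsv")
    membership = nio.read_bin_membership(SIM / "bins.tsv")
    quality = nio.read_quality_table(SIM / "quality.tsv")
    ann = nio.read_annotation_table(SIM / "annotations.tsv", catalog)

    mags = nio.build_mags(membership, table.lengths, quality)
    retained = filter_mags(mags.values())
    gene_sets = nio.mag_gene_sets(ann, membership)

    by_genus: dict[str, list] = {}
    for m in retained:
        name = (m.taxonomy.rank("genus")
                if not m.taxonomy.is_unknown("genus") else "unknown")
        by_genus.setdefault(name, []).append(m)
    rows = []
    for genus in sorted(by_genus):
        for gene in sorted(catalog.gene_symbols):
            ev = taxon_gene_presence(by_genus[genus], gene, gene_sets)
            rows.append({"taxon": genus, **ev.__dict__,
                         "hq_carriers": ";".join(ev.hq_carriers)})
    presence = pd.DataFrame(rows)
    presence.to_csv(BASE / "presence.tsv", sep="\t", index=False)
    n_present = int(presence["present"].sum())
    print(f"{n_present} (genus, gene) presence calls over "
          f"{len(by_genus)} genera")

    summary = count_multitype(gene_sets, NITRATE_REDUCTASE_TYPES,
                              catalog.complex_rules(),
                              denominator=len(retained))
    print(f"nitrate reductase: {summary.n_with_any} MAGs with >=1 type "
          f"({summary.pct_with_any(1)}%), {summary.n_multi} with >1 "
          f"({summary.pct_multi(2) if summary.n_with_any else 0}% of carriers)")

    taxa = [m.taxonomy for m in retained]
    n_sp, pct_sp = novelty_summary(taxa, "species")
    print(f"unknown species: {n_sp} MAGs ({pct_sp}%)")

    ani = nio.read_ani_matrix(SIM / "ani.tsv")
    clusters = cluster_species_from_ani(ani, quality)
    (clusters.rename("cluster_rep").rename_axis("mag_id").reset_index()
     .to_csv(BASE / "species_clusters.tsv", sep="\t", index=False))
    print(f"{clusters.nunique()} species clusters at ANI >= 95%")
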