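"""End-to-end orchestration: profile -> magdepth -> presence -> summarize ->
compare, driven by one config dict, with a manifest recording every
parameter and input digest. Identical inputs and config produce
byte-identical tables (the manifest id is content-derived)."""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from . import io as nio
from .abundance import gene_depth_profile, mag_depth_table, community_composition
from .catalog import load_catalog
from .community_stats import (
    compare_gene_across_groups,
    gene_medians_by_group,
    pathway_abundance,
)
from .errors import NitroprofileError
from .genome_profiles import (
    PresenceRule,
    cluster_species_from_ani,
    filter_mags,
    taxon_gene_presence,
)

DEFAULTS: dict[str, Any] = {
    "marker": "rpsB",
    "read_length": nio.DEFAULT_READ_LENGTH,
    "rank": "genus",
    "ani_threshold": 95.0,
    "aggregation": "sum",
    "group_by": ["lake", "month"],
    "length_weighted": False,
    "min_completeness": 50.0,
    "max_contamination": 10.0,
    "presence_min_fraction": 0.25,
    "presence_hq_completeness": 90.0,
    "seed": 0,
}

INPUT_KEYS = ("depths", "annotations", "bins", "quality", "samples", "ani")


class PipelineStageError(NitroprofileError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(stage: str, message: str) -> None:
    print(f"[nitroprofile:{stage}] {message}", file=sys.stderr)


def run_all(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Path]:
    """Run every stage; returns a map of table name -> written path.

    config["inputs"] maps depths/annotations/bins/quality/samples[/ani]
    to file paths; remaining keys override DEFAULTS.
    """
    params = {**DEFAULTS, **{k: v for k, v in config.items() if k != "inputs"}}
    inputs: dict[str, str] = dict(config.get("inputs", {}))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    required = [k for k in INPUT_KEYS if k != "ani"]
    missing = [k for k in required if k not in inputs]
    if missing:
        raise PipelineStageError("inputs", f"missing input paths: {missing}")
    for key, p in inputs.items():
        if not Path(p).exists():
            raise PipelineStageError("inputs", f"{key} file not found: {p}")

    digests = {k: _sha256(Path(p)) for k, p in sorted(inputs.items())}
    manifest_core = json.dumps(
        {"params": params, "inputs": digests, "version": __version__},
        sort_keys=True, default=str,
    )
    manifest_id = hashlib.sha256(manifest_core.encode()).hexdigest()[:12]

    def write(df: pd.DataFrame, name: str) -> Path:
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# manifest_id={manifest_id}\n")
            df.to_csv(fh, sep="\t", index=False)
        return path

    stage = "load"
    try:
        catalog = load_catalog(params.get("catalog"))
        table = nio.read_depth_table(inputs["depths"])
        annotations = nio.read_annotation_table(inputs["annotations"], catalog)
        membership = nio.read_bin_membership(inputs["bins"])
        quality = nio.read_quality_table(inputs["quality"])
        samples = nio.read_sample_metadata(inputs["samples"])
        _log(stage, f"{len(table.contig_ids)} contigs, "
                    f"{len(samples)} samples, {len(quality)} MAGs")
    except NitroprofileError as e:
        raise PipelineStageError(stage, str(e)) from e

    written: dict[str, Path] = {}
    try:
        stage = "profile"
        gene_depths = gene_depth_profile(
            samples, table, annotations, catalog,
            marker=params["marker"], read_length=params["read_length"],
        )
        written["gene_depth"] = write(gene_depths, "gene_depth.tsv")
        medians = pd.concat([
            gene_medians_by_group(gene_depths, samples, g)
            for g in ("all", "lake", "month")
        ])
        written["gene_medians"] = write(medians, "gene_medians.tsv")

        stage = "magdepth"
        mags = nio.build_mags(membership, table.lengths, quality)
        retained = filter_mags(
            mags.values(),
            nio.QualityThresholds(params["min_completeness"],
                                  params["max_contamination"]),
        )
        _log(stage, f"{len(retained)}/{len(mags)} MAGs pass the quality filter")
        retained_map = {m.mag_id: m for m in retained}
        mag_depths = mag_depth_table(
            retained_map, samples, table,
            length_weighted=params["length_weighted"],
        )
        written["mag_depth"] = write(mag_depths, "mag_depth.tsv")
        taxonomies = {m.mag_id: m.taxonomy for m in retained}
        composition = community_composition(
            mag_depths, taxonomies, params["rank"]
        )
        written["composition"] = write(composition, "composition.tsv")

        stage = "presence"
        gene_sets = nio.mag_gene_sets(annotations, membership)
        rule = PresenceRule(params["presence_min_fraction"],
                            params["presence_hq_completeness"])
        rows = []
        by_taxon: dict[str, list] = {}
        for m in retained:
            tax = m.taxonomy
            name = (tax.rank(params["rank"])
                    if not tax.is_unknown(params["rank"]) else "unknown")
            by_taxon.setdefault(name, []).append(m)
        for taxon in sorted(by_taxon):
            for gene in sorted(catalog.gene_symbols):
                ev = taxon_gene_presence(by_taxon[taxon], gene, gene_sets, rule)
                rows.append({
                    "taxon": taxon, "rank": params["rank"], **ev.__dict__,
                    "hq_carriers": ";".join(ev.hq_carriers),
                })
        written["presence"] = write(pd.DataFrame(rows), "presence.tsv")

        if "ani" in inputs:
            stage = "species"
            ani = nio.read_ani_matrix(inputs["ani"])
            clusters = cluster_species_from_ani(
                ani, quality, threshold=params["ani_threshold"]
            )
            cdf = clusters.rename("cluster_rep").rename_axis("mag_id").reset_index()
            written["species_clusters"] = write(cdf, "species_clusters.tsv")
            _log(stage, f"{clusters.nunique()} species clusters at "
                        f"ANI >= {params['ani_threshold']}")

        stage = "summarize"
        pathways = pathway_abundance(gene_depths, catalog,
                                     params["aggregation"])
        written["pathways"] = write(pathways, "pathways.tsv")

        stage = "compare"
        comparisons = []
        for grouping in params["group_by"]:
            c = compare_gene_across_groups(gene_depths, samples, grouping)
            if not c.empty:
                c["grouping"] = grouping
                comparisons.append(c)
        if comparisons:
            written["comparisons"] = write(
                pd.concat(comparisons, ignore_index=True), "comparisons.tsv"
            )
    except NitroprofileError as e:
        raise PipelineStageError(stage, str(e)) from e

    manifest = {
        "manifest_id": manifest_id,
        "version": __version__,
        "params": params,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "input_digests": digests,
        "outputs": {k: str(v) for k, v in written.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    written["manifest"] = out / "manifest.json"
    _log("done", f"wrote {len(written)} outputs to {out}")
    return written


def read_report_table(path: str | Path) -> pd.DataFrame:
    """Read a pipeline output table (skipping the manifest comment line)."""
    return pd.read_csv(path, sep="\t", comment="#")
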