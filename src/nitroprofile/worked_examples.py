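"""Report-table cohorts for the Altun-mountain saline-lake survey.

The survey's genome-level summary statistics (taxonomy-novelty percentages,
multi-enzyme co-occurrence percentages) are exact roundings of ratios of
MAG counts. This module reconstructs those counts as explicit cohorts —
taxonomy lists and per-MAG gene sets with the published marginals — so the
summary operations can recompute every percentage from data rather than
from arithmetic on two numbers.
"""

from __future__ import annotations

from .io import TaxonomyString, parse_taxonomy

#: Bacterial MAGs recovered across the four lakes.
N_BACTERIAL_MAGS = 1593
#: All MAGs (bacterial + 8 archaeal) — the multi-type denominators.
N_TOTAL_MAGS = 1601

#: Unknown-taxon counts among the 1,593 bacterial MAGs, per rank (nested:
#: a MAG unknown at a rank is unknown at every rank below it).
UNKNOWN_COUNTS = {
    "phylum": 1,
    "order": 5,
    "family": 38,
    "genus": 376,
    "species": 1440,
}

#: Nitrate-reductase carriage: 341 MAGs encode >=1 of the three types
#: (Nar/Nap/Nas), 47 of them more than one.
NITRATE_ANY, NITRATE_MULTI = 341, 47
#: Ammonium-forming/assimilatory nitrite reductases (NirBD/Nrf/NirA):
#: 206 MAGs encode >=1 type, 18 more than one.
NITRITE_ANY, NITRITE_MULTI = 206, 18
#: NO-forming denitrifier nitrite reductases: 310 MAGs encode nirK and/or
#: nirS; 7 encode both.
DENITR_NIR_ANY, DENITR_NIR_BOTH = 310, 7


def _tax(upto: str) -> TaxonomyString:
    """A taxonomy string assigned down to (and including) rank ``upto``."""
    ranks = ["d__Bacteria", "p__P", "c__C", "o__O", "f__F", "g__G", "s__S"]
    cut = {"domain": 1, "phylum": 2, "class": 3, "order": 4,
           "family": 5, "genus": 6, "species": 7}[upto]
    parts = ranks[:cut] + [r[:3] for r in ranks[cut:]]
    return parse_taxonomy(";".join(parts))


def novelty_cohort() -> list[TaxonomyString]:
    """1,593 bacterial-MAG taxonomies with the published unknown marginals."""
    u = UNKNOWN_COUNTS
    blocks = [
        (u["phylum"], "domain"),                       # unknown from phylum down
        (u["order"] - u["phylum"], "class"),           # unknown from order down
        (u["family"] - u["order"], "order"),           # unknown from family down
        (u["genus"] - u["family"], "family"),          # unknown from genus down
        (u["species"] - u["genus"], "genus"),          # unknown species only
        (N_BACTERIAL_MAGS - u["species"], "species"),  # fully classified
    ]
    cohort: list[TaxonomyString] = []
    for count, assigned_to in blocks:
        cohort.extend(_tax(assigned_to) for _ in range(count))
    assert len(cohort) == N_BACTERIAL_MAGS
    return cohort


def _gene_set_cohort(
    n_multi: int, multi_genes: set[str],
    n_single: int, single_genes: set[str],
    n_total: int,
) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for i in range(n_total):
        if i < n_multi:
            sets[f"MAG{i:04d}"] = set(multi_genes)
        elif i < n_multi + n_single:
            sets[f"MAG{i:04d}"] = set(single_genes)
        else:
            sets[f"MAG{i:04d}"] = set()
    return sets


def nitrate_reductase_cohort() -> dict[str, set[str]]:
    """1,601 per-MAG gene sets: 47 with two nitrate-reductase types
    (complete NarGHI + NapAB), 294 with one (complete NarGHI)."""
    return _gene_set_cohort(
        NITRATE_MULTI, {"narG", "narH", "narI", "napA"},
        NITRATE_ANY - NITRATE_MULTI, {"narG", "narH", "narI"},
        N_TOTAL_MAGS,
    )


def nitrite_reductase_cohort() -> dict[str, set[str]]:
    """1,601 per-MAG gene sets: 18 with two ammonium-forming nitrite
    reductase types (NirBD + Nrf), 188 with one (NirBD)."""
    return _gene_set_cohort(
        NITRITE_MULTI, {"nirB", "nrfA"},
        NITRITE_ANY - NITRITE_MULTI, {"nirB"},
        N_TOTAL_MAGS,
    )


def denitrifier_nir_cohort() -> dict[str, set[str]]:
    """1,601 per-MAG gene sets: 7 with both nirK and nirS, 303 with one."""
    return _gene_set_cohort(
        DENITR_NIR_BOTH, {"nirK", "nirS"},
        DENITR_NIR_ANY - DENITR_NIR_BOTH, {"nirK"},
        N_TOTAL_MAGS,
    )
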