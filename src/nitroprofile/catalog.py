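"""Nitrogen-cycle gene catalog.

Maps short gene symbols (nirB, nifH, nasA, ...) to KEGG orthology ids,
enzyme complexes (NarGHI, NorBC, ...) and the seven canonical nitrogen-cycle
processes, plus the single-copy marker *rpsB* and a small set of
organic-nitrogen utilization genes. The catalog ships as an editable TSV so
KO revisions never touch code; all downstream logic keys on ``gene_symbol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import FormatError, ValidationError

#: The seven canonical nitrogen-cycle processes.
PROCESSES: tuple[str, ...] = (
    "nitrogen_fixation",
    "nitrification",
    "denitrification",
    "dissimilatory_nitrate_reduction",
    "assimilatory_nitrate_reduction",
    "anammox",
    "ammonification",
)

#: Auxiliary categories that complete the catalog partition.
AUX_CATEGORIES: tuple[str, ...] = ("marker", "organic_nitrogen_utilization")

#: Default single-copy marker gene (ribosomal protein S2).
DEFAULT_MARKER = "rpsB"

# Multi-subunit complexes scored only when every required subunit is present.
_ALL_SUBUNIT_COMPLEXES = frozenset({"NarGHI", "NorBC"})

# narG/nxrA and narH/nxrB are homologs sharing one KO each; hits to the
# nitrite-oxidoreductase labels are counted as the nitrate-reductase genes.
NAR_NXR_SYNONYMS: Mapping[str, str] = {"nxrA": "narG", "nxrB": "narH"}

_COLUMNS = ("gene_symbol", "ko_id", "complex_id", "subunit_role", "process")


@dataclass(frozen=True)
class CatalogEntry:
    """One catalog gene: symbol, KO, enzyme complex and process membership."""

    gene_symbol: str
    ko_id: str
    complex_id: str
    subunit_role: str
    process: str


@dataclass(frozen=True)
class ComplexRule:
    """Presence rule for an enzyme complex.

    mode="all_subunits": every gene in ``required_genes`` must be present
    (the both-subunit convention used for NorBC and NarGHI).
    mode="any_subunit": one is enough.
    """

    complex_id: str
    required_genes: frozenset[str]
    mode: str = "any_subunit"

    def __post_init__(self) -> None:
        if self.mode not in ("all_subunits", "any_subunit"):
            raise ValidationError(f"unknown complex rule mode: {self.mode!r}")
        if not self.required_genes:
            raise ValidationError(f"complex {self.complex_id}: empty gene set")


@dataclass(frozen=True)
class TypeGroupScheme:
    """Named grouping of complexes into enzyme 'types' for co-occurrence counts.

    e.g. the three prokaryotic nitrate-reductase types
    Nar={NarGHI}, Nap={NapAB}, Nas={Nas}.
    """

    scheme_id: str
    groups: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, complexes in self.groups.items():
            overlap = seen & set(complexes)
            if overlap:
                raise ValidationError(
                    f"scheme {self.scheme_id}: complexes {sorted(overlap)} "
                    f"appear in more than one type group (at {label})"
                )
            seen |= set(complexes)


@dataclass
class Catalog:
    """The full gene catalog with complex rules."""

    entries: dict[str, CatalogEntry] = field(default_factory=dict)

    def __contains__(self, gene_symbol: str) -> bool:
        return gene_symbol in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_symbols(self) -> set[str]:
        return set(self.entries)

    @property
    def marker(self) -> str:
        return DEFAULT_MARKER

    def entry(self, gene_symbol: str) -> CatalogEntry:
        try:
            return self.entries[gene_symbol]
        except KeyError:
            raise ValidationError(
                f"gene symbol {gene_symbol!r} not in catalog"
            ) from None

    def complexes(self) -> dict[str, frozenset[str]]:
        """complex_id -> member gene symbols."""
        members: dict[str, set[str]] = {}
        for e in self.entries.values():
            members.setdefault(e.complex_id, set()).add(e.gene_symbol)
        return {cid: frozenset(g) for cid, g in members.items()}

    def complex_rules(self) -> dict[str, ComplexRule]:
        """Default per-complex rules (all_subunits for NarGHI and NorBC)."""
        rules = {}
        for cid, genes in self.complexes().items():
            mode = "all_subunits" if cid in _ALL_SUBUNIT_COMPLEXES else "any_subunit"
            rules[cid] = ComplexRule(cid, genes, mode)
        return rules


def _default_catalog_text() -> str:
    return (
        resources.files("nitroprofile.data")
        .joinpath("nitrogen_catalog.tsv")
        .read_text()
    )


def load_catalog(path: str | Path | None = None) -> Catalog:
    """Load the catalog from ``path`` or the packaged default TSV.

    Raises FormatError naming the offending line on malformed rows and
    ValidationError on duplicate gene symbols or unknown process labels.
    """
    if path is None:
        text = _default_catalog_text()
        source = "<default catalog>"
    else:
        text = Path(path).read_text()
        source = str(path)

    valid_processes = set(PROCESSES) | set(AUX_CATEGORIES)
    entries: dict[str, CatalogEntry] = {}
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if not header_seen:
            if tuple(fields) != _COLUMNS:
                raise FormatError(
                    f"{source}:{lineno}: expected header {_COLUMNS}, got {fields}"
                )
            header_seen = True
            continue
        if len(fields) != len(_COLUMNS):
            raise FormatError(
                f"{source}:{lineno}: expected {len(_COLUMNS)} columns, "
                f"got {len(fields)}"
            )
        entry = CatalogEntry(*fields)
        if entry.process not in valid_processes:
            raise FormatError(
                f"{source}:{lineno}: unknown process {entry.process!r}; "
                f"valid: {sorted(valid_processes)}"
            )
        if entry.gene_symbol in entries:
            raise ValidationError(
                f"{source}:{lineno}: duplicate gene_symbol {entry.gene_symbol!r}"
            )
        entries[entry.gene_symbol] = entry
    if not header_seen:
        raise FormatError(f"{source}: no header line found")
    return Catalog(entries)


def genes_for_process(catalog: Catalog, process: str) -> set[str]:
    """Gene symbols belonging to one process (or auxiliary category)."""
    valid = set(PROCESSES) | set(AUX_CATEGORIES)
    if process not in valid:
        raise ValidationError(
            f"unknown process {process!r}; valid labels: {sorted(valid)}"
        )
    return {
        e.gene_symbol for e in catalog.entries.values() if e.process == process
    }


def complex_present(gene_set: Iterable[str], rule: ComplexRule) -> bool:
    """Whether ``gene_set`` satisfies the complex presence rule."""
    present = set(gene_set)
    if rule.mode == "all_subunits":
        return rule.required_genes <= present
    return bool(rule.required_genes & present)


def resolve_nar_nxr(hits, symbol_column: str = "gene_symbol"):
    """Relabel nxrA->narG and nxrB->narH hits (shared KEGG KOs).

    Accepts a pandas DataFrame (returns a relabeled copy) or an iterable of
    gene symbols (returns a list). Output size equals input size.
    """
    try:
        import pandas as pd  # local: keep catalog importable without pandas
    except ImportError:  # pragma: no cover
        pd = None
    if pd is not None and isinstance(hits, pd.DataFrame):
        out = hits.copy()
        out[symbol_column] = out[symbol_column].replace(dict(NAR_NXR_SYNONYMS))
        return out
    return [NAR_NXR_SYNONYMS.get(s, s) for s in hits]


#: Three prokaryotic nitrate-reductase types.
NITRATE_REDUCTASE_TYPES = TypeGroupScheme(
    "nitrate_reductase",
    {
        "Nar": frozenset({"NarGHI"}),
        "Nap": frozenset({"NapAB"}),
        "Nas": frozenset({"Nas"}),
    },
)

#: Three ammonium-forming / assimilatory nitrite-reductase types.
NITRITE_REDUCTASE_TYPES = TypeGroupScheme(
    "nitrite_reductase",
    {
        "NirBD": frozenset({"NirBD"}),
        "Nrf": frozenset({"Nrf"}),
        "NirA": frozenset({"NirA"}),
    },
)

#: NO-forming denitrifier nitrite reductases (mutually exclusive in most taxa).
DENITRIFIER_NIR_TYPES = TypeGroupScheme(
    "denitrifier_nir",
    {
        "NirK": frozenset({"NirK"}),
        "NirS": frozenset({"NirS"}),
    },
)


def validate_closed_world(catalog: Catalog, referenced: Iterable[str]) -> None:
    """Check every referenced gene symbol resolves in the catalog."""
    missing = sorted(set(referenced) - catalog.gene_symbols)
    if missing:
        raise ValidationError(
            f"gene symbols not in catalog: {missing}"
        )
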