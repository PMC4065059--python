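"""Local interaction store: parsing, deduplication, indexing, lookups.

Reads custom tab-separated interaction tables and a PSI-MI TAB 2.5
column subset, collapses duplicate evidence under canonical pair keys,
and answers neighborhood / identifier-resolution / ortholog queries.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .types import (
    EMPTY_PMID,
    EntityKind,
    EntityRef,
    EvidenceType,
    InteractionRecord,
    PairKey,
    Publication,
    canonical_pair,
    canonical_pair_key,
)

NATIVE_COLUMNS = [
    "id_a",
    "id_b",
    "organism_a",
    "organism_b",
    "evidence",
    "method",
    "pmid",
    "source_db",
]

MISSING = "."


class FormatError(ValueError):
    """Raised on malformed interaction / catalog tables."""


def _clean(value: str) -> str:
    value = value.strip()
    return "" if value in ("", MISSING, "-") else value


def _read_native_tsv(path: Path) -> list[InteractionRecord]:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            warnings.warn(f"empty interaction table: {path}")
            return []
        missing = [c for c in NATIVE_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"missing mandatory column(s) {missing} in {path}")
        idx = {c: header.index(c) for c in NATIVE_COLUMNS}
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            ev = _clean(row[idx["evidence"]])
            try:
                evidence = EvidenceType(ev)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: invalid evidence value {ev!r} "
                    f"(expected 'experimental' or 'predicted')"
                ) from None
            a = EntityRef.from_accession(
                _clean(row[idx["id_a"]]), organism=_clean(row[idx["organism_a"]])
            )
            b = EntityRef.from_accession(
                _clean(row[idx["id_b"]]), organism=_clean(row[idx["organism_b"]])
            )
            records.append(
                InteractionRecord(
                    a=a,
                    b=b,
                    evidence_type=evidence,
                    method=_clean(row[idx["method"]]),
                    pmid=_clean(row[idx["pmid"]]) or None,
                    source_db=_clean(row[idx["source_db"]]),
                )
            )
    return records


def _strip_namespace(token: str) -> str:
    # "uniprotkb:P12345" -> "P12345"; keep bare tokens as-is
    return token.split(":", 1)[1] if ":" in token else token


def _psimi_label(field_value: str) -> str:
    # 'psi-mi:"MI:0018"(two hybrid)' -> "two hybrid"; bare tokens pass through
    value = _clean(field_value)
    if "(" in value and value.endswith(")"):
        return value[value.index("(") + 1 : -1]
    return _strip_namespace(value)


def _psimitab_taxon(field_value: str) -> str:
    # "taxid:9606(Homo sapiens)" -> "9606"
    value = _clean(field_value)
    if not value:
        return ""
    value = _strip_namespace(value)
    return value.split("(", 1)[0]


def _read_psimitab25(path: Path) -> list[InteractionRecord]:
    """Minimal PSI-MI TAB 2.5 subset: ids, method, pmid, taxids, source db.

    Controlled-vocabulary parsing is out of scope; rows are treated as
    experimental unless the method text mentions prediction.
    """
    records = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                raise FormatError(
                    f"{path}:{lineno}: PSI-MI TAB 2.5 needs >= 15 columns, got {len(cols)}"
                )
            id_a = _strip_namespace(_clean(cols[0]))
            id_b = _strip_namespace(_clean(cols[1]))
            if not id_a or not id_b:
                raise FormatError(f"{path}:{lineno}: missing interactor id")
            method = _psimi_label(cols[6])
            pmid = ""
            for tok in _clean(cols[8]).split("|"):
                if tok.startswith("pubmed:"):
                    pmid = _strip_namespace(tok)
                    break
            org_a = _psimitab_taxon(cols[9])
            org_b = _psimitab_taxon(cols[10])
            source = _psimi_label(cols[12])
            evidence = (
                EvidenceType.PREDICTED
                if "predict" in method.lower()
                else EvidenceType.EXPERIMENTAL
            )
            records.append(
                InteractionRecord(
                    a=EntityRef.from_accession(id_a, organism=org_a),
                    b=EntityRef.from_accession(id_b, organism=org_b),
                    evidence_type=evidence,
                    method=method,
                    pmid=pmid or None,
                    source_db=source,
                )
            )
    if not records:
        warnings.warn(f"empty interaction table: {path}")
    return records


def read_interaction_table(path, dialect: str = "native_tsv") -> list[InteractionRecord]:
    """Parse an interaction table into records.

    ``dialect`` is ``native_tsv`` (header-matched custom TSV) or
    ``psimitab25`` (minimal PSI-MI TAB 2.5 column subset).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native_tsv":
        return _read_native_tsv(path)
    if dialect == "psimitab25":
        return _read_psimitab25(path)
    raise ValueError(f"unknown dialect {dialect!r}")


@dataclass
class PairEvidence:
    """Merged evidence for one unique unordered pair."""

    first: str
    second: str
    experimental: bool = False
    methods: set[str] = field(default_factory=set)
    sources: set[str] = field(default_factory=set)
    pmids: set[str] = field(default_factory=set)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.first, self.second)


@dataclass
class AnnotationCatalog:
    """Identifier, ortholog and term annotation lookups.

    ``cc_terms`` maps entity id -> selected cellular-component terms;
    ``bp_terms`` / ``kegg_terms`` map term id -> (name, member ids);
    ``symbol_map`` maps symbol -> candidate ``EntityRef`` list;
    ``ortholog_map`` maps (id, organism) -> target-organism id.
    """

    cc_terms: dict[str, set[str]] = field(default_factory=dict)
    bp_terms: dict[str, tuple[str, set[str]]] = field(default_factory=dict)
    kegg_terms: dict[str, tuple[str, set[str]]] = field(default_factory=dict)
    symbol_map: dict[str, list[EntityRef]] = field(default_factory=dict)
    ortholog_map: dict[tuple[str, str], str] = field(default_factory=dict)


class InteractionStore:
    """Deduplicated, indexed collection of interaction evidence.

    One evidence row survives per ``PairKey`` (pair + pmid); pair-level
    aggregates merge sources, methods and the publication set across
    rows of the same unordered pair.
    """

    def __init__(self) -> None:
        self.entities: dict[str, EntityRef] = {}
        self.evidence: dict[PairKey, InteractionRecord] = {}
        self.pairs: dict[tuple[str, str], PairEvidence] = {}
        self.publications: dict[str, Publication] = {}
        self._adjacency: dict[str, set[str]] = {}

    # -- construction ---------------------------------------------------

    def add_records(self, records: Iterable[InteractionRecord]) -> None:
        for rec in records:
            self._add_record(rec)

    def _register_entity(self, ent: EntityRef) -> None:
        known = self.entities.get(ent.id)
        if known is None:
            self.entities[ent.id] = ent
        elif known.symbol is None and ent.symbol is not None:
            self.entities[ent.id] = ent

    def _add_record(self, rec: InteractionRecord) -> None:
        self._register_entity(rec.a)
        self._register_entity(rec.b)
        key = canonical_pair_key(rec)
        if key not in self.evidence:
            self.evidence[key] = rec
        pe = self.pairs.get(key.pair)
        if pe is None:
            pe = PairEvidence(first=key.first, second=key.second)
            self.pairs[key.pair] = pe
            if key.first != key.second:
                self._adjacency.setdefault(key.first, set()).add(key.second)
                self._adjacency.setdefault(key.second, set()).add(key.first)
            else:
                self._adjacency.setdefault(key.first, set())
        if rec.evidence_type is EvidenceType.EXPERIMENTAL:
            pe.experimental = True
        if rec.method:
            pe.methods.add(rec.method)
        if rec.source_db:
            pe.sources.add(rec.source_db)
        if key.pmid != EMPTY_PMID:
            pe.pmids.add(key.pmid)

    def add_publications(self, pubs: Iterable[Publication]) -> None:
        for pub in pubs:
            self.publications[pub.pmid] = pub

    # -- queries --------------------------------------------------------

    def publication(self, pmid: str) -> Publication:
        return self.publications.get(pmid, Publication(pmid=pmid, interaction_count=None))

    def pair_publications(self, pair: tuple[str, str]) -> frozenset[Publication]:
        pe = self.pairs[pair]
        return frozenset(self.publication(p) for p in pe.pmids)

    def neighbors(
        self,
        entity_id: str,
        include_metabolites: bool = False,
        include_drugs: bool = False,
    ) -> set[str]:
        """Distinct partners over unique pairs; self excluded.

        Metabolite / drug partners appear only when the matching flag is
        set; an absent entity yields the empty set.
        """
        out = set()
        for other in self._adjacency.get(entity_id, ()):
            kind = self.entities[other].entity_kind
            if kind is EntityKind.METABOLITE and not include_metabolites:
                continue
            if kind is EntityKind.DRUG and not include_drugs:
                continue
            out.add(other)
        return out

    def degree(self, entity_id: str, organism: Optional[str] = None) -> int:
        """Unique-pair degree, optionally restricted to one organism."""
        if organism is None:
            return len(self._adjacency.get(entity_id, ()))
        return sum(
            1
            for other in self._adjacency.get(entity_id, ())
            if self.entities[other].organism == organism
        )

    def n_pairs(self, organism: Optional[str] = None) -> int:
        """Number of unique pairs, optionally both-endpoints organism-filtered."""
        if organism is None:
            return len(self.pairs)
        return sum(
            1
            for (a, b) in self.pairs
            if self.entities[a].organism == organism
            and self.entities[b].organism == organism
        )

    def organism_entities(self, organism: str) -> set[str]:
        return {eid for eid, e in self.entities.items() if e.organism == organism}


def deduplicate(records: Sequence[InteractionRecord]) -> InteractionStore:
    """Collapse duplicate evidence rows into a store of unique pairs."""
    store = InteractionStore()
    store.add_records(records)
    return store


@dataclass
class ResolutionReport:
    """Partition of input tokens into resolved / ambiguous / unresolved."""

    resolved: dict[str, EntityRef] = field(default_factory=dict)
    ambiguous: dict[str, list[EntityRef]] = field(default_factory=dict)
    unresolved: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.resolved) + len(self.ambiguous) + len(self.unresolved)


def resolve_identifiers(
    tokens: Sequence[str],
    catalog: AnnotationCatalog,
    organism: str,
    store: Optional[InteractionStore] = None,
) -> ResolutionReport:
    """Resolve accessions and gene symbols to entity references.

    Accession-shaped tokens (present in the store or in no symbol map)
    match directly; symbols prefer reviewed candidates, falling back to
    unreviewed ones only when no reviewed candidate exists in the
    organism. Same-tier multiplicity is reported as ambiguous, never
    silently chosen.
    """
    report = ResolutionReport()
    for token in tokens:
        if store is not None and token in store.entities:
            report.resolved[token] = store.entities[token]
            continue
        candidates = [
            c
            for c in catalog.symbol_map.get(token, [])
            if not organism or not c.organism or c.organism == organism
        ]
        if not candidates:
            report.unresolved.append(token)
            continue
        reviewed = [c for c in candidates if c.reviewed]
        tier = reviewed if reviewed else candidates
        if len(tier) == 1:
            report.resolved[token] = tier[0]
        else:
            report.ambiguous[token] = list(tier)
    return report


def map_orthologs(
    entities: Sequence[EntityRef],
    catalog: AnnotationCatalog,
    target_organism: str,
) -> tuple[list[EntityRef], list[EntityRef], dict[str, int]]:
    """Replace entities by their target-organism orthologs.

    Returns (mapped, unmapped, multiplicity) where ``multiplicity``
    counts how many sources collapsed onto each target id (many-to-one
    pairs are collapsed, not duplicated).
    """
    if not catalog.ortholog_map:
        raise ValueError("ortholog_map is empty; configure ortholog data first")
    mapped: dict[str, EntityRef] = {}
    multiplicity: dict[str, int] = {}
    unmapped: list[EntityRef] = []
    for ent in entities:
        if ent.organism == target_organism:
            mapped.setdefault(ent.id, ent)
            multiplicity[ent.id] = multiplicity.get(ent.id, 0) + 1
            continue
        target = catalog.ortholog_map.get((ent.id, ent.organism))
        if target is None:
            unmapped.append(ent)
            continue
        if target not in mapped:
            mapped[target] = EntityRef.from_accession(target, organism=target_organism)
        multiplicity[target] = multiplicity.get(target, 0) + 1
    return list(mapped.values()), unmapped, multiplicity


def select_cc_terms(
    raw_annotations: dict[str, set[str]],
    ancestor_map: dict[str, str],
    min_genes: int = 10,
) -> dict[str, set[str]]:
    """Group child CC terms under selected ancestors and size-filter them.

    Each child term is replaced by its mapped ancestor; ancestors
    annotated for fewer than ``min_genes`` entities are dropped
    store-wide. Children missing from the ancestor map are kept as-is
    with a warning.
    """
    grouped: dict[str, set[str]] = {}
    missing: set[str] = set()
    for entity, terms in raw_annotations.items():
        out = set()
        for term in terms:
            ancestor = ancestor_map.get(term)
            if ancestor is None:
                missing.add(term)
                ancestor = term
            out.add(ancestor)
        grouped[entity] = out
    if missing:
        warnings.warn(
            f"{len(missing)} CC term(s) missing from the ancestor map were kept as-is"
        )
    counts: dict[str, int] = {}
    for terms in grouped.values():
        for term in terms:
            counts[term] = counts.get(term, 0) + 1
    keep = {t for t, c in counts.items() if c >= min_genes}
    return {entity: terms & keep for entity, terms in grouped.items()}


# -- store directory loading -------------------------------------------

def read_publications_table(path) -> list[Publication]:
    """Read `pmid<TAB>interaction_count` rows."""
    pubs = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("pmid"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected pmid<TAB>count")
            count: Optional[int]
            count = None if parts[1] in (MISSING, "") else int(parts[1])
            pubs.append(Publication(pmid=parts[0], interaction_count=count))
    return pubs


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Read GMT-like `term_id<TAB>term_name<TAB>id1<TAB>id2...` rows."""
    terms: dict[str, tuple[str, set[str]]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected term_id, term_name, members")
            members = {p for p in parts[2:] if p}
            if members:
                terms[parts[0]] = (parts[1], members)
    return terms


def read_symbol_map(path) -> dict[str, list[EntityRef]]:
    """Read `symbol<TAB>id<TAB>reviewed(0/1)<TAB>organism` rows."""
    out: dict[str, list[EntityRef]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("symbol\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected symbol, id, reviewed, organism"
                )
            symbol, eid, reviewed, organism = parts[:4]
            out.setdefault(symbol, []).append(
                EntityRef.from_accession(
                    eid, organism=organism, symbol=symbol, reviewed=reviewed == "1"
                )
            )
    return out


def read_ortholog_map(path) -> dict[tuple[str, str], str]:
    """Read `source_id<TAB>source_organism<TAB>target_id<TAB>target_organism`."""
    out: dict[tuple[str, str], str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("source_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 ortholog columns")
            out[(parts[0], parts[1])] = parts[2]
    return out


STORE_FILES = {
    "interactions": "interactions.tsv",
    "publications": "publications.tsv",
    "cc": "cc.gmt",
    "bp": "bp.gmt",
    "kegg": "kegg.gmt",
    "symbols": "symbols.tsv",
    "orthologs": "orthologs.tsv",
}


def load_store_dir(directory) -> tuple[InteractionStore, AnnotationCatalog]:
    """Load a store directory written by the fixture generator / CLI."""
    directory = Path(directory)
    records = read_interaction_table(directory / STORE_FILES["interactions"])
    store = deduplicate(records)
    pubs_path = directory / STORE_FILES["publications"]
    if pubs_path.exists():
        store.add_publications(read_publications_table(pubs_path))
    catalog = AnnotationCatalog()
    cc_path = directory / STORE_FILES["cc"]
    if cc_path.exists():
        for term_id, (_, members) in read_gmt(cc_path).items():
            for member in members:
                catalog.cc_terms.setdefault(member, set()).add(term_id)
    bp_path = directory / STORE_FILES["bp"]
    if bp_path.exists():
        catalog.bp_terms = read_gmt(bp_path)
    kegg_path = directory / STORE_FILES["kegg"]
    if kegg_path.exists():
        catalog.kegg_terms = read_gmt(kegg_path)
    sym_path = directory / STORE_FILES["symbols"]
    if sym_path.exists():
        catalog.symbol_map = read_symbol_map(sym_path)
    ortho_path = directory / STORE_FILES["orthologs"]
    if ortho_path.exists():
        catalog.ortholog_map = read_ortholog_map(ortho_path)
    return store, catalog
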