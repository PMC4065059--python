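"""Seeded synthetic stores, catalogs and query files.

Everything every other module consumes can be generated here with
controllable topology (preferential attachment), evidence composition
and annotation structure, so the test suite needs no downloads.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx

from .store import (
    STORE_FILES,
    AnnotationCatalog,
    InteractionStore,
    deduplicate,
)
from .types import (
    EntityRef,
    EvidenceType,
    InteractionRecord,
    Publication,
    SyntheticStoreSpec,
    canonical_pair,
)

SOURCE_DBS = ["BioGRID", "IntAct", "MINT", "DIP", "HPRD"]
SMALL_MOLECULE_DBS = {"metabolite": "HMDB", "drug": "DrugBank"}
METHODS = ["two hybrid", "pull down", "affinity chromatography", "genetic interference"]

#: fraction of protein edges treated as high-overlap when evidence is
#: coupled to shared-neighbor counts
COUPLING_TOP_FRACTION = 0.15


@dataclass
class SyntheticStore:
    """Bundle returned by :func:`synth_store`."""

    spec: SyntheticStoreSpec
    records: list[InteractionRecord]
    store: InteractionStore
    catalog: AnnotationCatalog
    publications: list[Publication]
    protein_ids: list[str] = field(default_factory=list)
    metabolite_ids: list[str] = field(default_factory=list)
    drug_ids: list[str] = field(default_factory=list)


def _protein_id(i: int) -> str:
    return f"P{i + 1:05d}"


def _poisson(rng: random.Random, lam: float) -> int:
    # Knuth's method; lambdas here are tiny
    import math

    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def synth_store(spec: SyntheticStoreSpec) -> SyntheticStore:
    """Generate a deterministic scale-free interaction store.

    Protein topology is preferential attachment; metabolites and drugs
    attach to random proteins. Evidence type, publication multiplicity
    and co-localization are sampled per ``spec``; with
    ``evidence_fsw_coupling`` near 1, strong multi-paper evidence is
    concentrated on edges with many shared neighbors.
    """
    rng = random.Random(spec.rng_seed)
    proteins = [_protein_id(i) for i in range(spec.n_proteins)]
    m = max(1, min(spec.attachment_m, spec.n_proteins - 1))
    if spec.n_proteins > 1:
        graph = nx.barabasi_albert_graph(spec.n_proteins, m, seed=spec.rng_seed)
    else:
        graph = nx.empty_graph(1)
    protein_edges = [
        canonical_pair(proteins[u], proteins[v]) for u, v in sorted(graph.edges)
    ]

    metabolites = [f"HMDB{i + 1:07d}" for i in range(spec.n_metabolites)]
    drugs = [f"DB{i + 1:05d}" for i in range(spec.n_drugs)]
    small_edges = []
    for mol in metabolites + drugs:
        for partner in rng.sample(proteins, k=min(len(proteins), rng.randint(1, 3))):
            small_edges.append(canonical_pair(mol, partner))
    small_edges = sorted(set(small_edges))

    # publication pool with HT mix
    n_pubs = max(3, int(round(len(protein_edges) * spec.pub_rate / 2)) + 2)
    publications = []
    for i in range(n_pubs):
        if rng.random() < spec.ht_fraction:
            count = rng.randint(501, 3000)
        else:
            count = rng.randint(1, 500)
        publications.append(Publication(pmid=f"PM{i + 1:06d}", interaction_count=count))
    ht_pool = [p for p in publications if p.interaction_count > 500]
    lt_pool = [p for p in publications if p.interaction_count <= 500]

    # rank protein edges by neighborhood overlap (FSW) for evidence coupling
    from . import scoring

    named_graph = nx.relabel_nodes(graph, dict(enumerate(proteins)), copy=True)
    fsw_cfg = scoring.make_fsw_config(named_graph)
    overlap = {
        canonical_pair(u, v): scoring.fsw_score(u, v, named_graph, fsw_cfg)
        for u, v in named_graph.edges
    }
    ranked = sorted(protein_edges, key=lambda e: (-overlap[e], e))
    n_high = max(1, int(COUPLING_TOP_FRACTION * len(ranked)))
    high_overlap = set(ranked[:n_high])

    def sample_pubs(n: int) -> list[Publication]:
        pool = publications
        n = min(n, len(pool))
        return rng.sample(pool, k=n) if n else []

    cc_terms = [f"CC{i + 1:03d}" for i in range(max(1, spec.cc_vocab))]
    catalog = AnnotationCatalog()
    entities = proteins + metabolites + drugs
    for eid in entities:
        n_cc = min(len(cc_terms), 1 + _poisson(rng, 0.5))
        catalog.cc_terms[eid] = set(rng.sample(cc_terms, k=n_cc))

    records: list[InteractionRecord] = []
    organism = spec.organism

    def emit(pair, experimental: bool, pubs: list[Publication], source_pool) -> None:
        a = EntityRef.from_accession(pair[0], organism=organism)
        b = EntityRef.from_accession(pair[1], organism=organism)
        ev = EvidenceType.EXPERIMENTAL if experimental else EvidenceType.PREDICTED
        if not pubs:
            records.append(
                InteractionRecord(
                    a=a, b=b, evidence_type=ev, method=rng.choice(METHODS),
                    pmid=None, source_db=rng.choice(source_pool),
                )
            )
            return
        for pub in pubs:
            records.append(
                InteractionRecord(
                    a=a, b=b, evidence_type=ev, method=rng.choice(METHODS),
                    pmid=pub.pmid, source_db=rng.choice(source_pool),
                )
            )

    for pair in protein_edges:
        coupled = rng.random() < spec.evidence_fsw_coupling
        if coupled:
            if pair in high_overlap:
                # strong evidence: experimental, two papers, one non-HT
                pubs = []
                if lt_pool:
                    pubs.append(rng.choice(lt_pool))
                if ht_pool:
                    pubs.append(rng.choice(ht_pool))
                while len(pubs) < 2 and len(publications) >= 2:
                    extra = rng.choice(publications)
                    if extra not in pubs:
                        pubs.append(extra)
                emit(pair, True, pubs, SOURCE_DBS)
                # co-localize the endpoints for a shot at the top class
                shared = rng.choice(cc_terms)
                catalog.cc_terms[pair[0]].add(shared)
                catalog.cc_terms[pair[1]].add(shared)
            else:
                # weak evidence: at most one paper
                experimental = rng.random() < spec.experimental_fraction
                pubs = sample_pubs(min(1, _poisson(rng, spec.pub_rate)))
                emit(pair, experimental, pubs, SOURCE_DBS)
        else:
            experimental = rng.random() < spec.experimental_fraction
            pubs = sample_pubs(_poisson(rng, spec.pub_rate))
            emit(pair, experimental, pubs, SOURCE_DBS)

    for pair in small_edges:
        kind = "metabolite" if pair[0].startswith("HMDB") or pair[1].startswith("HMDB") else "drug"
        pubs = sample_pubs(_poisson(rng, spec.pub_rate / 2))
        emit(pair, True, pubs, [SMALL_MOLECULE_DBS[kind]])

    # BP / KEGG catalogs over proteins
    def make_terms(prefix: str, vocab: int) -> dict[str, tuple[str, set[str]]]:
        terms: dict[str, tuple[str, set[str]]] = {}
        assignments: dict[str, set[str]] = {p: set() for p in proteins}
        term_ids = [f"{prefix}{i + 1:03d}" for i in range(vocab)]
        for p in proteins:
            k = min(len(term_ids), _poisson(rng, spec.annotation_density))
            for t in rng.sample(term_ids, k=k):
                assignments[p].add(t)
        for t in term_ids:
            members = {p for p, ts in assignments.items() if t in ts}
            if members:
                terms[t] = (f"{prefix.lower()} process {t[-3:]}", members)
        return terms

    catalog.bp_terms = make_terms("BP", spec.bp_vocab)
    catalog.kegg_terms = make_terms("KG", spec.kegg_vocab)

    for i, p in enumerate(proteins):
        symbol = f"SYM{i + 1:04d}"
        catalog.symbol_map[symbol] = [
            EntityRef.from_accession(
                p, organism=organism, symbol=symbol, reviewed=rng.random() < 0.8
            )
        ]
    catalog.ortholog_map = {
        (f"Q{i + 1:05d}", "queryorg"): p for i, p in enumerate(proteins)
    }

    store = deduplicate(records)
    store.add_publications(publications)
    return SyntheticStore(
        spec=spec,
        records=records,
        store=store,
        catalog=catalog,
        publications=publications,
        protein_ids=proteins,
        metabolite_ids=metabolites,
        drug_ids=drugs,
    )


def synth_queries(
    bundle: SyntheticStore,
    n_seeds: int,
    fc_fraction: float = 0.5,
    rng_seed: int = 0,
    n_up: Optional[int] = None,
    n_down: Optional[int] = None,
) -> tuple[list[str], list[tuple[str, float]]]:
    """Sample a seed list and a fold-change table from the store.

    Fold changes follow a three-component mixture: mass at/above the
    +1.3 cutoff, at/below -1.3, and a null band in between. ``n_up`` /
    ``n_down`` pin the regulated counts exactly (the remaining entries
    fall in the null band).
    """
    rng = random.Random(rng_seed)
    proteins = bundle.protein_ids
    if n_seeds > len(proteins):
        raise ValueError(f"n_seeds={n_seeds} exceeds store size {len(proteins)}")
    seeds = sorted(rng.sample(proteins, k=n_seeds))

    entries: list[tuple[str, float]] = []
    pool = list(proteins)
    rng.shuffle(pool)
    if n_up is None and n_down is None:
        n_reg = int(round(fc_fraction * len(pool)))
        n_up = n_reg // 2 + n_reg % 2
        n_down = n_reg // 2
    n_up = n_up or 0
    n_down = n_down or 0
    total = min(len(pool), n_up + n_down + max(0, len(pool) - n_up - n_down))
    for i, p in enumerate(pool[:total]):
        if i < n_up:
            fc = round(1.3 + rng.random() * 2.5, 3)
        elif i < n_up + n_down:
            fc = round(-1.3 - rng.random() * 2.5, 3)
        else:
            fc = round(rng.uniform(-1.29, 1.29), 3)
        entries.append((p, fc))
    entries.sort()
    return seeds, entries


# -- file emission --------------------------------------------------------

def write_store_dir(bundle: SyntheticStore, directory) -> Path:
    """Write every fixture file in the store's native text formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with (directory / STORE_FILES["interactions"]).open("w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\torganism_a\torganism_b\tevidence\tmethod\tpmid\tsource_db\n")
        for rec in bundle.records:
            fh.write(
                f"{rec.a.id}\t{rec.b.id}\t{rec.a.organism or '.'}\t"
                f"{rec.b.organism or '.'}\t{rec.evidence_type.value}\t"
                f"{rec.method or '.'}\t{rec.pmid or '.'}\t{rec.source_db or '.'}\n"
            )

    with (directory / STORE_FILES["publications"]).open("w", encoding="utf-8") as fh:
        fh.write("pmid\tinteraction_count\n")
        for pub in bundle.publications:
            count = "." if pub.interaction_count is None else pub.interaction_count
            fh.write(f"{pub.pmid}\t{count}\n")

    cc_members: dict[str, set[str]] = {}
    for eid, terms in bundle.catalog.cc_terms.items():
        for t in terms:
            cc_members.setdefault(t, set()).add(eid)
    with (directory / STORE_FILES["cc"]).open("w", encoding="utf-8") as fh:
        for t in sorted(cc_members):
            members = "\t".join(sorted(cc_members[t]))
            fh.write(f"{t}\tcompartment {t[-3:]}\t{members}\n")

    for key, terms in (("bp", bundle.catalog.bp_terms), ("kegg", bundle.catalog.kegg_terms)):
        with (directory / STORE_FILES[key]).open("w", encoding="utf-8") as fh:
            for t in sorted(terms):
                name, members = terms[t]
                fh.write(f"{t}\t{name}\t" + "\t".join(sorted(members)) + "\n")

    with (directory / STORE_FILES["symbols"]).open("w", encoding="utf-8") as fh:
        fh.write("symbol\tid\treviewed\torganism\n")
        for symbol in sorted(bundle.catalog.symbol_map):
            for ref in bundle.catalog.symbol_map[symbol]:
                fh.write(
                    f"{symbol}\t{ref.id}\t{1 if ref.reviewed else 0}\t{ref.organism}\n"
                )

    with (directory / STORE_FILES["orthologs"]).open("w", encoding="utf-8") as fh:
        fh.write("source_id\tsource_organism\ttarget_id\ttarget_organism\n")
        for (src, src_org) in sorted(bundle.catalog.ortholog_map):
            tgt = bundle.catalog.ortholog_map[(src, src_org)]
            fh.write(f"{src}\t{src_org}\t{tgt}\t{bundle.spec.organism}\n")

    return directory


def write_seed_list(seeds: list[str], path) -> None:
    Path(path).write_text("\n".join(seeds) + "\n", encoding="utf-8")


def write_foldchange_table(entries: list[tuple[str, float]], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for token, fc in entries:
            fh.write(f"{token}\t{fc}\n")
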