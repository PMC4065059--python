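import pytest

from ixnet.fixtures import SyntheticStore, synth_store
from ixnet.store import deduplicate
from ixnet.types import (
    EntityRef,
    EvidenceType,
    InteractionRecord,
    Publication,
    SyntheticStoreSpec,
)


def make_record(
    id_a: str,
    id_b: str,
    evidence: str = "experimental",
    method: str = "two hybrid",
    pmid: str | None = None,
    source_db: str = "BioGRID",
    organism: str = "org",
) -> InteractionRecord:
    return InteractionRecord(
        a=EntityRef.from_accession(id_a, organism=organism),
        b=EntityRef.from_accession(id_b, organism=organism),
        evidence_type=EvidenceType(evidence),
        method=method,
        pmid=pmid,
        source_db=source_db,
    )


def make_store(edges, organism: str = "org", publications=None):
    """Store from (id_a, id_b[, pmid]) tuples; all experimental."""
    records = []
    for edge in edges:
        pmid = edge[2] if len(edge) > 2 else None
        records.append(make_record(edge[0], edge[1], pmid=pmid, organism=organism))
    store = deduplicate(records)
    if publications:
        store.add_publications(
            Publication(pmid=p, interaction_count=c) for p, c in publications
        )
    return store


@pytest.fixture(scope="session")
def bundle() -> SyntheticStore:
    return synth_store(SyntheticStoreSpec(n_proteins=80, n_metabolites=6, n_drugs=4,
                                          rng_seed=7))


@pytest.fixture(scope="session")
def coupled_bundle() -> SyntheticStore:
    return synth_store(
        SyntheticStoreSpec(
            n_proteins=120,
            n_metabolites=0,
            n_drugs=0,
            evidence_fsw_coupling=0.9,
            experimental_fraction=0.5,
            pub_rate=0.8,
            rng_seed=11,
        )
    )
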