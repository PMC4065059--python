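"""Core domain types shared across the package.

Entities are proteins, metabolites or drugs identified by accession
strings; interactions are evidence-bearing undirected pairs; the store
aggregates evidence rows under canonical pair keys.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

EMPTY_PMID = ""  # sentinel for unpublished evidence rows


class EntityKind(str, Enum):
    PROTEIN = "protein"
    METABOLITE = "metabolite"
    DRUG = "drug"


class EvidenceType(str, Enum):
    EXPERIMENTAL = "experimental"
    PREDICTED = "predicted"


_METABOLITE_RE = re.compile(r"^(HMDB|YMDB|ECMDB)", re.IGNORECASE)
_DRUG_RE = re.compile(r"^DB\d+$", re.IGNORECASE)


def infer_entity_kind(accession: str) -> EntityKind:
    """Classify an accession by its namespace prefix.

    HMDB/YMDB/ECMDB ids are metabolites, DrugBank ``DB``+digits ids are
    drugs, everything else is treated as a protein accession.
    """
    if _METABOLITE_RE.match(accession):
        return EntityKind.METABOLITE
    if _DRUG_RE.match(accession):
        return EntityKind.DRUG
    return EntityKind.PROTEIN


@dataclass(frozen=True)
class EntityRef:
    """A protein, metabolite or drug reference.

    ``(id, organism)`` is the store-level identity; ``symbol`` and
    ``reviewed`` (Swiss-Prot-reviewed vs unreviewed) are optional
    annotation fields.
    """

    id: str
    entity_kind: EntityKind
    organism: str = ""
    symbol: Optional[str] = None
    reviewed: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("EntityRef.id must be non-empty")

    @classmethod
    def from_accession(
        cls,
        accession: str,
        organism: str = "",
        symbol: Optional[str] = None,
        reviewed: Optional[bool] = None,
    ) -> "EntityRef":
        return cls(
            id=accession,
            entity_kind=infer_entity_kind(accession),
            organism=organism,
            symbol=symbol,
            reviewed=reviewed,
        )


@dataclass(frozen=True)
class Publication:
    """A PubMed record with the number of interactions it describes.

    ``interaction_count`` of ``None`` means the count is unknown; such
    papers are conservatively treated as high-throughput.
    """

    pmid: str
    interaction_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.interaction_count is not None and self.interaction_count < 0:
            raise ValueError("interaction_count must be >= 0")


@dataclass(frozen=True)
class InteractionRecord:
    """One evidence-bearing edge between two entities."""

    a: EntityRef
    b: EntityRef
    evidence_type: EvidenceType
    method: str = ""
    pmid: Optional[str] = None
    source_db: str = ""


@dataclass(frozen=True, order=True)
class PairKey:
    """Canonical (order-insensitive) identity of one evidence row.

    ``first <= second`` lexicographically; rows without a publication
    carry the empty-pmid sentinel so unpublished duplicates still
    collapse.
    """

    first: str
    second: str
    pmid: str = EMPTY_PMID

    @property
    def pair(self) -> tuple[str, str]:
        return (self.first, self.second)


def canonical_pair(id_a: str, id_b: str) -> tuple[str, str]:
    """Order a pair of accessions lexicographically."""
    return (id_a, id_b) if id_a <= id_b else (id_b, id_a)


def canonical_pair_key(rec: InteractionRecord) -> PairKey:
    """Canonical pair key of a record: ordered ids plus pmid (or sentinel)."""
    first, second = canonical_pair(rec.a.id, rec.b.id)
    return PairKey(first=first, second=second, pmid=rec.pmid or EMPTY_PMID)


@dataclass
class EvidenceProfile:
    """Aggregated evidence for a unique pair; input to the class score."""

    experimental: bool
    publications: frozenset[Publication] = frozenset()
    same_cc: bool = False


@dataclass(frozen=True)
class ClassScore:
    """Additive confidence total with its class label and edge width."""

    total: int
    class_label: str  # one of "A".."E" or "unclassified"
    edge_width: float


@dataclass
class EnrichmentCounts:
    """Hypergeometric quadruple: k of n drawn vs K of N in the background."""

    k: int
    n: int
    K: int
    N: int

    def validate(self) -> None:
        if not 0 <= self.k:
            raise ValueError("k must satisfy 0 <= k")
        if self.k > self.K:
            raise ValueError("k must satisfy k <= K")
        if self.k > self.n:
            raise ValueError("k must satisfy k <= n")
        if self.n > self.N:
            raise ValueError("n must satisfy n <= N")
        if self.K > self.N:
            raise ValueError("K must satisfy K <= N")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    counts: EnrichmentCounts
    p_value: float
    mode_used: str  # "exact" | "log_gamma"
    members: frozenset[str] = frozenset()
    enriched: bool = False


@dataclass
class NodeSignificanceInputs:
    """Counts feeding one node's binomial-proportion z-score.

    ``k_i``/``n`` are the node's unique-pair interactions and the total
    pairs inside the subnetwork; ``K_i``/``N`` the same counts in the
    organism-filtered store.
    """

    node_id: str
    k_i: int
    n: int
    K_i: int
    N: int


@dataclass
class FswConfig:
    """Neighborhood-overlap scoring options.

    ``n_avg`` is the average neighborhood size of the scored graph and is
    computed, not user-set; ``lambda_mode='none'`` disables the
    pseudo-count for ablation.
    """

    include_self: bool = True
    lambda_mode: str = "chua_pseudocount"  # or "none"
    n_avg: float = 0.0


@dataclass
class BuildConfig:
    """Parameters of seed expansion and the ordered filter pipeline."""

    depth: int = 1
    include_metabolites: bool = False
    include_drugs: bool = False
    delete_degree_01: bool = False
    class_cutoff: Optional[str] = None  # minimal acceptable class label
    fsw_cutoff: Optional[float] = None
    pvalue_cutoff: Optional[float] = None
    background_organism: str = ""
    bait: Optional[str] = None
    iterate_degree_prune: bool = False  # iterated 2-core variant, off by default
    protect_seeds: bool = False
    recompute_fsw_post_filter: bool = False

    def __post_init__(self) -> None:
        if self.depth not in (1, 2, 3):
            raise ValueError("depth must be 1, 2 or 3")
        for name in ("fsw_cutoff", "pvalue_cutoff"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ExpressionConfig:
    """Fold-change cutoffs (closed boundaries) and node-size scaling."""

    up_cutoff: float = 1.3
    down_cutoff: float = -1.3
    size_scaling: str = "proportional_abs_fc"  # or "fixed"

    def __post_init__(self) -> None:
        if not (self.up_cutoff > 0 > self.down_cutoff):
            raise ValueError("need up_cutoff > 0 > down_cutoff")


@dataclass
class SyntheticStoreSpec:
    """Parameters of the synthetic store/catalog generator."""

    n_proteins: int = 100
    n_metabolites: int = 10
    n_drugs: int = 5
    attachment_m: int = 2
    experimental_fraction: float = 0.7
    pub_rate: float = 1.2
    ht_fraction: float = 0.3
    cc_vocab: int = 8
    bp_vocab: int = 20
    kegg_vocab: int = 12
    annotation_density: float = 2.0
    evidence_fsw_coupling: float = 0.0
    organism: str = "synthia"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        for name in ("n_metabolites", "n_drugs", "attachment_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.experimental_fraction <= 1.0:
            raise ValueError("experimental_fraction must be in [0, 1]")
        if not 0.0 <= self.evidence_fsw_coupling <= 1.0:
            raise ValueError("evidence_fsw_coupling must be in [0, 1]")
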