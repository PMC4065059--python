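import random
import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ixnet.store import (
    FormatError,
    AnnotationCatalog,
    deduplicate,
    map_orthologs,
    read_interaction_table,
    resolve_identifiers,
    select_cc_terms,
)
from ixnet.types import (
    EMPTY_PMID,
    EntityKind,
    EntityRef,
    PairKey,
    canonical_pair_key,
    infer_entity_kind,
)

from conftest import make_record, make_store


class TestEntityKind:
    @pytest.mark.parametrize(
        "accession,kind",
        [
            ("P12345", EntityKind.PROTEIN),
            ("Q9Z999", EntityKind.PROTEIN),
            ("HMDB0000122", EntityKind.METABOLITE),
            ("YMDB00042", EntityKind.METABOLITE),
            ("ECMDB00012", EntityKind.METABOLITE),
            ("DB00316", EntityKind.DRUG),
            ("DBP1", EntityKind.PROTEIN),  # DB not followed by digits only
        ],
    )
    def test_namespace_inference(self, accession, kind):
        assert infer_entity_kind(accession) is kind

    def test_empty_id_rejected(self):
        with pytest.raises(ValueError):
            EntityRef.from_accession("")


class TestReadInteractionTable:
    def test_native_two_rows(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "id_a\tid_b\torganism_a\torganism_b\tevidence\tmethod\tpmid\tsource_db\n"
            "P1\tP2\torg\torg\texperimental\ttwo hybrid\t123\tBioGRID\n"
            "P1\tHMDB0000122\torg\torg\tpredicted\t.\t.\tHMDB\n"
        )
        records = read_interaction_table(path)
        assert len(records) == 2
        assert records[0].a.id == "P1"
        assert records[0].pmid == "123"
        assert records[1].evidence_type.value == "predicted"
        assert records[1].pmid is None
        assert records[1].b.entity_kind is EntityKind.METABOLITE

    def test_invalid_evidence_names_row(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "id_a\tid_b\torganism_a\torganism_b\tevidence\tmethod\tpmid\tsource_db\n"
            "P1\tP2\torg\torg\texp?\t.\t.\tX\n"
        )
        with pytest.raises(FormatError, match=":2"):
            read_interaction_table(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("id_a\tid_b\torganism_a\torganism_b\tmethod\tpmid\tsource_db\n")
        with pytest.raises(FormatError, match="evidence"):
            read_interaction_table(path)

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("")
        with pytest.warns(UserWarning):
            assert read_interaction_table(path) == []

    def test_psimitab_line_matches_hand_parse(self, tmp_path):
        # hand-parsed reference: ids P12345/Q67890, method "two hybrid",
        # pmid 11111, taxid 9606 both sides, source IntAct
        line = "\t".join(
            [
                "uniprotkb:P12345",
                "uniprotkb:Q67890",
                "-", "-", "-", "-",
                'psi-mi:"MI:0018"(two hybrid)',
                "-",
                "pubmed:11111",
                "taxid:9606(Homo sapiens)",
                "taxid:9606(Homo sapiens)",
                "-",
                'psi-mi:"MI:0469"(IntAct)',
                "-", "-",
            ]
        )
        path = tmp_path / "t.mitab"
        path.write_text(line + "\n")
        (rec,) = read_interaction_table(path, dialect="psimitab25")
        assert rec.a.id == "P12345"
        assert rec.b.id == "Q67890"
        assert rec.method == "two hybrid"
        assert rec.pmid == "11111"
        assert rec.a.organism == "9606"
        assert rec.b.organism == "9606"
        assert rec.source_db == "IntAct"
        assert rec.evidence_type.value == "experimental"


class TestPairKey:
    def test_symmetry(self):
        k1 = canonical_pair_key(make_record("Q9Z999", "A0A001", pmid="123"))
        k2 = canonical_pair_key(make_record("A0A001", "Q9Z999", pmid="123"))
        assert k1 == k2 == PairKey("A0A001", "Q9Z999", "123")

    def test_empty_pmid_sentinel_distinct(self):
        k_no = canonical_pair_key(make_record("P1", "P2"))
        k_yes = canonical_pair_key(make_record("P1", "P2", pmid="5"))
        assert k_no.pmid == EMPTY_PMID
        assert k_no != k_yes

    def test_four_records_two_keys(self):
        # derived by hand: two symmetric duplicates -> 2 distinct keys
        records = [
            make_record("P1", "P2", pmid="1"),
            make_record("P2", "P1", pmid="1"),
            make_record("P3", "P4", pmid="2"),
            make_record("P4", "P3", pmid="2"),
        ]
        keys = {canonical_pair_key(r) for r in records}
        assert keys == {PairKey("P1", "P2", "1"), PairKey("P3", "P4", "2")}


class TestDeduplicate:
    def test_sources_merged_on_same_pair_pmid(self):
        records = [
            make_record("P1", "P2", pmid="9", source_db="BioGRID"),
            make_record("P2", "P1", pmid="9", source_db="IntAct"),
        ]
        store = deduplicate(records)
        assert len(store.evidence) == 1
        assert store.pairs[("P1", "P2")].sources == {"BioGRID", "IntAct"}

    def test_pmids_accumulate_at_pair_level(self):
        # hand count: 2 evidence keys collapse into 1 unique pair with 2 pmids
        records = [make_record("P1", "P2", pmid="1"), make_record("P1", "P2", pmid="2")]
        store = deduplicate(records)
        assert len(store.evidence) == 2
        assert len(store.pairs) == 1
        assert store.pairs[("P1", "P2")].pmids == {"1", "2"}

    def test_idempotence(self):
        records = [
            make_record("P1", "P2", pmid="1"),
            make_record("P2", "P1", pmid="1"),
            make_record("P1", "P3"),
        ]
        once = deduplicate(records)
        again = deduplicate(list(once.evidence.values()))
        assert set(once.evidence) == set(again.evidence)
        assert set(once.pairs) == set(again.pairs)

    @given(st.permutations(list(range(6))), st.data())
    @settings(max_examples=25, deadline=None)
    def test_order_insensitive(self, perm, data):
        ids = ["P1", "P2", "P3", "P4"]
        base = [
            make_record(
                data.draw(st.sampled_from(ids), label=f"a{i}"),
                data.draw(st.sampled_from(ids), label=f"b{i}"),
                pmid=data.draw(st.sampled_from([None, "1", "2"]), label=f"p{i}"),
            )
            for i in range(6)
        ]
        shuffled = [base[i] for i in perm]
        s1, s2 = deduplicate(base), deduplicate(shuffled)
        assert set(s1.evidence) == set(s2.evidence)
        assert {
            k: (v.experimental, frozenset(v.pmids), frozenset(v.sources))
            for k, v in s1.pairs.items()
        } == {
            k: (v.experimental, frozenset(v.pmids), frozenset(v.sources))
            for k, v in s2.pairs.items()
        }

    def test_unique_pairs_bounded_by_records(self, bundle):
        assert len(bundle.store.pairs) <= len(bundle.records)


class TestResolveIdentifiers:
    @pytest.fixture()
    def catalog(self):
        cat = AnnotationCatalog()
        cat.symbol_map = {
            "GSY1": [
                EntityRef.from_accession("P1", organism="org", symbol="GSY1", reviewed=True),
                EntityRef.from_accession("T1", organism="org", symbol="GSY1", reviewed=False),
            ],
            "RAW2": [
                EntityRef.from_accession("T2", organism="org", symbol="RAW2", reviewed=False)
            ],
            "AMB3": [
                EntityRef.from_accession("P3", organism="org", symbol="AMB3", reviewed=True),
                EntityRef.from_accession("P4", organism="org", symbol="AMB3", reviewed=True),
            ],
        }
        return cat

    def test_reviewed_preferred(self, catalog):
        report = resolve_identifiers(["GSY1"], catalog, "org")
        assert report.resolved["GSY1"].id == "P1"

    def test_unreviewed_fallback(self, catalog):
        report = resolve_identifiers(["RAW2"], catalog, "org")
        assert report.resolved["RAW2"].id == "T2"
        assert report.resolved["RAW2"].reviewed is False

    def test_unknown_token_unresolved(self, catalog):
        report = resolve_identifiers(["XYZ_NOT_A_GENE"], catalog, "org")
        assert report.unresolved == ["XYZ_NOT_A_GENE"]

    def test_same_tier_ambiguity_reported(self, catalog):
        report = resolve_identifiers(["AMB3"], catalog, "org")
        assert {c.id for c in report.ambiguous["AMB3"]} == {"P3", "P4"}

    def test_accession_matches_store_directly(self, catalog):
        store = make_store([("P9", "P8")])
        report = resolve_identifiers(["P9"], catalog, "org", store=store)
        assert report.resolved["P9"].id == "P9"

    @given(st.lists(st.sampled_from(["GSY1", "RAW2", "AMB3", "NOPE", "P7"]), max_size=8))
    @settings(max_examples=30, deadline=None)
    def test_partition_property(self, tokens):
        cat = AnnotationCatalog()
        cat.symbol_map = {
            "GSY1": [EntityRef.from_accession("P1", organism="org", reviewed=True)],
            "AMB3": [
                EntityRef.from_accession("P3", organism="org", reviewed=True),
                EntityRef.from_accession("P4", organism="org", reviewed=True),
            ],
            "RAW2": [EntityRef.from_accession("T2", organism="org", reviewed=False)],
        }
        report = resolve_identifiers(list(dict.fromkeys(tokens)), cat, "org")
        assert len(report) == len(set(tokens))


class TestMapOrthologs:
    def test_identity_when_target_is_source(self):
        cat = AnnotationCatalog()
        cat.ortholog_map = {("X", "other"): "Y"}
        ents = [EntityRef.from_accession("P1", organism="org")]
        mapped, unmapped, _ = map_orthologs(ents, cat, "org")
        assert [e.id for e in mapped] == ["P1"] and not unmapped

    def test_partial_mapping(self):
        cat = AnnotationCatalog()
        cat.ortholog_map = {("A", "src"): "P1", ("B", "src"): "P2"}
        ents = [EntityRef.from_accession(x, organism="src") for x in ("A", "B", "C")]
        mapped, unmapped, _ = map_orthologs(ents, cat, "org")
        assert {e.id for e in mapped} == {"P1", "P2"}
        assert [e.id for e in unmapped] == ["C"]

    def test_many_to_one_collapses_with_multiplicity(self):
        # hand-applied table: A->P1, B->P1, C->P2
        cat = AnnotationCatalog()
        cat.ortholog_map = {("A", "src"): "P1", ("B", "src"): "P1", ("C", "src"): "P2"}
        ents = [EntityRef.from_accession(x, organism="src") for x in ("A", "B", "C")]
        mapped, unmapped, mult = map_orthologs(ents, cat, "org")
        assert sorted(e.id for e in mapped) == ["P1", "P2"]
        assert mult == {"P1": 2, "P2": 1}

    def test_empty_map_is_configuration_error(self):
        with pytest.raises(ValueError, match="ortholog_map"):
            map_orthologs([EntityRef.from_accession("A", organism="s")],
                          AnnotationCatalog(), "org")


class TestSelectCcTerms:
    def test_ancestor_grouping_retained_at_threshold(self):
        raw = {f"E{i}": {f"child{i % 3}"} for i in range(12)}
        ancestors = {f"child{j}": "nucleus" for j in range(3)}
        out = select_cc_terms(raw, ancestors, min_genes=10)
        assert all(out[e] == {"nucleus"} for e in raw)

    def test_small_ancestor_dropped_everywhere(self):
        raw = {f"E{i}": {"c"} for i in range(9)}
        out = select_cc_terms(raw, {"c": "tiny"}, min_genes=10)
        assert all(terms == set() for terms in out.values())

    def test_min_genes_one_drops_nothing(self):
        raw = {"E1": {"a"}, "E2": {"b"}}
        out = select_cc_terms(raw, {"a": "A", "b": "B"}, min_genes=1)
        assert out == {"E1": {"A"}, "E2": {"B"}}

    def test_unknown_child_kept_with_warning(self):
        raw = {f"E{i}": {"orphan"} for i in range(10)}
        with pytest.warns(UserWarning, match="ancestor map"):
            out = select_cc_terms(raw, {}, min_genes=10)
        assert out["E0"] == {"orphan"}

    @given(st.integers(min_value=1, max_value=6), st.integers(min_value=0, max_value=99))
    @settings(max_examples=25, deadline=None)
    def test_no_surviving_term_below_threshold(self, min_genes, seed):
        rng = random.Random(seed)
        raw = {
            f"E{i}": {f"c{rng.randint(0, 4)}" for _ in range(rng.randint(1, 3))}
            for i in range(rng.randint(1, 15))
        }
        ancestors = {f"c{j}": f"anc{j % 2}" for j in range(5)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = select_cc_terms(raw, ancestors, min_genes=min_genes)
        counts: dict[str, int] = {}
        for terms in out.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        assert all(c >= min_genes for c in counts.values())


class TestNeighbors:
    def test_kind_flags(self):
        store = make_store([("P1", "P2"), ("P1", "HMDB0000001"), ("P1", "DB00001")])
        assert store.neighbors("P1") == {"P2"}
        assert store.neighbors("P1", include_metabolites=True) == {"P2", "HMDB0000001"}
        assert store.neighbors("P1", include_metabolites=True, include_drugs=True) == {
            "P2", "HMDB0000001", "DB00001",
        }

    def test_absent_entity_empty(self):
        assert make_store([("P1", "P2")]).neighbors("ZZ") == set()

    def test_duplicate_evidence_counts_once(self):
        # hand-listed unique partners: {P2}
        store = make_store([("P1", "P2", "1"), ("P1", "P2", "2"), ("P2", "P1", "3")])
        assert store.neighbors("P1") == {"P2"}

    def test_self_interaction_excluded(self):
        store = make_store([("P1", "P1"), ("P1", "P2")])
        assert store.neighbors("P1") == {"P2"}
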