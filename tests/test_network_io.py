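import warnings

import pytest

import fruitwalk as fw
from fruitwalk.network_io import normalize_gene_id


# ---------------------------------------------------------------------------
# WeightedNetwork container
# ---------------------------------------------------------------------------

def test_network_rejects_out_of_range_scores():
    with pytest.raises(ValueError, match="outside"):
        fw.WeightedNetwork({("a", "b"): 149})
    with pytest.raises(ValueError, match="outside"):
        fw.WeightedNetwork({("a", "b"): 1000})


def test_network_rejects_self_edges():
    with pytest.raises(ValueError, match="self-edge"):
        fw.WeightedNetwork({("a", "a"): 500})


def test_from_edge_list_collapses_symmetric_duplicates_keeping_max():
    net = fw.WeightedNetwork.from_edge_list(
        [("a", "b", 900), ("b", "a", 700), ("a", "a", 400), ("b", "c", 200)]
    )
    assert net.n_edges == 2
    assert net.score("a", "b") == 900  # max of the conflicting pair
    assert net.score("b", "a") == 900
    assert net.score("a", "c") is None


# ---------------------------------------------------------------------------
# STRING links parsing
# ---------------------------------------------------------------------------

def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


def test_parse_string_links_toy_dedup(tmp_path):
    path = _write(
        tmp_path,
        "links.txt",
        "protein1 protein2 combined_score\n"
        "3702.A 3702.B 900\n"
        "3702.B 3702.A 900\n"
        "3702.A 3702.C 300\n"
        "3702.C 3702.A 300\n",
    )
    net = fw.parse_string_links(path, organism_code="3702")
    assert net.n_nodes == 3
    assert net.n_edges == 2
    assert net.score("3702.A", "3702.B") == 900


def test_parse_string_links_filters_other_organisms(tmp_path):
    path = _write(
        tmp_path,
        "links.txt",
        "3702.A 3702.B 900\n9606.X 9606.Y 500\n3702.A 9606.Y 700\n",
    )
    net = fw.parse_string_links(path, organism_code="3702")
    assert net.n_nodes == 2
    assert net.n_edges == 1


def test_parse_string_links_empty_after_filter(tmp_path):
    path = _write(tmp_path, "links.txt", "9606.X 9606.Y 500\n")
    with pytest.raises(ValueError, match="empty network after organism filter"):
        fw.parse_string_links(path, organism_code="3702")


def test_parse_string_links_malformed_line_names_line_number(tmp_path):
    path = _write(tmp_path, "links.txt", "a b 500\na b c d\n")
    with pytest.raises(ValueError, match="line 2"):
        fw.parse_string_links(path)
    path2 = _write(tmp_path, "links2.txt", "a b 500\nc d xyz\n")
    with pytest.raises(ValueError, match="line 2.*non-integer"):
        fw.parse_string_links(path2)


def test_parse_string_links_gzip_transparent(tmp_path):
    import gzip

    path = tmp_path / "links.txt.gz"
    with gzip.open(path, "wt") as fh:
        fh.write("a b 400\nb c 500\n")
    net = fw.parse_string_links(path)
    assert net.n_edges == 2


def test_parse_string_links_idempotent_on_reserialization(tmp_path):
    net = fw.WeightedNetwork.from_edge_list(
        [("G0", "G1", 900), ("G1", "G2", 333), ("G0", "G3", 151)]
    )
    out = tmp_path / "roundtrip.txt"
    fw.write_string_links(net, out, organism_code="3702")
    reparsed = fw.parse_string_links(out, organism_code="3702")
    original = {
        (f"3702.{a}.1", f"3702.{b}.1"): s for a, b, s in net.edges()
    }
    assert {(a, b): s for a, b, s in reparsed.edges()} == original


# ---------------------------------------------------------------------------
# OBO parsing and term closure
# ---------------------------------------------------------------------------

CHAIN_OBO = """format-version: 1.2
ontology: test

[Term]
id: T:1
name: level1

[Term]
id: T:2
name: level2
is_a: T:1

[Term]
id: T:3
name: level3
is_a: T:2

[Term]
id: T:4
name: level4
relationship: part_of T:3

[Term]
id: T:5
name: level5
is_a: T:4

[Term]
id: T:9
name: obsolete term
is_obsolete: true
"""


@pytest.fixture
def chain_ontology(tmp_path):
    path = tmp_path / "chain.obo"
    path.write_text(CHAIN_OBO)
    return fw.parse_obo(path)


def test_parse_obo_chain(chain_ontology):
    assert set(chain_ontology.terms) == {"T:1", "T:2", "T:3", "T:4", "T:5"}
    n_links = sum(len(p) for p in chain_ontology.parents.values())
    assert n_links == 4
    assert chain_ontology.parents["T:4"] == frozenset({"T:3"})  # part_of


def test_parse_obo_excludes_obsolete(chain_ontology):
    assert "T:9" not in chain_ontology.terms


def test_parse_obo_minimal_two_terms(tmp_path):
    path = tmp_path / "mini.obo"
    path.write_text(
        "format-version: 1.2\nontology: t\n\n[Term]\nid: A:1\nname: parent\n"
        "\n[Term]\nid: A:2\nname: child\nis_a: A:1\n"
    )
    onto = fw.parse_obo(path)
    assert len(onto.terms) == 2
    assert onto.parents["A:2"] == frozenset({"A:1"})


def test_parse_obo_missing_id_errors(tmp_path):
    path = tmp_path / "bad.obo"
    path.write_text("format-version: 1.2\nontology: t\n\n[Term]\nname: orphan\n")
    with pytest.raises(ValueError, match="stanza"):
        fw.parse_obo(path)


def test_parse_obo_dangling_parent_warns_and_drops(tmp_path):
    path = tmp_path / "dangling.obo"
    path.write_text(
        "format-version: 1.2\nontology: t\n\n[Term]\nid: A:1\nname: child\n"
        "is_a: A:999\n"
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        onto = fw.parse_obo(path)
    assert any("undefined" in str(w.message) for w in caught)
    assert onto.parents["A:1"] == frozenset()


def test_term_closure_full_chain(chain_ontology):
    # brute-force expectation: every term sits below T:1
    assert fw.term_closure(chain_ontology, "T:1") == {
        "T:1", "T:2", "T:3", "T:4", "T:5"
    }


def test_term_closure_leaf_is_singleton(chain_ontology):
    assert fw.term_closure(chain_ontology, "T:5") == {"T:5"}


def test_term_closure_nested_along_chain(chain_ontology):
    # closure of a child is a subset of the closure of its parent
    for child, parent in [("T:2", "T:1"), ("T:3", "T:2"), ("T:4", "T:3")]:
        assert fw.term_closure(chain_ontology, child) <= fw.term_closure(
            chain_ontology, parent
        )
        assert child in fw.term_closure(chain_ontology, child)


def test_term_closure_unknown_root(chain_ontology):
    with pytest.raises(ValueError, match="unknown"):
        fw.term_closure(chain_ontology, "T:404")


# ---------------------------------------------------------------------------
# Seeds from annotations
# ---------------------------------------------------------------------------

def test_seeds_from_annotations_hand_case():
    catalog = fw.AnnotationCatalog(
        {
            "g1": frozenset({"T1"}),
            "g2": frozenset({"T2"}),
            "g3": frozenset({"T1", "T3"}),
        }
    )
    seeds = fw.seeds_from_annotations(catalog, {"T1"})
    assert seeds.genes == ("g1", "g3")


def test_seeds_from_annotations_disjoint_terms_error():
    catalog = fw.AnnotationCatalog({"g1": frozenset({"T1"})})
    with pytest.raises(ValueError, match="no seed genes"):
        fw.seeds_from_annotations(catalog, {"T9"})


def test_seed_set_rejects_duplicates_and_empty():
    with pytest.raises(ValueError):
        fw.SeedSet(("a", "a"))
    with pytest.raises(ValueError):
        fw.SeedSet(())


# ---------------------------------------------------------------------------
# Seed mapping onto protein nodes
# ---------------------------------------------------------------------------

def test_normalize_gene_id_strips_prefix_and_suffix():
    assert normalize_gene_id("3702.AT1G01010.1") == "AT1G01010"
    assert normalize_gene_id("AT1G01010") == "AT1G01010"
    assert normalize_gene_id("3702.AT1G01010.1", strip_organism_prefix=False) == (
        "3702.AT1G01010"
    )


def test_map_seeds_normalization(two_node_network):
    net = fw.WeightedNetwork({("3702.AT1G01010.1", "3702.AT2G02020.1"): 800})
    seeds = fw.SeedSet(("AT1G01010",))
    mapped, report = fw.map_seeds_to_network(seeds, net)
    assert report.n_mapped == 1 and report.n_unmapped == 0
    assert mapped.node_groups["AT1G01010"] == ("3702.AT1G01010.1",)


def test_map_seeds_multi_isoform():
    net = fw.WeightedNetwork(
        {("3702.AT1.1", "3702.AT1.2"): 500, ("3702.AT1.1", "3702.AT9.1"): 400}
    )
    mapped, report = fw.map_seeds_to_network(fw.SeedSet(("AT1",)), net)
    assert mapped.node_groups["AT1"] == ("3702.AT1.1", "3702.AT1.2")
    assert "AT1" in report.multi_isoform


def test_map_seeds_identity_when_already_node_ids(two_node_network):
    mapped, report = fw.map_seeds_to_network(
        fw.SeedSet(("a",)), two_node_network
    )
    assert mapped.node_ids == ("a",)
    assert report.n_unmapped == 0


def test_map_seeds_zero_mapped_error(two_node_network):
    with pytest.raises(ValueError, match="zero seed genes mapped"):
        fw.map_seeds_to_network(fw.SeedSet(("XYZ",)), two_node_network)


# ---------------------------------------------------------------------------
# Flat tables
# ---------------------------------------------------------------------------

def test_load_gene_list_with_comments(tmp_path):
    path = tmp_path / "genes.txt"
    path.write_text("# header\nAT1G01010\nAT2G02020  # inline\n\nAT1G01010\n")
    assert fw.load_gene_list(path) == ("AT1G01010", "AT2G02020")


def test_load_annotation_table(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text("g1\tGO:1\ng1\tGO:2\ng2\tKEGG:9\n")
    catalog = fw.load_annotation_table(path)
    assert catalog.terms_of("g1") == frozenset({"GO:1", "GO:2"})
    assert catalog.term_universe() == ("GO:1", "GO:2", "KEGG:9")


def test_load_annotation_table_malformed(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("g1\tGO:1\tEXTRA\n")
    with pytest.raises(ValueError, match="line 1"):
        fw.load_annotation_table(path)
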