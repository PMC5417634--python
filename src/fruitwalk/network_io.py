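"""Input readers and core graph containers.

This module owns the standard input dialects of the pipeline: STRING-style
weighted protein links, OBO ontologies (via :mod:`obonet`), one-identifier-
per-line gene lists and two-column gene→term annotation tables.  It also
holds the :class:`WeightedNetwork` container used by every downstream stage
and the seed-set plumbing (ontology term closure, annotation lookup, and
gene→protein-node mapping).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import obonet
import scipy.sparse as sp

SCORE_MIN = 150
SCORE_MAX = 999

__all__ = [
    "SCORE_MIN",
    "SCORE_MAX",
    "WeightedNetwork",
    "SeedSet",
    "OntologyGraph",
    "AnnotationCatalog",
    "MappingReport",
    "parse_string_links",
    "parse_obo",
    "term_closure",
    "seeds_from_annotations",
    "map_seeds_to_network",
    "load_gene_list",
    "load_annotation_table",
    "normalize_gene_id",
]


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class WeightedNetwork:
    """Undirected interaction network with integer confidence scores.

    Edge scores follow the STRING combined-score convention: integers in
    [150, 999].  Self-edges are rejected and each unordered node pair is
    stored once.  Nodes without any edge are allowed (they are kept so that
    propagation vectors stay aligned with the declared node universe).
    """

    def __init__(
        self,
        edges: Mapping[tuple[str, str], int],
        extra_nodes: Iterable[str] = (),
    ) -> None:
        adj: dict[str, dict[str, int]] = {}
        canon: dict[tuple[str, str], int] = {}
        for (a, b), score in edges.items():
            if a == b:
                raise ValueError(f"self-edge on node {a!r} is not allowed")
            score = int(score)
            if not SCORE_MIN <= score <= SCORE_MAX:
                raise ValueError(
                    f"edge ({a!r}, {b!r}) score {score} outside "
                    f"[{SCORE_MIN}, {SCORE_MAX}]"
                )
            key = _canonical(a, b)
            if key in canon:
                raise ValueError(f"duplicate edge {key!r}")
            canon[key] = score
            adj.setdefault(a, {})[b] = score
            adj.setdefault(b, {})[a] = score
        nodes = set(adj)
        nodes.update(extra_nodes)
        self._nodes: tuple[str, ...] = tuple(sorted(nodes))
        self._index: dict[str, int] = {n: i for i, n in enumerate(self._nodes)}
        self._adj = adj
        self._edges = canon
        if not self._nodes:
            raise ValueError("network has no nodes")

    @classmethod
    def from_edge_list(
        cls,
        triples: Iterable[tuple[str, str, int]],
        extra_nodes: Iterable[str] = (),
    ) -> "WeightedNetwork":
        """Build a network from (a, b, score) triples.

        Symmetric duplicates (a-b and b-a) collapse to one undirected edge;
        conflicting duplicate scores keep the maximum; self-pairs are dropped.
        """
        merged: dict[tuple[str, str], int] = {}
        for a, b, score in triples:
            if a == b:
                continue
            key = _canonical(a, b)
            prev = merged.get(key)
            merged[key] = int(score) if prev is None else max(prev, int(score))
        return cls(merged, extra_nodes=extra_nodes)

    # -- basic queries -----------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def node_index(self) -> dict[str, int]:
        return self._index

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def edges(self) -> Iterator[tuple[str, str, int]]:
        for (a, b), s in self._edges.items():
            yield a, b, s

    def score(self, a: str, b: str) -> int | None:
        """Interaction score of the a-b edge, or None if absent."""
        return self._adj.get(a, {}).get(b)

    def neighbors(self, node: str) -> dict[str, int]:
        if node not in self._index:
            raise KeyError(node)
        return dict(self._adj.get(node, {}))

    def isolated_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self._nodes if n not in self._adj)

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Symmetric score-weighted adjacency in the node ordering."""
        n = self.n_nodes
        rows, cols, vals = [], [], []
        for (a, b), s in self._edges.items():
            i, j = self._index[a], self._index[b]
            rows += [i, j]
            cols += [j, i]
            vals += [s, s]
        return sp.csr_matrix(
            (np.asarray(vals, dtype=float), (rows, cols)), shape=(n, n)
        )


@dataclass(frozen=True)
class SeedSet:
    """Ordered, duplicate-free list of seed gene identifiers.

    ``node_groups`` is filled by :func:`map_seeds_to_network`: it maps each
    seed gene to the network node(s) it resolved to (several nodes when a
    gene has multiple protein isoforms in the network).
    """

    genes: tuple[str, ...]
    provenance: str = ""
    node_groups: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("seed set is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("seed set contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    @property
    def node_ids(self) -> tuple[str, ...]:
        """All network node identifiers covered by the seeds."""
        if self.node_groups is None:
            return self.genes
        out: list[str] = []
        for g in self.genes:
            out.extend(self.node_groups[g])
        return tuple(dict.fromkeys(out))


@dataclass(frozen=True)
class OntologyGraph:
    """Term DAG with is_a/part_of parent links (child -> parents)."""

    terms: Mapping[str, str]  # id -> name
    parents: Mapping[str, frozenset[str]]

    def children_map(self) -> dict[str, set[str]]:
        children: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                children[p].add(child)
        return children


@dataclass(frozen=True)
class AnnotationCatalog:
    """Mapping gene identifier -> set of namespaced term identifiers."""

    annotations: Mapping[str, frozenset[str]]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.annotations))

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.annotations.get(gene, frozenset())

    def term_universe(self) -> tuple[str, ...]:
        universe: set[str] = set()
        for terms in self.annotations.values():
            universe.update(terms)
        return tuple(sorted(universe))

    def unannotated_genes(self) -> tuple[str, ...]:
        return tuple(sorted(g for g, t in self.annotations.items() if not t))


# ---------------------------------------------------------------------------
# STRING links
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_string_links(
    path: str | Path, organism_code: str | None = None
) -> WeightedNetwork:
    """Parse a STRING-style links file into a :class:`WeightedNetwork`.

    The file holds whitespace-separated ``protein1 protein2 combined_score``
    triples, optionally with a header line, optionally gzip-compressed.
    When ``organism_code`` is given, only lines whose *both* protein
    identifiers carry the ``<code>.`` prefix are kept (STRING files bundle
    many organisms; e.g. code ``"3702"`` selects Arabidopsis thaliana).
    Symmetric duplicate rows collapse to one undirected edge, conflicting
    duplicate scores keep the maximum, and self-pairs are dropped.
    """
    prefix = f"{organism_code}." if organism_code else None
    triples: list[tuple[str, str, int]] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(fields)}"
                )
            a, b, score_text = fields
            try:
                score = int(score_text)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ValueError(
                    f"{path}: line {lineno}: non-integer score {score_text!r}"
                ) from None
            if prefix is not None and not (
                a.startswith(prefix) and b.startswith(prefix)
            ):
                continue
            triples.append((a, b, score))
    if not triples:
        raise ValueError("empty network after organism filter")
    return WeightedNetwork.from_edge_list(triples)


# ---------------------------------------------------------------------------
# OBO ontology
# ---------------------------------------------------------------------------

_PARENT_RELATIONS = ("is_a", "part_of")


def parse_obo(path: str | Path) -> OntologyGraph:
    """Read an OBO 1.2 flat file into an :class:`OntologyGraph`.

    Obsolete terms are excluded.  Both ``is_a`` and ``part_of`` relations
    become parent links (the fruit-anatomy branch of the Plant Ontology
    attaches parts such as pericarp via ``part_of``).  A parent reference
    to a term the file never defines is dropped with a warning.
    """
    try:
        graph = obonet.read_obo(Path(path))
    except KeyError as exc:
        raise ValueError(f"{path}: stanza missing required {exc} field") from exc
    terms: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        if "name" in data or data:  # dangling parents carry no data at all
            terms[node] = data.get("name", node)
    parents: dict[str, set[str]] = {t: set() for t in terms}
    for child, parent, relation in graph.edges(keys=True):
        if relation not in _PARENT_RELATIONS or child not in terms:
            continue
        if parent not in terms:
            warnings.warn(
                f"{path}: dropping {relation} link {child} -> undefined "
                f"term {parent}",
                stacklevel=2,
            )
            continue
        parents[child].add(parent)
    return OntologyGraph(
        terms=terms,
        parents={t: frozenset(ps) for t, ps in parents.items()},
    )


def term_closure(ontology: OntologyGraph, root: str) -> set[str]:
    """Root plus every descendant reachable through child links."""
    if root not in ontology.terms:
        raise ValueError(f"unknown ontology term {root!r}")
    children = ontology.children_map()
    closure = {root}
    frontier = [root]
    while frontier:
        term = frontier.pop()
        for child in children.get(term, ()):
            if child not in closure:
                closure.add(child)
                frontier.append(child)
    return closure


# ---------------------------------------------------------------------------
# Seed construction and mapping
# ---------------------------------------------------------------------------

def seeds_from_annotations(
    catalog: AnnotationCatalog, terms: set[str], provenance: str = ""
) -> SeedSet:
    """Every gene annotated to at least one of ``terms``, sorted."""
    if not catalog.annotations:
        raise ValueError("annotation catalog is empty")
    hits = sorted(
        g for g, ann in catalog.annotations.items() if ann & set(terms)
    )
    if not hits:
        raise ValueError("no seed genes for given terms")
    return SeedSet(tuple(hits), provenance=provenance or ",".join(sorted(terms)))


def normalize_gene_id(
    node_id: str,
    strip_organism_prefix: bool = True,
    strip_transcript_suffix: bool = True,
) -> str:
    """Reduce a protein node identifier to a bare gene identifier.

    ``3702.AT1G01010.1`` -> ``AT1G01010``: the leading all-digit organism
    code and the trailing all-digit transcript suffix are stripped when the
    corresponding switch is on.  Identifiers without those decorations pass
    through unchanged.
    """
    parts = node_id.split(".")
    if strip_organism_prefix and len(parts) > 1 and parts[0].isdigit():
        parts = parts[1:]
    if strip_transcript_suffix and len(parts) > 1 and parts[-1].isdigit():
        parts = parts[:-1]
    return ".".join(parts)


@dataclass(frozen=True)
class MappingReport:
    """Outcome of joining gene-level seed IDs onto protein-level nodes."""

    mapped: tuple[str, ...]
    unmapped: tuple[str, ...]
    multi_isoform: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def n_mapped(self) -> int:
        return len(self.mapped)

    @property
    def n_unmapped(self) -> int:
        return len(self.unmapped)


def map_seeds_to_network(
    seeds: SeedSet,
    network: WeightedNetwork,
    strip_organism_prefix: bool = True,
    strip_transcript_suffix: bool = True,
) -> tuple[SeedSet, MappingReport]:
    """Resolve seed gene identifiers to network protein nodes.

    A seed gene whose normalized form matches several protein isoform nodes
    maps to all of them (the initial probability mass is later split equally
    among a gene's nodes).  Returns the mapped seed set (with node groups)
    and a report listing unmapped seeds.
    """
    gene_to_nodes: dict[str, list[str]] = {}
    for node in network.nodes:
        gene = normalize_gene_id(
            node, strip_organism_prefix, strip_transcript_suffix
        )
        gene_to_nodes.setdefault(gene, []).append(node)
        if gene != node:
            gene_to_nodes.setdefault(node, []).append(node)
    groups: dict[str, tuple[str, ...]] = {}
    unmapped: list[str] = []
    for gene in seeds.genes:
        nodes = gene_to_nodes.get(gene)
        if nodes:
            groups[gene] = tuple(sorted(dict.fromkeys(nodes)))
        else:
            unmapped.append(gene)
    if not groups:
        raise ValueError("zero seed genes mapped to network nodes")
    mapped = SeedSet(
        tuple(g for g in seeds.genes if g in groups),
        provenance=seeds.provenance,
        node_groups=groups,
    )
    report = MappingReport(
        mapped=tuple(groups),
        unmapped=tuple(unmapped),
        multi_isoform={
            g: ns for g, ns in groups.items() if len(ns) > 1
        },
    )
    return mapped, report


# ---------------------------------------------------------------------------
# Flat tables
# ---------------------------------------------------------------------------

def load_gene_list(path: str | Path) -> tuple[str, ...]:
    """One identifier per line; '#' comments and blank lines allowed."""
    genes: list[str] = []
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return tuple(dict.fromkeys(genes))


def load_annotation_table(path: str | Path) -> AnnotationCatalog:
    """Two-column TSV ``gene<TAB>term``, multiple rows per gene."""
    ann: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields"
                )
            gene, term = (f.strip() for f in fields)
            ann.setdefault(gene, set()).add(term)
    return AnnotationCatalog({g: frozenset(t) for g, t in ann.items()})
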