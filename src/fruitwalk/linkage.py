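"""Guilt-by-association linkage filters.

Two scores tie a candidate gene back to the validated seed set:

* MIS, the maximum interaction score — the strongest direct edge between
  the candidate and any seed (STRING combined score, 150–999).  The
  default cutoff 900 is STRING's "highest confidence" floor and is
  inclusive (MIS >= 900 passes).
* MFS, the maximum function score — the best cosine similarity between
  the candidate's functional-annotation vector and any seed's.  The
  default cutoff 0.9 is exclusive (MFS > 0.9 passes).

Annotation vectors live over the sorted union of GO terms and KEGG
pathways in the catalog.  Two vectorizers are provided: plain binary term
incidence, and a neighborhood-enrichment score in which component t is
-log10 of the hypergeometric upper-tail p-value of the overlap between
the gene's network-neighborhood annotations and term t.  The enrichment
form is the pipeline default: it follows the enrichment-score literature
this style of screen builds on, and it produces the smooth near-one MFS
values characteristic of genes embedded in a co-annotated neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .network_io import AnnotationCatalog, SeedSet, WeightedNetwork

__all__ = [
    "AnnotationVector",
    "CandidateRecord",
    "max_interaction_score",
    "build_annotation_vectors",
    "cosine_similarity",
    "max_function_score",
    "build_candidate_records",
    "final_filter",
    "records_to_frame",
    "MIS_THRESHOLD",
    "MFS_THRESHOLD",
]

MIS_THRESHOLD = 900
MFS_THRESHOLD = 0.9


@dataclass(frozen=True)
class AnnotationVector:
    """Non-negative functional profile over a fixed term universe."""

    gene: str
    values: np.ndarray
    universe: tuple[str, ...]
    vectorizer: str = "binary"

    @property
    def is_zero(self) -> bool:
        return not np.any(self.values)


@dataclass(frozen=True)
class CandidateRecord:
    """One gene's full evidence row across the pipeline stages."""

    gene: str
    rwr_probability: float
    p_value: float
    mis: int | None
    mfs: float | None

    def passes(
        self,
        mis_threshold: int = MIS_THRESHOLD,
        mfs_threshold: float = MFS_THRESHOLD,
    ) -> bool:
        return (
            self.mis is not None
            and self.mis >= mis_threshold
            and self.mfs is not None
            and self.mfs > mfs_threshold
        )


def max_interaction_score(
    gene: str, seeds: SeedSet, network: WeightedNetwork
) -> int | None:
    """Strongest direct edge between ``gene`` and any seed node.

    Returns None when the gene has no seed neighbor (such a gene cannot
    pass the MIS filter).
    """
    if gene not in network:
        raise ValueError(f"gene {gene!r} is not a network node")
    neighbors = network.neighbors(gene)
    scores = [
        neighbors[s] for s in seeds.node_ids if s in neighbors and s != gene
    ]
    return max(scores) if scores else None


def build_annotation_vectors(
    catalog: AnnotationCatalog,
    genes: Sequence[str],
    vectorizer: str = "binary",
    network: WeightedNetwork | None = None,
    universe: Sequence[str] | None = None,
) -> dict[str, AnnotationVector]:
    """Vectorize each gene's functional annotations.

    binary
        Component t is 1 iff the gene is annotated to term t.
    enrichment
        Component t is -log10 of the hypergeometric upper-tail p-value of
        the overlap between the annotations of the gene's network
        neighbors and term t (0 when no neighbor carries t).  Requires
        ``network``.

    A gene absent from the catalog gets the all-zero vector (flagged via
    :attr:`AnnotationVector.is_zero`); it flows through the pipeline and
    simply fails the MFS filter.
    """
    if vectorizer not in ("binary", "enrichment"):
        raise ValueError("vectorizer must be 'binary' or 'enrichment'")
    universe = tuple(universe) if universe is not None else catalog.term_universe()
    term_index = {t: i for i, t in enumerate(universe)}
    vectors: dict[str, AnnotationVector] = {}
    if vectorizer == "binary":
        for gene in genes:
            values = np.zeros(len(universe))
            for term in catalog.terms_of(gene):
                if term in term_index:
                    values[term_index[term]] = 1.0
            vectors[gene] = AnnotationVector(gene, values, universe, "binary")
        return vectors
    if network is None:
        raise ValueError("the enrichment vectorizer requires a network")
    catalog_genes = set(catalog.annotations)
    n_background = len(catalog_genes)
    term_counts = np.zeros(len(universe))
    for g in catalog_genes:
        for term in catalog.terms_of(g):
            if term in term_index:
                term_counts[term_index[term]] += 1
    for gene in genes:
        neighborhood = [
            n for n in network.neighbors(gene) if n in catalog_genes
        ] if gene in network else []
        values = np.zeros(len(universe))
        if neighborhood:
            draw = len(neighborhood)
            overlap = np.zeros(len(universe))
            for n in neighborhood:
                for term in catalog.terms_of(n):
                    if term in term_index:
                        overlap[term_index[term]] += 1
            hit = overlap > 0
            tail = hypergeom.sf(
                overlap[hit] - 1, n_background, term_counts[hit], draw
            )
            values[hit] = -np.log10(np.maximum(tail, np.finfo(float).tiny))
        vectors[gene] = AnnotationVector(gene, values, universe, "enrichment")
    return vectors


def cosine_similarity(v: AnnotationVector, w: AnnotationVector) -> float:
    """Cosine of two annotation vectors; 0 when either vector is zero."""
    if len(v.values) != len(w.values):
        raise ValueError("annotation vectors span different universes")
    nv = np.linalg.norm(v.values)
    nw = np.linalg.norm(w.values)
    if nv == 0.0 or nw == 0.0:
        return 0.0
    return float(np.dot(v.values, w.values) / (nv * nw))


def max_function_score(
    gene: str,
    seeds: SeedSet,
    vectors: Mapping[str, AnnotationVector],
) -> float | None:
    """Best cosine similarity between ``gene`` and any seed.

    Seeds are compared at the network-node level (a mapped seed's profile
    lives on its protein node(s); an unmapped-style seed set falls back to
    its gene identifiers).  None when the gene's own vector is all-zero
    (no usable profile); seeds with zero vectors contribute similarity 0
    and are harmless.
    """
    v = vectors[gene]
    if v.is_zero:
        return None
    best = 0.0
    for seed in seeds.node_ids:
        w = vectors.get(seed)
        if w is None:
            continue
        best = max(best, cosine_similarity(v, w))
    return best


def build_candidate_records(
    candidates: Sequence[tuple[str, float, float]],
    seeds: SeedSet,
    network: WeightedNetwork,
    vectors: Mapping[str, AnnotationVector],
) -> list[CandidateRecord]:
    """Assemble full evidence rows for (gene, probability, p_value) triples."""
    records = []
    for gene, probability, p_value in candidates:
        records.append(
            CandidateRecord(
                gene=gene,
                rwr_probability=probability,
                p_value=p_value,
                mis=max_interaction_score(gene, seeds, network),
                mfs=max_function_score(gene, seeds, vectors),
            )
        )
    return records


def final_filter(
    records: Sequence[CandidateRecord],
    mis_threshold: int = MIS_THRESHOLD,
    mfs_threshold: float = MFS_THRESHOLD,
) -> list[CandidateRecord]:
    """Keep records with MIS >= threshold and MFS > threshold.

    The MIS boundary is inclusive ("no less than"), the MFS boundary
    exclusive ("larger than").  Output sorted by descending propagation
    probability, ties broken by gene identifier.
    """
    kept = [r for r in records if r.passes(mis_threshold, mfs_threshold)]
    kept.sort(key=lambda r: (-r.rwr_probability, r.gene))
    return kept


def records_to_frame(
    records: Sequence[CandidateRecord],
    mis_threshold: int = MIS_THRESHOLD,
    mfs_threshold: float = MFS_THRESHOLD,
) -> pd.DataFrame:
    """Serialize records; absent scores become the string "NA"."""
    rows = [
        {
            "gene": r.gene,
            "probability": r.rwr_probability,
            "p_value": r.p_value,
            "mis": r.mis if r.mis is not None else "NA",
            "mfs": r.mfs if r.mfs is not None else "NA",
            "is_putative": r.passes(mis_threshold, mfs_threshold),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["gene", "probability", "p_value", "mis", "mfs", "is_putative"]
    )
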