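"""End-to-end orchestration of the prioritization funnel.

Stages run in a fixed order: network + seed construction, random walk
with restart, permutation filtering, linkage filtering.  Every
intermediate table can be persisted so a stage can be inspected or re-run
in isolation, and a manifest records the survivor counts of the funnel
(RWR genes -> candidates -> putative genes, always non-increasing).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .linkage import (
    MFS_THRESHOLD,
    MIS_THRESHOLD,
    CandidateRecord,
    build_annotation_vectors,
    build_candidate_records,
    final_filter,
    records_to_frame,
)
from .network_io import (
    AnnotationCatalog,
    MappingReport,
    SeedSet,
    WeightedNetwork,
    load_annotation_table,
    load_gene_list,
    map_seeds_to_network,
    normalize_gene_id,
    parse_obo,
    parse_string_links,
    seeds_from_annotations,
    term_closure,
)
from .permutation import (
    PermutationConfig,
    PermutationResult,
    empirical_pvalues,
    null_probabilities,
    sample_null_seed_sets,
)
from .rwr import (
    ProbabilityVector,
    RWRConfig,
    build_transition_matrix,
    initial_vector,
    run_rwr,
    select_rwr_genes,
)

__all__ = [
    "RunManifest",
    "PipelineResult",
    "GeneSetComparison",
    "run_pipeline",
    "run_from_config",
    "compare_gene_sets",
]

logger = logging.getLogger("fruitwalk")


@dataclass(frozen=True)
class RunManifest:
    """Survivor counts of the funnel plus provenance."""

    n_nodes: int
    n_edges: int
    n_seeds_requested: int
    n_seeds_mapped: int
    n_isolated_nodes: int
    n_rwr_genes: int
    n_candidates: int
    n_putative: int
    config: Mapping[str, object] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.n_putative <= self.n_candidates <= self.n_rwr_genes:
            raise ValueError(
                "funnel counts must be non-increasing: "
                f"{self.n_rwr_genes} RWR genes -> {self.n_candidates} "
                f"candidates -> {self.n_putative} putative"
            )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


@dataclass(frozen=True)
class PipelineResult:
    probabilities: ProbabilityVector
    rwr_genes: list[tuple[str, float]]
    permutation: PermutationResult
    records: list[CandidateRecord]
    putative: list[CandidateRecord]
    manifest: RunManifest
    mapping_report: MappingReport

    @property
    def putative_genes(self) -> tuple[str, ...]:
        return tuple(r.gene for r in self.putative)

    @property
    def candidate_genes(self) -> tuple[str, ...]:
        return self.permutation.candidates


def _config_echo(rwr_config: RWRConfig, perm_config: PermutationConfig,
                 vectorizer: str, mis_threshold: int, mfs_threshold: float
                 ) -> dict[str, object]:
    return {
        "rwr": dataclasses.asdict(rwr_config),
        "permutation": dataclasses.asdict(perm_config),
        "linkage": {
            "vectorizer": vectorizer,
            "mis_threshold": mis_threshold,
            "mfs_threshold": mfs_threshold,
        },
    }


def run_pipeline(
    network: WeightedNetwork,
    seeds: SeedSet,
    catalog: AnnotationCatalog,
    rwr_config: RWRConfig | None = None,
    perm_config: PermutationConfig | None = None,
    vectorizer: str = "enrichment",
    mis_threshold: int = MIS_THRESHOLD,
    mfs_threshold: float = MFS_THRESHOLD,
    out_dir: str | Path | None = None,
    strip_organism_prefix: bool = True,
    strip_transcript_suffix: bool = True,
) -> PipelineResult:
    """Run the four-stage funnel and optionally persist every table."""
    rwr_config = rwr_config or RWRConfig()
    perm_config = perm_config or PermutationConfig()

    # -- stage 1: seed mapping onto the network ---------------------------
    mapped_seeds, report = map_seeds_to_network(
        seeds, network, strip_organism_prefix, strip_transcript_suffix
    )
    if report.n_unmapped:
        logger.warning(
            "%d of %d seed genes did not map to a network node: %s",
            report.n_unmapped, len(seeds), ", ".join(report.unmapped[:10]),
        )
    isolated = network.isolated_nodes()
    if isolated:
        logger.warning("%d isolated network nodes (self-loops added)", len(isolated))

    # -- stage 2: random walk with restart --------------------------------
    matrix = build_transition_matrix(network)
    p0 = initial_vector(mapped_seeds, matrix.nodes)
    probabilities = run_rwr(matrix, p0, rwr_config)
    rwr_genes = select_rwr_genes(probabilities, mapped_seeds, rwr_config)

    # -- stage 3: permutation filter --------------------------------------
    if perm_config.set_size is None:
        perm_config = dataclasses.replace(
            perm_config, set_size=len(mapped_seeds.node_ids)
        )
    null_sets = sample_null_seed_sets(network, perm_config, seeds=mapped_seeds)
    nulls = null_probabilities(matrix, null_sets, rwr_config)
    permutation = empirical_pvalues(
        probabilities, nulls, rwr_genes, perm_config, null_sets=null_sets
    )

    # -- stage 4: linkage filters ------------------------------------------
    candidate_rows = permutation.table[permutation.table["is_candidate"]]
    triples = [
        (row.gene, row.probability, row.p_value)
        for row in candidate_rows.itertuples()
    ]
    entities = list(
        dict.fromkeys([g for g, _, _ in triples] + list(mapped_seeds.node_ids))
    )

    def effective_terms(entity: str) -> frozenset[str]:
        terms = catalog.terms_of(entity)
        if not terms:
            terms = catalog.terms_of(
                normalize_gene_id(
                    entity, strip_organism_prefix, strip_transcript_suffix
                )
            )
        return terms

    # The lookup catalog covers every network node so the enrichment
    # vectorizer can annotate whole neighborhoods, not just candidates.
    effective = AnnotationCatalog(
        {e: effective_terms(e) for e in set(entities) | set(network.nodes)}
    )
    vectors = build_annotation_vectors(
        effective,
        entities,
        vectorizer=vectorizer,
        network=network,
        universe=catalog.term_universe(),
    )
    records = build_candidate_records(triples, mapped_seeds, network, vectors)
    putative = final_filter(records, mis_threshold, mfs_threshold)

    manifest = RunManifest(
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
        n_seeds_requested=len(seeds),
        n_seeds_mapped=len(mapped_seeds),
        n_isolated_nodes=len(isolated),
        n_rwr_genes=len(rwr_genes),
        n_candidates=len(triples),
        n_putative=len(putative),
        config=_config_echo(
            rwr_config, perm_config, vectorizer, mis_threshold, mfs_threshold
        ),
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    result = PipelineResult(
        probabilities=probabilities,
        rwr_genes=rwr_genes,
        permutation=permutation,
        records=records,
        putative=putative,
        manifest=manifest,
        mapping_report=report,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), mis_threshold, mfs_threshold)
    return result


def _write_outputs(
    result: PipelineResult,
    out_dir: Path,
    mis_threshold: int,
    mfs_threshold: float,
) -> None:
    """Persist every stage table (TSV with headers) plus the manifest.

    The data tables are byte-reproducible under an identical config and
    seed; the manifest JSON carries the wall-clock timestamp and is the
    one file allowed to differ between identical runs.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(result.rwr_genes, columns=["gene", "probability"]).to_csv(
        out_dir / "rwr_genes.tsv", sep="\t", index=False
    )
    result.permutation.table.to_csv(
        out_dir / "permutation.tsv", sep="\t", index=False
    )
    records_to_frame(result.records, mis_threshold, mfs_threshold).to_csv(
        out_dir / "candidates.tsv", sep="\t", index=False
    )
    records_to_frame(result.putative, mis_threshold, mfs_threshold).to_csv(
        out_dir / "putative.tsv", sep="\t", index=False
    )
    (out_dir / "manifest.json").write_text(result.manifest.to_json() + "\n")


# ---------------------------------------------------------------------------
# Config-file front end
# ---------------------------------------------------------------------------

def _load_inputs(config: Mapping[str, object]):
    network = parse_string_links(
        str(config["links"]), organism_code=config.get("organism")
    )
    if "seed_list" in config:
        seeds = SeedSet(
            load_gene_list(str(config["seed_list"])), provenance="seed list file"
        )
    else:
        ontology = parse_obo(str(config["ontology"]))
        terms = term_closure(ontology, str(config["seed_term_root"]))
        po_catalog = load_annotation_table(str(config["seed_annotations"]))
        seeds = seeds_from_annotations(po_catalog, terms)
    catalog = load_annotation_table(str(config["annotations"]))
    return network, seeds, catalog


def run_from_config(
    config: Mapping[str, object], rng_seed: int | None = None
) -> PipelineResult:
    """Run the pipeline from a flat key-value configuration mapping.

    Recognized keys: ``links``, ``organism``, ``seed_list`` (or
    ``ontology`` + ``seed_term_root`` + ``seed_annotations``),
    ``annotations``, ``out_dir``, plus dotted scalars ``rwr.c``,
    ``rwr.tolerance``, ``rwr.threshold``, ``rwr.update_rule``,
    ``perm.n_sets``, ``perm.alpha``, ``perm.rng_seed``,
    ``linkage.vectorizer``, ``linkage.mis_threshold``,
    ``linkage.mfs_threshold``.  ``rng_seed`` overrides ``perm.rng_seed``.
    """
    network, seeds, catalog = _load_inputs(config)
    rwr_config = RWRConfig(
        restart_probability=float(config.get("rwr.c", 0.8)),
        tolerance=float(config.get("rwr.tolerance", 1e-6)),
        probability_threshold=float(config.get("rwr.threshold", 1e-5)),
        update_rule=str(config.get("rwr.update_rule", "standard")),
    )
    perm_config = PermutationConfig(
        n_sets=int(config.get("perm.n_sets", 1000)),
        alpha=float(config.get("perm.alpha", 0.05)),
        rng_seed=int(
            rng_seed if rng_seed is not None else config.get("perm.rng_seed", 0)
        ),
    )
    return run_pipeline(
        network,
        seeds,
        catalog,
        rwr_config=rwr_config,
        perm_config=perm_config,
        vectorizer=str(config.get("linkage.vectorizer", "enrichment")),
        mis_threshold=int(config.get("linkage.mis_threshold", MIS_THRESHOLD)),
        mfs_threshold=float(config.get("linkage.mfs_threshold", MFS_THRESHOLD)),
        out_dir=config.get("out_dir"),
    )


# ---------------------------------------------------------------------------
# Gene-set comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSetComparison:
    shared: tuple[str, ...]
    only_a: tuple[str, ...]
    only_b: tuple[str, ...]

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_only_a(self) -> int:
        return len(self.only_a)

    @property
    def n_only_b(self) -> int:
        return len(self.only_b)


def compare_gene_sets(
    set_a: Sequence[str],
    set_b: Sequence[str],
    normalize: bool = False,
) -> GeneSetComparison:
    """Exact intersection/differences of two gene lists.

    With ``normalize`` the same identifier normalization used for seed
    mapping is applied to both lists first, so protein-level and
    gene-level lists can be compared.
    """
    def norm(genes: Sequence[str]) -> set[str]:
        if normalize:
            return {normalize_gene_id(g) for g in genes}
        return set(genes)

    a, b = norm(set_a), norm(set_b)
    return GeneSetComparison(
        shared=tuple(sorted(a & b)),
        only_a=tuple(sorted(a - b)),
        only_b=tuple(sorted(b - a)),
    )
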