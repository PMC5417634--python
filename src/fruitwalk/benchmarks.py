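"""Reference benchmark procedures for the propagation pipeline.

Small, fully self-contained study designs used both by the test suite and
by the reproduction script: oracle agreement between the iterative walker
and the dense linear solve, the hand-solvable two-node stationary vector,
permutation-null calibration, and planted-module recovery.  Each function
takes explicit seeds so every number it returns is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kstest

from .network_io import SeedSet, WeightedNetwork
from .permutation import (
    PermutationConfig,
    empirical_pvalues,
    null_probabilities,
    sample_null_seed_sets,
)
from .pipeline import run_pipeline
from .rwr import (
    RWRConfig,
    build_transition_matrix,
    initial_vector,
    run_rwr,
    solve_rwr_direct,
)
from .synthetic import (
    PlantedModuleSpec,
    evaluate_recovery,
    generate_annotations,
    generate_planted_network,
    split_seeds,
)

__all__ = [
    "random_weighted_network",
    "oracle_equivalence_gap",
    "two_node_stationary",
    "CalibrationResult",
    "permutation_calibration",
    "RecoverySummary",
    "planted_recovery",
]


def random_weighted_network(
    rng: np.random.Generator, n_nodes: int = 100, edge_probability: float = 0.08
) -> WeightedNetwork:
    """Erdős–Rényi network with uniform STRING-range scores."""
    names = [f"n{i:04d}" for i in range(n_nodes)]
    iu, ju = np.triu_indices(n_nodes, k=1)
    keep = rng.random(len(iu)) < edge_probability
    scores = rng.integers(150, 1000, size=len(iu))
    triples = [
        (names[i], names[j], int(s))
        for i, j, s, k in zip(iu, ju, scores, keep)
        if k
    ]
    return WeightedNetwork.from_edge_list(triples, extra_nodes=names)


def oracle_equivalence_gap(
    n_graphs: int = 20,
    n_nodes: int = 100,
    n_seeds: int = 5,
    base_seed: int = 0,
) -> float:
    """Largest L1 gap between iterative propagation and the dense solve.

    Runs both routes on ``n_graphs`` independent random networks and
    returns the worst disagreement; the iterative route uses a stopping
    tolerance tight enough that the two should agree to well below 1e-8.
    """
    worst = 0.0
    for g in range(n_graphs):
        rng = np.random.default_rng(base_seed + g)
        network = random_weighted_network(rng, n_nodes=n_nodes)
        matrix = build_transition_matrix(network)
        seeds = SeedSet(
            tuple(sorted(rng.choice(matrix.nodes, n_seeds, replace=False)))
        )
        p0 = initial_vector(seeds, matrix.nodes)
        iterative = run_rwr(matrix, p0, RWRConfig(tolerance=1e-11))
        direct = solve_rwr_direct(matrix, p0)
        worst = max(worst, float(np.abs(iterative.values - direct.values).sum()))
    return worst


def two_node_stationary(restart_probability: float = 0.8) -> tuple[float, float]:
    """Stationary vector on the two-node path seeded at one end.

    The closed form is p = c (I - (1-c) M)^-1 p0; at c = 0.8 this gives
    (5/6, 1/6).  Computed here by the production iterative route.
    """
    network = WeightedNetwork({("a", "b"): 900})
    matrix = build_transition_matrix(network)
    p0 = initial_vector(SeedSet(("a",)), matrix.nodes)
    p = run_rwr(
        matrix,
        p0,
        RWRConfig(restart_probability=restart_probability, tolerance=1e-13),
    )
    return p["a"], p["b"]


@dataclass(frozen=True)
class CalibrationResult:
    ks_statistic: float
    ks_pvalue: float
    n_genes: int
    n_candidates: int


def permutation_calibration(
    rng_seed: int = 0,
    n_nodes: int = 200,
    n_sets: int = 200,
    set_size: int = 10,
) -> CalibrationResult:
    """Null calibration: observed seeds drawn from the null sampler.

    On a featureless network (no planted signal) an observed seed set
    drawn from the same distribution as the null sets confers no real
    signal, so the empirical p-values over all scored genes should be
    close to uniform.  Returns the KS test of that uniformity.
    """
    spec = PlantedModuleSpec(
        n_nodes=n_nodes,
        module_size=set_size * 2,
        p_in=0.05,
        p_out=0.05,
        score_in=(150, 999),
        score_out=(150, 999),
        share_in=0.05,
        share_out=0.05,
        rng_seed=rng_seed,
    )
    network, _ = generate_planted_network(spec)
    matrix = build_transition_matrix(network)
    rwr_config = RWRConfig(probability_threshold=0.0)
    (observed_set,) = sample_null_seed_sets(
        network,
        PermutationConfig(n_sets=1, set_size=set_size, rng_seed=rng_seed + 900),
    )
    seeds = SeedSet(tuple(sorted(observed_set)), provenance="null-drawn")
    observed = run_rwr(matrix, initial_vector(seeds, matrix.nodes), rwr_config)
    genes = [
        (node, float(value))
        for node, value in zip(observed.nodes, observed.values)
        if node not in set(seeds.node_ids) and value > 0
    ]
    perm_config = PermutationConfig(
        n_sets=n_sets, set_size=set_size, rng_seed=rng_seed + 500
    )
    null_sets = sample_null_seed_sets(network, perm_config)
    nulls = null_probabilities(matrix, null_sets, rwr_config)
    result = empirical_pvalues(
        observed, nulls, genes, perm_config, null_sets=null_sets
    )
    pvalues = result.table["p_value"].to_numpy()
    stat, pvalue = kstest(pvalues, "uniform")
    return CalibrationResult(
        ks_statistic=float(stat),
        ks_pvalue=float(pvalue),
        n_genes=len(pvalues),
        n_candidates=len(result.candidates),
    )


@dataclass(frozen=True)
class RecoverySummary:
    mean_precision: float
    mean_recall: float
    precisions: tuple[float, ...]
    recalls: tuple[float, ...]
    funnels: tuple[tuple[int, int, int], ...]


def planted_recovery(
    n_replicates: int = 10,
    n_sets: int = 200,
    base_seed: int = 0,
) -> RecoverySummary:
    """Held-out recovery under the strong-signal planted-module design.

    One full pipeline run per replicate seed; returns per-replicate and
    mean precision/recall of the held-out module members among the
    putative genes, plus each run's survivor funnel.
    """
    precisions: list[float] = []
    recalls: list[float] = []
    funnels: list[tuple[int, int, int]] = []
    for r in range(n_replicates):
        spec = PlantedModuleSpec(rng_seed=base_seed + r)
        network, module = generate_planted_network(spec)
        catalog = generate_annotations(spec, module)
        seeds, held_out = split_seeds(module, spec.seed_fraction, spec.rng_seed)
        result = run_pipeline(
            network,
            seeds,
            catalog,
            perm_config=PermutationConfig(
                n_sets=n_sets, rng_seed=base_seed + 1000 + r
            ),
        )
        report = evaluate_recovery(result.putative_genes, held_out)
        precisions.append(report.precision)
        recalls.append(report.recall)
        funnels.append(
            (
                result.manifest.n_rwr_genes,
                result.manifest.n_candidates,
                result.manifest.n_putative,
            )
        )
    return RecoverySummary(
        mean_precision=float(np.mean(precisions)),
        mean_recall=float(np.mean(recalls)),
        precisions=tuple(precisions),
        recalls=tuple(recalls),
        funnels=tuple(funnels),
    )
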