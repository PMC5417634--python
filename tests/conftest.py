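import logging

import pytest

import fruitwalk as fw

logging.getLogger("fruitwalk").setLevel(logging.ERROR)


@pytest.fixture
def two_node_network():
    return fw.WeightedNetwork({("a", "b"): 900})


@pytest.fixture
def star_network():
    # hub A with spokes B (150) and C (450)
    return fw.WeightedNetwork({("A", "B"): 150, ("A", "C"): 450})


@pytest.fixture(scope="session")
def strong_signal_run():
    """One strong-signal planted-module pipeline run, shared across tests."""
    spec = fw.PlantedModuleSpec(rng_seed=1)
    network, module = fw.generate_planted_network(spec)
    catalog = fw.generate_annotations(spec, module)
    seeds, held_out = fw.split_seeds(module, spec.seed_fraction, spec.rng_seed)
    result = fw.run_pipeline(
        network,
        seeds,
        catalog,
        perm_config=fw.PermutationConfig(n_sets=200, rng_seed=7),
    )
    return {
        "spec": spec,
        "network": network,
        "module": module,
        "catalog": catalog,
        "seeds": seeds,
        "held_out": held_out,
        "result": result,
    }
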