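"""Shared fixtures: small synthetic worlds built once per session."""

import numpy as np
import pytest

from novocomp.synthetic import (
    PlantedMarker,
    ScenarioSpec,
    build_scenario,
    gc_markov,
    paper_shaped_scenario,
)


@pytest.fixture(scope="session")
def mini_scenario():
    """Three genomes, 5 core families at 90% identity, 2 singletons each:
    the canonical planted-truth world for clustering tests."""
    spec = ScenarioSpec(
        genome_ids=["g1", "g2", "g3"],
        markov={g: gc_markov(0.60, 0.7) for g in ["g1", "g2", "g3"]},
        seed=42,
        n_core_families=5,
        core_identity=0.90,
        core_length=200,
        n_singletons={"g1": 2, "g2": 2, "g3": 2},
    )
    return build_scenario(spec)


@pytest.fixture(scope="session")
def marker_scenario():
    """Three small genomes with every marker kind planted: LuxI (intact and
    broken triad), LuxR solo, Rieske spacings 17/19, an ectoine cassette,
    and plasmid-borne singletons on a complete genome."""
    spec = ScenarioSpec(
        genome_ids=["alpha", "beta", "gamma"],
        markov={g: gc_markov(0.63, 0.7) for g in ["alpha", "beta", "gamma"]},
        seed=11,
        n_core_families=4,
        core_identity=0.85,
        core_length=180,
        unique_families={("alpha", "beta"): (2, 0.9)},
        n_singletons={"alpha": 5, "beta": 2, "gamma": 2},
        singleton_on_plasmid={"alpha": 2},
        plasmids={"alpha": ["alpha_p1"]},
        markers=[
            PlantedMarker("luxI", ["alpha"]),
            PlantedMarker("luxI", ["beta"], {"triad_intact": False}),
            PlantedMarker("luxR_solo", ["alpha"]),
            PlantedMarker("rieske", ["alpha"], {"spacing": 19}),
            PlantedMarker("rieske", ["gamma"], {"spacing": 17}),
            PlantedMarker("ect_cassette", ["alpha", "beta"], {"identity": 0.9}),
        ],
    )
    return build_scenario(spec)


@pytest.fixture(scope="session")
def six_genome_spec():
    return paper_shaped_scenario(7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
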