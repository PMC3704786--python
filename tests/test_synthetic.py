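"""The synthetic-data generator: Markov genomes, ortholog families,
planted markers and determinism."""

import numpy as np
import pytest

from novocomp.signature import DINUCS, dinuc_profile
from novocomp.synthetic import (
    MarkovParams,
    PlantedMarker,
    ScenarioSpec,
    build_scenario,
    expected_profile,
    gc_markov,
    gen_genome,
    gen_markov_sequence,
    gen_ortholog_family,
    pairwise_identity,
)


class TestMarkovGenomes:
    def test_uniform_chain_expected_rho_is_one(self):
        prof = expected_profile(MarkovParams.uniform())
        for d in DINUCS:
            assert prof.rho[d] == pytest.approx(1.0)

    def test_cg_suppressed_chain(self):
        params = gc_markov(0.6, cg_factor=0.5)
        exp = expected_profile(params)
        assert exp.rho["CG"] < 1.0

    def test_realized_rho_converges_to_analytic(self):
        """Observed rho* approaches the stationary-chain prediction."""
        params = gc_markov(0.6, cg_factor=0.5, aa_factor=1.3)
        rep, exp = gen_genome(params, 300_000, seed=9)
        obs = dinuc_profile(rep)
        for d in DINUCS:
            assert obs.rho[d] == pytest.approx(exp.rho[d], abs=0.03)

    def test_seed_determinism(self):
        params = gc_markov(0.62, 0.7)
        r1, _ = gen_genome(params, 5000, seed=3)
        r2, _ = gen_genome(params, 5000, seed=3)
        r3, _ = gen_genome(params, 5000, seed=4)
        assert r1.seq == r2.seq
        assert r1.seq != r3.seq

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            MarkovParams(np.full(4, 0.25), np.full((4, 4), 0.3))
        with pytest.raises(ValueError):
            MarkovParams(np.array([0.5, 0.5, 0.2, -0.2]), np.full((4, 4), 0.25))

    def test_stationary_start(self):
        params = gc_markov(0.65, 0.6)
        rng = np.random.default_rng(0)
        seq = gen_markov_sequence(params, 50_000, rng)
        pi = params.stationary()
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(pi[1] + pi[2], abs=0.02)


class TestOrthologFamilies:
    def test_target_one_identical(self):
        copies, ident = gen_ortholog_family(100, 3, 1.0, 0)
        assert len(set(copies)) == 1
        assert np.all(ident == 1.0)

    def test_target_recovery(self):
        """Mean realised identity over 10 length-300 families hits the
        target within the binomial standard error."""
        vals = [gen_ortholog_family(300, 2, 0.8, seed)[1][0, 1] for seed in range(10)]
        assert np.mean(vals) == pytest.approx(0.8, abs=0.03)

    def test_low_identity_family_below_clustering_cutoff(self):
        copies, ident = gen_ortholog_family(300, 2, 0.5, 2)
        assert ident[0, 1] < 0.65

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            gen_ortholog_family(100, 2, 0.0, 0)

    def test_pairwise_identity_helper(self):
        assert pairwise_identity("AAAA", "AACA") == 0.75
        with pytest.raises(ValueError):
            pairwise_identity("AA", "AAA")


class TestScenario:
    def test_determinism_bytewise(self, tmp_path):
        spec = ScenarioSpec(
            genome_ids=["x", "y"],
            markov={g: gc_markov(0.6, 0.7) for g in ["x", "y"]},
            seed=5,
            n_core_families=3,
            core_length=120,
            n_singletons={"x": 1, "y": 1},
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        build_scenario(spec, outdir=d1)
        build_scenario(spec, outdir=d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_ground_truth_consistent_with_emitted_genomes(self, marker_scenario):
        genomes, truth = marker_scenario
        all_ids = {(g.id, p.id) for g in genomes for p in g.proteome}
        clustered = {tuple(m) for c in truth.clusters for m in c}
        assert clustered == all_ids  # truth covers every protein exactly once
        assert len(clustered) == sum(len(c) for c in truth.clusters)

    def test_planted_rieske_and_triad(self, marker_scenario):
        from novocomp import refsets
        from novocomp.traits import check_luxI_triad, rieske_spacing

        genomes, truth = marker_scenario
        by_id = {(g.id, p.id): p for g in genomes for p in g.proteome}
        lux_ref = refsets.load_refset("luxI").members[0][1]
        for m in truth.markers["luxI"]:
            rep = check_luxI_triad(by_id[(m["genome"], m["protein"])].seq, lux_ref)
            assert rep.verdict == m["triad_intact"]
        for m in truth.markers["rieske"]:
            assert rieske_spacing(by_id[(m["genome"], m["protein"])].seq) == m["spacing"]

    def test_luxr_solo_isolated_from_luxi(self, marker_scenario):
        genomes, truth = marker_scenario
        for m in truth.markers["luxR_solo"]:
            g = next(x for x in genomes if x.id == m["genome"])
            solo = next(p for p in g.proteome if p.id == m["protein"])
            lux_ids = {
                t["protein"] for t in truth.markers["luxI"] if t["genome"] == g.id
            }
            for p in g.proteins_on(solo.replicon_id):
                if p.id in lux_ids:
                    assert abs(p.gene_order_index - solo.gene_order_index) > 5

    def test_mandatory_seed_and_validation(self):
        with pytest.raises(ValueError):
            ScenarioSpec(
                genome_ids=["x"], markov={"x": gc_markov()}, seed=None
            )
        with pytest.raises(ValueError, match="plasmid"):
            ScenarioSpec(
                genome_ids=["x"],
                markov={"x": gc_markov()},
                seed=1,
                n_singletons={"x": 2},
                singleton_on_plasmid={"x": 1},
            )

    def test_infeasible_layout_rejected(self):
        spec = ScenarioSpec(
            genome_ids=["x", "y"],
            markov={g: gc_markov() for g in ["x", "y"]},
            seed=2,
            n_core_families=4,
            core_length=300,
            chromosome_length={"x": 1500},  # cannot hold 4 ~900 bp genes
        )
        with pytest.raises(ValueError, match="cannot hold"):
            build_scenario(spec)

    def test_default_world_shape(self, six_genome_spec):
        spec = six_genome_spec
        assert len(spec.genome_ids) == 6
        lux_total = sum(
            len(m.genome_ids) for m in spec.markers if m.kind == "luxI"
        )
        assert lux_total == 5  # five AHL synthases across the set
        spacings = {
            m.params.get("spacing") for m in spec.markers if m.kind == "rieske"
        }
        assert spacings == {17, 19}
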