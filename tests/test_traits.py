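"""Trait screening: reference screens, motifs, cassettes and pI."""

import numpy as np
import pytest

from novocomp import refsets
from novocomp.records import ProteinRecord
from novocomp.synthetic import mutate_protein, random_protein
from novocomp.traits import (
    PKA_EMBOSS,
    ReferenceSet,
    check_luxI_triad,
    detect_cassette,
    isoelectric_point,
    median_proteome_pI,
    net_charge,
    rieske_spacing,
    screen,
)


def _prot(pid, seq, gid="g", rep="c", order=0):
    return ProteinRecord(pid, gid, rep, seq, order)


class TestScreen:
    def test_exact_member_hits_100(self):
        rs = refsets.load_refset("luxI")
        hit = screen([_prot("q", rs.members[0][1])], rs)
        assert len(hit) == 1
        assert hit[0].pct_identity == 100.0

    def test_unrelated_proteome_is_negative(self, rng):
        """The Nqr screen on unrelated proteins: a meaningful zero."""
        prots = [_prot(f"q{i}", random_protein(150, rng), order=i) for i in range(5)]
        assert screen(prots, refsets.load_refset("nqr")) == []

    def test_best_reference_per_query(self, rng):
        rs = refsets.load_refset("luxR")
        cand = mutate_protein(rs.members[0][1], 0.3, rng)
        hits = screen([_prot("q", cand)], rs)
        assert len(hits) == 1  # one row per query even with several passing refs

    def test_filter_superset_property(self, rng):
        rs = refsets.load_refset("luxI")
        cand = [_prot("q", mutate_protein(rs.members[0][1], 0.5, rng))]
        loose = {h.query_id for h in screen(cand, rs, min_identity=0, max_evalue=np.inf)}
        strict = {h.query_id for h in screen(cand, rs)}
        assert strict <= loose

    def test_refset_validation(self):
        with pytest.raises(ValueError):
            ReferenceSet(name="bad", members=[])
        with pytest.raises(ValueError):
            ReferenceSet(name="dup", members=[("a", "MK", ""), ("a", "ML", "")])


class TestLuxITriad:
    def test_reference_vs_itself(self):
        ref = refsets.load_refset("luxI").members[0][1]
        rep = check_luxI_triad(ref, ref)
        assert rep.verdict
        assert rep.residues_found == {"24": "R", "28": "F", "34": "W"}

    def test_substitution_at_28_fails(self):
        ref = refsets.load_refset("luxI").members[0][1]
        broken = ref[:27] + "A" + ref[28:]
        rep = check_luxI_triad(broken, ref)
        assert not rep.verdict
        assert rep.residues_found["28"] == "A"

    def test_planted_divergent_candidate_passes(self, rng):
        """Triad survives detection at ~60% overall identity."""
        ref = refsets.load_refset("luxI").members[0][1]
        cand = mutate_protein(ref, 0.4, rng, preserve=frozenset([23, 27, 33]))
        assert check_luxI_triad(cand, ref).verdict


class TestRieske:
    def test_constructed_spacings(self, rng):
        safe = "ADEFGIKLMNPQRSTVWY"
        for gap in (17, 19):
            s = (
                random_protein(25, rng, safe)
                + "CAH" + random_protein(gap, rng, safe) + "CLLH"
                + random_protein(30, rng, safe)
            )
            assert rieske_spacing(s) == gap

    def test_no_motif(self):
        assert rieske_spacing("MAAAAKLLLG") is None

    def test_locality_under_flanks(self, rng):
        safe = "ADEFGIKLMNPQRSTVWY"
        core = "CAH" + random_protein(17, rng, safe) + "CLLH"
        flank = random_protein(40, rng, safe)
        assert rieske_spacing(core) == rieske_spacing(flank + core + flank) == 17

    def test_planted_markers(self, marker_scenario):
        genomes, truth = marker_scenario
        by_id = {(g.id, p.id): p for g in genomes for p in g.proteome}
        for m in truth.markers["rieske"]:
            p = by_id[(m["genome"], m["protein"])]
            assert rieske_spacing(p.seq) == m["spacing"]


class TestCassette:
    def test_planted_cassette_complete(self, marker_scenario):
        genomes, truth = marker_scenario
        with_cassette = {m["genome"] for m in truth.markers["ect_cassette"]}
        for g in genomes:
            call = detect_cassette(g, refsets.ect_refsets(), window=20000)
            assert call.complete == (g.id in with_cassette)
            if call.complete:
                assert call.window_span <= 20000

    def test_single_component_incomplete(self, rng):
        ectb = refsets.load_refset("ectB").members[0][1]
        from novocomp.records import GenomeRecord, Replicon

        g = GenomeRecord(
            "g",
            [Replicon("c", "ACGT" * 1000)],
            [ProteinRecord("b", "g", "c", ectb, 0, start=100, end=100 + 3 * len(ectb))],
        )
        call = detect_cassette(g, refsets.ect_refsets())
        assert call.components_found == {"EctB"}
        assert not call.complete


class TestIsoelectricPoint:
    def test_basic_and_acidic_extremes(self):
        assert isoelectric_point("KKKKK") > 9
        assert isoelectric_point("DDDDD") < 4.5

    def test_bisection_matches_grid_oracle(self, rng):
        """Bisection root equals a dense-grid scan of the charge curve."""
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        grid = np.linspace(0.0, 14.0, 140001)
        for _ in range(25):
            pep = "".join(rng.choice(aa, rng.integers(5, 120)))
            z = net_charge(pep, grid)
            grid_root = grid[int(np.argmin(np.abs(z)))]
            assert isoelectric_point(pep) == pytest.approx(grid_root, abs=0.001)

    def test_monotonicity_under_appends(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            pep = "".join(rng.choice(aa, 30))
            base = isoelectric_point(pep)
            assert isoelectric_point(pep + "K") >= base - 1e-9
            assert isoelectric_point(pep + "D") <= base + 1e-9

    def test_x_residues_ignored_for_charge(self):
        assert net_charge("KXXK", 7.0) == pytest.approx(net_charge("KK", 7.0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            isoelectric_point("")


class TestMedianPI:
    def test_single_protein(self, rng):
        p = _prot("p", random_protein(50, rng))
        assert median_proteome_pI([p]) == pytest.approx(isoelectric_point(p.seq))

    def test_odd_count_median(self):
        prots = [_prot(f"p{i}", s, order=i) for i, s in enumerate(["DDDDD", "DKDKA", "KKKKK"])]
        pis = sorted(isoelectric_point(p.seq) for p in prots)
        assert median_proteome_pI(prots) == pytest.approx(pis[1])

    def test_even_count_mean_of_middle(self):
        prots = [
            _prot(f"p{i}", s, order=i)
            for i, s in enumerate(["DDDDD", "DDKKA", "DKKKA", "KKKKK"])
        ]
        pis = sorted(isoelectric_point(p.seq) for p in prots)
        assert median_proteome_pI(prots) == pytest.approx(0.5 * (pis[1] + pis[2]))
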