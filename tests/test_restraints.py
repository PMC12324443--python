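"""Distance-restraint mapping: chain maps, measurement, ensembles, clusters."""

import numpy as np
import pytest

from phixlink.config import PipelineConfig
from phixlink.datamodel import Chain, CrosslinkRecord, ProteinRecord, StructureModel
from phixlink.restraints import (SATISFIED, UNMAPPED, VIOLATED, CopyDistance,
                                 DistanceMeasurement, assign_chains,
                                 build_chain_maps, classify, classify_band,
                                 detect_violation_clusters,
                                 ensemble_satisfaction, measure_and_classify,
                                 measure_crosslink)
from phixlink.synthetic import generate_toy_complex, simulate_crosslinks


def _chain(chain_id, seq, coords, start=1):
    n = len(seq)
    return Chain(chain_id, np.arange(start, start + n), seq,
                 np.asarray(coords, dtype=float))


class TestChainMaps:
    def test_exact_subsequence_offsets(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        coords = np.column_stack([3.8 * np.arange(56), np.zeros(56), np.zeros(56)])
        chain = _chain("A", seq[4:60], coords, start=1)
        model = StructureModel("m", [chain], {"A": "P1"})
        m, = build_chain_maps([ProteinRecord("P1", seq)], model)
        assert m.identity == 1.0
        assert m.offset_map[5] == 1 and m.offset_map[60] == 56
        assert 4 not in m.offset_map

    def test_single_substitution_accepted(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        mutated = "A" + seq[1:] if seq[0] != "A" else "C" + seq[1:]
        coords = np.column_stack([3.8 * np.arange(100), np.zeros(100),
                                  np.zeros(100)])
        chain = _chain("A", mutated, coords)
        model = StructureModel("m", [chain], {"A": "P1"})
        m, = build_chain_maps([ProteinRecord("P1", seq)], model)
        assert m.identity == pytest.approx(0.99)

    def test_unrelated_sequence_rejected(self):
        rng = np.random.default_rng(2)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        rejected = 0
        for trial in range(10):
            seq = "".join(rng.choice(aas, size=80))
            other = "".join(rng.choice(aas, size=80))
            coords = np.column_stack([3.8 * np.arange(80), np.zeros(80),
                                      np.zeros(80)])
            model = StructureModel("m", [_chain("A", other, coords)],
                                   {"A": "P1"})
            maps = build_chain_maps([ProteinRecord("P1", seq)], model, 0.95)
            rejected += not maps
        assert rejected == 10  # random ~5% expected identity never reaches 0.95

    def test_assign_chains_by_best_identity(self):
        model, proteins = generate_toy_complex(2, 30, seed=3)
        blank = StructureModel("m", model.chains, {})
        assign_chains(proteins, blank)
        assert blank.chain_to_protein == {"A": "SYNP01", "B": "SYNP02"}


class TestMeasure:
    def _line_model(self):
        a = _chain("A", "KAY", [(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)])
        b = _chain("B", "KAY", [(3, 4, 0), (10, 10, 10), (20, 20, 20)])
        model = StructureModel("m", [a, b], {"A": "PA", "B": "PB"})
        proteins = [ProteinRecord("PA", "KAY"), ProteinRecord("PB", "KAY")]
        return model, proteins

    def test_three_four_five_triangle(self):
        model, proteins = self._line_model()
        maps = build_chain_maps(proteins, model)
        m = measure_crosslink(CrosslinkRecord("PA", 1, "PB", 1), model, maps)
        assert m.min_distance == pytest.approx(5.0)

    def test_minimum_over_copies(self):
        # two copies of PB: one at 40 A, one at 22 A from the PA residue
        a = _chain("A", "K", [(0, 0, 0)])
        b1 = _chain("B", "Y", [(40, 0, 0)])
        b2 = _chain("C", "Y", [(22, 0, 0)])
        model = StructureModel("m", [a, b1, b2],
                               {"A": "PA", "B": "PB", "C": "PB"})
        proteins = [ProteinRecord("PA", "K"), ProteinRecord("PB", "Y")]
        maps = build_chain_maps(proteins, model, min_identity=0.0)
        m = measure_crosslink(CrosslinkRecord("PA", 1, "PB", 1), model, maps)
        assert m.min_distance == pytest.approx(22.0)
        assert {round(c.distance) for c in m.per_copy} == {40, 22}

    def test_self_link_minimizes_over_intra_and_inter_copy(self):
        c1 = _chain("A", "KY", [(0, 0, 0), (50, 0, 0)])
        c2 = _chain("B", "KY", [(0, 5, 0), (50, 5, 0)])
        model = StructureModel("m", [c1, c2], {"A": "PP", "B": "PP"})
        proteins = [ProteinRecord("PP", "KY")]
        maps = build_chain_maps(proteins, model, min_identity=0.0)
        m = measure_crosslink(CrosslinkRecord("PP", 1, "PP", 2), model, maps)
        # intra-copy distance 50, inter-copy sqrt(50^2+25) ~ 50.2;
        # the (res1 on A, res2 on B) placement is NOT shorter, but
        # (res1 on A, res2 on B) reversed assignment gives sqrt(2500+25) too;
        # shortest is intra-copy 50
        assert m.min_distance == pytest.approx(50.0)
        assert len(m.per_copy) == 4  # 2 intra + 2 inter placements

    def test_unmapped_when_residue_absent(self):
        model, proteins = self._line_model()
        maps = build_chain_maps(proteins, model)
        m = measure_crosslink(CrosslinkRecord("PA", 1, "PB", 9), model, maps)
        assert m.status == UNMAPPED and m.per_copy == []

    def test_symmetry_of_endpoint_order(self):
        model, proteins = self._line_model()
        maps = build_chain_maps(proteins, model)
        m1 = measure_crosslink(CrosslinkRecord("PA", 2, "PB", 3), model, maps)
        m2 = measure_crosslink(CrosslinkRecord("PB", 3, "PA", 2), model, maps)
        assert m1.min_distance == m2.min_distance


class TestClassify:
    def _m(self, d):
        xl = CrosslinkRecord("PA", 1, "PB", 2)
        return DistanceMeasurement(xl, "s", [CopyDistance("A", 1, "B", 2, d)],
                                   d, VIOLATED)

    @pytest.mark.parametrize("d,expected", [
        (26.9, SATISFIED),
        (27.0, SATISFIED),   # inclusive cutoff
        (27.1, VIOLATED),
    ])
    def test_binary_threshold(self, d, expected):
        assert classify(self._m(d), 27.0) == expected

    @pytest.mark.parametrize("d,band", [
        (10.0, 0),
        (21.5, 1),           # lower edge belongs to the middle band
        (25.0, 1),
        (28.5, 2),
        (40.0, 2),
    ])
    def test_distance_bands(self, d, band):
        assert classify_band(self._m(d), (21.5, 28.5)) == band

    def test_unmapped_is_preserved(self):
        xl = CrosslinkRecord("PA", 1, "PB", 2)
        m = DistanceMeasurement(xl, "s", [], float("inf"), UNMAPPED)
        assert classify(m, 27.0) == UNMAPPED
        assert classify_band(m) is None


class TestEnsemble:
    def test_satisfied_on_any_member(self):
        a = _chain("A", "K", [(0, 0, 0)])
        b_far = _chain("B", "Y", [(30, 0, 0)])
        b_near = _chain("B", "Y", [(20, 0, 0)])
        proteins = [ProteinRecord("PA", "K"), ProteinRecord("PB", "Y")]
        s1 = StructureModel("s1", [a, b_far], {"A": "PA", "B": "PB"})
        s2 = StructureModel("s2", [a, b_near], {"A": "PA", "B": "PB"})
        xl = [CrosslinkRecord("PA", 1, "PB", 1)]
        cfg = PipelineConfig(min_chain_identity=0.0)
        rep = ensemble_satisfaction(xl, [s1, s2], proteins, cfg)
        assert rep.summary == 1.0
        assert rep.best_structure[xl[0].pair_key] == "s2"
        rep1 = ensemble_satisfaction(xl, [s1], proteins, cfg)
        assert rep1.summary == 0.0

    def test_summary_invariant_to_structure_order(self):
        from phixlink.synthetic import displace_chain
        model, proteins = generate_toy_complex(3, 40, seed=9)
        alt = displace_chain(model, "C", seed=10)
        records, _ = simulate_crosslinks(model, proteins, 30, 5, seed=1)
        cfg = PipelineConfig()
        fwd = ensemble_satisfaction(records, [model, alt], proteins, cfg)
        rev = ensemble_satisfaction(records, [alt, model], proteins, cfg)
        assert fwd.summary == rev.summary
        assert fwd.satisfied_any == rev.satisfied_any

    def test_adding_structures_never_decreases_summary(self):
        from phixlink.synthetic import displace_chain
        model, proteins = generate_toy_complex(3, 40, seed=11)
        alt = displace_chain(model, "C", seed=12)
        records, _ = simulate_crosslinks(model, proteins, 30, 10, seed=2)
        cfg = PipelineConfig()
        one = ensemble_satisfaction(records, [alt], proteins, cfg)
        two = ensemble_satisfaction(records, [alt, model], proteins, cfg)
        assert two.summary >= one.summary

    def test_simulated_links_fully_satisfied_on_generating_structure(self):
        model, proteins = generate_toy_complex(3, 50, seed=13)
        records, truth = simulate_crosslinks(model, proteins, 50, 0, seed=3)
        rep = ensemble_satisfaction(records, [model], proteins,
                                    PipelineConfig())
        assert rep.summary == 1.0

    def test_requires_at_least_one_structure(self):
        with pytest.raises(ValueError):
            ensemble_satisfaction([], [], [], PipelineConfig())


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_min_over_copies_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_chains = int(rng.integers(2, 5))
        model, proteins = generate_toy_complex(n_chains, 30, seed)
        # make the last chain a genuine second copy of the first protein
        last = model.chains[-1]
        model.chains[-1] = Chain(last.chain_id, last.resnums,
                                 model.chains[0].sequence, last.coords)
        model.chain_to_protein[last.chain_id] = "SYNP01"
        maps = build_chain_maps(proteins, model, min_identity=0.0)
        accs = sorted(set(model.chain_to_protein.values()))
        for _ in range(40):
            pa, pb = rng.choice(accs, size=2)
            ra = int(rng.integers(1, 31))
            rb = int(rng.integers(1, 31))
            if pa == pb and ra == rb:
                continue
            xl = CrosslinkRecord(pa, ra, pb, rb)
            m = measure_crosslink(xl, model, maps)
            best = np.inf
            for c1 in model.chains:
                if model.chain_to_protein[c1.chain_id] != xl.protein_a:
                    continue
                for c2 in model.chains:
                    if model.chain_to_protein[c2.chain_id] != xl.protein_b:
                        continue
                    if c1.chain_id == c2.chain_id and xl.residue_a == xl.residue_b:
                        continue
                    d = np.linalg.norm(c1.coords[xl.residue_a - 1] -
                                       c2.coords[xl.residue_b - 1])
                    best = min(best, float(d))
            if np.isinf(best):
                assert m.status == UNMAPPED
            else:
                assert m.min_distance == best


class TestViolationClusters:
    def _violated(self, pa, ra, pb, rb):
        xl = CrosslinkRecord(pa, ra, pb, rb)
        return DistanceMeasurement(xl, "s",
                                   [CopyDistance("A", ra, "B", rb, 40.0)],
                                   40.0, VIOLATED)

    def test_three_colocated_links_form_one_cluster(self):
        ms = [self._violated("X", 10, "Y", 200),
              self._violated("X", 12, "Y", 205),
              self._violated("X", 15, "Y", 198)]
        clusters = detect_violation_clusters(ms, window=10, min_size=3)
        assert len(clusters) == 1 and clusters[0].size == 3
        assert clusters[0].span_a == (10, 15)

    def test_distant_third_link_leaves_pair_cluster(self):
        ms = [self._violated("X", 10, "Y", 200),
              self._violated("X", 12, "Y", 205),
              self._violated("X", 90, "Y", 400)]
        clusters = detect_violation_clusters(ms, window=10, min_size=2)
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_scattered_violations_yield_no_cluster(self):
        ms = [self._violated(f"X{i}", 10, f"Y{i}", 20) for i in range(5)]
        assert detect_violation_clusters(ms, window=10, min_size=2) == []

    def test_satisfied_links_ignored(self):
        sat = self._violated("X", 11, "Y", 201)
        sat.status = SATISFIED
        ms = [self._violated("X", 10, "Y", 200), sat,
              self._violated("X", 12, "Y", 205)]
        clusters = detect_violation_clusters(ms, window=10, min_size=2)
        assert clusters[0].size == 2
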