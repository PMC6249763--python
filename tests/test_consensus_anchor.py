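import itertools

import numpy as np
import pytest
from scipy import stats

import mapanchor as ma
from mapanchor.consensus_anchor import (
    assign_chromosome,
    build_anchor_plan,
    compare_maps,
    consensus_positions,
    order_scaffolds,
    ordering_objective,
    orient_scaffold,
    spearman_rho,
)
from mapanchor.io_formats import GeneticMap, MapPlacement


def _map(name, weight, rows):
    """rows: (marker, lg, cm, scaffold, pos)"""
    return GeneticMap(name, weight,
                      [MapPlacement(*r) for r in rows])


class TestSpearman:
    def test_identical_orders(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)

    def test_reversed(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_single_swap_is_point_eight(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 12/60
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1], [1])


class TestAssignChromosome:
    def test_weighted_majority(self):
        a = _map("A", 2, [("m1", 5, 1, "s", 10), ("m2", 5, 2, "s", 20),
                          ("m3", 5, 3, "s", 30)])
        c = _map("C", 1, [("m4", 11, 1, "s", 40), ("m5", 11, 2, "s", 50)])
        assert assign_chromosome("s", [a, c]) == 5  # score 6 vs 2

    def test_weight_beats_count(self):
        a = _map("A", 1, [("m1", 1, 1, "s", 10)])
        b = _map("B", 2, [("m2", 1, 1, "s", 20), ("m3", 1, 2, "s", 30)])
        assert assign_chromosome("s", [a, b]) == 1

    def test_tie_goes_unplaced(self):
        a = _map("A", 1, [("m1", 1, 1, "s", 10)])
        b = _map("B", 1, [("m2", 2, 1, "s", 20)])
        assert assign_chromosome("s", [a, b]) == 0

    def test_unmapped_scaffold_unplaced(self):
        a = _map("A", 1, [("m1", 1, 1, "other", 10)])
        assert assign_chromosome("s", [a]) == 0


class TestConsensusPositions:
    def test_agreeing_maps(self):
        # both maps span 0..10 cM on LG1; scaffold at 2 cM -> 0.2
        a = _map("A", 2, [("x", 1, 0, "edge", 1), ("m", 1, 2, "s", 10),
                          ("y", 1, 10, "edge2", 5)])
        b = _map("B", 2, [("p", 1, 0, "edge", 2), ("q", 1, 2, "s", 99),
                          ("r", 1, 10, "edge2", 9)])
        pos = consensus_positions(["s"], 1, [a, b])
        assert pos["s"] == pytest.approx(0.2)

    def test_weighted_average(self):
        # 0.1 at weight 2 and 0.4 at weight 1 -> (0.2 + 0.4)/3 = 0.2
        a = _map("A", 2, [("x", 1, 0, "e1", 1), ("m", 1, 1, "s", 10),
                          ("y", 1, 10, "e2", 5)])
        b = _map("B", 1, [("p", 1, 0, "e1", 2), ("q", 1, 4, "s", 99),
                          ("r", 1, 10, "e2", 9)])
        pos = consensus_positions(["s"], 1, [a, b])
        assert pos["s"] == pytest.approx(0.2)

    def test_single_map_position(self):
        a = _map("A", 2, [("x", 1, 0, "e1", 1), ("m", 1, 7, "s", 10),
                          ("y", 1, 10, "e2", 5)])
        pos = consensus_positions(["s"], 1, [a])
        assert pos["s"] == pytest.approx(0.7)


def _random_instance(rng, n_scaffolds, n_maps):
    """A random ordering instance: scaffolds with 1-3 markers per map."""
    scaffolds = [f"s{i}" for i in range(n_scaffolds)]
    maps = []
    for k in range(n_maps):
        rows = []
        mid = 0
        for s in scaffolds:
            for _ in range(rng.integers(1, 4)):
                mid += 1
                rows.append((f"M{k}_{mid}", 1, float(rng.uniform(0, 100)),
                             s, int(rng.integers(1, 1_000_000))))
        maps.append(_map(f"map{k}", float(rng.integers(1, 3)), rows))
    return scaffolds, maps


def _brute_force_best(scaffolds, maps):
    """Independent enumeration oracle over the collinearity objective,
    computed directly from map placements with scipy."""
    best_j, best = -np.inf, None
    for perm in itertools.permutations(sorted(scaffolds)):
        rank = {s: i for i, s in enumerate(perm)}
        j = 0.0
        for gmap in maps:
            pls = [p for p in gmap.placements if p.scaffold in rank]
            if len(pls) < 2:
                continue
            cm = [p.cm for p in pls]
            induced = [rank[p.scaffold] * 10**9 + p.pos for p in pls]
            rho = stats.spearmanr(cm, induced).statistic
            if np.isfinite(rho):
                j += gmap.weight * rho
        if j > best_j:
            best_j, best = j, perm
    return best_j


class TestOrdering:
    def test_monotone_single_map(self):
        rows = [("m1", 1, 1.0, "a", 10), ("m2", 1, 2.0, "b", 10),
                ("m3", 1, 3.0, "c", 10)]
        gmap = _map("A", 2, rows)
        order = order_scaffolds(["b", "c", "a"], 1, [gmap])
        assert order == ["a", "b", "c"]
        assert ordering_objective(order, 1, [gmap]) == pytest.approx(2.0)

    def test_optimizer_attains_enumerated_maximum(self):
        rng = np.random.default_rng(77)
        for _ in range(40):
            scaffolds, maps = _random_instance(rng, int(rng.integers(3, 7)),
                                               int(rng.integers(1, 4)))
            oracle = _brute_force_best(scaffolds, maps)
            got = order_scaffolds(scaffolds, 1, maps)
            assert ordering_objective(got, 1, maps) == pytest.approx(oracle, abs=1e-9)

    def test_hillclimb_matches_enumeration_on_small_instances(self):
        rng = np.random.default_rng(78)
        hits = 0
        for _ in range(30):
            scaffolds, maps = _random_instance(rng, 5, 2)
            oracle = _brute_force_best(scaffolds, maps)
            got = order_scaffolds(scaffolds, 1, maps, method="hillclimb")
            hits += ordering_objective(got, 1, maps) >= oracle - 1e-9
        # steepest ascent can stall in a local optimum, but rarely
        assert hits >= 27

    def test_equal_positions_tie_break_by_id(self):
        rows = [("m1", 1, 5.0, "b", 10), ("m2", 1, 5.0, "a", 10)]
        gmap = _map("A", 1, rows)
        assert order_scaffolds(["b", "a"], 1, [gmap])[0] == "a"

    def test_weight_monotonicity(self):
        """Raising a map's weight never lowers that map's rho at the optimum."""
        rng = np.random.default_rng(79)
        for _ in range(10):
            scaffolds, maps = _random_instance(rng, 5, 2)

            def rho_of(gmap, order):
                rank = {s: i for i, s in enumerate(order)}
                pls = [p for p in gmap.placements if p.scaffold in rank]
                cm = [p.cm for p in pls]
                ind = [rank[p.scaffold] * 10**9 + p.pos for p in pls]
                return stats.spearmanr(cm, ind).statistic

            base = rho_of(maps[0], order_scaffolds(scaffolds, 1, maps))
            boosted_maps = [GeneticMap(maps[0].name, maps[0].weight * 2,
                                       list(maps[0].placements)), maps[1]]
            boosted = rho_of(boosted_maps[0],
                             order_scaffolds(scaffolds, 1, boosted_maps))
            assert boosted >= base - 1e-9


class TestOrientation:
    def test_monotone_increasing(self):
        gmap = _map("A", 2, [("m1", 1, 5.0, "s", 100_000),
                             ("m2", 1, 5.8, "s", 500_000)])
        assert orient_scaffold("s", 1, [gmap]) == "+"

    def test_monotone_decreasing(self):
        gmap = _map("A", 2, [("m1", 1, 5.8, "s", 100_000),
                             ("m2", 1, 5.0, "s", 500_000)])
        assert orient_scaffold("s", 1, [gmap]) == "-"

    def test_identical_cm_is_undetermined(self):
        gmap = _map("A", 2, [("m1", 1, 5.0, "s", 100_000),
                             ("m2", 1, 5.0, "s", 500_000)])
        assert orient_scaffold("s", 1, [gmap]) == "?"

    def test_single_marker_is_undetermined(self):
        gmap = _map("A", 2, [("m1", 1, 5.0, "s", 100_000)])
        assert orient_scaffold("s", 1, [gmap]) == "?"


class TestPlanRecovery:
    def test_conservation_every_scaffold_once(self, small_world, small_plan):
        _t, scaffolds, _m = small_world
        seen = [a.scaffold for a in small_plan.anchors]
        assert sorted(seen) == sorted(set(seen))
        assert set(scaffolds.ids()) <= set(seen)

    def test_zero_noise_recovers_truth(self):
        """Noise-free maps reproduce the true order and orientation for every
        scaffold with >= 2 markers at distinct cM."""
        for seed in (1, 2, 3):
            truth, scaffolds = ma.simulate_genome(
                n_chrom=3, chrom_len=500_000, n_scaffolds=15, seed=seed,
                markers_per_chrom=50, cm_per_mb=25.0)
            maps = [ma.true_map(truth, "MH", 2.0),
                    ma.true_map(truth, "YM", 2.0, marker_fraction=0.8,
                                seed=seed + 100)]
            plan = ma.build_anchor_plan(scaffolds, maps)
            orient_truth = {s: o for s, _c, _st, o in truth.scaffold_truth}
            for chrom, _len in truth.chromosomes:
                got = plan.ordered_scaffolds(chrom)
                expected = [s for s in truth.true_order(chrom) if s in got]
                assert got == expected
            for a in plan.anchors:
                if a.orientation in "+-":
                    assert a.orientation == orient_truth[a.scaffold]

    def test_jittered_maps_mostly_recover_order(self):
        """>= 95% of anchored scaffolds keep their true order position under
        0.5-cM jitter and 2% local swaps, across 20 seeds."""
        correct = total = 0
        for seed in range(20):
            truth, scaffolds = ma.simulate_genome(
                n_chrom=3, chrom_len=500_000, n_scaffolds=15, seed=seed,
                markers_per_chrom=50, cm_per_mb=25.0)
            maps = [
                ma.perturb_map(ma.true_map(truth, "MH", 2.0),
                               jitter_cm=0.5, swap_rate=0.02, seed=seed + 200),
                ma.perturb_map(ma.true_map(truth, "YM", 2.0),
                               jitter_cm=0.5, swap_rate=0.02, seed=seed + 300),
            ]
            plan = ma.build_anchor_plan(scaffolds, maps)
            for chrom, _len in truth.chromosomes:
                got = plan.ordered_scaffolds(chrom)
                expected = [s for s in truth.true_order(chrom) if s in got]
                total += len(got)
                correct += sum(g == e for g, e in zip(got, expected))
        assert total > 0
        assert correct / total >= 0.95


class TestCompareMaps:
    def test_consensus_from_single_map_is_unity(self):
        truth, scaffolds = ma.simulate_genome(n_chrom=2, chrom_len=500_000,
                                              n_scaffolds=8, seed=41,
                                              markers_per_chrom=40,
                                              cm_per_mb=25.0)
        gmap = ma.true_map(truth, "MH", 2.0)
        plan = ma.build_anchor_plan(scaffolds, [gmap])
        conc = compare_maps(plan, [gmap])
        rho = conc.to_frame()["rho"].dropna()
        assert (rho > 0.999).all()

    def test_no_shared_markers_recorded_missing(self):
        gmap = _map("A", 1, [("m1", 1, 1.0, "sX", 10), ("m2", 1, 2.0, "sX", 20)])
        other = _map("B", 1, [("m3", 2, 1.0, "sY", 10), ("m4", 2, 2.0, "sY", 20)])
        plan = build_anchor_plan(["sY"], [other])
        conc = compare_maps(plan, [gmap, other])
        row = conc.to_frame().query("map == 'A'")
        assert np.isnan(row["rho"]).all()
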