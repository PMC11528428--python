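import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smlmeq import (
    ClusterSizeDistribution,
    MoleculeMap,
    ParameterError,
    UndefinedConstantError,
    cluster_molecules,
    compute_ka,
    compute_kd_molar,
    csr_reference,
    energy_equivalent,
    extrapolate_to_infinite_dilution,
    mask_from_polygon,
    match_pairs,
    nnd_distribution,
    occupancy_analysis,
    poisson_reference_constants,
    stepwise_constants,
    threshold_scan,
)

from conftest import csr_disk


class TestNndDistribution:
    def test_homo_pair(self):
        np.testing.assert_allclose(
            nnd_distribution([[0, 0], [20.0, 0]]), [20.0, 20.0]
        )

    def test_hetero_single(self):
        np.testing.assert_allclose(
            nnd_distribution([[0, 0]], [[40.0, 0]]), [40.0]
        )

    def test_brute_force_oracle(self, rng):
        pts = rng.uniform(0, 1000, (300, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        np.testing.assert_allclose(nnd_distribution(pts), d.min(axis=1))
        other = rng.uniform(0, 1000, (200, 2))
        dx = np.linalg.norm(pts[:, None] - other[None], axis=-1)
        np.testing.assert_allclose(nnd_distribution(pts, other), dx.min(axis=1))


class TestMatchPairs:
    def test_single_pair_within_threshold(self):
        m = match_pairs([[0, 0]], [[10.0, 0]], 25.0)
        assert m.n_pairs == 1 and m.free_a.size == 0 and m.free_b.size == 0

    def test_greedy_chain_takes_closest(self):
        # a0 -10- b0 -12- a1: only the 10 nm pair forms, a1 stays free
        a = [[0.0, 0.0], [22.0, 0.0]]
        b = [[10.0, 0.0]]
        m = match_pairs(a, b, 15.0)
        assert m.n_pairs == 1
        assert m.pairs[0].tolist() == [0, 0]
        assert m.free_a.tolist() == [1]

    def test_homo_matching_is_exclusive(self):
        pts = [[0.0, 0.0], [5.0, 0.0], [10.0, 0.0]]
        m = match_pairs(pts, None, 20.0)
        assert m.n_pairs == 1
        assert m.free_a.size == 1

    def test_greedy_is_near_optimal_matching(self):
        # greedy is maximal, so always >= optimum/2; at these densities it
        # is within 1 of the maximum matching in almost every realization
        import networkx as nx

        close = 0
        trials = 200
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            a = rng.uniform(0, 60, (6, 2))
            b = rng.uniform(0, 60, (6, 2))
            m = match_pairs(a, b, 30.0)
            g = nx.Graph()
            for i in range(6):
                for j in range(6):
                    if np.linalg.norm(a[i] - b[j]) <= 30.0:
                        g.add_edge(("a", i), ("b", j))
            optimum = len(nx.max_weight_matching(g, maxcardinality=True))
            assert math.ceil(optimum / 2) <= m.n_pairs <= optimum
            if m.n_pairs >= optimum - 1:
                close += 1
        assert close / trials >= 0.95

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_conservation_of_molecules(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 500, (40, 2))
        b = rng.uniform(0, 500, (30, 2))
        m = match_pairs(a, b, 50.0)
        assert 2 * m.n_pairs + m.free_a.size + m.free_b.size == 70
        mh = match_pairs(a, None, 50.0)
        assert 2 * mh.n_pairs + mh.free_a.size == 40


class TestConstants:
    def test_ka_arithmetic(self):
        res = compute_ka(50, 100, 100, 100.0)
        assert res.ka_um2 == pytest.approx(0.5)
        assert res.log_k == pytest.approx(math.log10(0.5))

    def test_zero_pairs_flagged_not_raised(self):
        res = compute_ka(0, 100, 100, 100.0)
        assert res.ka_um2 == 0.0
        assert not res.defined and math.isnan(res.log_k)

    def test_zero_free_raises(self):
        with pytest.raises(UndefinedConstantError):
            compute_ka(10, 0, 5, 100.0)

    def test_homo_uses_squared_free_count(self):
        res = compute_ka(10, 20, None, 50.0)
        assert res.ka_um2 == pytest.approx(10 * 50.0 / 400)
        assert res.mode == "homo_association"

    def test_molar_concentration_one_molecule(self):
        # 1 molecule in 1 um^2 x 100 nm = 1e-16 L -> 16.6 nM
        res = compute_kd_molar(1, 1, 1, 1.0, 100.0)
        assert res.kd_molar == pytest.approx(1.66e-8, rel=0.01)

    def test_depth_doubling_halves_kd(self):
        k100 = compute_kd_molar(10, 50, 200, 20.0, 100.0).kd_molar
        k200 = compute_kd_molar(10, 50, 200, 20.0, 200.0).kd_molar
        assert k200 == pytest.approx(k100 / 2)

    def test_delta_g_conversion(self):
        assert energy_equivalent(0.3) == pytest.approx(743.0, abs=1.0)

    def test_closed_loop_recovery_no_noise(self):
        import smlmeq as sq

        poly = sq.make_cell_pattern((18, 18), 200.0, 0.1, seed=5)
        gt = sq.place_molecules(
            poly, 50.0, -2.0, pair_separation_nm=0.0, loc_sigma_nm=0.0, seed=6
        )
        a = gt.molecules.select("A")
        b = gt.molecules.select("B")
        m = match_pairs(a, b, 10.0)
        res = compute_ka(m.n_pairs, m.free_a.size, m.free_b.size, gt.pattern_area_um2)
        assert res.log_k == pytest.approx(-2.0, abs=0.05)


class TestExtrapolation:
    def test_exact_line_intercept(self):
        series = extrapolate_to_infinite_dilution(
            [(0.1, -1.5), (0.2, -1.4), (0.3, -1.3)]
        )
        assert series.intercept == pytest.approx(-1.6)
        assert series.slope == pytest.approx(1.0)
        assert series.intercept_se == pytest.approx(0.0, abs=1e-12)

    def test_repeated_abscissa_rejected(self):
        with pytest.raises(ParameterError):
            extrapolate_to_infinite_dilution([(0.1, -1.5), (0.1, -1.4)])

    def test_noisy_recovery_within_two_se(self, rng):
        hits = 0
        for _ in range(40):
            x = np.linspace(50, 400, 8)
            y = -1.6 + 0.001 * x + rng.normal(0, 0.05, 8)
            s = extrapolate_to_infinite_dilution(list(zip(x, y)))
            if abs(s.intercept + 1.6) <= 2 * s.intercept_se:
                hits += 1
        assert hits >= 32  # ~95% coverage, loose binomial bound


class TestClusters:
    def test_isolated_points_are_monomers(self):
        dist = cluster_molecules([[0, 0], [1000.0, 0], [0, 1000.0]], 25.0, 10.0)
        assert dist.n_j.tolist() == [3]

    def test_chain_is_transitively_linked(self):
        pts = [[0.0, 0], [10.0, 0], [20.0, 0], [30.0, 0]]
        dist = cluster_molecules(pts, 15.0, 10.0)
        assert dist.n_j[3] == 1 and dist.total_molecules == 4

    def test_union_find_oracle(self, rng):
        pts = rng.uniform(0, 2000, (400, 2))
        linkage = 60.0
        dist = cluster_molecules(pts, linkage, 4.0)
        parent = list(range(400))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(400):
            for j in range(i + 1, 400):
                if np.linalg.norm(pts[i] - pts[j]) <= linkage:
                    parent[find(i)] = find(j)
        sizes = np.bincount([find(i) for i in range(400)])
        expect = np.bincount(sizes[sizes > 0])[1:]
        np.testing.assert_array_equal(dist.n_j, expect)

    def test_stepwise_arithmetic(self):
        dist = ClusterSizeDistribution(n_j=np.array([100, 20]), area_um2=50.0)
        steps = stepwise_constants(dist)
        assert steps == [(2, pytest.approx(0.1))]

    def test_stepwise_skips_empty_class(self):
        dist = ClusterSizeDistribution(n_j=np.array([50, 0, 4]), area_um2=10.0)
        assert [j for j, _ in stepwise_constants(dist)] == []

    def test_geometric_distribution_constant_steps(self):
        # n_j = n_1 (q n_1 / A)^(j-1)  ->  Ka_j = q for every j
        n1, q, area = 200.0, 0.05, 40.0
        n_j = np.array([n1 * (q * n1 / area) ** (j - 1) for j in range(1, 6)])
        steps = stepwise_constants(ClusterSizeDistribution(n_j=n_j, area_um2=area))
        for _, ka in steps:
            assert ka == pytest.approx(q)

    def test_reference_curve_scales_as_inverse_j(self):
        ref = poisson_reference_constants(0.1, [2, 4, 8])
        assert ref[0][1] == pytest.approx(0.1)
        assert ref[1][1] == pytest.approx(0.05)
        assert ref[2][1] == pytest.approx(0.025)


class TestCsrReference:
    def _mask(self):
        from shapely.geometry import box

        return mask_from_polygon(box(0, 0, 5.0, 5.0), 50.0, (0, 0, 5000, 5000))

    def _map(self, rng, n=200):
        pts = rng.uniform(500, 4500, (n, 2))
        species = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
        return MoleculeMap(x=pts[:, 0], y=pts[:, 1], species=species)

    def test_deterministic_and_counts_preserved(self, rng):
        mask = self._mask()
        mols = self._map(rng)
        r1 = csr_reference(mols, mask, "both_csr", seed=5)
        r2 = csr_reference(mols, mask, "both_csr", seed=5)
        np.testing.assert_array_equal(r1.x, r2.x)
        assert (r1.species == mols.species).all()

    def test_points_inside_mask(self, rng):
        mask = self._mask()
        ref = csr_reference(self._map(rng), mask, "both_csr", seed=1)
        assert mask.contains(ref.x, ref.y).all()

    def test_partial_scenario_keeps_other_species_fixed(self, rng):
        mask = self._mask()
        mols = self._map(rng)
        ref = csr_reference(mols, mask, "a_csr", seed=2)
        b = mols.species == "B"
        np.testing.assert_array_equal(ref.x[b], mols.x[b])
        assert not np.array_equal(ref.x[~b], mols.x[~b])


class TestThresholdScan:
    def test_null_data_has_small_delta(self, rng):
        from shapely.geometry import box

        mask = mask_from_polygon(box(0, 0, 8.0, 8.0), 50.0, (0, 0, 8000, 8000))
        n = 4000
        pts = rng.uniform(0, 8000, (n, 2))
        species = np.array(["A", "B"])[rng.integers(0, 2, n)]
        mols = MoleculeMap(x=pts[:, 0], y=pts[:, 1], species=species)
        points, _ = threshold_scan(mols, mask, [20.0, 40.0], n_csr=8, seed=3)
        for p in points:
            assert abs(p.delta) < 0.1

    def test_associated_data_peaks_near_pair_scale(self):
        import smlmeq as sq

        gt, frame = sq.simulate_field(120.0, -1.0, pattern_area_um2=60.0, seed=21)
        mask = mask_from_polygon(gt.pattern_polygon, 50.0, frame)
        points, best = threshold_scan(
            gt.molecules, mask, [10, 20, 40, 80, 160], n_csr=6, seed=4
        )
        assert 10 <= best <= 40  # pair distances ~5 nm Rayleigh scale
        deltas = {p.proximity_nm: p.delta for p in points}
        assert deltas[160] < deltas[best]


class TestOccupancy:
    def test_fraction_bound_tabulated(self):
        receptors = np.array([[0.0, 0], [30.0, 0], [60.0, 0]])
        labels = np.zeros(3, dtype=int)  # one cluster of j=3
        ligands = np.array([[0.0, 5.0], [30.0, -5.0]])
        occ = occupancy_analysis(receptors, labels, ligands, proximity_nm=10.0)
        assert occ.counts == {(3, 2): 1}
        assert occ.p_bound[3] == pytest.approx(2.0 / 3.0)

    def test_saturated_sites(self):
        receptors = np.array([[0.0, 0], [100.0, 0], [200.0, 0]])
        labels = np.array([0, 0, 1])
        ligands = receptors + np.array([2.0, 0.0])
        occ = occupancy_analysis(receptors, labels, ligands, 10.0)
        assert occ.p_bound == {2: 1.0, 1: 1.0}

    def test_random_reference_binds_less_than_associated(self, rng):
        import smlmeq as sq
        from shapely.geometry import box

        poly = box(0, 0, 10.0, 10.0)
        gt = sq.place_molecules(poly, 80.0, -1.0, loc_sigma_nm=2.0, seed=31)
        rec = gt.molecules.select("A")
        lig = gt.molecules.select("B")
        mask = mask_from_polygon(poly, 50.0, (0, 0, 10000, 10000))
        dist = cluster_molecules(rec, 40.0, 100.0)
        occ = occupancy_analysis(
            rec, dist.labels, lig, 15.0, randomization="ligand_csr", mask=mask, seed=32
        )
        shared = [j for j in occ.p_bound if j in occ.reference_p_bound and occ.p_bound[j] > 0]
        assert shared
        better = sum(occ.p_bound[j] > occ.reference_p_bound[j] for j in shared)
        assert better >= 0.8 * len(shared)
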