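import itertools

import numpy as np
import pytest

from cernet.cerna_infer import (
    CeRNAConfig,
    CeRNAPair,
    candidate_pairs,
    correlation_baseline,
    empirical_sc_pvalue,
    hypergeom_filter,
    hypergeom_shared_pvalue,
    infer_cerna_pairs,
    pairs_to_frame,
    partial_correlation,
    pearson_filter,
    sc_filter,
    sensitivity_correlation,
)
from cernet.preprocess import bh_adjust

from conftest import make_interactions, zscore_matrix


def correlated_rows(rng, r, n=100):
    """Two rows whose *empirical* correlation equals r exactly."""
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    z = z - x * (z @ x) / (x @ x)
    z = (z - z.mean()) / z.std()
    y = r * x + np.sqrt(1 - r * r) * z
    return x, y


class TestCandidatePairs:
    def test_one_mirna_three_targets(self):
        net = make_interactions([("m", "a"), ("m", "b"), ("m", "c")])
        pairs = candidate_pairs(net)
        assert {(p.rna_i, p.rna_j) for p in pairs} == {("a", "b"), ("a", "c"),
                                                       ("b", "c")}
        assert all(p.shared_mirnas == ("m",) for p in pairs)

    def test_disjoint_regulators_no_pair(self):
        net = make_interactions([("m1", "a"), ("m2", "b")])
        assert candidate_pairs(net) == []

    def test_counts(self):
        net = make_interactions(
            [("m1", "a"), ("m2", "a"), ("m1", "b"), ("m3", "b"), ("m4", "c")]
        )
        pairs = candidate_pairs(net, n_total_mirnas=10)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.n_total, p.n_i, p.n_j, p.n_ij) == (10, 2, 2, 1)

    def test_matches_quadratic_oracle(self, rng):
        mirnas = [f"m{i}" for i in range(8)]
        rnas = [f"g{i:02d}" for i in range(30)]
        edges = sorted(
            {
                (mirnas[rng.integers(8)], rnas[rng.integers(30)])
                for _ in range(70)
            }
        )
        net = make_interactions(edges)
        got = {(p.rna_i, p.rna_j): set(p.shared_mirnas)
               for p in candidate_pairs(net)}

        regs = {}
        for m, g in edges:
            regs.setdefault(g, set()).add(m)
        oracle = {}
        for a, b in itertools.combinations(sorted(regs), 2):
            shared = regs[a] & regs[b]
            if shared:
                oracle[(a, b)] = shared
        assert got == oracle


class TestPearsonFilter:
    def test_identical_vectors_kept(self, rng):
        x = rng.standard_normal(50)
        expr = zscore_matrix([x, x + 0.0], ["a", "b"])
        pairs = [CeRNAPair("a", "b", ("m",), 5, 1, 1, 1)]
        kept = pearson_filter(pairs, expr, CeRNAConfig())
        assert kept and kept[0].pearson_r == pytest.approx(1.0)
        assert kept[0].pearson_p == 0.0

    def test_r_below_threshold_dropped_despite_tiny_p(self, rng):
        x, y = correlated_rows(rng, 0.49, n=5000)
        expr = zscore_matrix([x, y], ["a", "b"])
        pairs = [CeRNAPair("a", "b", ("m",), 5, 1, 1, 1)]
        kept = pearson_filter(pairs, expr, CeRNAConfig())
        assert kept == []
        assert pairs[0].pearson_p < 1e-10  # significant yet dropped

    def test_r_matches_sum_formula_oracle(self, rng):
        for _ in range(100):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30)
            expr = zscore_matrix([x, y], ["a", "b"])
            p = CeRNAPair("a", "b", ("m",), 5, 1, 1, 1)
            pearson_filter([p], expr, CeRNAConfig(min_corr=-1.0))
            xs = (x - x.mean()) / x.std()
            ys = (y - y.mean()) / y.std()
            oracle = float(np.sum(xs * ys) / 30)
            assert p.pearson_r == pytest.approx(oracle, abs=1e-12)

    def test_too_few_samples_error(self):
        expr = zscore_matrix([[0.0, 1.0], [1.0, 0.0]], ["a", "b"])
        with pytest.raises(ValueError):
            pearson_filter([CeRNAPair("a", "b", ("m",), 5, 1, 1, 1)], expr,
                           CeRNAConfig())


class TestHypergeomSharedPvalue:
    def test_full_overlap_of_three(self):
        # DERIVED: of the C(10,3)=120 equally likely draws exactly one
        # achieves overlap 3
        assert hypergeom_shared_pvalue(10, 3, 3, 3) == pytest.approx(1 / 120)

    def test_forced_overlap_is_one(self):
        assert hypergeom_shared_pvalue(5, 5, 2, 2) == pytest.approx(1.0)

    def test_single_draw(self):
        assert hypergeom_shared_pvalue(10, 1, 1, 1) == pytest.approx(0.1)

    def test_bound_violations_error(self):
        with pytest.raises(ValueError):
            hypergeom_shared_pvalue(10, 3, 3, 4)
        with pytest.raises(ValueError):
            hypergeom_shared_pvalue(3, 5, 2, 1)

    def test_enumeration_oracle_small(self):
        # spot-check against subset enumeration (full sweep in acceptance)
        for n_tot, ni, nj, nij in [(8, 3, 4, 2), (9, 4, 4, 1), (7, 5, 3, 3)]:
            universe = range(n_tot)
            target = set(range(nj))
            total = hits = 0
            for draw in itertools.combinations(universe, ni):
                total += 1
                hits += len(set(draw) & target) >= nij
            assert hypergeom_shared_pvalue(n_tot, ni, nj, nij) == pytest.approx(
                hits / total, abs=1e-12
            )


class TestHypergeomFilter:
    def test_single_pair(self):
        p = CeRNAPair("a", "b", ("m",), 20, 4, 4, 3)
        p.hyper_p = np.nan
        kept = hypergeom_filter([p], CeRNAConfig())
        assert p.hyper_p_adj == pytest.approx(p.hyper_p)

    def test_uniform_ties(self):
        pairs = [
            CeRNAPair(f"a{i:03d}", f"b{i:03d}", ("m",), 100, 10, 10, 5)
            for i in range(100)
        ]
        hypergeom_filter(pairs, CeRNAConfig())
        adjs = {p.hyper_p_adj for p in pairs}
        assert len(adjs) == 1
        assert adjs.pop() == pytest.approx(pairs[0].hyper_p)

    def test_matches_bh_oracle(self, rng):
        pairs = []
        for i in range(25):
            n_i = int(rng.integers(2, 8))
            n_j = int(rng.integers(2, 8))
            n_ij = int(rng.integers(1, min(n_i, n_j) + 1))
            pairs.append(CeRNAPair(f"a{i:02d}", f"b{i:02d}", ("m",) * 1, 30,
                                   n_i, n_j, n_ij))
        hypergeom_filter(pairs, CeRNAConfig())
        oracle = bh_adjust([p.hyper_p for p in pairs])
        np.testing.assert_allclose([p.hyper_p_adj for p in pairs], oracle,
                                   atol=1e-15)


class TestPartialCorrelation:
    def test_empty_conditioning_equals_pearson(self, rng):
        x, y = correlated_rows(rng, 0.6)
        pc, _ = partial_correlation(x, y, None)
        assert pc == pytest.approx(0.6, abs=1e-12)

    def test_first_order_recursion_oracle(self, rng):
        # DERIVED: pc = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))
        for _ in range(50):
            x = rng.standard_normal(60)
            y = rng.standard_normal(60)
            z = rng.standard_normal(60)
            r_xy = np.corrcoef(x, y)[0, 1]
            r_xz = np.corrcoef(x, z)[0, 1]
            r_yz = np.corrcoef(y, z)[0, 1]
            oracle = (r_xy - r_xz * r_yz) / np.sqrt(
                (1 - r_xz**2) * (1 - r_yz**2)
            )
            pc, _ = partial_correlation(x, y, z)
            assert pc == pytest.approx(oracle, abs=1e-10)

    def test_recursion_textbook_values(self):
        # r_xy=0.8, r_xz=r_yz=0.6 -> pc = (0.8-0.36)/0.64 = 0.6875
        assert (0.8 - 0.36) / np.sqrt(0.64 * 0.64) == pytest.approx(0.6875)

    def test_x_linear_in_z_annihilated(self, rng):
        z = rng.standard_normal(50)
        x = 2.0 * z + 1.0
        y = rng.standard_normal(50)
        pc, p = partial_correlation(x, y, z)
        assert abs(pc) < 1e-8
        assert p == 1.0

    def test_rank_deficient_z_errors(self, rng):
        z = rng.standard_normal(40)
        Z = np.column_stack([z, 2 * z])
        with pytest.raises(ValueError, match="rank"):
            partial_correlation(rng.standard_normal(40),
                                rng.standard_normal(40), Z)

    def test_symmetry_in_arguments(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        Z = rng.standard_normal((50, 2))
        assert partial_correlation(x, y, Z) == partial_correlation(y, x, Z)


class TestSensitivityCorrelation:
    def _pair(self, shared):
        return CeRNAPair("a", "b", tuple(shared), 10, len(shared),
                         len(shared), len(shared))

    def test_sc_identity(self, rng):
        m = rng.standard_normal(80)
        x = -0.7 * m + 0.5 * rng.standard_normal(80)
        y = -0.7 * m + 0.5 * rng.standard_normal(80)
        expr = zscore_matrix([x, y], ["a", "b"])
        mirna = zscore_matrix([m], ["m1"])
        p = self._pair(["m1"])
        sensitivity_correlation(p, expr, mirna)
        assert p.sc == p.pearson_r - p.pc  # exact identity

    def test_irrelevant_shared_mirnas_give_small_sc(self):
        # DERIVED: null simulation at n = 200
        scs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(200)
            y = rng.standard_normal(200)
            m = rng.standard_normal(200)
            expr = zscore_matrix([x, y], ["a", "b"])
            mirna = zscore_matrix([m], ["m1"])
            p = self._pair(["m1"])
            sensitivity_correlation(p, expr, mirna)
            scs.append(abs(p.sc))
        assert np.mean(scs) < 0.05

    def test_fully_mediated_pair_sc_near_corr(self, rng):
        m = rng.standard_normal(200)
        x = m + 1e-4 * rng.standard_normal(200)
        y = m + 1e-4 * rng.standard_normal(200)
        expr = zscore_matrix([x, y], ["a", "b"])
        mirna = zscore_matrix([m], ["m1"])
        p = self._pair(["m1"])
        sensitivity_correlation(p, expr, mirna)
        assert p.pearson_r > 0.999
        assert abs(p.pc) < 0.2
        assert p.sc == pytest.approx(p.pearson_r - p.pc)


class TestEmpiricalScPvalue:
    def _setup(self, rng, n=200, pool_size=8):
        m = rng.standard_normal((pool_size, n))
        shared = ["p0", "p1"]
        x = -0.8 * m[0] - 0.8 * m[1] + 0.4 * rng.standard_normal(n)
        y = -0.8 * m[0] - 0.8 * m[1] + 0.4 * rng.standard_normal(n)
        mirna = zscore_matrix(m, [f"p{i}" for i in range(pool_size)])
        expr = zscore_matrix([x, y], ["a", "b"])
        pair = CeRNAPair("a", "b", tuple(shared), pool_size, 2, 2, 2)
        sensitivity_correlation(pair, expr, mirna)
        return pair, expr, mirna

    def test_pool_equal_to_shared_set_gives_zero(self, rng):
        pair, expr, mirna = self._setup(rng)
        cfg = CeRNAConfig(sc_resamples=50)
        with pytest.warns(UserWarning):
            p = empirical_sc_pvalue(pair, expr, mirna, ["p0", "p1"], cfg)
        assert p == 0.0  # strict '>' never satisfied when sampled == original

    def test_planted_pair_significant(self):
        # DERIVED: shared miRNAs are the only true regulators in the pool
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pair, expr, mirna = self._setup(rng)
            cfg = CeRNAConfig(sc_resamples=200, seed=seed)
            p = empirical_sc_pvalue(pair, expr, mirna,
                                    list(mirna.feature_ids), cfg)
            hits += p < 0.05
        assert hits >= 18

    def test_deterministic_under_seed(self, rng):
        pair, expr, mirna = self._setup(rng)
        cfg = CeRNAConfig(sc_resamples=100, seed=7)
        pool = list(mirna.feature_ids)
        a = empirical_sc_pvalue(pair, expr, mirna, pool, cfg)
        b = empirical_sc_pvalue(pair, expr, mirna, pool, cfg)
        assert a == b

    def test_pool_too_small_errors(self, rng):
        pair, expr, mirna = self._setup(rng)
        with pytest.raises(ValueError):
            empirical_sc_pvalue(pair, expr, mirna, ["p0"], CeRNAConfig())


class TestScFilter:
    def _pair(self, sc, pc_p, emp_p):
        p = CeRNAPair("a", "b", ("m",), 10, 1, 1, 1)
        p.sc, p.pc_p, p.sc_empirical_p = sc, pc_p, emp_p
        return p

    def test_negative_sc_dropped(self):
        assert sc_filter([self._pair(-0.1, 0.001, 0.001)], CeRNAConfig()) == []

    def test_all_conditions_met_kept(self):
        kept = sc_filter([self._pair(0.2, 0.01, 0.01)], CeRNAConfig())
        assert len(kept) == 1

    def test_disabled_filter_passes_everything(self):
        pairs = [self._pair(-0.5, 0.9, 0.9), self._pair(0.2, 0.01, 0.01)]
        cfg = CeRNAConfig(sc_filter_enabled=False)
        assert len(sc_filter(pairs, cfg)) == 2
        assert len(sc_filter(pairs, CeRNAConfig())) <= 2  # monotone relaxation


class TestPipelineProperties:
    def test_stage_outputs_nest(self, rng):
        # filter pipeline is monotone: each stage's survivors are a subset
        m = rng.standard_normal((4, 120))
        x = -0.9 * m[0] - 0.9 * m[1] + 0.3 * rng.standard_normal(120)
        y = -0.9 * m[0] - 0.9 * m[1] + 0.3 * rng.standard_normal(120)
        w = rng.standard_normal(120)
        expr = zscore_matrix([x, y, w], ["a", "b", "c"])
        mirna = zscore_matrix(m, [f"m{i}" for i in range(4)])
        net = make_interactions(
            [("m0", "a"), ("m1", "a"), ("m0", "b"), ("m1", "b"), ("m0", "c")]
        )
        final, cand = infer_cerna_pairs(net, expr, mirna,
                                        CeRNAConfig(sc_resamples=100, seed=1))
        ids_final = {(p.rna_i, p.rna_j) for p in final}
        ids_cand = {(p.rna_i, p.rna_j) for p in cand}
        assert ids_final <= ids_cand
        frame = pairs_to_frame(final)
        if len(frame):
            np.testing.assert_array_equal(
                frame["sc"], frame["pearson_r"] - frame["pc"]
            )

    def test_pair_statistics_symmetric(self, rng):
        x, y = correlated_rows(rng, 0.7)
        z = rng.standard_normal(100)
        r1, p1 = partial_correlation(x, y, z)
        r2, p2 = partial_correlation(y, x, z)
        assert (r1, p1) == (r2, p2)


class TestCorrelationBaseline:
    def test_positively_correlated_mirna_edge_removed(self, rng):
        m = rng.standard_normal(100)
        up = 0.9 * m + 0.1 * rng.standard_normal(100)  # positively regulated
        down = -0.9 * m + 0.1 * rng.standard_normal(100)
        down2 = -0.9 * m + 0.1 * rng.standard_normal(100)
        expr = zscore_matrix([up, down, down2], ["u", "d", "e"])
        mirna = zscore_matrix([m], ["m0"])
        net = make_interactions([("m0", "u"), ("m0", "d"), ("m0", "e")])
        pairs, cand = correlation_baseline(expr, net, mirna)
        members = {r for p in cand for r in (p.rna_i, p.rna_j)}
        assert "u" not in members
        assert {(p.rna_i, p.rna_j) for p in pairs} == {("d", "e")}

    def test_null_data_nearly_empty(self):
        # DERIVED: planted-null data keeps <= 5% of candidate pairs
        kept = cand_n = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = rng.standard_normal((3, 150))
            rows = rng.standard_normal((8, 150))
            expr = zscore_matrix(rows, [f"g{i}" for i in range(8)])
            mirna = zscore_matrix(m, [f"m{i}" for i in range(3)])
            edges = [(f"m{i % 3}", f"g{i % 8}") for i in range(20)]
            net = make_interactions(sorted(set(edges)))
            pairs, cand = correlation_baseline(expr, net, mirna)
            kept += len(pairs)
            cand_n += len(cand)
        assert cand_n == 0 or kept / max(cand_n, 1) <= 0.05
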