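import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popband import (BandMatrix, amova_two_level, grouped_amova,
                     pairwise_phi_pt, permutation_test, squared_distance)
from popband.synthetic import SyntheticPopGenConfig, simulate_band_matrix

from conftest import random_band_matrix


def brute_force_amova(values, labels):
    """Independent oracle: explicit pairwise squared distances and the
    sums-of-squares identities evaluated term by term."""
    n = len(labels)
    d2 = [[sum((a - b) ** 2 for a, b in zip(values[i], values[j]))
           for j in range(n)] for i in range(n)]
    groups = sorted(set(labels))
    k = len(groups)
    ss_total = sum(d2[i][j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_within += sum(d2[i][j] for i in idx for j in idx if i < j) / len(idx)
    ss_among = ss_total - ss_within
    vw = ss_within / (n - k)
    sizes = [labels.count(g) for g in groups]
    n0 = (n - sum(s * s for s in sizes) / n) / (k - 1)
    va = max((ss_among / (k - 1) - vw) / n0, 0.0)
    phi = va / (va + vw) if va + vw > 0 else 0.0
    return ss_among, ss_within, va, vw, phi


class TestSquaredDistance:
    def test_mismatch_counts(self):
        assert squared_distance([1, 0, 1, 1], [1, 1, 0, 1]) == 2
        assert squared_distance([1, 1], [1, 1]) == 0
        assert squared_distance([0, 1, 0], [1, 0, 1]) == 3
        with pytest.raises(ValueError):
            squared_distance([1, 0], [1, 0, 1])


class TestAmovaTwoLevel:
    def test_complete_fixation_gives_phi_one(self):
        vals = np.array([[0, 0, 0]] * 3 + [[1, 1, 1]] * 3)
        m = BandMatrix(tuple(f"s{i}" for i in range(6)),
                       ("A",) * 3 + ("B",) * 3, ("l1", "l2", "l3"), vals)
        r = amova_two_level(m)
        assert r.vw == 0.0
        assert r.phi_pt == pytest.approx(1.0)
        assert r.pct_among == pytest.approx(100.0)

    def test_identical_population_multisets_give_phi_zero(self):
        block = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0]])
        vals = np.vstack([block, block])
        m = BandMatrix(tuple(f"s{i}" for i in range(6)),
                       ("A",) * 3 + ("B",) * 3, ("l1", "l2", "l3"), vals)
        assert amova_two_level(m).phi_pt == 0.0

    def test_zero_total_variance_is_degenerate(self):
        vals = np.ones((4, 3), dtype=int)
        m = BandMatrix(tuple(f"s{i}" for i in range(4)),
                       ("A", "A", "B", "B"), ("l1", "l2", "l3"), vals)
        r = amova_two_level(m)
        assert r.degenerate and r.phi_pt == 0.0

    def test_small_population_rejected(self):
        vals = np.array([[1, 0], [0, 1], [1, 1]])
        m = BandMatrix(("a", "b", "c"), ("A", "A", "B"), ("l1", "l2"), vals)
        with pytest.raises(ValueError, match="< 2 samples"):
            amova_two_level(m)

    def test_unbalanced_toy_instance_matches_oracle(self):
        vals = np.array([[1, 0, 1, 0], [1, 1, 1, 0], [0, 0, 1, 1],
                         [0, 1, 0, 1], [0, 1, 0, 0]])
        labels = ("A", "A", "A", "B", "B")
        m = BandMatrix(tuple(f"s{i}" for i in range(5)), labels,
                       tuple(f"l{j}" for j in range(4)), vals)
        r = amova_two_level(m)
        ss_a, ss_w, va, vw, phi = brute_force_amova(vals.tolist(), list(labels))
        assert r.ss_among == pytest.approx(ss_a)
        assert r.ss_within == pytest.approx(ss_w)
        assert r.va == pytest.approx(va)
        assert r.vw == pytest.approx(vw)
        assert r.phi_pt == pytest.approx(phi)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 8), st.integers(1, 6),
           st.integers(2, 3))
    def test_oracle_equivalence_on_small_instances(self, seed, n, L, k):
        rng = np.random.default_rng(seed)
        m = random_band_matrix(rng, n=n, L=L, k=min(k, n // 2))
        r = amova_two_level(m)
        *_, va, vw, phi = brute_force_amova(m.values.tolist(),
                                            list(m.population_labels))
        assert r.phi_pt == pytest.approx(phi, abs=1e-12)
        assert r.va == pytest.approx(va) and r.vw == pytest.approx(vw)

    def test_invariant_under_relabelling_and_locus_permutation(self, study_matrix):
        m, _ = study_matrix
        r = amova_two_level(m)
        relabel = {"CG": "w", "DN": "x", "PQ": "y", "CD": "z"}
        r2 = amova_two_level(m, tuple(relabel[p] for p in m.population_labels))
        assert r2.phi_pt == pytest.approx(r.phi_pt)
        rng = np.random.default_rng(0)
        cp = rng.permutation(m.n_loci)
        m3 = BandMatrix(m.sample_ids, m.population_labels,
                        tuple(m.locus_ids[j] for j in cp), m.values[:, cp])
        assert amova_two_level(m3).phi_pt == pytest.approx(r.phi_pt)

    def test_pct_among_is_hundred_times_phi(self, study_matrix):
        m, _ = study_matrix
        r = amova_two_level(m)
        assert r.pct_among == pytest.approx(100.0 * r.phi_pt)
        assert r.pct_among + r.pct_within == pytest.approx(100.0)


class TestPermutationTest:
    def test_strong_signal_reaches_minimum_p(self, study_matrix):
        m, _ = study_matrix
        r = permutation_test(m, n_perm=999, seed=42)
        assert r.p_value == pytest.approx(1 / 1000)

    def test_same_seed_reproduces_p(self, tiny_matrix):
        r1 = permutation_test(tiny_matrix, n_perm=199, seed=9)
        r2 = permutation_test(tiny_matrix, n_perm=199, seed=9)
        assert r1.p_value == r2.p_value

    def test_p_bounded_below_by_one_over_nperm_plus_one(self, tiny_matrix):
        r = permutation_test(tiny_matrix, n_perm=99, seed=1)
        assert r.p_value >= 1 / 100


class TestPairwiseAndGrouped:
    def test_pairwise_symmetric_and_order_independent(self, study_matrix):
        m, _ = study_matrix
        pw = pairwise_phi_pt(m, n_perm=99, seed=5)
        assert pw[("CG", "DN")] is pw[("DN", "CG")]
        # reversing the sample order must not change any pair's statistic
        rev = BandMatrix(m.sample_ids[::-1], m.population_labels[::-1],
                        m.locus_ids, m.values[::-1],
                        primer_of_locus=m.primer_of_locus)
        pw_rev = pairwise_phi_pt(rev, n_perm=99, seed=5)
        for key in (("CG", "DN"), ("PQ", "CD")):
            assert pw[key].phi_pt == pytest.approx(pw_rev[key].phi_pt)
            assert pw[key].p_value == pw_rev[key].p_value

    def test_population_vs_identical_copy_is_zero(self):
        block = np.array([[1, 0, 1, 0], [0, 1, 1, 0], [1, 1, 0, 1]])
        vals = np.vstack([block, block])
        m = BandMatrix(tuple(f"s{i}" for i in range(6)),
                       ("A",) * 3 + ("B",) * 3,
                       tuple(f"l{j}" for j in range(4)), vals)
        pw = pairwise_phi_pt(m, n_perm=99, seed=3)
        assert pw[("A", "B")].phi_pt == 0.0

    def test_identity_grouping_equals_plain_amova(self, study_matrix):
        m, _ = study_matrix
        r = amova_two_level(m)
        g = grouped_amova(m, {p: p for p in m.populations})
        assert g.phi_pt == pytest.approx(r.phi_pt)

    def test_two_unit_pooling_and_single_group_error(self, study_matrix):
        m, _ = study_matrix
        g = grouped_amova(m, {"CG": "main", "DN": "main",
                              "PQ": "isl", "CD": "isl"})
        assert g.df_among == 1
        assert 0.0 <= g.phi_pt <= 1.0
        with pytest.raises(ValueError, match="single group"):
            grouped_amova(m, {p: "one" for p in m.populations})


class TestCalibration:
    def test_type_i_error_near_nominal_under_null(self):
        """Permutation p at alpha = 0.05 rejects ~5% of null datasets."""
        n_rep, alpha = 220, 0.05
        rejections = 0
        base = np.random.SeedSequence(12345).generate_state(n_rep) % (2**31)
        for i in range(n_rep):
            cfg = SyntheticPopGenConfig(
                population_names=("A", "B"), n_per_population=(10, 10),
                n_loci=25, primer_counts=None, fst=0.0, seed=int(base[i]))
            m, _ = simulate_band_matrix(cfg)
            r = permutation_test(m, n_perm=99, seed=int(base[i]) + 1)
            rejections += r.p_value <= alpha
        rate = rejections / n_rep
        tol = 3 * np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= tol

    def test_mean_phi_monotone_in_simulated_differentiation(self):
        """Average estimated Phi_PT increases along an Fst grid."""
        grid = [0.0, 0.05, 0.1, 0.2, 0.3]
        n_rep = 50
        means = []
        for f in grid:
            vals = []
            for rep in range(n_rep):
                cfg = SyntheticPopGenConfig(
                    population_names=("A", "B", "C"), n_per_population=(12, 12, 12),
                    n_loci=30, primer_counts=None, fst=f,
                    seed=100_000 + rep * 10 + int(f * 100))
                m, _ = simulate_band_matrix(cfg)
                vals.append(amova_two_level(m).phi_pt)
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))
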