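"""Community metrics: filters, evenness, beta diversity, turnover, stability."""

import numpy as np
import pandas as pd
import pytest

from richsync.metrics import (
    baselga_decompose,
    community_metrics,
    evar,
    evenness,
    filter_rare,
    filter_rare_cube,
    jaccard_beta,
    mean_patch_richness,
    pielou,
    stability,
    turnover_rate,
)
from richsync.simulate import AbundanceCube


def presence_from_lists(*patch_lists):
    """Species x patch boolean matrix from per-patch species lists."""
    pool = sorted(set().union(*patch_lists))
    return np.array([[sp in pl for pl in patch_lists] for sp in pool])


class TestFilterRare:
    @staticmethod
    def _table(cells_present, P=10, T=10, species="sp1"):
        # one focal species present in `cells_present` distinct cells, plus a
        # ubiquitous background species so the table is never empty
        rows = []
        for p in range(P):
            for t in range(T):
                rows.append(("bg", p, t, 1.0))
        for k in range(cells_present):
            rows.append((species, k % P, k // P, 2.0))
        return pd.DataFrame(rows, columns=["species", "patch", "time", "abundance"])

    def test_boundary_count_retained(self):
        # 5 of 100 cells with threshold 5% -> exactly at the >= boundary
        out = filter_rare(self._table(5), min_occupancy=0.05)
        assert "sp1" in set(out["species"])

    def test_below_boundary_removed(self):
        out = filter_rare(self._table(4), min_occupancy=0.05)
        assert "sp1" not in set(out["species"])

    def test_zero_threshold_is_identity(self):
        t = self._table(2)
        out = filter_rare(t, min_occupancy=0.0)
        pd.testing.assert_frame_equal(out, t)

    def test_cube_filter_agrees_with_table_filter(self, rng):
        N = (rng.uniform(0, 1, size=(8, 5, 12)) > 0.7) * rng.uniform(1, 9, (8, 5, 12))
        kept_cube = filter_rare_cube(N, 0.05)
        survivors_cube = {s for s in range(8) if kept_cube[s].any()}
        occ = (N > 0).reshape(8, -1).sum(axis=1)
        assert survivors_cube == {s for s in range(8) if occ[s] >= 0.05 * 5 * 12}


class TestRichnessEvenness:
    def test_mean_richness_of_constant_matrix(self):
        assert mean_patch_richness(np.full((4, 6), 7)) == 7.0

    def test_mean_richness_simple_average(self):
        assert mean_patch_richness(np.array([[1, 3], [2, 2]])) == 2.0

    def test_mean_richness_matches_loop_oracle(self, rng):
        R = rng.integers(0, 9, size=(7, 11))
        total = sum(R[p, t] for p in range(7) for t in range(11))
        assert mean_patch_richness(R) == pytest.approx(total / 77)

    def test_evar_equal_abundances_is_one(self):
        assert evar(np.array([4.0, 4.0, 4.0])) == pytest.approx(1.0)

    def test_evar_matches_hand_formula(self):
        # abundances (10, 1): var of ln over the 2 species (population var)
        ln = np.log([10.0, 1.0])
        expected = 1 - (2 / np.pi) * np.arctan(np.var(ln))
        assert evar(np.array([10.0, 1.0])) == pytest.approx(expected, abs=1e-12)

    def test_pielou_equal_abundances_is_one(self):
        assert pielou(np.array([2.0, 2.0, 2.0, 2.0])) == pytest.approx(1.0)

    def test_evenness_over_cube_averages_cells(self):
        # two cells: one perfectly even (Evar 1), one with the (10,1) value
        N = np.zeros((2, 1, 2))
        N[:, 0, 0] = [5.0, 5.0]
        N[:, 0, 1] = [10.0, 1.0]
        expected = (1.0 + evar(np.array([10.0, 1.0]))) / 2
        assert evenness(N) == pytest.approx(expected)

    def test_single_species_cells_rejected(self):
        N = np.zeros((2, 1, 2))
        N[0] = 3.0
        with pytest.raises(ValueError, match="2 or more species"):
            evenness(N)


class TestBetaDiversity:
    def test_identical_lists_give_similarity_one(self):
        pres = presence_from_lists({"a", "b"}, {"a", "b"}, {"a", "b"})
        assert jaccard_beta(pres) == pytest.approx(1.0)

    def test_disjoint_lists_give_zero(self):
        pres = presence_from_lists({"a"}, {"b"})
        assert jaccard_beta(pres) == pytest.approx(0.0)

    def test_half_overlap_hand_count(self):
        # A={a,b,c}, B={b,c,d}: |A&B|=2, |A|B|=4 -> 0.5
        pres = presence_from_lists({"a", "b", "c"}, {"b", "c", "d"})
        assert jaccard_beta(pres) == pytest.approx(0.5)

    def test_invariant_to_abundance_rescaling(self, rng):
        N = (rng.uniform(0, 1, (6, 4, 8)) > 0.6) * rng.uniform(1, 5, (6, 4, 8))
        assert jaccard_beta(N) == pytest.approx(jaccard_beta(N * 10))


class TestBaselga:
    def test_identical_lists_no_dissimilarity(self):
        pres = presence_from_lists({"a", "b"}, {"a", "b"})
        assert baselga_decompose(pres) == (0.0, 0.0)

    def test_nested_pair_is_pure_nestedness(self):
        # A strictly inside B: no replacement, all dissimilarity from
        # richness difference
        pres = presence_from_lists({"a", "b"}, {"a", "b", "c", "d"})
        jtu, jne = baselga_decompose(pres)
        assert jtu == 0.0
        assert jne == pytest.approx(2 / 4)  # (b+c)/(a+b+c) = 2/4

    def test_three_lists_match_pairwise_formula_oracle(self):
        lists = [{"a", "b", "c"}, {"b", "c", "d"}, {"a", "d", "e"}]
        pres = presence_from_lists(*lists)
        jtu_vals, jne_vals = [], []
        for i in range(1, 3):
            for j in range(i):
                A = len(lists[i] & lists[j])
                B = len(lists[i] - lists[j])
                C = len(lists[j] - lists[i])
                jac = (B + C) / (A + B + C)
                jtu = 2 * min(B, C) / (A + 2 * min(B, C))
                jtu_vals.append(jtu)
                jne_vals.append(jac - jtu)
        jtu, jne = baselga_decompose(pres)
        assert jtu == pytest.approx(np.mean(jtu_vals), abs=1e-12)
        assert jne == pytest.approx(np.mean(jne_vals), abs=1e-12)

    @pytest.mark.parametrize("method", ["pairwise", "multisite"])
    def test_components_nonnegative_and_sum_to_total(self, rng, method):
        for _ in range(10):
            pres = rng.uniform(0, 1, size=(10, 5)) > 0.5
            if not pres.any(axis=0).all():
                continue
            jtu, jne = baselga_decompose(pres, method=method)
            assert jtu >= -1e-12 and jne >= -1e-12
            if method == "multisite":
                sizes = pres.sum(axis=0).astype(float)
                a = pres.T.astype(float) @ pres.astype(float)
                ii, jj = np.tril_indices(5, k=-1)
                B = (sizes[:, None] - a)[ii, jj]
                C = (sizes[None, :] - a)[ii, jj]
                core = sizes.sum() - pres.any(axis=1).sum()
                total = (np.minimum(B, C).sum() + np.maximum(B, C).sum()) / (
                    core + np.minimum(B, C).sum() + np.maximum(B, C).sum()
                )
                assert jtu + jne == pytest.approx(total, abs=1e-12)


class TestTurnover:
    def test_constant_composition_zero(self):
        pres = np.ones((3, 2, 5))
        assert turnover_rate(pres) == 0.0

    def test_complete_replacement_is_one(self):
        # alternate between two disjoint sets each step
        pres = np.zeros((2, 1, 4))
        pres[0, 0, ::2] = 1
        pres[1, 0, 1::2] = 1
        assert turnover_rate(pres) == 1.0

    def test_hand_counted_example(self):
        # t1={a,b}, t2={b,c}: (1 gain + 1 loss) / 3 observed = 2/3
        pres = np.zeros((3, 1, 2))
        pres[[0, 1], 0, 0] = 1   # a, b
        pres[[1, 2], 0, 1] = 1   # b, c
        assert turnover_rate(pres) == pytest.approx(2 / 3)

    def test_both_empty_pairs_skipped(self):
        pres = np.zeros((2, 1, 4))
        pres[0, 0, 0] = 1
        pres[0, 0, 3] = 1
        # pairs: (t0,t1): loss/1; (t1,t2): both empty -> skipped; (t2,t3): gain/1
        assert turnover_rate(pres) == pytest.approx(1.0)


class TestStability:
    def test_constant_totals_give_zero(self):
        N = np.ones((2, 3, 5))
        assert stability(N) == 0.0

    def test_hand_computed_cv(self):
        # totals (10, 20, 10, 20): -sd/mean with sample sd
        N = np.zeros((1, 1, 4))
        N[0, 0] = [10, 20, 10, 20]
        totals = np.array([10.0, 20, 10, 20])
        expected = -totals.std(ddof=1) / totals.mean()
        assert stability(N) == pytest.approx(expected, abs=1e-12)

    def test_scale_invariant_and_nonpositive(self, rng):
        N = rng.uniform(0, 5, size=(4, 3, 10))
        s = stability(N)
        assert s <= 0
        assert stability(N * 10) == pytest.approx(s, abs=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            stability(np.zeros((2, 2, 5)))


class TestCommunityMetrics:
    def test_full_aggregation_on_simulated_cube(self, small_cube):
        m = community_metrics(small_cube)
        assert 0 <= m.beta_jaccard <= 1
        assert 0 <= m.turnover_rate <= 1
        assert 0 <= m.evenness <= 1
        assert m.stability <= 0
        assert m.beta_turnover_component >= 0
        assert m.beta_nestedness_component >= 0
        assert 0 <= m.mean_richness <= small_cube.n_species
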