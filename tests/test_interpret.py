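"""Attention-site analysis: expansion, top-k, permutation null, z-score."""

import itertools

import numpy as np
import pytest

from crossdti.interpret import (ExpandedAttentionMap, NullProfile,
                                analyze_sites, consistency_number,
                                expand_attention, null_profile,
                                residue_aggregate, shift_analysis,
                                top_sites, topk_sensitivity, z_score)


def identity_spans(n):
    return [(i, i + 1) for i in range(n)]


def simple_map(values):
    values = np.asarray(values, dtype=float)
    return ExpandedAttentionMap(values=values,
                                protein_spans=identity_spans(values.shape[0]),
                                drug_spans=identity_spans(values.shape[1]))


class TestExpansion:
    def test_single_character_tokens_identity(self):
        w = np.arange(6, dtype=float).reshape(2, 3)
        out = expand_attention(w, identity_spans(2), identity_spans(3))
        np.testing.assert_array_equal(out.values, w)

    def test_multi_residue_token_broadcasts(self):
        # protein token 2 covers residues 3..5; single-atom drug tokens
        w = np.array([[0.1], [0.2], [0.7]])
        out = expand_attention(w, [(0, 1), (1, 2), (2, 5)], [(0, 1)])
        np.testing.assert_allclose(out.values[:, 0],
                                   [0.1, 0.2, 0.7, 0.7, 0.7])

    def test_head_axis_is_averaged(self):
        w = np.stack([np.zeros((2, 2)), np.ones((2, 2))])
        out = expand_attention(w, identity_spans(2), identity_spans(2))
        np.testing.assert_allclose(out.values, 0.5)

    def test_pad_rows_discarded(self):
        w = np.random.default_rng(0).random((6, 4))
        out = expand_attention(w, identity_spans(3), identity_spans(2))
        assert out.values.shape == (3, 2)
        np.testing.assert_array_equal(out.values, w[:3, :2])

    def test_inconsistent_spans_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            expand_attention(np.ones((2, 2)), [(0, 1), (2, 3)],
                             identity_spans(2))


class TestTopSites:
    def test_unique_maximum_first(self):
        m = simple_map([[0.0, 0.9], [0.1, 0.2]])
        sites = top_sites(m, k=1)
        assert (sites[0].residue, sites[0].atom) == (1, 2)

    def test_uniform_map_tie_break_row_major(self):
        sites = top_sites(simple_map(np.ones((2, 3))), k=5)
        assert [(s.residue, s.atom) for s in sites] == \
            [(1, 1), (1, 2), (1, 3), (2, 1), (2, 2)]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.random((6, 4))
        sites = top_sites(simple_map(vals), k=24)
        oracle = sorted(((r + 1, a + 1, vals[r, a])
                         for r in range(6) for a in range(4)),
                        key=lambda t: (-t[2], t[0], t[1]))
        assert [(s.residue, s.atom) for s in sites] == \
            [(r, a) for r, a, _ in oracle]

    def test_k_larger_than_cells_warns_and_returns_all(self):
        with pytest.warns(UserWarning, match="exceeds"):
            sites = top_sites(simple_map(np.ones((2, 2))), k=10)
        assert len(sites) == 4


class TestConsistency:
    def test_counting_example(self):
        m = simple_map(np.eye(15))
        sites = top_sites(m, k=3)  # residues 1..3 on the diagonal
        sites = [s._replace(residue=r) for s, r in zip(sites, (5, 10, 12))]
        assert consistency_number(sites, {10, 99}) == 1

    def test_empty_binding_set_zero(self):
        sites = top_sites(simple_map(np.ones((3, 3))), k=4)
        assert consistency_number(sites, frozenset()) == 0

    def test_all_sites_on_binding_residues(self):
        sites = top_sites(simple_map(np.ones((3, 2))), k=6)
        assert consistency_number(sites, {1, 2, 3}) == 6


class TestNull:
    def test_closed_form_expectation(self):
        # k sites on distinct residues, b random binding residues:
        # E[consistency] = k * b / L
        L, b, k = 40, 6, 10
        residues = list(range(1, k + 1))
        prof = null_profile([(residues, b, L)], iterations=4000, seed=0)
        expected = k * b / L
        se = prof.draws.std() / np.sqrt(len(prof.draws))
        assert abs(prof.mean - expected) < 3 * se + 1e-9

    def test_exact_enumeration_small_protein(self):
        # L <= 10: enumerate all binding placements exactly
        L, b = 8, 3
        residues = [1, 1, 4, 7]  # multiplicity on residue 1
        exact = np.mean([sum(r in subset for r in residues)
                         for subset in itertools.combinations(
                             range(1, L + 1), b)])
        prof = null_profile([(residues, b, L)], iterations=6000, seed=1)
        se = prof.draws.std() / np.sqrt(len(prof.draws))
        assert abs(prof.mean - exact) < 3 * se + 1e-9

    def test_full_coverage_binding_always_k(self):
        prof = null_profile([([1, 2, 3], 5, 5)], iterations=50, seed=2)
        assert (prof.draws == 3).all()

    def test_fixed_seed_reproducible(self):
        entry = [([2, 5, 9], 2, 12)]
        a = null_profile(entry, iterations=100, seed=3)
        b = null_profile(entry, iterations=100, seed=3)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_binding_larger_than_protein_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            null_profile([([1], 9, 5)], iterations=10, seed=0)


class TestZScore:
    def test_reported_summary_statistics_reproduce(self):
        # printed summary: observed 2.020 against null mean 1.64, SD 0.119
        rng = np.random.default_rng(0)
        draws = rng.normal(1.64, 0.119, 200000)
        draws = (draws - draws.mean()) / draws.std() * 0.119 + 1.64
        z = z_score(2.020, NullProfile(draws=draws))
        assert z == pytest.approx(3.186, rel=0.005)

    def test_observed_equal_to_null_mean_is_zero(self):
        prof = NullProfile(draws=np.array([1.0, 2.0, 3.0]))
        assert z_score(2.0, prof) == 0.0

    def test_linear_in_observed(self):
        prof = NullProfile(draws=np.array([0.0, 2.0]))
        assert z_score(3.0, prof) == 2 * z_score(1.5, prof) + 1.0

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            z_score(1.0, NullProfile(draws=np.ones(10)))


class TestAnalyses:
    def make_pairs(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(n):
            vals = rng.random((20, 6))
            binding = frozenset(int(x) + 1 for x in
                                rng.choice(20, size=4, replace=False))
            pairs.append((simple_map(vals), binding))
        return pairs

    def test_topk_consistency_non_decreasing_in_k(self):
        pairs = self.make_pairs()
        results = topk_sensitivity(pairs, [5, 10, 30, 60],
                                   iterations=200, seed=0)
        means = [r.experimental_mean for r in results]
        assert means == sorted(means)

    def test_k_equal_full_map_counts_all_binding_cells(self):
        pairs = self.make_pairs(n=3)
        for amap, binding in pairs:
            with pytest.warns(UserWarning):
                sites = top_sites(amap, k=10000)
            # every binding residue contributes one count per drug column
            assert consistency_number(sites, binding) == \
                len(binding) * amap.drug_length

    def test_shift_zero_reproduces_base_analysis(self):
        pairs = self.make_pairs()
        base = analyze_sites(pairs, k=15, iterations=300, seed=4)
        table = shift_analysis(pairs, shifts=(-1, 0, 1), k=15,
                               iterations=300, seed=4)
        zero = [r for r in table if r.shift == 0][0]
        assert zero.experimental_mean == base.experimental_mean
        assert zero.z == base.z

    def test_constructed_offset_is_recovered_by_shift(self):
        # attention concentrated exactly one residue left of binding
        vals = np.zeros((20, 3))
        binding = frozenset({6, 11, 16})
        for r in (5, 10, 15):
            vals[r - 1, 0] = 1.0
        pairs = [(simple_map(vals), binding)]
        table = shift_analysis(pairs, shifts=(-1, 0, 1), k=3,
                               iterations=100, seed=0)
        by_shift = {r.shift: r.experimental_mean for r in table}
        assert by_shift[1] == 3.0
        assert by_shift[1] > by_shift[0] and by_shift[1] > by_shift[-1]

    def test_unannotated_dtis_excluded(self):
        pairs = self.make_pairs(n=4) + [(simple_map(np.ones((5, 2))),
                                         frozenset())]
        res = analyze_sites(pairs, k=5, iterations=50, seed=0)
        assert res.n_dti == 4

    def test_residue_aggregation_modes(self):
        m = simple_map([[0.1, 0.9], [0.4, 0.2]])
        np.testing.assert_allclose(residue_aggregate(m, "max"), [0.9, 0.4])
        np.testing.assert_allclose(residue_aggregate(m, "mean"),
                                   [0.5, 0.3])
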