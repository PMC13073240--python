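import numpy as np
import pytest

import scposition as sp
from scposition.containers import ExpressionMatrix
from scposition.stats import bh_adjust, rank_sum_test


def _lognorm(values, genes=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i:02d}" for i in range(values.shape[1])]
    cells = [f"c{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(cells, genes, values, layer="lognorm")


def hvg_oracle(m, n_top, n_bins):
    """Brute-force dispersion/bin/z computation, independent of hvg_rank."""
    mean = m.values.mean(axis=0)
    var = m.values.var(axis=0, ddof=1)
    rows = [
        (g, mu, v / mu)
        for g, mu, v in zip(m.gene_ids, mean, var)
        if mu > 0
    ]
    rows.sort(key=lambda r: (r[1], r[0]))  # by mean, symbol
    n = len(rows)
    binned = {}
    for rank, (g, mu, d) in enumerate(rows):
        b = min((rank * n_bins) // n, n_bins - 1)
        binned.setdefault(b, []).append((g, d))
    zscores = {}
    for b, members in binned.items():
        ds = np.array([d for _, d in members])
        sd = ds.std(ddof=1) if len(ds) > 1 else 0.0
        for g, d in members:
            zscores[g] = (d - ds.mean()) / sd if sd > 0 else 0.0
    ranked = sorted(zscores, key=lambda g: (-round(zscores[g], 10), g))
    return ranked[:n_top]


class TestHvgRank:
    def test_matches_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(42)
        m = _lognorm(rng.gamma(2.0, 1.0, size=(30, 50)).round(3))
        got, table = sp.hvg_rank(m, n_top=12, n_bins=5)
        assert got.genes == hvg_oracle(m, 12, 5)

    def test_bimodal_gene_ranks_first(self):
        # one gene high in half the cells among otherwise flat genes
        vals = np.ones((40, 6))
        vals[:20, 3] = 3.0
        rng = np.random.default_rng(0)
        vals += rng.normal(0, 0.01, vals.shape)
        got, _ = sp.hvg_rank(_lognorm(np.abs(vals)), n_top=3, n_bins=2)
        assert got.genes[0] == "g03"

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(1)
        m = _lognorm(rng.gamma(2.0, 1.0, size=(25, 30)))
        perm = rng.permutation(25)
        shuffled = ExpressionMatrix(
            m.cell_ids[perm], m.gene_ids, m.values[perm], "lognorm"
        )
        assert sp.hvg_rank(m, 10)[0].genes == sp.hvg_rank(shuffled, 10)[0].genes

    def test_dispersion_z_zero_mean_within_bins(self):
        rng = np.random.default_rng(2)
        _, table = sp.hvg_rank(_lognorm(rng.gamma(2.0, 1.0, size=(30, 40))), 10, n_bins=4)
        for _, grp in table.groupby("bin_index"):
            if len(grp) >= 2 and grp["dispersion_z"].abs().sum() > 0:
                assert abs(grp["dispersion_z"].mean()) < 1e-9

    def test_too_few_eligible_genes_errors(self):
        with pytest.raises(ValueError, match="nonzero mean"):
            sp.hvg_rank(_lognorm(np.zeros((5, 4))), n_top=3)


class TestMergeUnion:
    def test_observed_overlap_gives_expected_union_size(self):
        # two 100-gene lists sharing 63 genes merge to 137
        shared = [f"s{i}" for i in range(63)]
        a = sp.GeneSet("a", shared + [f"a{i}" for i in range(37)], "hvg")
        b = sp.GeneSet("b", shared + [f"b{i}" for i in range(37)], "hvg")
        merged = sp.merge_union([a, b])
        assert len(merged) == 137
        assert merged.provenance == "hvg"
        # four 100-gene lists at pairwise overlap reproduce a 251-size union
        c = sp.GeneSet("c", shared[:40] + [f"c{i}" for i in range(60)], "hvg")
        d = sp.GeneSet("d", shared[40:63] + [f"a{i}" for i in range(23)] + [f"d{i}" for i in range(54)], "hvg")
        assert len(sp.merge_union([a, b, c, d])) == 251

    def test_idempotent_and_order_preserving(self):
        s = sp.GeneSet("s", ["z", "a", "m"])
        assert sp.merge_union([s, s]).genes == ["z", "a", "m"]


class TestDeMarkers:
    def test_exclusive_gene_selected_with_positive_logfc(self):
        vals = np.zeros((30, 5))
        vals[:10, 2] = 5.0  # gene g02 exclusive to compartment A
        rng = np.random.default_rng(3)
        vals[:, [0, 1, 3, 4]] = rng.gamma(2, 1, (30, 4))
        m = _lognorm(vals)
        ann = sp.CellAnnotation(m.cell_ids, ["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        got = sp.de_markers(m, ann)
        assert "g02" in got.genes

    def test_small_compartment_errors_by_name(self):
        m = _lognorm(np.ones((5, 4)))
        ann = sp.CellAnnotation(m.cell_ids, ["A", "A", "A", "B", "B"])
        with pytest.raises(ValueError, match="'B'"):
            sp.de_markers(m, ann)


class TestRankSumAndBh:
    def test_exact_two_sided_p_for_disjoint_triples(self):
        p = rank_sum_test(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p[0] == pytest.approx(0.1, abs=1e-12)

    def test_matches_enumeration_oracle_small_groups(self):
        # exhaustive null enumeration for tie-free samples, n,m ≤ 8
        from itertools import combinations

        rng = np.random.default_rng(7)
        for _ in range(5):
            n, m_ = rng.integers(3, 7, size=2)
            pooled = rng.permutation(np.arange(1.0, n + m_ + 1))
            x, y = pooled[:n], pooled[n:]
            u_obs = sum((xi > yj) for xi in x for yj in y)
            total = 0
            as_extreme = 0
            ranks = np.arange(1.0, n + m_ + 1)
            mean_u = n * m_ / 2
            for combo in combinations(range(n + m_), int(n)):
                mask = np.zeros(n + m_, bool)
                mask[list(combo)] = True
                u = ranks[mask].sum() - n * (n + 1) / 2
                total += 1
                if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
                    as_extreme += 1
            expected = as_extreme / total
            got = rank_sum_test(x, y)[0]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_bh_step_up_worked_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_bh_matches_step_up_formula(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=20)
        # step-up oracle: adj_(i) = min_{j≥i} ( m p_(j) / j ), in sorted order
        order = np.argsort(p)
        m = len(p)
        adj_sorted = np.minimum.accumulate(
            (m * p[order] / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)


class TestRfeAndMi:
    def _planted(self, seed=0, n_cells=90, n_genes=10, informative=(0, 4, 9)):
        rng = np.random.default_rng(seed)
        labels = np.repeat(["A", "B", "C"], n_cells // 3)
        vals = rng.gamma(2, 1, (n_cells, n_genes))
        for cls, g in zip("ABC", informative):
            vals[labels == cls, g] += 3.0
        m = _lognorm(vals)
        return m, sp.CellAnnotation(m.cell_ids, labels)

    def test_rfe_recovers_planted_genes(self):
        hits = 0
        for seed in range(20):
            m, ann = self._planted(seed)
            got = sp.rfe_select(m, ann, sp.GeneSet("cand", list(m.gene_ids)), 3, seed=seed)
            hits += set(got.genes) == {"g00", "g04", "g09"}
        assert hits >= 18

    def test_rfe_target_equal_size_is_identity(self, small_lognorm):
        lognorm, ann, _ = small_lognorm
        gs = sp.GeneSet("cand", lognorm.gene_ids[:5].tolist())
        assert sp.rfe_select(lognorm, ann, gs, 5).genes == gs.genes

    def test_rfe_gene_column_order_invariance(self):
        m, ann = self._planted(3)
        perm = np.random.default_rng(0).permutation(m.n_genes)
        shuffled = ExpressionMatrix(m.cell_ids, m.gene_ids[perm], m.values[:, perm], "lognorm")
        gs = sp.GeneSet("cand", sorted(m.gene_ids))
        a = sp.rfe_select(m, ann, gs, 3, seed=1)
        b = sp.rfe_select(shuffled, ann, gs, 3, seed=1)
        assert set(a.genes) == set(b.genes)

    def test_mi_perfect_dependence_reaches_ln3(self):
        labels = np.repeat(["A", "B", "C"], 20)
        vals = np.tile(
            np.repeat([0.0, 1.0, 2.0], 20)[:, None], (1, 2)
        )
        rng = np.random.default_rng(1)
        vals[:, 1] = rng.uniform(size=60)
        m = _lognorm(vals)
        ann = sp.CellAnnotation(m.cell_ids, labels)
        got = sp.mi_rank(m, ann, sp.GeneSet("cand", list(m.gene_ids)), 2, n_quantile_bins=3)
        from scposition.features import _quantile_mi

        mi = _quantile_mi(vals[:, 0], np.repeat([0, 1, 2], 20), 3)
        assert mi == pytest.approx(np.log(3), abs=1e-9)
        assert got.genes[0] == "g00"

    def test_mi_near_zero_for_shuffled_labels_and_nonnegative(self):
        from scposition.features import _quantile_mi

        rng = np.random.default_rng(2)
        x = rng.gamma(2, 1, 600)
        labels = rng.integers(0, 3, 600)
        mi = _quantile_mi(x, labels, 8)
        assert 0.0 <= mi <= 0.02


class TestRandomSetAndOverlap:
    def test_seed_reproducibility_and_full_draw(self):
        universe = [f"g{i}" for i in range(50)]
        assert sp.random_set(universe, 10, 7).genes == sp.random_set(universe, 10, 7).genes
        full = sp.random_set(universe, 50, 3)
        assert sorted(full.genes) == sorted(universe)

    def test_inclusion_frequency_is_uniform(self):
        universe = [f"g{i}" for i in range(40)]
        n, draws = 10, 1000
        counts = {g: 0 for g in universe}
        for seed in range(draws):
            for g in sp.random_set(universe, n, seed).genes:
                counts[g] += 1
        p = n / len(universe)
        sigma = np.sqrt(draws * p * (1 - p))
        for g, c in counts.items():
            assert abs(c - draws * p) < 4 * sigma

    def test_overlap_report_venn_accounting(self):
        a = sp.GeneSet("a", [f"x{i}" for i in range(198)] + [f"s{i}" for i in range(53)])
        b = sp.GeneSet("b", [f"s{i}" for i in range(53)] + [f"y{i}" for i in range(51)])
        rep = sp.overlap_report(a, b)
        assert (rep.n_shared, rep.n_only_a, rep.n_only_b) == (53, 198, 51)
        assert rep.frac_of_a == pytest.approx(0.211, abs=5e-4)
        assert rep.frac_of_b == pytest.approx(0.510, abs=5e-4)

    def test_overlap_disjoint_and_subset(self):
        a = sp.GeneSet("a", ["1", "2"])
        b = sp.GeneSet("b", ["3"])
        rep = sp.overlap_report(a, b)
        assert (rep.n_shared, rep.frac_of_a, rep.frac_of_b) == (0, 0.0, 0.0)
        assert sp.overlap_report(a, sp.GeneSet("c", ["1", "2", "9"])).frac_of_a == 1.0
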