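import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from _oracles import ld_blocks_oracle
from conftest import make_panel
from snpenrich.ld import GenotypeLd, SparseLd, r2_matrix
from snpenrich.pruning import (
    LdBlockAssignment,
    build_ld_blocks,
    child_rng,
    prune_and_average,
    random_prune,
)


def sparse_from_matrix(panel, r2):
    ids = panel.df["snp_id"].to_numpy()
    rows = [
        (ids[i], ids[j], float(r2[i, j]))
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if r2[i, j] > 0
    ]
    return SparseLd(pd.DataFrame(rows, columns=["snp_id_a", "snp_id_b", "r2"]))


class TestBuildLdBlocks:
    def test_threshold_partitions(self):
        panel = make_panel([1000, 2000, 3000])
        r2 = np.eye(3)
        r2[0, 1] = r2[1, 0] = 0.5
        r2[0, 2] = r2[2, 0] = 0.05
        r2[1, 2] = r2[2, 1] = 0.1
        a = build_ld_blocks(panel, sparse_from_matrix(panel, r2))
        assert a.block_id[0] == a.block_id[1] != a.block_id[2]

    def test_transitive_chaining(self):
        panel = make_panel([1000, 2000, 3000])
        r2 = np.eye(3)
        r2[0, 1] = r2[1, 0] = 0.3
        r2[1, 2] = r2[2, 1] = 0.3
        a = build_ld_blocks(panel, sparse_from_matrix(panel, r2))
        assert len(set(a.block_id)) == 1

    def test_independent_snps_all_singletons(self):
        panel = make_panel([1000, 2000, 3000])
        a = build_ld_blocks(panel, sparse_from_matrix(panel, np.eye(3)))
        assert a.n_blocks == 3

    def test_window_limits_edges(self):
        panel = make_panel([1, 2_000_002])
        r2 = np.full((2, 2), 0.9)
        a = build_ld_blocks(panel, sparse_from_matrix(panel, r2), window_size=1_000_000)
        assert a.n_blocks == 2

    def test_r2_out_of_range_rejected(self):
        panel = make_panel([1000, 2000])
        with pytest.raises(ValueError):
            SparseLd(pd.DataFrame({"snp_id_a": ["rs0"], "snp_id_b": ["rs1"], "r2": [1.5]}))

    def test_matches_union_find_oracle(self, rng):
        """Connected-component blocks equal a brute-force union-find on
        random panels, for both LD backends."""
        for trial in range(8):
            n = int(rng.integers(20, 120))
            chroms = np.where(rng.random(n) < 0.5, "chr1", "chr2")
            pos = rng.choice(2_000_000, size=n, replace=False) + 1
            order = np.lexsort((pos, chroms))
            chroms, pos = chroms[order], pos[order]
            panel = make_panel(pos, chrom=chroms)
            # random sparse symmetric r2
            r2 = np.zeros((n, n))
            for _ in range(n * 2):
                i, j = rng.integers(0, n, 2)
                if i != j:
                    r2[i, j] = r2[j, i] = rng.random()
            window = int(rng.integers(10_000, 1_500_000))
            got = build_ld_blocks(panel, sparse_from_matrix(panel, r2), window, 0.2)
            want = ld_blocks_oracle(panel.chroms, panel.positions, r2, window, 0.2)
            assert np.array_equal(got.block_id, want)

    def test_genotype_backend_agrees_with_matrix(self, rng):
        n, m = 40, 300
        g = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        pos = np.sort(rng.choice(500_000, n, replace=False)) + 1
        panel = make_panel(pos)
        r2 = r2_matrix(g)
        got = build_ld_blocks(panel, GenotypeLd(g), 1_000_000, 0.2)
        want = ld_blocks_oracle(panel.chroms, panel.positions, r2, 1_000_000, 0.2)
        assert np.array_equal(got.block_id, want)

    def test_monomorphic_snp_isolated(self):
        g = np.array([[1, 1, 1, 1], [0, 1, 2, 1]], dtype=np.int8)
        panel = make_panel([100, 200])
        a = build_ld_blocks(panel, GenotypeLd(g))
        assert a.n_blocks == 2

    def test_greedy_mode_caps_span(self):
        # chain 0-1-2 with pair distances < window but 0..2 span > window
        panel = make_panel([1, 700_000, 1_400_000])
        r2 = np.eye(3)
        r2[0, 1] = r2[1, 0] = 0.5
        r2[1, 2] = r2[2, 1] = 0.5
        comp = build_ld_blocks(panel, sparse_from_matrix(panel, r2), mode="components")
        greedy = build_ld_blocks(panel, sparse_from_matrix(panel, r2), mode="greedy")
        assert comp.n_blocks == 1
        assert greedy.n_blocks == 2  # SNP 2 is > 1 Mb from the clump seed


class TestRandomPrune:
    def test_one_per_block_and_singletons_forced(self):
        a = LdBlockAssignment(np.array([0, 0, 0, 1]))
        idx = random_prune(a, 0)
        assert len(idx) == 2 and 3 in idx and idx[0] in (0, 1, 2)

    def test_deterministic_given_seed(self):
        a = LdBlockAssignment(np.array([0, 0, 1, 1, 2]))
        assert np.array_equal(random_prune(a, 42), random_prune(a, 42))
        assert not all(
            np.array_equal(random_prune(a, s), random_prune(a, 0)) for s in range(1, 20)
        )

    def test_uniform_within_block(self):
        """Each member of a size-3 block is drawn ~1/3 of the time."""
        a = LdBlockAssignment(np.array([0, 0, 0]))
        counts = np.zeros(3, int)
        for s in range(10_000):
            counts[random_prune(a, s)[0]] += 1
        assert chisquare(counts).pvalue > 0.01


class TestPruneAndAverage:
    def test_constant_statistic_zero_sd(self, rng):
        panel = make_panel(np.arange(1, 21))
        a = LdBlockAssignment(rng.integers(0, 5, 20))
        a.block_id = np.unique(a.block_id, return_inverse=True)[1]
        ps = prune_and_average(panel, a, lambda idx: 7.0, n_iter=30, seed=1)
        assert ps.mean == 7.0 and ps.sd == 0.0

    def test_singleton_blocks_identity(self):
        panel = make_panel(np.arange(1, 11))
        a = LdBlockAssignment(np.arange(10))
        ps = prune_and_average(panel, a, lambda idx: float(len(idx)), n_iter=10, seed=0)
        assert ps.mean == 10.0 and ps.sd == 0.0

    def test_bernoulli_half_block(self):
        """A size-2 block with one annotated member contributes ~0.5."""
        member = np.array([True, False, True])
        a = LdBlockAssignment(np.array([0, 0, 1]))
        panel = make_panel([1, 2, 3])
        ps = prune_and_average(
            panel, a, lambda idx: float(member[idx].sum()), n_iter=400, seed=3
        )
        # second block always contributes 1; first contributes Bern(0.5)
        se = 0.5 / np.sqrt(400)
        assert abs(ps.mean - 1.5) < 3 * se

    def test_failures_recorded_then_hard_error(self):
        panel = make_panel([1, 2])
        a = LdBlockAssignment(np.array([0, 1]))

        calls = {"n": 0}

        def flaky(idx):
            calls["n"] += 1
            if calls["n"] % 4 == 0:
                raise RuntimeError("boom")
            return 1.0

        ps = prune_and_average(panel, a, flaky, n_iter=8, seed=0)
        assert np.isnan(ps.values).sum() == 2 and ps.mean == 1.0

        with pytest.raises(RuntimeError, match="unusable"):
            prune_and_average(panel, a, lambda idx: 1 / 0, n_iter=4, seed=0)

    def test_child_seeds_reproducible_in_isolation(self):
        a = LdBlockAssignment(np.array([0, 0, 1, 1, 2, 2]))
        draws = [random_prune(a, child_rng(9, it)) for it in range(5)]
        again = random_prune(a, child_rng(9, 3))
        assert np.array_equal(draws[3], again)


def test_enrichment_stable_across_pruning_master_seeds(small_study):
    """With block-level signal, the pruned-and-averaged enrichment statistic
    (-log10 p) agrees within one order of magnitude across master seeds."""
    from snpenrich.enrichment import fisher_enrichment
    from snpenrich.gwas import AnnotationMask, SnpPanel, annotate
    from snpenrich.intervals import build_compendium
    from snpenrich.ld import SparseLd

    comp = build_compendium("HNISZ_generic", small_study.marks, binding_marks=["BRD4"])
    mask = annotate(small_study.panel, comp)
    assignment = build_ld_blocks(small_study.panel, SparseLd(small_study.sparse_ld))

    def neglog_p(idx):
        sub = SnpPanel(small_study.panel.df.iloc[idx].reset_index(drop=True))
        m = AnnotationMask("enh", mask.member[idx])
        return -np.log10(fisher_enrichment(sub, m).p_hyper)

    means = [
        prune_and_average(small_study.panel, assignment, neglog_p, n_iter=100, seed=s).mean
        for s in (1, 2)
    ]
    assert means[0] > 1.0  # the signal survives pruning at all
    assert abs(means[0] - means[1]) < 1.0
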