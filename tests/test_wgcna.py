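"""Co-expression network construction, module detection and gene screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.metrics import adjusted_rand_score

from mirhub import wgcna


def _expr(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes, columns=[f"s{j}" for j in range(values.shape[1])])


def _tom_oracle(a: np.ndarray) -> np.ndarray:
    """Triple-loop reference for the topological overlap."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    w = np.ones((n, n))
    for x in range(n):
        for y in range(n):
            if x == y:
                continue
            l = sum(a[x, u] * a[u, y] for u in range(n) if u != x and u != y)
            w[x, y] = (l + a[x, y]) / (min(k[x], k[y]) + 1.0 - a[x, y])
    return w


def _random_adjacency(rng, n):
    s = rng.uniform(0, 1, size=(n, n))
    a = (s + s.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


class TestSimilarity:
    def test_self_similarity_is_one(self):
        s = wgcna.similarity(_expr([[1, 2, 3, 4], [4, 1, 2, 2]]))
        assert s.iloc[0, 0] == 1.0 and s.iloc[1, 1] == 1.0

    def test_perfect_anticorrelation_scores_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        s = wgcna.similarity(_expr([x, -2 * x]))
        assert s.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_printed_sum_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 4.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        expected = abs(num / den)
        s = wgcna.similarity(_expr([x, y]))
        assert s.iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_named_in_error(self):
        with pytest.raises(ValueError, match="flatgene"):
            wgcna.similarity(_expr([[1, 2, 3], [5, 5, 5]], genes=["ok", "flatgene"]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            wgcna.similarity(_expr([[1, 2], [2, 1]]))


class TestAdjacency:
    def test_beta_one_keeps_off_diagonal_similarity(self, rng):
        s = wgcna.similarity(_expr(rng.normal(size=(5, 20))))
        a = wgcna.adjacency(s, 1)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(a.to_numpy()[off], s.to_numpy()[off])
        assert np.all(np.diag(a.to_numpy()) == 0)

    def test_known_power(self):
        s = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        assert wgcna.adjacency(s, 4).loc["a", "b"] == pytest.approx(0.0625)

    def test_matches_elementwise_loop_oracle(self, rng):
        s = rng.uniform(0, 1, size=(10, 10))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        a = wgcna.adjacency(s, 6)
        for i in range(10):
            for j in range(10):
                expected = 0.0 if i == j else s[i, j] ** 6
                assert a[i, j] == pytest.approx(expected, abs=1e-15)


class TestTopologicalOverlap:
    def test_uniform_half_adjacency_hand_value(self):
        """Three genes with all off-diagonal a=0.5: k=1, l=0.25, w=0.75/1.5=0.5."""
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        w = wgcna.topological_overlap(a)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(w[off], 0.5)
        assert np.all(np.diag(w) == 1.0)

    def test_empty_adjacency_gives_zero_overlap(self):
        w = wgcna.topological_overlap(np.zeros((4, 4)))
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(w[off], 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        a = _random_adjacency(rng, 20)
        assert np.max(np.abs(wgcna.topological_overlap(a) - _tom_oracle(a))) < 1e-10

    def test_asymmetric_input_rejected(self, rng):
        a = rng.uniform(0, 1, size=(5, 5))
        with pytest.raises(ValueError, match="symmetric"):
            wgcna.topological_overlap(a)

    @given(hnp.arrays(np.float64, (6, 6), elements=st.floats(0, 1)))
    @settings(max_examples=50, derandomize=True)
    def test_range_preserved_on_valid_inputs(self, raw):
        a = (raw + raw.T) / 2.0
        np.fill_diagonal(a, 0.0)
        w = wgcna.topological_overlap(a)
        assert w.min() >= -1e-12 and w.max() <= 1.0 + 1e-12


class TestDissimilarity:
    def test_complements_tom_elementwise(self, rng):
        a = _random_adjacency(rng, 8)
        w = wgcna.topological_overlap(a)
        d = wgcna.dissimilarity(w)
        off = ~np.eye(8, dtype=bool)
        assert np.allclose((d + w)[off], 1.0)
        assert np.all(np.diag(d) == 0.0)


class TestSoftThreshold:
    def test_planted_power_law_scores_highly(self, rng):
        k = (rng.pareto(1.5, size=3000) + 1) * 2
        r2, slope = wgcna.scale_free_fit(k)
        assert r2 >= 0.9
        assert slope < 0

    def test_zero_cut_returns_smallest_candidate(self, rng):
        expr = _expr(rng.normal(size=(30, 20)))
        beta, _ = wgcna.pick_soft_threshold(expr, candidates=[2, 3, 4], r2_cut=0.0)
        assert beta == 2

    def test_mean_connectivity_strictly_decreases(self, rng):
        expr = _expr(rng.normal(size=(40, 30)))
        _, table = wgcna.pick_soft_threshold(expr)
        mk = table["mean_k"].to_numpy()
        assert np.all(np.diff(mk) < 0)


class TestClusterCut:
    @staticmethod
    def _block_diss(sizes, within=0.0, between=1.0):
        n = sum(sizes)
        d = np.full((n, n), between)
        start = 0
        for s in sizes:
            d[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(d, 0.0)
        return d

    def test_separable_blocks_recovered(self):
        labels = wgcna.cluster_cut(self._block_diss([20, 20]), min_module_size=10)
        assert set(labels) == {1, 2}
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1

    def test_small_block_left_unassigned(self):
        d = self._block_diss([5], between=1.0)
        # 5 correlated genes among 30 noise genes, min size 10: nothing labeled
        rng = np.random.default_rng(0)
        noise = rng.uniform(0.95, 1.0, size=(35, 35))
        noise = (noise + noise.T) / 2
        noise[:5, :5] = 0.05
        np.fill_diagonal(noise, 0.0)
        labels = wgcna.cluster_cut(noise, min_module_size=10)
        assert labels.max() == 0

    def test_min_module_size_floor_validated(self):
        with pytest.raises(ValueError):
            wgcna.cluster_cut(np.zeros((4, 4)), min_module_size=1)

    def test_permutation_equivariance(self, planted_runs):
        """Permuting the gene order permutes the labels identically (ARI = 1)."""
        run = planted_runs[0]
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(run.expr))
        expr_p = run.expr.iloc[perm]
        sim = wgcna.similarity(expr_p)
        adj = wgcna.adjacency(sim, run.result.beta)
        diss = wgcna.dissimilarity(wgcna.topological_overlap(adj))
        labels_p = wgcna.cluster_cut(diss, min_module_size=10)
        assert adjusted_rand_score(run.result.labels.values[perm], labels_p) == pytest.approx(1.0)


class TestModuleEigengene:
    def test_identical_genes_give_common_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = _expr(np.tile(profile, (4, 1)))
        me = wgcna.module_eigengene(expr, np.ones(4, dtype=int))
        assert abs(np.corrcoef(me.iloc[0], profile)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(me.iloc[0], profile)[0, 1] > 0  # sign convention
        assert me.iloc[0].std(ddof=1) == pytest.approx(1.0)

    def test_sign_invariance_under_gene_negation(self, rng):
        values = rng.normal(size=(6, 30))
        labels = np.ones(6, dtype=int)
        me_a = wgcna.module_eigengene(_expr(values), labels)
        me_b = wgcna.module_eigengene(_expr(-values), labels)
        r = np.corrcoef(me_a.iloc[0], me_b.iloc[0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_singleton_module_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than 2"):
            wgcna.module_eigengene(_expr(rng.normal(size=(3, 10))), np.array([1, 2, 2]))

    def test_recovers_planted_latent_factor(self, planted_runs):
        hits = []
        for run in planted_runs[:5]:
            me = wgcna.module_eigengene(run.expr, run.truth.module_label)
            r = np.corrcoef(me.loc["ME1"], run.truth.latent_factors[0])[0, 1]
            hits.append(abs(r))
        assert min(hits) >= 0.9


class TestMergeModules:
    def test_identical_eigengenes_merge(self, rng):
        common = rng.normal(size=30)
        values = np.vstack([common + 0.01 * rng.normal(size=30) for _ in range(20)])
        labels = np.repeat([1, 2], 10)
        merged = wgcna.merge_modules(_expr(values), labels, cut_height=0.25)
        assert len(set(merged)) == 1

    def test_orthogonal_eigengenes_not_merged(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        values = np.vstack(
            [a + 0.05 * rng.normal(size=40) for _ in range(10)]
            + [b + 0.05 * rng.normal(size=40) for _ in range(10)]
        )
        labels = np.repeat([1, 2], 10)
        merged = wgcna.merge_modules(_expr(values), labels, cut_height=0.25)
        assert len(set(merged)) == 2

    def test_artificial_split_is_healed(self, planted_runs):
        run = planted_runs[0]
        labels = run.truth.module_label.copy()
        members = np.flatnonzero(labels == 1)
        split = labels.copy()
        split[members[: len(members) // 2]] = labels.max() + 1
        merged = wgcna.merge_modules(run.expr, split, cut_height=0.25)
        assert len(set(merged[members])) == 1


class TestModuleTrait:
    def test_trait_equal_to_eigengene(self, rng):
        values = rng.normal(size=(12, 50))
        labels = np.ones(12, dtype=int)
        expr = _expr(values)
        me = wgcna.module_eigengene(expr, labels)
        traits = pd.DataFrame({"t": me.iloc[0]}, index=me.columns)
        mt = wgcna.module_trait(me, traits)
        assert mt["r"].iloc[0] == pytest.approx(1.0)
        assert mt["p"].iloc[0] < 1e-30

    def test_moderate_correlation_large_n_is_significant(self):
        """r = 0.3 at n = 372 is far below p = 1e-7 under the t transform."""
        p = wgcna._cor_pvalue(np.array([0.3]), n=372)[0]
        assert p < 1e-7

    def test_sample_mismatch_reported(self, rng):
        expr = _expr(rng.normal(size=(6, 10)))
        me = wgcna.module_eigengene(expr, np.ones(6, dtype=int))
        traits = pd.DataFrame({"t": np.arange(10.0)}, index=[f"x{j}" for j in range(10)])
        with pytest.raises(ValueError, match="mismatch"):
            wgcna.module_trait(me, traits)

    def test_null_trait_calibration(self, rng):
        """Against random traits, p < 0.05 in roughly 5% of replicates."""
        values = rng.normal(size=(10, 40))
        me = wgcna.module_eigengene(_expr(values), np.ones(10, dtype=int))
        mevec = me.iloc[0].to_numpy()
        n = len(mevec)
        hits = 0
        reps = 1000
        for _ in range(reps):
            t = rng.normal(size=n)
            r = np.corrcoef(mevec, t)[0, 1]
            hits += wgcna._cor_pvalue(np.array([r]), n)[0] < 0.05
        assert 0.03 <= hits / reps <= 0.07


class TestGeneScores:
    def test_gene_equal_to_eigengene_has_unit_mm(self, rng):
        common = rng.normal(size=40)
        values = np.vstack([common for _ in range(5)])
        expr = _expr(values + 0.0)
        labels = np.ones(5, dtype=int)
        me = wgcna.module_eigengene(expr, labels)
        trait = pd.Series(rng.normal(size=40), index=expr.columns)
        scores = wgcna.gene_scores(expr, me, trait, labels)
        assert np.allclose(np.abs(scores["MM"]), 1.0)

    def test_unassigned_gene_request_rejected(self, rng):
        expr = _expr(rng.normal(size=(6, 20)))
        labels = np.array([1, 1, 1, 1, 0, 0])
        me = wgcna.module_eigengene(expr, labels)
        trait = pd.Series(rng.normal(size=20), index=expr.columns)
        with pytest.raises(ValueError, match="unassigned"):
            wgcna.gene_scores(expr, me, trait, labels, genes=["g4"])

    def test_trait_linked_module_has_larger_gs(self, planted_runs):
        run = planted_runs[1]
        res = run.result
        member = res.scores["module"] == res.trait_module
        assert res.scores.loc[member, "GS"].abs().mean() > res.scores.loc[~member, "GS"].abs().mean()


class TestScreenKeyGenes:
    def _scores(self, rows):
        return pd.DataFrame(
            [{"gene": f"g{i}", "module": 1, "MM": mm, "GS": gs} for i, (mm, gs) in enumerate(rows)]
        )

    def test_boundaries_are_strict(self):
        assert wgcna.screen_key_genes(self._scores([(0.8, 0.5)])) == []
        assert wgcna.screen_key_genes(self._scores([(0.95, 0.2)])) == []
        assert wgcna.screen_key_genes(self._scores([(0.95, 0.25)])) == ["g0"]

    def test_matches_row_scan_oracle(self, rng):
        rows = [(rng.uniform(-1, 1), rng.uniform(-1, 1)) for _ in range(10)]
        scores = self._scores(rows)
        oracle = sorted(
            f"g{i}" for i, (mm, gs) in enumerate(rows) if abs(mm) > 0.8 and abs(gs) > 0.2
        )
        assert wgcna.screen_key_genes(scores) == oracle

    def test_raising_thresholds_never_adds_genes(self, rng):
        rows = [(rng.uniform(-1, 1), rng.uniform(-1, 1)) for _ in range(50)]
        scores = self._scores(rows)
        prev = set(wgcna.screen_key_genes(scores, 0.0, 0.0))
        for mm in np.linspace(0.0, 1.0, 6):
            for gs in np.linspace(0.0, 1.0, 6):
                cur = set(wgcna.screen_key_genes(scores, mm, gs))
                assert cur <= prev or (mm == 0.0 and gs == 0.0)
        # monotone along a single axis
        along = [set(wgcna.screen_key_genes(scores, mm, 0.1)) for mm in np.linspace(0, 1, 11)]
        for a, b in zip(along, along[1:]):
            assert b <= a
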