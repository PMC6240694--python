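"""Clustering, tree cutting, eigengenes, merging, reassignment, kME."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from coexnet import (
    ExpressionMatrix,
    ModulePartition,
    average_linkage,
    dynamic_tree_cut,
    generate,
    kme,
    merge_close_modules,
    module_eigengene,
    reassign_genes,
    signed_adjacency,
    spearman_correlation,
    topological_overlap,
)
from coexnet.containers import GREY
from coexnet.modules import partition_from_labels, trim_low_kme_genes

from conftest import small_config


def upgma_oracle(d: np.ndarray) -> list[float]:
    """Textbook UPGMA: returns the sorted merge heights."""
    clusters = {i: [i] for i in range(d.shape[0])}
    dist = {
        (i, j): d[i, j]
        for i in range(d.shape[0])
        for j in range(i + 1, d.shape[0])
    }
    heights = []
    next_id = d.shape[0]
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        merged = clusters[a] + clusters[b]
        del clusters[a], clusters[b]
        new_dist = {}
        for key, value in dist.items():
            if a in key or b in key:
                continue
            new_dist[key] = value
        for c, members in clusters.items():
            val = sum(d[x, y] for x in merged for y in members) / (
                len(merged) * len(members)
            )
            new_dist[(min(c, next_id), max(c, next_id))] = val
        clusters[next_id] = merged
        dist = new_dist
        next_id += 1
    return heights


def _zscore(x):
    return (x - x.mean()) / x.std()


def _module_expression(
    rng, factors: list[np.ndarray], sizes: list[int], loading: float = 0.9
):
    """Stack modules of genes loading on given sample factors."""
    rows, names = [], []
    for mi, (f, size) in enumerate(zip(factors, sizes)):
        for gi in range(size):
            eps = rng.standard_normal(len(f))
            rows.append(loading * f + np.sqrt(1 - loading**2) * eps)
            names.append(f"M{mi}_G{gi:03d}")
    frame = pd.DataFrame(
        np.array(rows), index=names,
        columns=[f"s{i}" for i in range(len(factors[0]))],
    )
    return ExpressionMatrix(frame)


class TestAverageLinkage:
    def test_three_point_hand_case(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        link = average_linkage(d)
        assert link[0, 2] == pytest.approx(0.1)
        assert link[1, 2] == pytest.approx(0.9)
        assert sorted(link[0, :2]) == [0, 1]

    def test_equal_distances_merge_at_equal_heights(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        link = average_linkage(d)
        np.testing.assert_allclose(link[:, 2], 0.5)

    def test_matches_textbook_upgma_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            x = rng.random((20, 20))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0.0)
            link = average_linkage(d)
            np.testing.assert_allclose(
                sorted(link[:, 2]), upgma_oracle(d), atol=1e-12
            )


class TestDynamicTreeCut:
    def _two_block_dissim(self, rng, n_block=50, within=0.1, between=0.9):
        n = 2 * n_block
        d = np.full((n, n), between)
        d[:n_block, :n_block] = within
        d[n_block:, n_block:] = within
        d += rng.normal(0, 0.01, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, 1.0)

    def test_two_planted_blocks_give_two_full_modules(self):
        rng = np.random.default_rng(1)
        d = self._two_block_dissim(rng)
        labels = dynamic_tree_cut(average_linkage(d), deep_split=2, min_module_size=30)
        assert len(set(labels)) == 2
        assert 0 not in set(labels)  # no grey
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1
        assert labels[0] != labels[50]

    def test_min_module_size_above_n_leaves_everything_grey(self):
        rng = np.random.default_rng(2)
        d = self._two_block_dissim(rng, n_block=10)
        with pytest.warns(UserWarning, match="unassigned"):
            labels = dynamic_tree_cut(
                average_linkage(d), deep_split=2, min_module_size=21
            )
        assert set(labels) == {0}

    def test_planted_five_module_recovery(self, default_dataset):
        expr = default_dataset.expression
        tom = topological_overlap(signed_adjacency(spearman_correlation(expr), 10))
        labels = dynamic_tree_cut(
            average_linkage(1.0 - tom.values), deep_split=2, min_module_size=30
        )
        truth = default_dataset.truth
        keep = [
            i for i, g in enumerate(expr.gene_ids)
            if truth.gene_modules[g] != "background"
        ]
        ari = adjusted_rand_score(
            [truth.gene_modules[expr.gene_ids[i]] for i in keep],
            [labels[i] for i in keep],
        )
        assert ari >= 0.9

    def test_invalid_deep_split_rejected(self):
        d = np.zeros((4, 4))
        from coexnet.errors import ValidationError

        with pytest.raises(ValidationError):
            dynamic_tree_cut(average_linkage(d), deep_split=7, min_module_size=2)


class TestModuleEigengene:
    def test_identical_member_profiles_explain_all_variance(self):
        rng = np.random.default_rng(3)
        profile = rng.standard_normal(10)
        frame = pd.DataFrame(
            np.tile(profile, (5, 1)), index=[f"G{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(10)],
        )
        expr = ExpressionMatrix(frame)
        part = ModulePartition(tuple(expr.gene_ids), ("m",) * 5)
        eig = module_eigengene(expr, part)
        assert eig.variance_explained["m"] == pytest.approx(1.0)
        z = _zscore(profile)
        np.testing.assert_allclose(
            eig.profiles["m"], z / np.linalg.norm(z), atol=1e-10
        )

    def test_sign_convention_follows_member_correlation(self, small_dataset):
        expr = small_dataset.expression
        genes = small_dataset.truth.members("planted_1")
        part = ModulePartition(tuple(genes), ("m",) * len(genes))
        sub = expr.select_genes(genes)
        eig = module_eigengene(sub, part)
        negated = ExpressionMatrix(-sub.frame)
        eig_neg = module_eigengene(negated, part)
        # flipping all members flips the eigengene (both keep positive
        # mean member correlation)
        np.testing.assert_allclose(
            eig.profiles["m"], -eig_neg.profiles["m"], atol=1e-8
        )

    def test_single_gene_module_is_normalized_z_profile(self, tiny_expression):
        part = ModulePartition(
            tuple(tiny_expression.gene_ids),
            ("m",) + (GREY,) * (tiny_expression.n_genes - 1),
        )
        eig = module_eigengene(tiny_expression, part)
        z = _zscore(tiny_expression.values[0])
        expected = z / np.linalg.norm(z)
        sign = np.sign(expected @ eig.profiles["m"])
        np.testing.assert_allclose(eig.profiles["m"], sign * expected, atol=1e-10)

    def test_variance_explained_matches_full_svd_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((30, 12))
        expr = ExpressionMatrix(
            pd.DataFrame(
                x, index=[f"G{i}" for i in range(30)],
                columns=[f"s{i}" for i in range(12)],
            )
        )
        part = ModulePartition(tuple(expr.gene_ids), ("m",) * 30)
        eig = module_eigengene(expr, part)
        z = np.apply_along_axis(_zscore, 1, x)
        s = np.linalg.svd(z, compute_uv=False)
        assert eig.variance_explained["m"] == pytest.approx(
            s[0] ** 2 / (s**2).sum(), abs=1e-8
        )


class TestMergeAndReassign:
    def _correlated_factor_expression(self, cor: float, seed: int = 5):
        rng = np.random.default_rng(seed)
        n_s = 40
        f1 = rng.standard_normal(n_s)
        f2 = cor * f1 + np.sqrt(1 - cor**2) * rng.standard_normal(n_s)
        expr = _module_expression(rng, [f1, f2], [40, 40], loading=0.95)
        labels = ("a",) * 40 + ("b",) * 40
        part = ModulePartition(tuple(expr.gene_ids), labels)
        return expr, part

    def test_highly_correlated_modules_merge(self):
        expr, part = self._correlated_factor_expression(0.97)
        eig = module_eigengene(expr, part)
        merged, _ = merge_close_modules(expr, part, eig, merge_cut_height=0.25)
        assert len(merged.modules) == 1

    def test_uncorrelated_modules_stay_separate(self):
        expr, part = self._correlated_factor_expression(0.0)
        eig = module_eigengene(expr, part)
        merged, _ = merge_close_modules(expr, part, eig, merge_cut_height=0.25)
        assert len(merged.modules) == 2

    def test_merging_is_idempotent(self):
        expr, part = self._correlated_factor_expression(0.97)
        eig = module_eigengene(expr, part)
        once, eig1 = merge_close_modules(expr, part, eig, 0.25)
        twice, _ = merge_close_modules(expr, once, eig1, 0.25)
        assert once.labels == twice.labels

    def test_no_eigengene_pair_below_cut_after_merge(self, small_dataset):
        expr = small_dataset.expression
        truth = small_dataset.truth
        labels = tuple(
            truth.gene_modules[g] if truth.gene_modules[g] != "background" else GREY
            for g in expr.gene_ids
        )
        part = ModulePartition(tuple(expr.gene_ids), labels)
        eig = module_eigengene(expr, part)
        _, eig_after = merge_close_modules(expr, part, eig, 0.25)
        me = np.stack(list(eig_after.profiles.values()))
        mc = me - me.mean(axis=1, keepdims=True)
        mc /= np.linalg.norm(mc, axis=1, keepdims=True)
        cor = mc @ mc.T
        off = cor[np.triu_indices(len(me), k=1)]
        assert np.all(1.0 - off >= 0.25)

    def test_misplaced_gene_moves_to_its_true_module(self):
        rng = np.random.default_rng(6)
        n_s = 40
        f1, f2 = rng.standard_normal(n_s), rng.standard_normal(n_s)
        expr = _module_expression(rng, [f1, f2], [30, 30], loading=0.95)
        labels = list(("a",) * 30 + ("b",) * 30)
        labels[0], labels[30] = "b", "a"  # swap two genes into wrong modules
        part = ModulePartition(tuple(expr.gene_ids), tuple(labels))
        eig = module_eigengene(expr, part)
        fixed = reassign_genes(expr, part, eig, reassign_threshold=0.2)
        assert fixed.label_of("M0_G000") == "a"
        assert fixed.label_of("M1_G000") == "b"

    def test_perfect_placement_is_unchanged(self):
        expr, part = self._correlated_factor_expression(0.0)
        eig = module_eigengene(expr, part)
        fixed = reassign_genes(expr, part, eig, reassign_threshold=0.2)
        assert fixed.labels == part.labels

    def test_zero_threshold_disables_reassignment(self):
        expr, part = self._correlated_factor_expression(0.0)
        eig = module_eigengene(expr, part)
        assert reassign_genes(expr, part, eig, 0.0).labels == part.labels

    def test_trim_sends_unrelated_genes_grey(self):
        rng = np.random.default_rng(7)
        f = rng.standard_normal(30)
        expr = _module_expression(rng, [f], [25], loading=0.9)
        noise = pd.DataFrame(
            rng.standard_normal((10, 30)), index=[f"N{i}" for i in range(10)],
            columns=expr.sample_ids,
        )
        full = ExpressionMatrix(pd.concat([expr.frame, noise]))
        part = ModulePartition(tuple(full.gene_ids), ("m",) * 35)
        eig = module_eigengene(full, part)
        trimmed = trim_low_kme_genes(full, part, eig, min_kme_to_stay=0.3)
        kept = set(trimmed.modules.get("m", ()))
        # exactly the genes at or above the kME floor survive
        table = kme(full, eig)
        expected = {g for g in full.gene_ids if table.loc[g, "m"] >= 0.3}
        assert kept == expected
        # the planted members overwhelmingly stay; most noise genes leave
        assert len(kept & {f"M0_G{i:03d}" for i in range(25)}) >= 23
        assert len(kept & {f"N{i}" for i in range(10)}) <= 3


class TestKME:
    def test_gene_equal_to_eigengene_profile(self):
        rng = np.random.default_rng(8)
        f = rng.standard_normal(20)
        expr = _module_expression(rng, [f], [10], loading=0.9)
        part = ModulePartition(tuple(expr.gene_ids), ("m",) * 10)
        eig = module_eigengene(expr, part)
        probe = pd.DataFrame([eig.profiles["m"]], index=["probe"], columns=expr.sample_ids)
        full = ExpressionMatrix(pd.concat([expr.frame, probe]))
        table = kme(full, eig)
        assert table.loc["probe", "m"] == pytest.approx(1.0)

    def test_background_genes_have_low_kme(self):
        """Pure-noise genes rarely reach |kME| 0.5 against planted modules."""
        hits = total = 0
        for seed in range(10):
            data = generate(small_config(seed=seed))
            expr = data.expression
            truth = data.truth
            labels = tuple(
                truth.gene_modules[g]
                if truth.gene_modules[g] != "background" else GREY
                for g in expr.gene_ids
            )
            part = ModulePartition(tuple(expr.gene_ids), labels)
            eig = module_eigengene(expr, part)
            table = kme(expr, eig)
            bg = [g for g in expr.gene_ids if truth.gene_modules[g] == "background"]
            sub = table.loc[bg].abs()
            hits += int((sub < 0.5).all(axis=1).sum())
            total += len(bg)
        assert hits / total >= 0.95

    def test_members_outrank_non_members(self, small_dataset):
        expr = small_dataset.expression
        truth = small_dataset.truth
        labels = tuple(
            truth.gene_modules[g] if truth.gene_modules[g] != "background" else GREY
            for g in expr.gene_ids
        )
        part = ModulePartition(tuple(expr.gene_ids), labels)
        eig = module_eigengene(expr, part)
        table = kme(expr, eig)
        for name in truth.module_names:
            members = truth.members(name)
            others = [g for g in expr.gene_ids if g not in members]
            assert (
                table.loc[members, name].mean() > table.loc[others, name].mean()
            )


class TestPartitionLabels:
    def test_labels_ordered_by_size(self):
        labels = np.array([1] * 5 + [2] * 10 + [0] * 3)
        part = partition_from_labels([f"G{i}" for i in range(18)], labels)
        modules = part.modules
        assert list(modules) == ["turquoise", "blue"]
        assert len(modules["turquoise"]) == 10
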