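"""Core/accessory likelihood model: worked values, fixed points, recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import motukit as mk
from motukit.pangenome import CorePangenomeModel, fit_motu_partitions


def matrix(rows: dict[str, list[int]], genomes: list[str]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=genomes)


def planted(n_genomes=10, completeness=0.9, n_core=50, n_acc=50, acc_freq=0.3, seed=0):
    """Presence matrix with known core/accessory labels, binomial degradation."""
    rng = np.random.default_rng(seed)
    core = rng.random((n_core, n_genomes)) < completeness
    acc = (rng.random((n_acc, n_genomes)) < acc_freq) & (
        rng.random((n_acc, n_genomes)) < completeness
    )
    X = np.vstack([core, acc]).astype(int)
    genes = [f"core{i:04d}" for i in range(n_core)] + [f"acc{i:04d}" for i in range(n_acc)]
    genomes = [f"g{i:02d}" for i in range(n_genomes)]
    df = pd.DataFrame(X, index=genes, columns=genomes)
    df = df.loc[df.sum(axis=1) > 0]
    comp = {g: completeness for g in genomes}
    return df, comp


class TestLogLik:
    def test_core_loglik_hand_values(self):
        c = [0.9] * 10
        assert mk.loglik_core([1] * 9 + [0], c) == pytest.approx(
            9 * math.log(0.9) + math.log(0.1), abs=1e-12
        )
        assert mk.loglik_core([1] * 9 + [0], c) == pytest.approx(-3.251, abs=1e-3)
        assert mk.loglik_core([1] + [0] * 9, c) == pytest.approx(-20.83, abs=5e-3)

    def test_accessory_loglik_hand_values(self):
        p = [0.3] * 10
        assert mk.loglik_accessory([1] + [0] * 9, p) == pytest.approx(-4.414, abs=1e-3)
        assert mk.loglik_accessory([1] * 9 + [0], p) == pytest.approx(-11.19, abs=5e-3)

    def test_worked_example_decision(self):
        c, p = [0.9] * 10, [0.3] * 10
        nine_of_ten = [1] * 9 + [0]
        one_of_ten = [1] + [0] * 9
        assert mk.loglik_core(nine_of_ten, c) > mk.loglik_accessory(nine_of_ten, p)
        assert mk.loglik_core(one_of_ten, c) < mk.loglik_accessory(one_of_ten, p)

    def test_half_carriage_depends_only_on_length(self):
        p = [0.5] * 8
        for row in ([1] * 8, [0] * 8, [1, 0] * 4):
            assert mk.loglik_accessory(row, p) == pytest.approx(8 * math.log(0.5))

    def test_complete_genomes_give_near_zero_core_loglik(self):
        assert mk.loglik_core([1] * 20, [0.999] * 20) == pytest.approx(
            20 * math.log(0.999)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            mk.loglik_core([1, 0], [0.9])
        with pytest.raises(ValueError, match="length mismatch"):
            mk.loglik_accessory([1, 0], [0.3, 0.3, 0.3])

    def test_extreme_probabilities_are_clamped_finite(self):
        assert np.isfinite(mk.loglik_core([0, 1], [1.0, 1.0]))
        assert np.isfinite(mk.loglik_accessory([1, 0], [0.0, 0.0]))


class TestModelValidation:
    def test_all_zero_rows_rejected(self):
        df = matrix({"g1": [0, 0]}, ["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            CorePangenomeModel(df, {"a": 0.9, "b": 0.9})

    def test_from_dataframe_drops_unobserved_rows(self):
        df = matrix({"g1": [1, 0], "g2": [0, 0]}, ["a", "b"])
        model = CorePangenomeModel.from_dataframe(df, {"a": 0.9, "b": 0.9})
        assert model.genes == ["g1"]

    def test_non_binary_cells_rejected(self):
        df = matrix({"g1": [1, 2]}, ["a", "b"])
        with pytest.raises(ValueError, match="0/1"):
            CorePangenomeModel(df, {"a": 0.9, "b": 0.9})

    def test_missing_completeness_named(self):
        df = matrix({"g1": [1, 1]}, ["a", "b"])
        with pytest.raises(ValueError, match="b"):
            CorePangenomeModel(df, {"a": 0.9})

    def test_percent_completeness_accepted(self):
        df = matrix({"g1": [1, 1]}, ["a", "b"])
        model = CorePangenomeModel(df, {"a": 90.0, "b": 85.0})
        assert model.completeness == pytest.approx([0.9, 0.85])


class TestFit:
    def test_complete_genome_limit_is_presence_in_all(self):
        rng = np.random.default_rng(4)
        X = (rng.random((200, 8)) < 0.6).astype(int)
        X[:20] = 1  # 20 genes in every genome
        X = X[X.sum(axis=1) > 0]
        df = pd.DataFrame(X, index=[f"g{i}" for i in range(len(X))],
                          columns=[f"m{i}" for i in range(8)])
        res = CorePangenomeModel(df, {f"m{i}": 0.999 for i in range(8)}).fit()
        expected_core = df.sum(axis=1) == 8
        assert (res.assignment == "core").equals(expected_core.rename("assignment"))

    def test_planted_frequencies_converge_fast(self):
        df, comp = planted(n_genomes=10, completeness=0.9, n_core=50, n_acc=50, seed=1)
        res = CorePangenomeModel(df, comp).fit()
        assert res.converged
        assert res.n_iterations <= 3
        recovered_core = set(res.core_genes)
        true_core = {g for g in df.index if g.startswith("core")}
        agree = len(recovered_core & true_core) / len(true_core)
        assert agree > 0.9

    def test_empty_gene_list(self):
        df = pd.DataFrame(index=pd.Index([], name="gene"), columns=["a", "b"]).fillna(0)
        res = CorePangenomeModel(df.astype(int), {"a": 0.9, "b": 0.9}).fit()
        assert res.converged and res.n_iterations == 0
        assert len(res.assignment) == 0

    def test_decision_rule_invariant(self):
        df, comp = planted(seed=7)
        res = CorePangenomeModel(df, comp).fit()
        assert np.array_equal(res.core_mask, res.ll_core > res.ll_acc)
        # recomputing with the reported carriage reproduces the likelihoods
        for i, gene in enumerate(res.model.genes[:10]):
            row = df.loc[gene].tolist()
            assert mk.loglik_accessory(row, res.carriage) == pytest.approx(res.ll_acc[i])

    def test_partition_independent_of_input_order(self):
        df, comp = planted(seed=3)
        res1 = CorePangenomeModel(df, comp).fit()
        shuffled = df.sample(frac=1.0, random_state=5)[
            list(np.random.default_rng(5).permutation(df.columns))
        ]
        res2 = CorePangenomeModel(shuffled, comp).fit()
        assert res1.assignment.sort_index().equals(res2.assignment.sort_index())

    def test_single_genome_motu(self):
        df = matrix({"g1": [1], "g2": [1]}, ["a"])
        res = CorePangenomeModel(df, {"a": 0.95}).fit()
        assert set(res.assignment) <= {"core", "accessory"}

    def test_reestimated_completeness_tracks_core_recovery(self):
        df, comp = planted(n_genomes=10, completeness=0.8, seed=9)
        res = CorePangenomeModel(df, comp).fit(reestimate_completeness=True)
        assert res.posterior_completeness is not None
        assert res.posterior_completeness.shape == (10,)
        # posterior completeness should sit near the true 0.8
        assert abs(res.posterior_completeness.mean() - 0.8) < 0.1

    def test_classify_profile_matches_fit(self):
        df, comp = planted(seed=11)
        res = CorePangenomeModel(df, comp).fit()
        for gene in res.model.genes[:20]:
            status, llc, lla = res.classify_profile(df.loc[gene].to_dict())
            assert status == res.assignment[gene]

    @given(
        arrays(np.int8, (12, 6), elements=st.integers(0, 1)),
        st.floats(min_value=0.6, max_value=0.999),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fit_terminates_and_respects_decision_rule(self, X, comp):
        X = X[X.sum(axis=1) > 0]
        df = pd.DataFrame(X, index=[f"g{i}" for i in range(len(X))],
                          columns=[f"m{i}" for i in range(6)])
        res = CorePangenomeModel(df, {f"m{i}": comp for i in range(6)}).fit()
        assert res.n_iterations <= 100
        assert np.array_equal(res.core_mask, res.ll_core > res.ll_acc)


class TestRecoveryScaling:
    @staticmethod
    def _f1(n_genomes, completeness, seed):
        rng = np.random.default_rng(seed)
        core = rng.random((1000, n_genomes)) < completeness
        acc = (rng.random((1000, n_genomes)) < 0.3) & (
            rng.random((1000, n_genomes)) < completeness
        )
        genes = [f"core{i}" for i in range(1000)] + [f"acc{i}" for i in range(1000)]
        df = pd.DataFrame(np.vstack([core, acc]).astype(int), index=genes,
                          columns=[f"g{i}" for i in range(n_genomes)])
        df = df.loc[df.sum(axis=1) > 0]
        res = CorePangenomeModel(df, {g: completeness for g in df.columns}).fit()
        truth = np.array([g.startswith("core") for g in df.index])
        found = res.core_mask
        tp = int((truth & found).sum())
        fp = int((~truth & found).sum())
        fn = int((truth & ~found).sum())
        return 2 * tp / (2 * tp + fp + fn)

    def test_f1_monotone_in_genomes_and_completeness(self):
        """Mean recovery F1 rises with more genomes and higher completeness."""
        grid = {
            (n, c): np.mean([self._f1(n, c, seed) for seed in range(5)])
            for n in (5, 10, 20) for c in (0.7, 0.8, 0.9)
        }
        for c in (0.7, 0.8, 0.9):
            assert grid[(5, c)] <= grid[(10, c)] <= grid[(20, c)]
        for n in (5, 10, 20):
            assert grid[(n, 0.7)] <= grid[(n, 0.8)] <= grid[(n, 0.9)]


class TestSummaries:
    def test_summary_counts_match_assignment(self):
        df, comp = planted(seed=2)
        res = CorePangenomeModel(df, comp).fit()
        text = res.summary()
        assert f"core genes:            {len(res.core_genes)}" in text
        assert f"accessory genes:       {len(res.accessory_genes)}" in text

    def test_partition_frame_and_multi_motu_summary(self):
        df, comp = planted(seed=2)
        motus = {"mOTU01": list(df.columns[:5]), "mOTU02": list(df.columns[5:])}
        fits = fit_motu_partitions(df, comp, motus)
        summary = mk.summarize_partitions(fits)
        assert len(summary) == 2
        for _, row in summary.iterrows():
            res = fits[row["motu_id"]]
            assert row["n_core"] == len(res.core_genes)
            assert row["n_accessory"] == len(res.accessory_genes)
        frame = fits["mOTU01"].to_frame()
        assert set(frame.columns) == {"gene", "assignment", "loglik_core",
                                      "loglik_accessory"}
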