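"""Pipeline: query mapping, copy-number normalization, summarization."""

import numpy as np
import pandas as pd
import pytest

from piphillin import (
    Assignment,
    PipelineError,
    ValidationError,
    contribution_table,
    function_abundance,
    genome_abundance,
    map_queries,
    run_piphillin,
    per_sample_spearman,
    synthetic,
)
from conftest import random_seq, toy_pack


def _assign(qid, genomes, identity=100.0, passed=True):
    return Assignment(qid, tuple(sorted(genomes)), identity, passed)


class TestMapQueries:
    def test_all_exact_queries_pass_at_100(self, small_table):
        seq = random_seq(np.random.default_rng(0), 80)
        pack = toy_pack({"g1": [seq]})
        queries = {q: seq for q in small_table.index}
        assignments, stats = map_queries(queries, small_table, pack, 100.0)
        assert stats.fraction_reads_passed == 1.0
        assert stats.n_queries_passed == 3
        assert all(a.passed for a in assignments)

    def test_no_query_above_cutoff_gives_empty_but_wellformed_tables(
        self, small_table
    ):
        pack = toy_pack({"g1": ["A" * 80]}, {"g1": {"F1": 2}})
        queries = {q: "T" * 80 for q in small_table.index}
        assignments, stats = map_queries(queries, small_table, pack, 99.0)
        assert stats.fraction_reads_passed == 0.0
        genome_table = genome_abundance(small_table, assignments, pack)
        assert genome_table.empty
        function_table = function_abundance(genome_table, pack)
        assert list(function_table.columns) == list(small_table.columns)
        assert (function_table.to_numpy() == 0).all()

    def test_read_weighted_fraction_with_known_identities(self):
        rng = np.random.default_rng(5)
        ref = random_seq(rng, 1000)
        # a query at exactly 97.0% identity: 30 substitutions in 1000 bp
        noisy = list(ref)
        for pos in range(0, 900, 30):
            noisy[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[noisy[pos]]
        pack = toy_pack({"g1": [ref]})
        queries = {"exact": ref, "noisy": "".join(noisy)}
        table = pd.DataFrame({"s1": [50.0, 30.0], "s2": [0.0, 20.0]},
                             index=["exact", "noisy"])
        assignments, stats = map_queries(queries, table, pack, 99.0)
        by_id = {a.query_id: a for a in assignments}
        assert by_id["noisy"].identity_pct == pytest.approx(97.0)
        assert not by_id["noisy"].passed
        # half of the 100 reads sit on the failing query
        assert stats.fraction_reads_passed == pytest.approx(0.5)

    def test_query_missing_from_table_warns_and_is_unweighted(self, small_table):
        seq = "ACGT" * 20
        pack = toy_pack({"g1": [seq]})
        queries = {"q1": seq, "phantom": seq}
        with pytest.warns(UserWarning, match="phantom"):
            _, stats = map_queries(
                queries, small_table.loc[["q1"]], pack, 50.0
            )
        assert stats.reads_total == small_table.loc["q1"].sum()
        with pytest.raises(ValidationError):
            map_queries(queries, small_table.loc[["q1"]], pack, 50.0,
                        on_missing="error")


class TestGenomeAbundance:
    def test_single_query_divided_by_copy_number(self):
        pack = toy_pack({"g1": ["ACGTACGT"] * 5})
        table = pd.DataFrame({"s1": [10.0]}, index=["q1"])
        out = genome_abundance(table, [_assign("q1", ["g1"])], pack)
        assert out.at["g1", "s1"] == pytest.approx(2.0)

    def test_additivity_then_division(self):
        pack = toy_pack({"g1": ["ACGTACGT"] * 2})
        table = pd.DataFrame({"s1": [6.0, 4.0]}, index=["q1", "q2"])
        out = genome_abundance(
            table, [_assign("q1", ["g1"]), _assign("q2", ["g1"])], pack
        )
        assert out.at["g1", "s1"] == pytest.approx(5.0)

    def test_tie_split_shares_counts(self):
        pack = toy_pack({"g1": ["ACGTACGT"] * 2, "g2": ["ACGTACGA"] * 4})
        table = pd.DataFrame({"s1": [8.0]}, index=["q1"])
        out = genome_abundance(table, [_assign("q1", ["g1", "g2"])], pack)
        assert out.at["g1", "s1"] == pytest.approx(2.0)
        assert out.at["g2", "s1"] == pytest.approx(1.0)

    def test_tie_first_gives_all_to_lexicographic_min(self):
        pack = toy_pack({"g1": ["ACGTACGT"] * 2, "g2": ["ACGTACGA"] * 4})
        table = pd.DataFrame({"s1": [8.0]}, index=["q1"])
        out = genome_abundance(
            table, [_assign("q1", ["g1", "g2"])], pack, tie_policy="first"
        )
        assert out.at["g1", "s1"] == pytest.approx(4.0)
        assert "g2" not in out.index

    def test_unknown_genome_is_consistency_error(self):
        pack = toy_pack({"g1": ["ACGT"]})
        table = pd.DataFrame({"s1": [1.0]}, index=["q1"])
        with pytest.raises(PipelineError, match="ghost"):
            genome_abundance(table, [_assign("q1", ["ghost"])], pack)


class TestFunctionAbundance:
    def test_single_genome_product(self):
        pack = toy_pack({"g1": ["ACGT"]}, {"g1": {"F": 3}})
        genome_table = pd.DataFrame({"s1": [2.0]}, index=["g1"])
        out = function_abundance(genome_table, pack)
        assert out.at["F", "s1"] == pytest.approx(6.0)

    def test_shared_function_sums_products(self):
        pack = toy_pack(
            {"g1": ["ACGT"], "g2": ["AAAA"]},
            {"g1": {"F": 3}, "g2": {"F": 1, "G": 2}},
        )
        genome_table = pd.DataFrame({"s1": [2.0, 5.0]}, index=["g1", "g2"])
        out = function_abundance(genome_table, pack)
        assert out.at["F", "s1"] == pytest.approx(2 * 3 + 5 * 1)
        assert out.at["G", "s1"] == pytest.approx(10.0)

    def test_matches_naive_triple_loop(self, noisy_bundle):
        pack = noisy_bundle.pack
        rng = np.random.default_rng(2)
        genome_table = pd.DataFrame(
            rng.random((len(pack.genome_ids), 3)),
            index=pack.genome_ids, columns=["a", "b", "c"],
        )
        out = function_abundance(genome_table, pack)
        for fid in pack.function_ids[::7]:
            for s in genome_table.columns:
                expected = 0.0
                for gid in pack.genome_ids:
                    expected += genome_table.at[gid, s] * pack.genomes[
                        gid
                    ].function_copies.get(fid, 0)
                assert out.at[fid, s] == pytest.approx(expected, rel=1e-12)


class TestContributionTable:
    def test_marginalizing_recovers_function_table(self, noisy_bundle):
        pack = noisy_bundle.pack
        rng = np.random.default_rng(3)
        genome_table = pd.DataFrame(
            rng.random((len(pack.genome_ids), 2)) * 10,
            index=pack.genome_ids, columns=["a", "b"],
        )
        contrib = contribution_table(genome_table, pack)
        func = function_abundance(genome_table, pack)
        marg = contrib.pivot_table(
            index="function_id", columns="sample_id", values="contribution",
            aggfunc="sum", fill_value=0.0,
        )
        common = func.loc[(func != 0).any(axis=1)]
        assert np.allclose(
            marg.loc[common.index, common.columns], common, atol=1e-9
        )

    def test_single_genome_contribution_equals_function_table(self):
        pack = toy_pack({"g1": ["ACGT"]}, {"g1": {"F": 3, "G": 1}})
        genome_table = pd.DataFrame({"s1": [2.0]}, index=["g1"])
        contrib = contribution_table(genome_table, pack)
        func = function_abundance(genome_table, pack)
        for _, row in contrib.iterrows():
            assert row["genome_id"] == "g1"
            assert row["contribution"] == func.at[row["function_id"], row["sample_id"]]

    def test_zero_abundance_rows_omitted_unless_requested(self):
        pack = toy_pack({"g1": ["ACGT"]}, {"g1": {"F": 3}})
        genome_table = pd.DataFrame({"s1": [0.0]}, index=["g1"])
        assert contribution_table(genome_table, pack).empty
        kept = contribution_table(genome_table, pack, include_zeros=True)
        assert len(kept) == 1 and kept["contribution"].iloc[0] == 0.0


class TestRunPipeline:
    @pytest.fixture(scope="class")
    @staticmethod
    def clean_dir(tmp_path_factory, clean_bundle):
        d = tmp_path_factory.mktemp("bundle")
        synthetic.write_bundle(clean_bundle, d)
        return d

    def test_exact_recovery_on_clean_community(self, clean_dir, clean_bundle, tmp_path):
        paths = run_piphillin(
            clean_dir / "queries.fasta", clean_dir / "query_table.csv",
            clean_dir / "pack", 100.0, "split", tmp_path / "out",
        )
        genome_table = pd.read_csv(paths["genome_abundance"], index_col=0)
        truth = clean_bundle.community.true_genome_table
        # equality up to one per-sample scale factor
        ratio = genome_table / truth.loc[genome_table.index, genome_table.columns]
        assert np.allclose(ratio, ratio.iloc[0], rtol=1e-9)
        pred = pd.read_csv(paths["function_abundance"], index_col=0)
        rho = per_sample_spearman(pred, clean_bundle.community.true_function_table)
        assert np.allclose(rho, 1.0, atol=1e-9)

    def test_identical_runs_are_byte_identical(self, clean_dir, tmp_path):
        args = (clean_dir / "queries.fasta", clean_dir / "query_table.csv",
                clean_dir / "pack", 99.0, "split")
        p1 = run_piphillin(*args, tmp_path / "r1")
        p2 = run_piphillin(*args, tmp_path / "r2")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_mass_bookkeeping(self, clean_dir, clean_bundle, tmp_path):
        paths = run_piphillin(
            clean_dir / "queries.fasta", clean_dir / "query_table.csv",
            clean_dir / "pack", 100.0, "split", tmp_path / "out",
        )
        genome_table = pd.read_csv(paths["genome_abundance"], index_col=0)
        pack = clean_bundle.pack
        copies = pack.ssu_copy_numbers().loc[genome_table.index]
        # sum_g abundance(g, s) * copy(g) == passing read mass in sample s
        recovered = genome_table.mul(copies, axis=0).sum(axis=0)
        expected = clean_bundle.community.query_table.sum(axis=0)
        assert np.allclose(recovered, expected, rtol=1e-9)

    def test_pipeline_linearity(self, clean_dir, tmp_path):
        doubled = pd.read_csv(clean_dir / "query_table.csv", index_col=0) * 2
        doubled.to_csv(tmp_path / "doubled.csv")
        p1 = run_piphillin(clean_dir / "queries.fasta",
                           clean_dir / "query_table.csv",
                           clean_dir / "pack", 100.0, "split", tmp_path / "r1")
        p2 = run_piphillin(clean_dir / "queries.fasta", tmp_path / "doubled.csv",
                           clean_dir / "pack", 100.0, "split", tmp_path / "r2")
        f1 = pd.read_csv(p1["function_abundance"], index_col=0)
        f2 = pd.read_csv(p2["function_abundance"], index_col=0)
        assert np.allclose(2 * f1, f2, rtol=1e-12)

    def test_failure_removes_partial_outputs(self, clean_dir, tmp_path):
        bad_table = tmp_path / "bad.csv"
        bad_table.write_text("query_id,s1\nq1,-5\n")
        out = tmp_path / "out"
        with pytest.raises(PipelineError, match=r"\[load-inputs\]"):
            run_piphillin(clean_dir / "queries.fasta", bad_table,
                          clean_dir / "pack", 99.0, "split", out)
        assert not any(out.iterdir())

    def test_copy_number_invariance(self):
        # scaling one genome's copy number and its reads by c leaves its
        # inferred abundance unchanged
        seq = random_seq(np.random.default_rng(8), 200)
        for c in (1, 3):
            pack = toy_pack({"g1": [seq] * (2 * c)}, {"g1": {"F": 1}})
            table = pd.DataFrame({"s1": [10.0 * c]}, index=["q1"])
            out = genome_abundance(table, [_assign("q1", ["g1"])], pack)
            assert out.at["g1", "s1"] == pytest.approx(5.0)
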