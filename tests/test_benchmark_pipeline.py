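import sys

import numpy as np
import pytest
from scipy import stats

from alnvalid import (
    MethodConfig,
    ScoreParams,
    build_benchmark_group,
    compare_all,
    compare_methods,
    evaluate_group,
    make_group,
    plan_runs,
    report,
    resample,
    run_method,
    sw_score,
)
from alnvalid.errors import ContractError, IntegrityError, ToolError
from alnvalid.synthetic_data import SyntheticSpec, generate

PSA = MethodConfig(name="psa", params=ScoreParams())


def stub_cfg(name, script):
    return MethodConfig(
        name=name, kind="external-msa", command=(sys.executable, script, "{input}")
    )


@pytest.fixture(scope="module")
def small_dataset():
    return generate(SyntheticSpec(n_families=3, seqs_per_family=4, length=60, seed=11)).dataset


class TestBuildBenchmarkGroup:
    def test_pooling_and_labels(self, write_fasta_file):
        fa = write_fasta_file("a.fasta", [("s1", "MKWV"), ("s2", "MKWT")])
        fb = write_fasta_file("b.fasta", [("s3", "GGHH")])
        ds = build_benchmark_group([("famA", fa), ("famB", fb)])
        assert len(ds) == 3
        assert ds.families == ["famA", "famB"]
        assert ds.labels["s3"] == "famB"

    def test_multi_family_sequence_excluded(self, write_fasta_file):
        fa = write_fasta_file("a.fasta", [("s1", "MKWV"), ("s2", "MKWT")])
        fb = write_fasta_file("b.fasta", [("s2", "MKWT"), ("s3", "GGHH")])
        ds = build_benchmark_group([("famA", fa), ("famB", fb)])
        assert sorted(ds.sequences.ids) == ["s1", "s3"]

    def test_all_excluded_is_error(self, write_fasta_file):
        fa = write_fasta_file("a.fasta", [("s1", "MKWV")])
        fb = write_fasta_file("b.fasta", [("s1", "MKWV")])
        with pytest.raises(ContractError, match="empty"):
            build_benchmark_group([("famA", fa), ("famB", fb)])

    def test_single_family_rejected(self, write_fasta_file):
        fa = write_fasta_file("a.fasta", [("s1", "MKWV")])
        with pytest.raises(ContractError):
            build_benchmark_group([("famA", fa)])


class TestResample:
    def test_replicate_size_is_floor(self, small_dataset):
        reps = resample(small_dataset, fraction=0.9, reps=5, seed=0)
        assert len(reps) == 5
        assert all(len(r) == int(0.9 * len(small_dataset)) for r in reps)

    def test_full_fraction_copies_dataset(self, small_dataset):
        (rep,) = resample(small_dataset, fraction=1.0, reps=1, seed=0)
        assert rep.sequences.ids == small_dataset.sequences.ids

    def test_deterministic_under_seed(self, small_dataset):
        a = resample(small_dataset, 0.9, 4, seed=9)
        b = resample(small_dataset, 0.9, 4, seed=9)
        assert [r.sequences.ids for r in a] == [r.sequences.ids for r in b]
        c = resample(small_dataset, 0.9, 4, seed=10)
        assert [r.sequences.ids for r in a] != [r.sequences.ids for r in c]

    def test_labels_carried_through(self, small_dataset):
        (rep,) = resample(small_dataset, 0.8, 1, seed=2)
        assert all(rep.labels[i] == small_dataset.labels[i] for i in rep.sequences.ids)

    def test_too_small_replicate_rejected(self, small_dataset):
        with pytest.raises(ContractError):
            resample(small_dataset, fraction=0.05, reps=1, seed=0)

    def test_family_proportions_preserved_on_average(self, small_dataset):
        """Unstratified 90% draws should not skew family proportions: a
        chi-square test of pooled counts over many replicates is calm."""
        reps = resample(small_dataset, 0.9, 50, seed=123)
        fams = small_dataset.families
        counts = np.zeros(len(fams))
        for rep in reps:
            for f in rep.labels.values():
                counts[fams.index(f)] += 1
        expected = np.array(
            [sum(1 for v in small_dataset.labels.values() if v == f) for f in fams],
            dtype=float,
        )
        expected = expected / expected.sum() * counts.sum()
        assert stats.chisquare(counts, expected).pvalue > 0.01


class TestPlanRuns:
    def test_full_design_counts(self, small_dataset):
        groups = [make_group(f"g{i}", small_dataset, reps=10, seed=i) for i in range(8)]
        cfgs = [MethodConfig(name=f"m{j}") for j in range(7)]
        plan = plan_runs(groups, cfgs)
        assert len(plan) == 616
        assert all(len(g.datasets) == 11 for g in groups)


class TestRunMethod:
    def test_internal_psa_contract(self, small_dataset):
        d = run_method(small_dataset, PSA)
        assert d.ids == small_dataset.sequences.ids
        assert np.allclose(d.values, d.values.T)

    def test_stub_adapter_passthrough(self, small_dataset, stub_aligner):
        """The adapter must reproduce msa_distance_matrix of the stub output:
        here every sequence is padded with trailing gaps, so the projected
        identity is computable directly."""
        from alnvalid import msa_distance_matrix
        from alnvalid.containers import AlignmentMatrix

        d = run_method(small_dataset, stub_cfg("stub", stub_aligner))
        L = max(len(s) for s in small_dataset.sequences)
        rows = [s.residues + "-" * (L - len(s)) for s in small_dataset.sequences]
        expected = msa_distance_matrix(
            AlignmentMatrix(small_dataset.sequences.ids, rows)
        )
        assert np.allclose(d.values, expected.values)

    def test_dropping_aligner_is_integrity_error(self, small_dataset, dropping_aligner):
        first = small_dataset.sequences.ids[0]
        with pytest.raises(IntegrityError, match=first):
            run_method(small_dataset, stub_cfg("dropper", dropping_aligner))

    def test_failing_tool_is_tool_error(self, small_dataset, tmp_path):
        bad = tmp_path / "bad.py"
        bad.write_text("import sys; sys.stderr.write('boom'); sys.exit(3)\n")
        with pytest.raises(ToolError, match="exited 3") as exc:
            run_method(small_dataset, stub_cfg("bad", str(bad)))
        assert "boom" in exc.value.stderr

    def test_missing_executable_is_tool_error(self):
        cfg = MethodConfig(
            name="ghost", kind="external-msa", command=("no-such-aligner-xyz", "{input}")
        )
        with pytest.raises(ToolError):
            cfg.resolve_executable()


class TestEvaluateGroup:
    def test_row_count(self, small_dataset, stub_aligner):
        group = make_group("g", small_dataset, reps=3, seed=0)
        cfgs = [PSA, stub_cfg("stub", stub_aligner)]
        table = evaluate_group(group, cfgs)
        assert len(table) == (1 + 3) * 2
        assert set(table["method"]) == {"psa", "stub"}
        assert table["sw"].between(-1, 1).all()
        assert table["rs"].between(0, 1).all()

    def test_no_methods_empty_table(self, small_dataset):
        group = make_group("g", small_dataset, reps=2, seed=0)
        assert evaluate_group(group, []).empty

    def test_psa_beats_column_shuffled_alignment(self, shuffling_aligner):
        """Desk-scale analogue of the PSA-vs-MSA contrast: destroying the
        columns of an alignment must lower SW relative to the pairwise
        route on well-separated families."""
        ds = generate(
            SyntheticSpec(n_families=3, seqs_per_family=5, length=80, seed=5)
        ).dataset
        sw_psa = sw_score(run_method(ds, PSA), ds.labels)
        sw_shuffled = sw_score(
            run_method(ds, stub_cfg("shuffler", shuffling_aligner)), ds.labels
        )
        assert sw_psa > sw_shuffled


class TestCompareMethods:
    def test_identical_vectors_p_one(self):
        assert compare_methods([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]).p_value == 1.0

    def test_identical_constant_vectors_p_one(self):
        assert compare_methods([0.5] * 5, [0.5] * 5).p_value == 1.0

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.001, size=10)
        b = a + 5.0
        res = compare_methods(a, b)
        assert res.p_value < 1e-6
        assert res.mean_difference == pytest.approx(-5.0, abs=0.01)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(0.5, size=10)
        assert compare_methods(a, b).p_value == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue
        )

    def test_paired_matches_scipy(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=8)
        b = a + rng.normal(0.3, 0.1, size=8)
        assert compare_methods(a, b, paired=True).p_value == pytest.approx(
            stats.ttest_rel(a, b).pvalue
        )

    @pytest.mark.parametrize("a,b", [([1.0], [2.0]), ([1, 2], [1, 2, 3])])
    def test_bad_shapes_rejected(self, a, b):
        with pytest.raises(ContractError):
            compare_methods(a, b)


class TestReporting:
    def test_report_files_and_determinism(self, small_dataset, tmp_path):
        group = make_group("g", small_dataset, reps=3, seed=1)
        table = evaluate_group(group, [PSA])
        comps = compare_all(table)
        paths1 = report(table, comps, tmp_path / "r1")
        paths2 = report(table, comps, tmp_path / "r2")
        for key in paths1:
            assert paths1[key].read_bytes() == paths2[key].read_bytes()
        header = (tmp_path / "r1" / "scores.tsv").read_text().splitlines()[0]
        assert header.split("\t") == ["group", "dataset", "method", "n", "sw", "rs"]

    def test_end_to_end_deterministic_with_internal_psa(self, small_dataset):
        t1 = evaluate_group(make_group("g", small_dataset, reps=2, seed=7), [PSA])
        t2 = evaluate_group(make_group("g", small_dataset, reps=2, seed=7), [PSA])
        assert t1.equals(t2)

    def test_summary_names_best_method(self, small_dataset, shuffling_aligner, tmp_path):
        group = make_group("g", small_dataset, reps=2, seed=2)
        cfgs = [PSA, stub_cfg("shuffler", shuffling_aligner)]
        table = evaluate_group(group, cfgs)
        report(table, [], tmp_path)
        summary = (tmp_path / "summary.tsv").read_text()
        sw_line = [l for l in summary.splitlines() if "\tSW\t" in l][0]
        assert "psa" in sw_line

    def test_empty_scores_rejected(self, tmp_path):
        import pandas as pd

        with pytest.raises(ContractError):
            report(pd.DataFrame(), [], tmp_path)
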