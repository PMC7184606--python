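import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from polyatails import simulate as sim
from polyatails import stats
from polyatails.io import filter_qc_pass


class TestSummarizeTails:
    def test_constant_sample_has_matching_median_and_mode(self):
        s = stats.summarize_tails(np.full(10, 60.0))
        assert s.median == 60.0
        assert s.mode == 60.0
        assert s.density.max() == 1.0

    def test_median_is_sample_median(self):
        s = stats.summarize_tails([10, 20, 30, 40, 50])
        assert s.median == 30.0

    def test_density_is_max_scaled(self, default_dataset):
        records, _, _ = default_dataset
        s = stats.summarize_tails(records["polya_length"].head(500))
        assert s.density.max() == pytest.approx(1.0)
        assert (s.density >= 0).all()

    def test_mode_recovers_generator_truth_at_5000_reads(self, default_dataset):
        # Ig-like WT law peaks at 60 nt in the default calibration
        records, samples, truth = default_dataset
        merged = filter_qc_pass(records).merge(samples, on="sample_id")
        tails = merged.loc[
            merged["transcript_id"].str.startswith("ig_like")
            & (merged["condition"] == "WT"),
            "polya_length",
        ].to_numpy()[:5000]
        s = stats.summarize_tails(tails)
        assert abs(s.mode - 60.0) <= 3.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty"):
            stats.summarize_tails([])


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert stats.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_evaluated_step_up(self):
        # min_{j>=i} p(j)*4/j: all four collapse to 0.04
        np.testing.assert_allclose(
            stats.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1.0, size=200)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(stats.bh_adjust(p), expected, atol=1e-12)

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_dominates_input_and_capped_at_one(self, p):
        q = stats.bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)

    @given(st.lists(st.floats(1e-9, 1.0), min_size=2, max_size=40), st.randoms())
    @settings(deadline=None, max_examples=30)
    def test_invariant_under_input_permutation(self, p, rnd):
        idx = list(range(len(p)))
        rnd.shuffle(idx)
        q = stats.bh_adjust(p)
        q_perm = stats.bh_adjust([p[i] for i in idx])
        np.testing.assert_allclose([q_perm[idx.index(i)] for i in range(len(p))], q)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            stats.bh_adjust([1.5])


def _two_sample_records(a, b, reps=("rep1", "rep1")):
    n1, n2 = len(a), len(b)
    records = pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(n1 + n2)],
            "transcript_id": "tx",
            "polya_length": np.concatenate([a, b]),
            "qc_tag": "PASS",
            "sample_id": ["s1"] * n1 + ["s2"] * n2,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "condition": ["WT", "KO"],
            "replicate_id": list(reps),
        }
    )
    return records, samples


class TestDifferentialTest:
    def test_single_batch_equals_pooled_t_test(self):
        # OLS with one binary predictor is algebraically the pooled t-test
        rng = np.random.default_rng(1)
        for _ in range(100):
            n1, n2 = rng.integers(5, 40, size=2)
            a, b = rng.gamma(9, 7, n1), rng.gamma(9, 6, n2)
            records, samples = _two_sample_records(a, b)
            res = stats.test_differential_tails(records, samples, min_reads=1)
            la = np.log2(np.maximum(a, 1.0))
            lb = np.log2(np.maximum(b, 1.0))
            _, p_t = sps.ttest_ind(lb, la, equal_var=True)
            assert abs(res["p_value"].iloc[0] - p_t) < 1e-10

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(200):
            pooled = rng.gamma(10, 6, 80)
            records, samples = _two_sample_records(pooled[:40], pooled[40:])
            res = stats.test_differential_tails(records, samples, min_reads=1)
            ps.append(res["p_value"].iloc[0])
        assert sps.kstest(ps, "uniform").pvalue > 1e-3

    def test_batch_predictor_absorbs_strong_batch_shifts(self):
        # strong replicate shifts, no condition effect: nominal false-positive rate
        cfg = sim.default_config(
            seed=13,
            classes=(sim.TailClassConfig("null", {"WT": 60.0, "KO": 60.0}),),
            n_transcripts_per_class=300,
            reads_nb_mean=30.0,
            batch_log2_shift=(0.0, 0.4, -0.4),
        )
        records, samples, _ = sim.simulate_tail_dataset(cfg)
        res = stats.test_differential_tails(filter_qc_pass(records), samples)
        frac = (res["p_value"] < 0.05).mean()
        lo, hi = sps.binom.interval(0.99, len(res), 0.05)
        assert lo / len(res) <= frac <= hi / len(res)

    def test_default_generator_flags_ig_not_bulk(self, default_dataset):
        records, samples, truth = default_dataset
        res = stats.test_differential_tails(filter_qc_pass(records), samples)
        res = res.merge(
            truth.drop_duplicates("transcript_id")[["transcript_id", "class_label"]],
            on="transcript_id",
        )
        by_class = res.groupby("class_label")["significant"].mean()
        assert by_class["ig_like"] == 1.0
        assert by_class["bulk"] == 0.0
        assert by_class["mito_like"] == 0.0

    def test_read_count_prefilter_defines_tested_set(self, default_dataset):
        records, samples, _ = default_dataset
        recs = filter_qc_pass(records)
        res = stats.test_differential_tails(recs, samples, min_reads=10**6)
        assert res.empty

    def test_one_condition_absent_raises(self):
        records, samples = _two_sample_records(np.full(5, 60.0), np.full(5, 60.0))
        samples["condition"] = "WT"
        with pytest.raises(ValueError, match="two condition"):
            stats.test_differential_tails(records, samples, min_reads=1)

    def test_degenerate_transcript_reported_with_p_one(self):
        records, samples = _two_sample_records(np.full(25, 60.0), np.full(25, 60.0))
        res = stats.test_differential_tails(records, samples)
        assert res["p_value"].iloc[0] == 1.0
        assert bool(res["degenerate"].iloc[0])

    def test_filter_monotonicity_in_delta_median(self, default_dataset):
        records, samples, _ = default_dataset
        recs = filter_qc_pass(records)
        res_lo = stats.test_differential_tails(recs, samples, min_delta_median=5.0)
        res_hi = stats.test_differential_tails(recs, samples, min_delta_median=15.0)
        sig_lo = set(res_lo.loc[res_lo["significant"], "transcript_id"])
        sig_hi = set(res_hi.loc[res_hi["significant"], "transcript_id"])
        assert sig_hi <= sig_lo


class TestSignificanceFilters:
    def test_hand_set_fixture_yields_expected_subset(self, request):
        fixture = pd.read_csv(
            request.path.parent / "data" / "significance_fixture.tsv", sep="\t"
        )
        flags = stats.apply_significance_filters(
            fixture, alpha=0.05, min_delta_median=10.0, min_reads=20
        )
        significant = set(fixture.loc[flags, "transcript_id"])
        assert significant == {"tx_a", "tx_e"}


class TestCompareCounts:
    def test_counts_per_condition(self):
        records = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(4)],
                "transcript_id": ["X", "X", "X", "X"],
                "polya_length": 50.0,
                "qc_tag": ["PASS", "PASS", "PASS", "PASS"],
                "sample_id": ["wt", "wt", "wt", "ko"],
            }
        )
        samples = pd.DataFrame(
            {"sample_id": ["wt", "ko"], "condition": ["WT", "KO"],
             "replicate_id": ["rep1", "rep1"]}
        )
        table = stats.compare_counts(records, samples)
        row = table.set_index("transcript_id").loc["X"]
        assert row["count_WT"] == 3 and row["count_KO"] == 1

    def test_empty_input_gives_empty_table(self):
        records = pd.DataFrame(
            columns=["read_id", "transcript_id", "polya_length", "qc_tag", "sample_id"]
        )
        samples = pd.DataFrame(
            {"sample_id": ["s"], "condition": ["WT"], "replicate_id": ["rep1"]}
        )
        assert stats.compare_counts(records, samples).empty

    def test_mean_count_matches_negative_binomial_mean(self, default_dataset):
        records, samples, _ = default_dataset
        table = stats.compare_counts(records, samples)
        counts = table["count_WT"].to_numpy(dtype=float)
        # per condition: 3 replicates x NB(mean 75), 10% QC failures
        mu = 3 * 75.0 * 0.9
        sd = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - mu) <= 3 * sd
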