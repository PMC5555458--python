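"""Adjusted counts, the IP-enrichment score, the NB differential test and
target calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _support import null_count_matrix
from ripseed.enrichment import (
    CountMatrix,
    RIPEnrichment,
    adjusted_counts,
    bh_adjust,
    call_targets,
    fold_change_summary,
    ip_enrichment_score,
    nb_differential,
)


def _matrix(data: dict, transcripts=None) -> CountMatrix:
    idx = transcripts or [f"t{i}" for i in range(len(next(iter(data.values()))))]
    return CountMatrix(pd.DataFrame(data, index=idx))


class TestAdjustedCounts:
    def test_direct_proportion(self):
        cm = _matrix({"IP:1": [5, 95], "CTRL:1": [0, 10], "TOTAL:1": [1, 0]})
        adj = adjusted_counts(cm)
        assert adj.loc["t0", "IP:1"] == pytest.approx(0.05)
        assert adj.loc["t0", "CTRL:1"] == 0.0
        assert adj.loc["t0", "TOTAL:1"] == 1.0

    def test_columns_sum_to_one(self, small_dataset):
        sums = adjusted_counts(small_dataset.counts).sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_zero_total_library_error_names_sample(self):
        cm = _matrix({"IP:1": [1, 2], "CTRL:1": [0, 0]})
        with pytest.raises(ValueError, match="CTRL:1"):
            adjusted_counts(cm)

    @settings(derandomize=True, max_examples=50)
    @given(k=st.integers(2, 1000))
    def test_scale_invariance(self, k):
        base = _matrix({"IP:1": [3, 7, 10], "CTRL:1": [1, 1, 8]})
        scaled = CountMatrix(base.frame * k)
        pd.testing.assert_frame_equal(adjusted_counts(base), adjusted_counts(scaled))


class TestEnrichmentScore:
    @pytest.mark.parametrize(
        "ip,ctrl,total,expected",
        [
            (0.02, 0.005, 0.01, 1.5),
            (0.013, 0.013, 0.2, 0.0),
            (0.0, 0.004, 0.002, -2.0),
            (0.0, 0.0, 0.0, 0.0),  # zero numerator over zero total
        ],
    )
    def test_formula(self, ip, ctrl, total, expected):
        assert ip_enrichment_score(ip, ctrl, total) == pytest.approx(expected)

    def test_undefined_when_total_zero_with_signal(self):
        assert np.isnan(ip_enrichment_score(0.01, 0.0, 0.0))

    @settings(derandomize=True, max_examples=100)
    @given(
        ip=st.floats(0, 1, allow_nan=False),
        ctrl=st.floats(0, 1, allow_nan=False),
        total=st.floats(1e-6, 1, allow_nan=False),
    )
    def test_antisymmetric_under_ip_ctrl_swap(self, ip, ctrl, total):
        fwd = ip_enrichment_score(ip, ctrl, total)
        rev = ip_enrichment_score(ctrl, ip, total)
        assert fwd == pytest.approx(-rev, abs=1e-12)


class TestBHAdjust:
    def test_worked_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.37]) == pytest.approx([0.37])
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_output_in_unit_interval_and_bounded_below_by_p(self, ps):
        q = bh_adjust(ps)
        assert ((q >= 0) & (q <= 1)).all()
        assert (q >= np.asarray(ps) - 1e-12).all()  # BH never decreases a p


class TestNBDifferential:
    def test_identical_groups_give_null_result(self):
        col = [10, 250, 3, 999, 0]
        cm = _matrix(
            {"IP:1": col, "IP:2": col, "CTRL:1": col, "CTRL:2": col}
        )
        res = nb_differential(cm)
        assert np.allclose(res["log2_fold_enrichment"], 0.0)
        assert np.allclose(res["p_value"], 1.0)

    def test_all_zero_transcript_flagged(self):
        cm = _matrix({"IP:1": [0, 5], "IP:2": [0, 9], "CTRL:1": [0, 7], "CTRL:2": [0, 4]})
        res = nb_differential(cm)
        assert res.loc["t0", "all_zero"]
        assert res.loc["t0", "p_value"] == 1.0
        assert res.loc["t0", "log2_fold_enrichment"] == 0.0

    def test_null_type_one_error_near_nominal(self):
        res = nb_differential(null_count_matrix(2000, seed=11))
        frac = (res["p_value"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_matches_pydeseq2_direction_on_simulation(self, small_dataset):
        """Independent cross-check: per-transcript log2FC should track DESeq2."""
        inference_frame = small_dataset.counts.frame
        cols = [c for c in inference_frame.columns if c.startswith(("IP", "CTRL"))]
        counts = inference_frame[cols].T
        meta = pd.DataFrame(
            {"condition": [c.split(":")[0] for c in cols]}, index=cols
        )
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        dds = DeseqDataSet(
            counts=counts.astype(int), metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        stat = DeseqStats(dds, contrast=["condition", "IP", "CTRL"], quiet=True)
        stat.summary()
        ref = stat.results_df["log2FoldChange"]

        mine = nb_differential(small_dataset.counts)["log2_fold_enrichment"]
        both = pd.concat([mine, ref], axis=1).dropna()
        r = np.corrcoef(both.iloc[:, 0], both.iloc[:, 1])[0, 1]
        assert r > 0.9


class TestTargetCalling:
    def test_direct_thresholding(self):
        res = pd.DataFrame(
            {"q_value": [0.05, 0.2], "log2_fold_enrichment": [1.0, 3.0]},
            index=["t1", "t2"],
        )
        assert call_targets(res, q_threshold=0.1) == {"t1"}

    def test_nothing_passes_when_all_q_one(self):
        res = pd.DataFrame(
            {"q_value": [1.0, 1.0], "log2_fold_enrichment": [2.0, 2.0]},
            index=["t1", "t2"],
        )
        assert call_targets(res) == set()

    def test_negative_fold_change_never_called(self):
        res = pd.DataFrame(
            {"q_value": [0.001], "log2_fold_enrichment": [-3.0]}, index=["t1"]
        )
        assert call_targets(res) == set()

    def test_empty_results_warn(self):
        with pytest.warns(UserWarning):
            assert call_targets(pd.DataFrame()) == set()

    def test_gene_collapse_any_isoform(self):
        res = pd.DataFrame(
            {"q_value": [0.01, 0.9], "log2_fold_enrichment": [2.0, 0.1]},
            index=["gA.1", "gA.2"],
        )
        assert call_targets(res, {"gA.1": "gA", "gA.2": "gA"}) == {"gA"}

    def test_target_set_shrinks_as_threshold_tightens(self, small_dataset):
        model = RIPEnrichment(small_dataset.counts, small_dataset.gene_map)
        frame = model.fit(q_threshold=0.5).frame
        prev = None
        for q in (0.5, 0.2, 0.1, 0.01):
            cur = call_targets(frame, small_dataset.gene_map, q_threshold=q)
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestFoldChangeSummary:
    def test_constant_fold_changes(self):
        res = pd.DataFrame(
            {"log2_fold_enrichment": [0.0, 0.0, 0.0]}, index=["a", "b", "c"]
        )
        s = fold_change_summary(res, {"a"})
        assert s == (1.0, 1.0, 1.0, 1.0)

    def test_targets_equal_all(self):
        res = pd.DataFrame(
            {"log2_fold_enrichment": [1.0, 2.0]}, index=["a", "b"]
        )
        s = fold_change_summary(res, {"a", "b"})
        assert s.median_fc_targets == s.median_fc_all
        assert s.mean_fc_targets == s.mean_fc_all

    def test_empty_target_set_gives_nan(self):
        res = pd.DataFrame({"log2_fold_enrichment": [1.0]}, index=["a"])
        s = fold_change_summary(res, set())
        assert np.isnan(s.median_fc_targets) and np.isnan(s.mean_fc_targets)


class TestModelSurface:
    def test_fit_results_roundtrip_tsv(self, small_dataset, tmp_path):
        from ripseed import io

        res = RIPEnrichment(small_dataset.counts, small_dataset.gene_map).fit()
        res.to_tsv(tmp_path / "res.tsv")
        back = pd.read_csv(tmp_path / "res.tsv", sep="\t", index_col="transcript_id")
        assert set(back.columns) >= {
            "gene_id", "adj_IP", "adj_CTRL", "adj_TOTAL",
            "enrichment_score", "log2_fold_enrichment", "p_value", "q_value",
            "is_target",
        }
        io.write_counts(tmp_path / "c.tsv", small_dataset.counts)
        model = RIPEnrichment.from_tsv(tmp_path / "c.tsv")
        assert model.counts.frame.equals(small_dataset.counts.frame)

    def test_summary_reports_target_counts(self, small_dataset):
        res = RIPEnrichment(small_dataset.counts, small_dataset.gene_map).fit()
        text = res.summary()
        assert "target genes" in text
        assert str(len(res.target_genes())) in text

    def test_requires_ip_and_ctrl(self):
        with pytest.raises(ValueError, match="CTRL"):
            RIPEnrichment(_matrix({"IP:1": [1], "TOTAL:1": [1]}))

    def test_fold_change_plot(self, small_dataset):
        import matplotlib

        matplotlib.use("Agg")
        res = RIPEnrichment(small_dataset.counts, small_dataset.gene_map).fit()
        ax = res.plot_fold_change()
        assert ax.get_ylabel().startswith("log2")
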