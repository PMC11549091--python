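import numpy as np
import pandas as pd
import pytest

from caf_atlas import cnv, qc, synthetic
from caf_atlas.cnv import (CALL_MINUS, CALL_PLUS, CALL_UNDEFINED, CNVProfile,
                           classify_malignancy, cnv_score, flag_ptch_high,
                           infer_cnv_profiles, malignant_reference_profile,
                           order_genes_genomically, score_and_classify)
from caf_atlas.core import ExpressionMatrix, LOGNORM


def lognorm_matrix(values, gene_meta=None, cell_prefix="c"):
    values = np.asarray(values, dtype=float)
    cells = np.asarray([f"{cell_prefix}{i}" for i in range(values.shape[0])],
                       dtype=object)
    genes = np.asarray([f"g{j}" for j in range(values.shape[1])], dtype=object)
    if gene_meta is None:
        gene_meta = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(values.shape[1]) * 100,
            "end": np.arange(values.shape[1]) * 100 + 50,
        }, index=list(genes))
    return ExpressionMatrix(values, cells, genes, LOGNORM, None, gene_meta)


class TestOrderGenes:
    def test_orders_by_chrom_then_start(self):
        meta = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [100, 50, 10],
            "end": [110, 60, 20],
        }, index=["gA", "gB", "gC"])
        order = order_genes_genomically(meta)
        assert list(order.genes) == ["gB", "gA", "gC"]

    def test_duplicate_coordinates_tie_break_by_symbol(self):
        meta = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [5, 5],
                             "end": [6, 6]}, index=["gZ", "gA"])
        order = order_genes_genomically(meta)
        assert list(order.genes) == ["gA", "gZ"]

    def test_single_chromosome_single_block(self):
        meta = pd.DataFrame({"chrom": "chr1", "start": range(10),
                             "end": range(1, 11)},
                            index=[f"g{i}" for i in range(10)])
        order = order_genes_genomically(meta)
        assert order.blocks() == [(0, 10)]

    def test_natural_chromosome_order(self):
        meta = pd.DataFrame({"chrom": ["chr10", "chr2", "chrX"],
                             "start": [1, 1, 1], "end": [2, 2, 2]},
                            index=["a", "b", "c"])
        order = order_genes_genomically(meta)
        assert list(order.genes) == ["b", "a", "c"]

    def test_missing_coordinates_excluded_with_warning(self):
        meta = pd.DataFrame({"chrom": ["chr1", None], "start": [1, np.nan],
                             "end": [2, np.nan]}, index=["ok", "bad"])
        with pytest.warns(UserWarning, match="without coordinates"):
            order = order_genes_genomically(meta)
        assert list(order.genes) == ["ok"]
        assert order.dropped == ["bad"]


class TestInferProfiles:
    def test_identical_reference_cells_give_zero_profiles(self):
        values = np.tile(np.linspace(1, 3, 30), (8, 1))
        matrix = lognorm_matrix(values)
        prof = infer_cnv_profiles(matrix, matrix.cell_ids, window=5)
        assert np.all(np.abs(prof.values) < 1e-6)

    def test_low_detection_gene_dropped(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(1, 2, (10, 20))
        values[:, 3] = 0.0
        values[:2, 3] = 1.0  # expressed in exactly 2 cells
        matrix = lognorm_matrix(values)
        prof = infer_cnv_profiles(matrix, matrix.cell_ids,
                                  min_cells_per_gene=3, window=3)
        assert "g3" not in set(prof.window_gene_map)
        assert prof.n_positions == 19

    def test_empty_reference_errors(self):
        matrix = lognorm_matrix(np.ones((4, 10)))
        with pytest.raises(ValueError, match="reference"):
            infer_cnv_profiles(matrix, [])

    def test_rpkm_matrix_rejected(self):
        matrix = lognorm_matrix(np.ones((4, 10)))
        matrix.space_tag = "rpkm"
        with pytest.raises(ValueError, match="log-normalized"):
            infer_cnv_profiles(matrix, matrix.cell_ids)

    def test_window_shrunk_with_warning(self):
        rng = np.random.default_rng(1)
        matrix = lognorm_matrix(rng.uniform(1, 2, (6, 12)))
        with pytest.warns(UserWarning, match="shrunk"):
            prof = infer_cnv_profiles(matrix, matrix.cell_ids, window=101)
        assert prof.n_positions == 12

    def test_smoothing_never_crosses_chromosomes(self):
        # step signal on chr2 only; chr1 positions must stay flat
        values = np.ones((6, 40))
        values[:3, 20:] = 3.0  # cells 0-2 elevated on chr2
        gene_meta = pd.DataFrame({
            "chrom": ["chr1"] * 20 + ["chr2"] * 20,
            "start": list(range(20)) * 2,
            "end": list(range(1, 21)) * 2,
        }, index=[f"g{j}" for j in range(40)])
        matrix = lognorm_matrix(values, gene_meta=gene_meta)
        prof = infer_cnv_profiles(matrix, matrix.cell_ids[3:], window=7,
                                  clip=5.0)
        chr1 = prof.chroms == "chr1"
        spread_chr1 = prof.values[0, chr1].max() - prof.values[0, chr1].min()
        assert spread_chr1 < 1e-12

    def test_planted_gain_elevates_segment_windows(self):
        cfg = synthetic.SimConfig(
            n_donors=2,
            clusters=[synthetic.ClusterSpec("ref", 60),
                      synthetic.ClusterSpec("mal", 60)],
            n_genes=600, n_chromosomes=2,
            cnv_segments=[synthetic.CNVSegment("chr1", 50, 200, 1.5)],
            malignant_cluster="mal", seed=4,
        )
        raw, truth = synthetic.generate_atlas(cfg)
        matrix = qc.lognormalize(raw)
        assert matrix.n_cells >= 200
        ref = matrix.cell_ids[(truth.cell_cluster == "ref").to_numpy()]
        prof = infer_cnv_profiles(matrix, ref)
        mal_mask = truth.is_malignant.reindex(list(prof.cell_ids)).to_numpy()
        gene_idx = {g: i for i, g in enumerate(prof.window_gene_map)}
        # interior of the planted segment vs chr1 flanks
        seg = [gene_idx[g] for g in (f"G{i:04d}" for i in range(100, 200))
               if g in gene_idx]
        flank = [gene_idx[g] for g in (f"G{i:04d}" for i in range(280, 300))
                 if g in gene_idx]
        mean_seg = prof.values[np.ix_(mal_mask, seg)].mean()
        mean_flank = prof.values[np.ix_(mal_mask, flank)].mean()
        assert mean_seg > 0
        assert mean_seg > mean_flank


class TestCnvScore:
    def test_zero_profile(self):
        assert cnv_score(np.zeros((1, 10)))[0] == 0.0

    def test_constant_profile_closed_form(self):
        assert cnv_score(np.full((1, 7), 0.3))[0] == pytest.approx(0.09)

    def test_matches_elementwise_oracle_exactly(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(5, 33))
        scores = cnv_score(values)
        for i in range(5):
            acc = 0.0
            for v in values[i]:
                acc += v * v
            # brute-force reference; summation order may differ at 1 ulp
            assert scores[i] == pytest.approx(acc / 33, rel=1e-12)

    def test_sum_option(self):
        values = np.random.default_rng(0).normal(size=(2, 9))
        assert np.allclose(cnv_score(values, mean=False),
                           cnv_score(values) * 9)

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError):
            cnv_score(np.empty((2, 0)))


def profile_of(values, cells=None):
    values = np.asarray(values, dtype=float)
    cells = cells or [f"c{i}" for i in range(values.shape[0])]
    genes = np.asarray([f"g{j}" for j in range(values.shape[1])], dtype=object)
    return CNVProfile(values, np.asarray(cells, dtype=object), genes,
                      np.asarray(["chr1"] * values.shape[1], dtype=object))


class TestMalignantReference:
    def test_identical_profiles_reference_equals_profile(self):
        row = np.linspace(-1, 1, 20)
        prof = profile_of(np.tile(row, (12, 1)))
        samples = pd.Series("s1", index=list(prof.cell_ids))
        refs = malignant_reference_profile(prof, samples)
        assert np.allclose(refs["s1"], row)

    def test_two_samples_no_cross_talk(self):
        values = np.vstack([np.ones((10, 5)), np.full((10, 5), -2.0)])
        prof = profile_of(values)
        samples = pd.Series(["s1"] * 10 + ["s2"] * 10,
                            index=list(prof.cell_ids))
        refs = malignant_reference_profile(prof, samples)
        assert np.allclose(refs["s1"], 1.0)
        assert np.allclose(refs["s2"], -2.0)

    def test_small_sample_falls_back_to_top1(self):
        prof = profile_of(np.random.default_rng(0).normal(size=(4, 6)))
        samples = pd.Series("s", index=list(prof.cell_ids))
        with pytest.warns(UserWarning, match="top-1"):
            refs = malignant_reference_profile(prof, samples, top_fraction=0.1)
        sos = cnv_score(prof)
        assert np.allclose(refs["s"], prof.values[np.argmax(sos)])


class TestClassify:
    @pytest.mark.parametrize("r,sos,lineage,expected", [
        (0.50, 0.020, "keratinocyte", CALL_PLUS),
        (0.50, 0.010, "keratinocyte", CALL_UNDEFINED),
        (0.30, 0.020, "keratinocyte", CALL_UNDEFINED),
        (0.30, 0.010, "keratinocyte", CALL_MINUS),
        (0.45, 0.017, "keratinocyte", CALL_PLUS),   # inclusive cutoffs
        (0.42, 0.030, "melanocyte", CALL_PLUS),
        (0.42, 0.020, "melanocyte", CALL_UNDEFINED),
        (0.0, 0.0, "keratinocyte", CALL_MINUS),     # flat profile convention
        (0.0, 0.0, "melanocyte", CALL_MINUS),
    ])
    def test_quadrants(self, r, sos, lineage, expected):
        assert classify_malignancy(r, sos, lineage)[0] == expected

    def test_nan_r_treated_as_zero(self):
        assert classify_malignancy(np.nan, 0.001, "keratinocyte")[0] == CALL_MINUS

    def test_unknown_lineage_errors(self):
        with pytest.raises(ValueError, match="lineage"):
            classify_malignancy(0.5, 0.02, "fibroblast")


class TestScaleInvariance:
    def test_rpkm_rescaling_leaves_calls_unchanged(self):
        cfg = synthetic.SimConfig(
            n_donors=2,
            clusters=[synthetic.ClusterSpec("ref", 40),
                      synthetic.ClusterSpec("mal", 40)],
            n_genes=400, n_chromosomes=2,
            cnv_segments=[synthetic.CNVSegment("chr1", 20, 150, 1.5)],
            malignant_cluster="mal", seed=8,
        )
        raw, truth = synthetic.generate_atlas(cfg)
        scaled = ExpressionMatrix(raw.values * 7.5, raw.cell_ids, raw.gene_ids,
                                  raw.space_tag, raw.cell_meta, raw.gene_meta)
        calls = []
        for m in (raw, scaled):
            ln = qc.lognormalize(m)
            ref = ln.cell_ids[(truth.cell_cluster == "ref").to_numpy()]
            prof = infer_cnv_profiles(ln, ref)
            calls.append(score_and_classify(
                prof, ln.cell_meta["sample"], "keratinocyte"))
        pd.testing.assert_frame_equal(calls[0], calls[1])


class TestFlagPtch:
    def make_matrix(self):
        rng = np.random.default_rng(6)
        values = rng.uniform(1, 2, (40, 4))
        genes = np.asarray(["PTCH1", "PTCH2", "other1", "other2"], dtype=object)
        cells = np.asarray([f"c{i}" for i in range(40)], dtype=object)
        return ExpressionMatrix(values, cells, genes, LOGNORM)

    def test_cell_at_healthy_mean_not_flagged(self):
        m = self.make_matrix()
        healthy = list(m.cell_ids[:30])
        mean1 = m.values[:30, 0].mean()
        m.values[35, :2] = [mean1, m.values[:30, 1].mean()]
        flags = flag_ptch_high(m, list(m.cell_ids[30:]), healthy)
        assert not flags.loc["c35"]

    def test_cell_three_sd_above_flagged(self):
        m = self.make_matrix()
        healthy = list(m.cell_ids[:30])
        g2 = m.values[:30, 1]
        m.values[36, 1] = g2.mean() + 3 * g2.std()
        m.values[36, 0] = 0.0
        flags = flag_ptch_high(m, list(m.cell_ids[30:]), healthy)
        assert flags.loc["c36"]

    def test_healthy_cluster_flagged_fraction_matches_recomputation(self):
        m = self.make_matrix()
        healthy = list(m.cell_ids)
        flags = flag_ptch_high(m, healthy, healthy, k_sd=1.0)
        expected = np.zeros(m.n_cells, dtype=bool)
        for g in (0, 1):
            col = m.values[:, g]
            expected |= col > col.mean() + 1.0 * col.std()
        assert np.array_equal(flags.to_numpy(), expected)

    def test_missing_genes_error(self):
        m = lognorm_matrix(np.ones((4, 5)))
        with pytest.raises(ValueError, match="PTCH"):
            flag_ptch_high(m, list(m.cell_ids), list(m.cell_ids))
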