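import numpy as np
import pandas as pd
import pytest

from metabodiverge import SynthConfig, filter_by_missingness, generate_panel
from metabodiverge.preprocess import impute_random_forest, process_blocks
from metabodiverge.synth import inject_missingness

from conftest import make_manual_panel


def _panel_with_zero_pattern(zeros_h, zeros_l, n_per_line=24):
    """Three metabolites: clean, asymmetric zeros, symmetric zeros."""
    rng = np.random.default_rng(0)
    n = 2 * n_per_line
    x = np.exp(rng.normal(10, 0.5, size=(n, 3)))
    line = np.repeat(["H", "L"], n_per_line)
    x[:zeros_h, 1] = 0.0  # H-line zeros for metabolite 1
    x[n_per_line : n_per_line + zeros_l, 1] = 0.0
    x[:3, 2] = 0.0
    x[n_per_line : n_per_line + 3, 2] = 0.0
    return make_manual_panel(x, line)


class TestFilterByMissingness:
    def test_kept_iff_below_threshold_in_at_least_one_line(self):
        # metabolite 1: 3 zeros in H (12.5%) but 1 in L (4.17%) -> kept;
        # metabolite 2: 3 zeros in both lines (12.5% each) -> removed
        panel = _panel_with_zero_pattern(zeros_h=3, zeros_l=1)
        filtered, report = filter_by_missingness(panel, max_zero_frac=0.10)
        assert list(report.kept) == ["M000", "M001"]
        assert list(report.removed) == ["M002"]
        np.testing.assert_allclose(
            report.zero_frac_by_line.loc["M001"], [3 / 24, 1 / 24]
        )

    def test_strictness_of_the_threshold(self):
        # exactly 10% zeros in the better line is NOT strictly below 10%
        rng = np.random.default_rng(1)
        x = np.exp(rng.normal(size=(40, 2)))
        x[:2, 1] = 0.0  # 2/20 = 10% in H
        x[20:23, 1] = 0.0  # 15% in L
        panel = make_manual_panel(x, np.repeat(["H", "L"], 20))
        _, report = filter_by_missingness(panel, max_zero_frac=0.10)
        assert "M001" in report.removed

    def test_filtering_is_idempotent(self, small_panel):
        once, _ = filter_by_missingness(small_panel)
        twice, report = filter_by_missingness(once)
        assert len(report.removed) == 0
        pd.testing.assert_frame_equal(once.abundance, twice.abundance)

    def test_partition_covers_all_metabolites(self, small_panel):
        _, report = filter_by_missingness(small_panel)
        union = report.kept.union(report.removed)
        assert union.sort_values().equals(small_panel.abundance.columns.sort_values())


class TestImputeRandomForest:
    def test_panel_without_zeros_returned_unchanged(self):
        rng = np.random.default_rng(2)
        panel = make_manual_panel(np.exp(rng.normal(size=(12, 4))), ["H"] * 6 + ["L"] * 6)
        out = impute_random_forest(panel, seed=0, n_estimators=10)
        pd.testing.assert_frame_equal(out.abundance, panel.abundance)

    def test_only_zero_cells_change_and_all_become_positive(self, small_panel):
        filtered, _ = filter_by_missingness(small_panel)
        out = impute_random_forest(filtered, seed=0, n_estimators=20)
        mask = (filtered.abundance == 0).to_numpy()
        assert (out.abundance > 0).all().all()
        before = filtered.abundance.to_numpy()
        after = out.abundance.to_numpy()
        assert (before[~mask] == after[~mask]).all()

    def test_collinear_column_imputed_near_linear_prediction(self):
        # metabolite 1 is exactly 2x metabolite 0; the forest should place
        # the single missing cell close to the closed-form 2 * x0
        rng = np.random.default_rng(3)
        x0 = np.exp(rng.normal(10, 0.8, size=48))
        noise = np.exp(rng.normal(10, 0.5, size=(48, 2)))
        x = np.column_stack([x0, 2.0 * x0, noise])
        hole = np.argsort(x0)[24]  # mid-range target, inside training support
        expected = x[hole, 1]
        x[hole, 1] = 0.0
        panel = make_manual_panel(x, np.repeat(["H", "L"], 24))
        out = impute_random_forest(panel, seed=4, n_estimators=100)
        got = out.abundance.iloc[hole, 1]
        assert abs(got - expected) / expected < 0.25

    def test_beats_median_imputation_on_correlated_panel(self):
        config = SynthConfig(
            n_per_line=24, n_metabolites_per_block=(8, 8, 8, 8),
            frac_affected=0.0, zero_rate_range=(0.0, 0.0),
            latent_rank=3, latent_sd=1.2, seed=6,
        )
        complete = generate_panel(config)
        holey = inject_missingness(complete, 0.10, seed=13)
        mask = holey.abundance == 0
        out = impute_random_forest(holey, seed=7, n_estimators=50)

        truth = np.log(complete.abundance.to_numpy()[mask.to_numpy()])
        rf = np.log(out.abundance.to_numpy()[mask.to_numpy()])
        med = holey.abundance.replace(0, np.nan).median()
        med_fill = np.log(
            pd.DataFrame(
                np.broadcast_to(med.to_numpy(), holey.abundance.shape),
                index=holey.abundance.index, columns=holey.abundance.columns,
            ).to_numpy()[mask.to_numpy()]
        )
        rmse_rf = np.sqrt(np.mean((rf - truth) ** 2))
        rmse_med = np.sqrt(np.mean((med_fill - truth) ** 2))
        assert rmse_rf < rmse_med

    def test_fully_zero_column_is_an_error(self):
        rng = np.random.default_rng(8)
        x = np.exp(rng.normal(size=(12, 3)))
        x[:, 2] = 0.0
        panel = make_manual_panel(x, ["H"] * 6 + ["L"] * 6)
        with pytest.raises(ValueError, match="fully-missing"):
            impute_random_forest(panel, seed=0, n_estimators=5)


class TestProcessBlocks:
    def test_join_width_loses_one_reference_per_block(self):
        config = SynthConfig(
            n_per_line=12, n_metabolites_per_block=(12, 8, 10, 6),
            zero_rate_range=(0.0, 0.0), seed=9,
        )
        panel = generate_panel(config)
        out = process_blocks(panel.split_blocks(), impute_seed=0, n_estimators=10)
        assert out.data.shape == (24, 36 - 4)
        assert set(out.block_of) == {
            "positive-early", "positive-late", "negative", "polar",
        }
        assert out.data.index.equals(panel.abundance.index)

    def test_single_block_matches_direct_staging(self, small_panel):
        from metabodiverge.compositional import select_alr_reference

        block = small_panel.split_blocks()["polar"]
        joined = process_blocks([block], impute_seed=1, n_estimators=10)
        filtered, _ = filter_by_missingness(block)
        imputed = impute_random_forest(filtered, seed=1, n_estimators=10)
        direct = select_alr_reference(imputed.abundance).transformed
        pd.testing.assert_frame_equal(joined.data, direct)

    def test_disjoint_sample_sets_rejected(self, small_panel):
        blocks = small_panel.split_blocks()
        a = blocks["polar"]
        b = blocks["negative"]
        shifted = b.abundance.copy()
        shifted.index = ["x" + str(i) for i in range(len(shifted))]
        bad = type(b)(
            abundance=shifted,
            samples=b.samples.set_axis(shifted.index),
            blocks=b.blocks,
        )
        with pytest.raises(ValueError, match="sample set"):
            process_blocks({"polar": a, "negative": bad})
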