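"""Normalization, dispersion, and the quasi-NB Wald tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from teshift import (
    RegulationCategory,
    SimulationConfig,
    bh_adjust,
    estimate_dispersion,
    filter_background,
    nb_glm,
    normalized_counts,
    simulate_counts,
    size_factors,
)
from teshift import test_assay_shift as assay_shift
from teshift import test_te_shift as te_shift

from conftest import make_matrix


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile([[10], [200], [3]], (1, 4))
        cm = make_matrix(counts)
        assert np.allclose(size_factors(cm), 1.0)

    def test_doubled_sample_has_doubled_factor(self):
        base = np.array([[10, 20], [100, 50], [7, 7]])
        doubled = np.column_stack([base, 2 * base[:, 0]])
        samples = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "assay": ["rna", "rna", "rna"],
                "condition": ["A", "A", "A"],
                "replicate": ["1", "2", "3"],
            }
        )
        from teshift import CountMatrix

        cm = CountMatrix(
            pd.DataFrame(doubled, index=[f"g{i}" for i in range(3)],
                         columns=samples["sample_id"]),
            samples,
        )
        f = size_factors(cm)
        assert f["s3"] / f["s1"] == pytest.approx(2.0, rel=1e-12)

    def test_hand_computed_median_of_ratios(self):
        # counts [[2,4],[8,16]]: per-gene geometric means sqrt(8), sqrt(128);
        # every ratio is 1/sqrt(2) or sqrt(2), so factors are [0.7071, 1.4142]
        df = pd.DataFrame([[2, 4], [8, 16]], columns=["s1", "s2"])
        f = size_factors(df)
        assert f.to_numpy() == pytest.approx([0.70710678, 1.41421356], rel=1e-8)
        assert np.prod(f) == pytest.approx(1.0)

    def test_no_fully_expressed_gene_errors(self):
        df = pd.DataFrame([[0, 4], [8, 0]], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="background filter"):
            size_factors(df)


class TestDispersion:
    @staticmethod
    def _norm(config):
        cm, _ = simulate_counts(config)
        bg = filter_background(cm)
        return normalized_counts(bg), bg

    def test_poisson_counts_give_near_zero_dispersion(self):
        lg = 3.0
        config = SimulationConfig(
            n_genes=500, seed=1, dispersion=0.0, conditions=("A", "B"),
            n_replicates=6, base_mean_log_range=(lg, lg), te_baseline_sd=0.0,
            category_proportions={RegulationCategory.UNREGULATED: 1.0},
        )
        norm, bg = self._norm(config)
        groups = [bg.sample_ids(assay=a, condition=c) for a in ("rna", "ribo") for c in ("A", "B")]
        disp = estimate_dispersion(norm, groups)
        assert disp.alpha_raw.median() <= 0.01
        assert disp.alpha_trend <= 0.01

    def test_nb_dispersion_recovered_with_many_replicates(self):
        lg = 3.0
        config = SimulationConfig(
            n_genes=300, seed=2, dispersion=0.2, conditions=("A", "B"),
            n_replicates=50, base_mean_log_range=(lg, lg), te_baseline_sd=0.0,
            category_proportions={RegulationCategory.UNREGULATED: 1.0},
        )
        norm, bg = self._norm(config)
        groups = [bg.sample_ids(assay=a, condition=c) for a in ("rna", "ribo") for c in ("A", "B")]
        disp = estimate_dispersion(norm, groups)
        assert 0.1 <= disp.alpha_raw.median() <= 0.3
        assert 0.1 <= disp.alpha_trend <= 0.3

    def test_constant_gene_clamped_to_zero(self):
        norm = pd.DataFrame(
            {"a1": [5.0, 3.0], "a2": [5.0, 9.0], "b1": [5.0, 2.0], "b2": [5.0, 8.0]},
            index=["const", "vary"],
        )
        disp = estimate_dispersion(norm, [["a1", "a2"], ["b1", "b2"]])
        assert disp.alpha_raw["const"] == 0.0

    def test_single_replicate_everywhere_errors(self):
        norm = pd.DataFrame({"a1": [5.0], "b1": [7.0]})
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersion(norm, [["a1"], ["b1"]])


class TestNbGlm:
    def test_matches_statsmodels_negative_binomial(self):
        # independent oracle: statsmodels GLM with the same fixed alpha, b=1
        rng = np.random.default_rng(0)
        design = np.column_stack([np.ones(8), np.r_[np.zeros(4), np.ones(4)]])
        for alpha, mean in [(0.1, 200), (0.01, 50), (0.3, 1000)]:
            size = 1 / alpha
            y = rng.negative_binomial(size, size / (size + mean), size=(1, 8)).astype(float)
            mine = nb_glm(y, design, np.array([alpha]), b=1.0)
            ref = sm.GLM(y[0], design, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
            assert mine["beta"][0] == pytest.approx(ref.params, abs=1e-6)
            assert mine["se"][0] == pytest.approx(ref.bse, abs=1e-6)
            assert mine["converged"][0]

    def test_group_mean_fit_for_saturated_design(self):
        y = np.array([[4.0, 6.0, 19.0, 21.0]])
        design = np.column_stack([np.ones(4), np.r_[0.0, 0.0, 1.0, 1.0]])
        fit = nb_glm(y, design, np.array([0.05]))
        mu = fit["mu"][0]
        assert mu[:2] == pytest.approx([5.0, 5.0], rel=1e-6)
        assert mu[2:] == pytest.approx([20.0, 20.0], rel=1e-6)
        assert fit["beta"][0, 1] == pytest.approx(np.log(4.0), rel=1e-8)


class TestAssayShift:
    def test_identical_replicate_sets_give_zero_fc(self):
        block = np.array([[12, 18], [100, 140], [7, 3]])
        counts = np.column_stack([block, block, block, block])  # rna/ribo x A/B
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)],
                "assay": ["rna"] * 2 + ["ribo"] * 2 + ["rna"] * 2 + ["ribo"] * 2,
                "condition": ["A"] * 4 + ["B"] * 4,
                "replicate": ["1", "2"] * 4,
            }
        )
        from teshift import CountMatrix

        cm = CountMatrix(
            pd.DataFrame(counts, index=["g0", "g1", "g2"], columns=samples["sample_id"]),
            samples,
        )
        res = assay_shift(cm, "rna", "A", "B")
        assert res["log2fc"].abs().max() < 1e-8
        assert (res["p"] > 0.999).all()

    def test_planted_fold_change_recovered(self):
        lg = float(np.log10(500))
        config = SimulationConfig(
            n_genes=2000, seed=3, dispersion=0.01, conditions=("A", "B"),
            base_mean_log_range=(lg, lg), te_baseline_sd=0.0, effect_log2fc=3.0,
            category_proportions={
                RegulationCategory.UP_TE_CONSTANT: 0.3,
                RegulationCategory.UNREGULATED: 0.7,
            },
        )
        cm, truth = simulate_counts(config)
        bg = filter_background(cm)
        res = assay_shift(bg, "rna", "A", "B")
        planted = truth.loc[bg.gene_ids, "log2fc_rna"] == 3.0
        err = (res.loc[planted.values, "log2fc"] - 3.0).abs()
        hit = (err < 0.5) & (res.loc[planted.values, "fdr"] < 0.01)
        assert hit.mean() >= 0.95

    def test_swapping_conditions_negates_fc_and_keeps_p(self, tested_dataset):
        bg, _, _ = tested_dataset
        f = size_factors(bg)
        ab = assay_shift(bg, "ribo", "NPC", "Neuron", factors=f)
        ba = assay_shift(bg, "ribo", "Neuron", "NPC", factors=f)
        assert np.nanmax(np.abs(ab["log2fc"] + ba["log2fc"])) < 1e-6
        assert np.nanmax(np.abs(ab["p"] - ba["p"])) < 1e-6

    def test_missing_condition_errors(self, tested_dataset):
        bg, _, _ = tested_dataset
        with pytest.raises(ValueError, match="condition"):
            assay_shift(bg, "rna", "NPC", "Astrocyte")


class TestTeShift:
    def test_equal_shifts_in_both_assays_cancel(self):
        # ribo and rna both quadruple: TE unchanged
        rng = np.random.default_rng(1)
        base = rng.poisson(300, size=(400, 4))
        counts = np.column_stack([base, 4 * base])
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)],
                "assay": ["rna", "rna", "ribo", "ribo"] * 2,
                "condition": ["A"] * 4 + ["B"] * 4,
                "replicate": ["1", "2"] * 4,
            }
        )
        from teshift import CountMatrix

        cm = CountMatrix(
            pd.DataFrame(counts, index=[f"g{i}" for i in range(400)],
                         columns=samples["sample_id"]),
            samples,
        )
        res = te_shift(cm, "A", "B")
        assert res["log2fc"].abs().median() < 0.1
        assert (res["fdr"] < 0.01).mean() < 0.02

    def test_ribo_only_shift_lands_on_interaction(self):
        lg = float(np.log10(500))
        config = SimulationConfig(
            n_genes=1500, seed=5, dispersion=0.01, conditions=("A", "B"),
            base_mean_log_range=(lg, lg), te_baseline_sd=0.0, effect_log2fc=2.0,
            category_proportions={
                # balanced induced/repressed keeps median-of-ratios unbiased
                RegulationCategory.TRANSLATIONALLY_INDUCED: 0.15,
                RegulationCategory.TRANSLATIONALLY_REPRESSED: 0.15,
                RegulationCategory.UNREGULATED: 0.7,
            },
        )
        cm, truth = simulate_counts(config)
        bg = filter_background(cm)
        res = te_shift(bg, "A", "B")
        planted = (truth.loc[bg.gene_ids, "log2fc_ribo"] == 2.0).to_numpy()
        err = (res.loc[planted, "log2fc"] - 2.0).abs()
        assert (err < 0.5).mean() >= 0.95

    def test_interaction_equals_difference_of_assay_shifts(self, tested_dataset):
        _, _, stats = tested_dataset
        gap = stats["log2fc_te"] - (stats["log2fc_ribo"] - stats["log2fc_rna"])
        assert np.nanmax(np.abs(gap)) < 1e-6

    def test_null_interaction_pvalues_uniform(self, null_config):
        from scipy import stats as sps

        cm, _ = simulate_counts(null_config)
        bg = filter_background(cm)
        res = te_shift(bg, "NPC", "Neuron")
        p = res.loc[res["tested"] & res["converged"], "p"].dropna()
        assert sps.kstest(p, "uniform").pvalue > 0.01


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_equal_ps_stay_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_stepup_hand_computation(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_monotone_and_clipped(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert adj.min() >= 0 and adj.max() <= 1

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])
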