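"""Normalization, multiple testing, and the two platform DE models."""

import warnings

import numpy as np
import pandas as pd
import pytest

from xplatcord.containers import ExpressionMatrix, InputError, SampleDesign
from xplatcord.diffexpr import (
    ARRAY_CRITERIA,
    SEQ_CRITERIA,
    ArrayDEModel,
    CountsDEModel,
    DegCriteria,
    array_lm_de,
    bh_adjust,
    call_degs,
    cpm_normalize,
    nb_wald_de,
)
from xplatcord.synthdata import SimConfig, generate_truth, simulate_counts, simulate_intensities


def counts_matrix(arr, samples=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=samples),
        kind="counts",
    )


class TestCpmNormalize:
    def test_million_total_is_identity(self):
        mat = counts_matrix([[500_000], [300_000], [200_000]])
        cpm = cpm_normalize(mat)
        np.testing.assert_allclose(cpm.values.to_numpy().ravel(), [500_000, 300_000, 200_000])

    def test_log2_of_zero_count_is_zero(self):
        mat = counts_matrix([[0], [10]])
        log = cpm_normalize(mat, log=True)
        assert log.values.iloc[0, 0] == 0.0
        assert log.kind == "log2_cpm"

    def test_hand_computed_toy_matrix(self):
        mat = counts_matrix([[10, 0], [30, 50], [60, 150]])
        cpm = cpm_normalize(mat)
        np.testing.assert_allclose(
            cpm.values.to_numpy(),
            [[1e5, 0.0], [3e5, 2.5e5], [6e5, 7.5e5]],
        )

    def test_columns_sum_to_one_million(self, rng):
        mat = counts_matrix(rng.integers(0, 500, size=(30, 6)))
        cpm = cpm_normalize(mat)
        np.testing.assert_allclose(cpm.values.sum(axis=0), 1e6)

    def test_zero_total_sample_named(self):
        mat = counts_matrix([[0, 5], [0, 5]], samples=["bad", "ok"])
        with pytest.raises(InputError, match="bad"):
            cpm_normalize(mat)

    def test_rejects_log_matrix(self):
        mat = ExpressionMatrix(pd.DataFrame({"s": [1.5]}, index=["g"]), "log2_intensity")
        with pytest.raises(InputError):
            cpm_normalize(mat)


def bh_oracle(p):
    """Quadratic-time reference: fdr_i = min_{j: p_j >= p_i} p_j * m / rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    fdr = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        fdr[idx] = running_min
    return np.minimum(fdr, 1.0)


class TestBhAdjust:
    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.4]), [0.4])

    def test_matches_quadratic_oracle_and_permutation_invariant(self, rng):
        for _ in range(25):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)
            perm = rng.permutation(len(p))
            np.testing.assert_allclose(bh_adjust(p[perm]), bh_adjust(p)[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(InputError):
            bh_adjust([])


class TestCountsDEModel:
    def test_null_type_one_error_calibrated(self):
        # permuted labels of one condition: ~5% rejections at p < 0.05
        cfg = SimConfig(n_genes=500, frac_de=0.0, n_reps=3, seed=1)
        truth = generate_truth(cfg)
        counts, design = simulate_counts(truth, cfg)
        res = nb_wald_de(counts, design, "UT")  # UT and CA share a null effect
        frac = (res.table["p"] < 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_parameter_recovery_large_replicates(self):
        cfg = SimConfig(
            n_genes=30, frac_de=0.4, n_reps=200, nb_dispersion=1e-3,
            lib_size_cv=0.01, flawed_probe_frac=0.0, seed=6,
        )
        truth = generate_truth(cfg)
        counts, design = simulate_counts(truth, cfg)
        res = nb_wald_de(counts, design, "HD")
        de = truth[truth["is_de"] & (truth["base_abundance"] > 100)]
        err = (res.table.loc[de.index, "log2fc"] - de["log2fc_HD"]).abs()
        assert (err < 0.1).all()

    def test_all_zero_gene_is_null(self, toy_design):
        arr = np.array([[0, 0, 0, 0, 0, 0], [5, 6, 7, 50, 60, 70]])
        mat = counts_matrix(arr, samples=toy_design.sample_ids)
        res = nb_wald_de(mat, toy_design, "HD")
        assert res.table.loc["g0", "p"] == 1.0
        assert res.table.loc["g0", "log2fc"] == 0.0
        assert not res.table.loc["g0", "is_deg"]

    def test_sign_matches_cpm_mean_difference(self):
        cfg = SimConfig(n_genes=200, frac_de=0.3, seed=3)
        truth = generate_truth(cfg)
        counts, design = simulate_counts(truth, cfg)
        res = nb_wald_de(counts, design, "HD")
        cpm = cpm_normalize(counts).values
        diff = cpm[design.samples("HD")].mean(axis=1) - cpm[design.samples("CA")].mean(axis=1)
        nonzero = counts.values.sum(axis=1) > 0
        assert (np.sign(res.table["log2fc"][nonzero]) == np.sign(diff[nonzero])).all()

    def test_too_few_replicates_rejected(self):
        design = SampleDesign.from_conditions(("CA", "HD"), n_reps=2)
        tbl = design.table.drop(index=["HD_2"])
        with pytest.raises(InputError):
            nb_wald_de(
                counts_matrix(np.ones((3, 3), dtype=int), samples=list(tbl.index)),
                SampleDesign(tbl),
                "HD",
            )

    def test_agrees_with_external_nb_glm_fitter(self):
        # independent route: the DESeq2 reimplementation in pydeseq2
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = SimConfig(
            n_genes=120, frac_de=0.3, n_reps=4, conditions=("CA", "HD"),
            flawed_probe_frac=0.0, seed=2,
        )
        truth = generate_truth(cfg)
        counts, design = simulate_counts(truth, cfg)
        res = nb_wald_de(counts, design, "HD")
        meta = pd.DataFrame(
            {"condition": [design.condition_of(s) for s in design.sample_ids]},
            index=design.sample_ids,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(
                counts=counts.values.T, metadata=meta, design="~condition", quiet=True
            )
            dds.deseq2()
            stat = DeseqStats(dds, contrast=["condition", "HD", "CA"], quiet=True)
            stat.summary()
        lfc = stat.results_df["log2FoldChange"]
        diff = (res.table["log2fc"] - lfc).abs()
        assert diff.median() < 0.1
        assert np.corrcoef(res.table["log2fc"], lfc)[0, 1] > 0.99


class TestArrayDEModel:
    def test_identical_groups_null(self, toy_design):
        vals = np.tile([[8.0, 9.0, 10.0]], (2, 2)).reshape(2, 6)
        mat = ExpressionMatrix(
            pd.DataFrame(vals, index=["g0", "g1"], columns=toy_design.sample_ids),
            "log2_intensity",
        )
        res = array_lm_de(mat, toy_design, "HD")
        np.testing.assert_allclose(res.table["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["p"], 1.0)

    def test_mean_shift_two_gives_linear_four(self, toy_design):
        vals = np.array([[8.0, 8.0, 8.0, 10.0, 10.0, 10.0]])
        vals = vals + np.array([[0, 0.01, -0.01, 0, 0.01, -0.01]])
        mat = ExpressionMatrix(
            pd.DataFrame(vals, index=["g0"], columns=toy_design.sample_ids),
            "log2_intensity",
        )
        res = array_lm_de(mat, toy_design, "HD")
        assert res.table.loc["g0", "log2fc"] == pytest.approx(2.0, abs=1e-9)
        assert res.table.loc["g0", "linear_fc"] == pytest.approx(4.0, abs=1e-6)
        assert res.table.loc["g0", "is_deg"]

    def test_null_calibration(self):
        cfg = SimConfig(n_genes=1000, frac_de=0.0, seed=2)
        truth = generate_truth(cfg)
        mat, design = simulate_intensities(truth, cfg)
        res = array_lm_de(mat, design, "HD")
        frac = (res.table["p"] < 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_constant_gene_p_one(self, toy_design):
        vals = np.full((1, 6), 7.0)
        mat = ExpressionMatrix(
            pd.DataFrame(vals, index=["g0"], columns=toy_design.sample_ids),
            "log2_intensity",
        )
        res = array_lm_de(mat, toy_design, "HD")
        assert res.table.loc["g0", "p"] == 1.0

    def test_unadjusted_p_drives_deg_call(self):
        # many null genes + one real: BH would kill marginal p-values, the
        # array convention keeps them
        cfg = SimConfig(n_genes=400, frac_de=0.05, array_noise_sd=0.35, seed=8)
        truth = generate_truth(cfg)
        mat, design = simulate_intensities(truth, cfg)
        res = array_lm_de(mat, design, "HD")
        assert res.table["fdr"].isna().all()
        assert (res.table["fdr_reference_only"] >= res.table["p"] - 1e-12).all()


class TestCallDegs:
    def make(self, **cols):
        defaults = dict(base_mean=1.0, log2fc=1.0, linear_fc=2.0, p=0.01, fdr=0.01)
        defaults.update(cols)
        table = pd.DataFrame(defaults, index=["g"])
        from xplatcord.diffexpr import DEResults

        return DEResults(table, "HD", "CA", "seq")

    def test_just_below_lfc_cutoff_not_deg(self):
        # significant FDR but 0.4 log2FC stays below the sequencing cutoff
        res = call_degs(self.make(log2fc=0.4, linear_fc=1.32), SEQ_CRITERIA)
        assert not res.table["is_deg"].iloc[0]

    def test_boundary_exact_half_not_deg(self):
        res = call_degs(self.make(log2fc=0.5, linear_fc=2.0**0.5), SEQ_CRITERIA)
        assert not res.table["is_deg"].iloc[0]

    def test_array_down_deg(self):
        res = call_degs(
            self.make(log2fc=-1.07, linear_fc=-2.1, fdr=np.nan), ARRAY_CRITERIA
        )
        assert res.table["is_deg"].iloc[0]
        assert res.table["direction"].iloc[0] == "down"

    def test_seq_mode_without_fdr_rejected(self):
        with pytest.raises(InputError):
            call_degs(self.make(fdr=np.nan), SEQ_CRITERIA)

    def test_fdr_threshold_monotonicity(self):
        cfg = SimConfig(n_genes=300, frac_de=0.2, seed=12)
        truth = generate_truth(cfg)
        counts, design = simulate_counts(truth, cfg)
        res = nb_wald_de(counts, design, "HD")
        n_prev = -1
        for fdr_max in (0.01, 0.05, 0.2, 1.0):
            n = call_degs(res, DegCriteria("seq", fdr_max=fdr_max)).n_deg
            assert n >= n_prev
            n_prev = n


class TestBhProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=80))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_adjusted_values_dominate_raw_and_match_oracle(self, p):
        fdr = bh_adjust(p)
        assert np.all(fdr >= np.asarray(p) - 1e-12)
        assert np.all((0.0 <= fdr) & (fdr <= 1.0))
        np.testing.assert_allclose(fdr, bh_oracle(p), atol=1e-12)
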