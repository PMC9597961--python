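import numpy as np
import pandas as pd
import pytest

from mirmod.expression import (
    bh_adjust,
    ddct,
    de_mirna,
    de_mrna,
    expressed_filter,
    normalize_cpm,
    normalize_fpkm,
    normalize_tmm,
    retained_mirnas,
    tmm_factors,
)
from mirmod.io import ExpressionMatrix, LibraryDesign


def _matrix(contrast_design, rows):
    df = pd.DataFrame(rows, columns=[d.library_id for d in contrast_design])
    return ExpressionMatrix(df, contrast_design)


def _two_genotype_design():
    libs = []
    for g in ("ST", "SS"):
        for cond in ("CT", "NaCl"):
            for r in (1, 2, 3):
                libs.append(LibraryDesign(f"{g}_T3_{cond}_r{r}", g, 3.0, cond, r))
    return libs


class TestNormalization:
    def test_cpm_unit_definition(self, contrast_design):
        rows = {"f1": [5] * 6, "f2": [999995] * 6}
        mat = _matrix(contrast_design, pd.DataFrame(rows).T.to_numpy())
        mat.values.index = ["f1", "f2"]
        cpm = normalize_cpm(mat)
        assert cpm.values.loc["f1"].tolist() == [5.0] * 6
        assert np.allclose(cpm.values.sum(axis=0), 1e6)

    def test_cpm_scale_invariance(self, contrast_design, rng):
        counts = rng.integers(1, 1000, size=(5, 6))
        mat = _matrix(contrast_design, counts)
        doubled = _matrix(contrast_design, counts * 2)
        pd.testing.assert_frame_equal(normalize_cpm(mat).values,
                                      normalize_cpm(doubled).values)

    def test_fpkm_closed_form(self, contrast_design):
        counts = np.full((2, 6), 100)
        counts[1, :] = 999900
        mat = _matrix(contrast_design, counts)
        mat.values.index = ["g1", "g2"]
        fpkm = normalize_fpkm(mat, {"g1": 1000, "g2": 500})
        assert fpkm.values.loc["g1"].tolist() == [100.0] * 6

    def test_fpkm_halves_with_double_length(self, contrast_design):
        counts = np.full((1, 6), 100)
        mat = _matrix(contrast_design, counts)
        mat.values.index = ["g1"]
        f1 = normalize_fpkm(mat, {"g1": 1000}).values.iloc[0, 0]
        f2 = normalize_fpkm(mat, {"g1": 2000}).values.iloc[0, 0]
        assert f2 == pytest.approx(f1 / 2)

    def test_zero_count_gives_zero(self, contrast_design):
        counts = np.array([[0] * 6, [10] * 6])
        mat = _matrix(contrast_design, counts)
        mat.values.index = ["g1", "g2"]
        assert (normalize_fpkm(mat, {"g1": 100, "g2": 100}).values.loc["g1"] == 0).all()


class TestTmm:
    def test_factors_are_one_for_pure_depth_differences(self, contrast_design, rng):
        base = rng.integers(50, 5000, size=30).astype(float)
        cols = {}
        for i, d in enumerate(contrast_design):
            cols[d.library_id] = np.round(base * (1 + 0.5 * i)).astype(int)
        mat = ExpressionMatrix(pd.DataFrame(cols), contrast_design)
        factors = tmm_factors(mat)
        assert np.allclose(factors, 1.0, atol=1e-6)

    def test_corrects_composition_shift_from_one_dominant_feature(self, contrast_design, rng):
        # one very abundant feature quadruples in the NaCl libraries; under
        # plain CPM every other feature appears down-regulated there, under
        # TMM the stable majority keeps its values
        base = rng.integers(100, 1000, size=50).astype(float)
        base[0] = 1e6
        cols = {}
        for d in contrast_design:
            col = base.copy()
            if d.condition == "NaCl":
                col[0] *= 4
            cols[d.library_id] = np.round(col).astype(int)
        mat = ExpressionMatrix(pd.DataFrame(cols), contrast_design)
        cpm = normalize_cpm(mat).values
        tmm = normalize_tmm(mat).values
        ct_lib, nacl_lib = "ST_T3_CT_r1", "ST_T3_NaCl_r1"
        cpm_ratio = cpm.loc[1:, nacl_lib] / cpm.loc[1:, ct_lib]
        tmm_ratio = tmm.loc[1:, nacl_lib] / tmm.loc[1:, ct_lib]
        assert cpm_ratio.mean() < 0.75          # compositional distortion
        assert abs(tmm_ratio.mean() - 1.0) < 0.05

    def test_factors_have_unit_geometric_mean(self, contrast_design, rng):
        counts = rng.integers(0, 2000, size=(40, 6))
        mat = ExpressionMatrix(
            pd.DataFrame(counts, columns=[d.library_id for d in contrast_design]),
            contrast_design)
        factors = tmm_factors(mat)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-9)


class TestExpressedFilter:
    def _norm(self, values_by_lib):
        design = _two_genotype_design()
        from mirmod.expression import NormalizedMatrix
        df = pd.DataFrame({d.library_id: values_by_lib(d) for d in design}, index=["f"])
        return NormalizedMatrix(df, design, "FPKM")

    def test_just_below_threshold_everywhere_not_expressed(self):
        norm = self._norm(lambda d: [0.99])
        status = expressed_filter(norm)
        assert not status.loc["f", "ST"] and not status.loc["f", "SS"]

    def test_threshold_met_in_single_st_library_is_genotype_specific(self):
        norm = self._norm(lambda d: [1.0 if d.library_id == "ST_T3_CT_r1" else 0.0])
        status = expressed_filter(norm)
        assert status.loc["f", "ST"] and not status.loc["f", "SS"]
        assert status.loc["f", "genotype_specific"]

    def test_expressed_in_both_genotypes_not_specific(self):
        norm = self._norm(lambda d: [2.0])
        status = expressed_filter(norm)
        assert not status.loc["f", "genotype_specific"]


class TestDeMirna:
    def _norm(self, ct, nacl, contrast_design):
        from mirmod.expression import NormalizedMatrix
        vals = {}
        for d in contrast_design:
            vals[d.library_id] = [ct[d.replicate - 1] if d.condition == "CT"
                                  else nacl[d.replicate - 1]]
        df = pd.DataFrame(vals, index=["f"])
        return NormalizedMatrix(df, contrast_design, "CPM")

    def test_worked_pooled_t_example(self, contrast_design):
        # CT (10, 12, 14) vs NaCl (20, 22, 24): pooled sd = 2, so
        # t = (12 - 22) / (2 * sqrt(2/3)) = -6.1237, df = 4, p = 0.00358
        norm = self._norm([10, 12, 14], [20, 22, 24], contrast_design)
        res = de_mirna(norm, "ST", 3.0)
        row = res.iloc[0]
        se = 2.0 * np.sqrt(2.0 / 3.0)
        assert row.t == pytest.approx(-10.0 / se, abs=1e-9)
        assert row.t == pytest.approx(-6.1237243570, abs=1e-6)
        from scipy import stats
        assert row.p_value == pytest.approx(2 * stats.t.sf(10.0 / se, df=4), abs=1e-12)
        assert row.status == "up"

    def test_identical_arms_are_ns_with_zero_log2fc(self, contrast_design):
        norm = self._norm([5, 5, 5], [5, 5, 5], contrast_design)
        row = de_mirna(norm, "ST", 3.0).iloc[0]
        assert row.log2fc == 0 and row.status == "ns"

    def test_alpha_threshold_is_strict(self, contrast_design):
        norm = self._norm([10, 12, 14], [20, 22, 24], contrast_design)
        p = de_mirna(norm, "ST", 3.0).iloc[0].p_value
        assert de_mirna(norm, "ST", 3.0, alpha=p * 1.01).iloc[0].status == "up"
        assert de_mirna(norm, "ST", 3.0, alpha=p * 0.99).iloc[0].status == "ns"

    def test_replicate_permutation_invariance(self, contrast_design):
        norm = self._norm([10, 14, 12], [22, 24, 20], contrast_design)
        base = self._norm([10, 12, 14], [20, 22, 24], contrast_design)
        pd.testing.assert_frame_equal(de_mirna(norm, "ST", 3.0), de_mirna(base, "ST", 3.0))

    def test_too_few_replicates_rejected(self):
        from mirmod.expression import NormalizedMatrix
        design = [LibraryDesign("ST_T3_CT_r1", "ST", 3.0, "CT", 1),
                  LibraryDesign("ST_T3_NaCl_r1", "ST", 3.0, "NaCl", 1)]
        norm = NormalizedMatrix(pd.DataFrame({"ST_T3_CT_r1": [1], "ST_T3_NaCl_r1": [1]},
                                             index=["f"]), design, "CPM")
        with pytest.raises(ValueError, match="replicates"):
            de_mirna(norm, "ST", 3.0)


class TestDeMrna:
    def _norm(self, ct, nacl, contrast_design):
        from mirmod.expression import NormalizedMatrix
        vals = {d.library_id: [ct[d.replicate - 1] if d.condition == "CT"
                               else nacl[d.replicate - 1]] for d in contrast_design}
        return NormalizedMatrix(pd.DataFrame(vals, index=["g"]), contrast_design, "FPKM")

    def test_significant_but_small_fold_change_is_ns(self, contrast_design):
        # ratio < 2 (log2fc < 1): significance alone is not enough
        norm = self._norm([10.0, 10.2, 9.8], [17.0, 17.2, 16.8], contrast_design)
        row = de_mrna(norm, "ST", 3.0).iloc[0]
        assert row.p_value < 0.05 and abs(row.log2fc) < 1
        assert row.status == "ns"

    def test_significant_large_fold_change_is_up(self, contrast_design):
        norm = self._norm([10.0, 10.2, 9.8], [43.0, 43.2, 42.8], contrast_design)
        row = de_mrna(norm, "ST", 3.0).iloc[0]
        assert row.p_value < 0.05 and row.log2fc > 1
        assert row.status == "up"

    def test_equal_replicates_are_ns(self, contrast_design):
        norm = self._norm([7.0] * 3, [7.0] * 3, contrast_design)
        assert de_mrna(norm, "ST", 3.0).iloc[0].status == "ns"


class TestDdct:
    def test_identity_when_ddct_zero(self):
        res = ddct([20, 20], [15, 15], [22, 22], [17, 17])
        assert res["relative_expression"] == pytest.approx(1.0, abs=1e-12)

    def test_one_cycle_halves_expression(self):
        res = ddct([21, 21], [15, 15], [22, 22], [17, 17])
        assert res["ddct"] == pytest.approx(1.0)
        assert res["relative_expression"] == pytest.approx(0.5, abs=1e-12)

    def test_minus_two_cycles_quadruples(self):
        res = ddct([18, 18], [15, 15], [22, 22], [17, 17])
        assert res["relative_expression"] == pytest.approx(4.0, abs=1e-12)


class TestHelpers:
    def test_bh_adjust_is_monotone_and_bounded(self, rng):
        p = rng.random(50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_retention_threshold(self, contrast_design):
        from mirmod.expression import NormalizedMatrix
        df = pd.DataFrame(
            {d.library_id: [2.0, 0.5] for d in contrast_design},
            index=["keep", "drop"])
        norm = NormalizedMatrix(df, contrast_design, "CPM")
        assert retained_mirnas(norm, 1.0) == ["keep"]

    def test_status_partition_on_simulated_data(self, default_result):
        statuses = set(default_result.de_mirna["status"]) | set(default_result.de_mrna["status"])
        assert statuses <= {"up", "down", "ns", "not_expressed"}
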