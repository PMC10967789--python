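"""Cohort pipeline: derivation map, summaries, gated tests, correlations, audit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ctdose
from ctdose import (
    audit_cohort,
    cohort_frame,
    compare_groups,
    derive_all,
    spearman_matrix,
    summarize,
)
from ctdose.cohort import DeriveError, holm_adjust


class TestDeriveAll:
    def test_phantom_sized_patient(self, body_table, f_table):
        rec = ctdose.PatientRecord(
            id="P1", sex="M", age=60, height=175, weight=85, bmi=85 / 1.75**2,
            ap=32.0, lat=32.0, topogram_length=400, diagnostic_length=400,
            ctdi_vol=8.0, dlp_topogram=5.0, dlp_diagnostic=300.0)
        (pair,), failures = derive_all([rec], body_table, f_table)
        _, dd = pair
        k32 = body_table.lookup(32.0)
        assert not failures
        assert dd.d_eff == pytest.approx(32.0)
        assert dd.ssde == pytest.approx(8.0 * k32)
        assert dd.dlp_ss == pytest.approx(300.0 * k32)
        assert dd.ed == pytest.approx(300.0 * 0.014)

    def test_zero_dlp_propagates(self, body_table, f_table):
        rec = ctdose.PatientRecord(
            id="P2", sex="F", age=55, height=160, weight=60, bmi=60 / 1.6**2,
            ap=24, lat=33, topogram_length=380, diagnostic_length=380,
            ctdi_vol=6.0, dlp_topogram=0.0, dlp_diagnostic=0.0)
        (pair,), _ = derive_all([rec], body_table, f_table)
        assert pair[1].dlp_ss == 0.0 and pair[1].ed == 0.0

    def test_pure_map_order_preserved(self, default_cohort, body_table, f_table):
        fwd, _ = derive_all(default_cohort, body_table, f_table)
        perm = list(reversed(default_cohort))
        rev, _ = derive_all(perm, body_table, f_table)
        assert [p[0].id for p in fwd] == [r.id for r in default_cohort]
        assert list(reversed([p[1] for p in rev])) == [p[1] for p in fwd]

    def test_per_record_failures_collected(self, default_cohort, body_table, f_table):
        class Broken:
            id = "BAD01"
            ap = -1.0  # invalid on purpose; bypasses record validation
            lat = 30.0
            ctdi_vol = 5.0
            dlp_topogram = 5.0
            dlp_diagnostic = 200.0

        mixed = [default_cohort[0], Broken()]
        derived, failures = derive_all(mixed, body_table, f_table)
        assert len(derived) == 1
        assert [fid for fid, _ in failures] == ["BAD01"]
        with pytest.raises(DeriveError):
            derive_all([Broken()], body_table, f_table)

    def test_topogram_dlp_switch(self, default_cohort, body_table, f_table):
        diag_only, _ = derive_all(default_cohort, body_table, f_table)
        total, _ = derive_all(default_cohort, body_table, f_table,
                              include_topogram_dlp=True)
        for (rec, a), (_, b) in zip(diag_only, total):
            assert b.ed == pytest.approx(a.ed + 0.014 * rec.dlp_topogram, rel=1e-12)

    def test_default_cohort_size_adjustment_level(self, default_frame):
        # the cohort-mean size adjustment should raise DLP by roughly 20%
        ratio = default_frame["dlp_ss"].mean() / default_frame["dlp_diagnostic"].mean()
        assert 1.15 <= ratio <= 1.25

    def test_mean_ed_linearity(self, default_frame):
        assert default_frame["ed"].mean() == pytest.approx(
            0.014 * default_frame["dlp_diagnostic"].mean(), rel=1e-12)


class TestSummarize:
    def _frame(self, values, sex="F"):
        return pd.DataFrame({"sex": [sex] * len(values), "x": values})

    def test_hand_computed_summary(self):
        s = summarize(self._frame([3.0, 4.0, 5.0]), "x")
        assert (s.mean, s.sd, s.min, s.max, s.n) == (4.0, 1.0, 3.0, 5.0, 3)

    def test_constant_column(self):
        s = summarize(self._frame([7.0, 7.0, 7.0]), "x")
        assert s.mean == 7.0 and s.sd == 0.0

    def test_two_values(self):
        a, b = 2.0, 5.0
        s = summarize(self._frame([a, b]), "x")
        assert s.mean == pytest.approx((a + b) / 2)
        assert s.sd == pytest.approx(abs(a - b) / np.sqrt(2))

    def test_stratification_and_empty_stratum(self):
        frame = pd.DataFrame({"sex": ["F", "F", "M", "M"], "x": [1.0, 2.0, 10.0, 12.0]})
        assert summarize(frame, "x", "M").mean == 11.0
        with pytest.raises(ValueError):
            summarize(frame[frame.sex == "F"], "x", "M")


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 2, size=30)
        c = compare_groups(x, x.copy())
        assert c.p_value > 0.9
        assert not c.significant

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, size=30)
        c = compare_groups(x, x + 10.0)
        assert c.p_value < 0.05

    def test_degenerate_group_routes_to_mann_whitney(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="ctdose"):
            c = compare_groups([5.0, 5.0, 5.0, 5.0], [4.0, 5.0, 6.0, 7.0])
        assert c.test_used == "mann_whitney"
        assert c.normality_p_f is None
        assert any("degenerate" in r.message for r in caplog.records)

    def test_gate_reproducible_from_normality_p_values(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            x = rng.exponential(2.0, size=rng.integers(8, 40))
            y = rng.normal(3, 1, size=rng.integers(8, 40))
            c = compare_groups(x, y)
            expect_t = c.normality_p_f >= c.alpha and c.normality_p_m >= c.alpha
            assert c.test_used == ("student_t" if expect_t else "mann_whitney")

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_default_cohort_dlp_ss_sex_difference(self, default_frame):
        c = compare_groups(default_frame.loc[default_frame.sex == "F", "dlp_ss"],
                           default_frame.loc[default_frame.sex == "M", "dlp_ss"],
                           variable="dlp_ss")
        assert c.significant


class TestSpearmanMatrix:
    def _frame(self, n=40, seed=3):
        rng = np.random.default_rng(seed)
        t = rng.normal(8, 2, size=n)
        return pd.DataFrame({
            "sex": ["F"] * n, "ctdi_vol": t,
            "same": t, "anti": -t, "const": np.ones(n),
            "noise": rng.normal(size=n),
        })

    def test_perfect_and_inverted_covariates(self):
        results = {r.covariate: r for r in spearman_matrix(
            self._frame(), covariates=("same", "anti", "noise"))}
        assert results["same"].rho == pytest.approx(1.0)
        assert results["anti"].rho == pytest.approx(-1.0)
        assert abs(results["noise"].rho) < 0.5

    def test_constant_covariate_reported_missing(self):
        (r,) = spearman_matrix(self._frame(), covariates=("const",))
        assert r.rho is None and "constant" in r.missing_reason

    def test_monotone_transform_invariance(self):
        frame = self._frame(seed=11)
        base = spearman_matrix(frame, covariates=("noise",))[0].rho
        frame2 = frame.assign(ctdi_vol=np.exp(frame.ctdi_vol / 4),
                              noise=frame.noise ** 3)
        transformed = spearman_matrix(frame2, covariates=("noise",))[0].rho
        assert transformed == pytest.approx(base, abs=1e-12)

    def test_minimum_stratum_size(self):
        with pytest.raises(ValueError):
            spearman_matrix(self._frame(n=4))

    def test_default_cohort_male_deff_near_calibration(self, default_frame):
        (r,) = spearman_matrix(default_frame, covariates=("d_eff",), stratum="M")
        assert r.rho == pytest.approx(0.87, abs=0.06)

    def test_holm_adjustment_monotone(self):
        p = [0.001, 0.04, 0.03, 0.5]
        adj = holm_adjust(p)
        assert all(a >= b for a, b in zip(adj, p))
        assert max(adj) <= 1.0


class TestAudit:
    def test_all_unchanged(self, default_cohort, body_table, f_table):
        import dataclasses
        same = [dataclasses.replace(r, diagnostic_length=r.topogram_length)
                for r in default_cohort]
        derived, _ = derive_all(same, body_table, f_table)
        audit = audit_cohort(cohort_frame(derived))
        assert audit.pct_unchanged == 100.0
        assert audit.pct_shortened == 0.0 and audit.pct_extended == 0.0

    def test_all_below_phantom(self, default_cohort, body_table, f_table):
        import dataclasses
        small = [dataclasses.replace(r, ap=31.0, lat=31.0) for r in default_cohort]
        derived, _ = derive_all(small, body_table, f_table)
        audit = audit_cohort(cohort_frame(derived))
        assert audit.pct_deff_below_phantom == 100.0

    def test_partitions_sum_to_100(self, default_frame):
        audit = audit_cohort(default_frame)
        assert audit.pct_shortened + audit.pct_unchanged + audit.pct_extended \
            == pytest.approx(100.0, abs=0.1)
        assert audit.pct_deff_below_phantom + audit.pct_deff_above_phantom \
            == pytest.approx(100.0, abs=0.1)

    def test_height_ratio_conventions_both_emitted(self, default_frame):
        audit = audit_cohort(default_frame)
        for stratum in ("all", "F", "M"):
            rom = audit.topogram_to_height_pct[stratum]
            mor = audit.topogram_to_height_pct_per_patient[stratum]
            assert 15 < rom < 35 and 15 < mor < 35
            assert rom == pytest.approx(mor, abs=1.0)  # conventions nearly agree

    def test_ratio_of_means_convention(self):
        # two symmetric records around mean length 368.34 mm / height 161.04 cm
        frame = pd.DataFrame({
            "sex": ["F", "F"],
            "height": [161.04, 161.04],
            "topogram_length": [368.34 - 10, 368.34 + 10],
            "diagnostic_length": [380.0, 380.0],
            "scan_delta_mm": [1.0, 1.0],
            "d_eff": [29.0, 29.0],
        })
        audit = audit_cohort(frame)
        assert round(audit.topogram_to_height_pct["F"], 1) == 22.9
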