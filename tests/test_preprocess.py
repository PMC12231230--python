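"""Variable-level preparation steps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resilcca import (
    VariableEntry,
    adjust_icv,
    apply_directionality,
    compute_composites,
    exclude_sparse,
    flag_surface_holes,
    harmonize_batches,
    impute_tmtb,
    orient_genotypes_to_risk,
    pmm_impute,
    qc_outliers,
    zscore_reference,
)
from resilcca.preprocess import PreprocessError


def cog_entry(name, direction="higher_is_better", transform="none"):
    return VariableEntry(
        name=name, role="cognition", direction=direction, transform=transform
    )


class TestDirectionality:
    def test_time_scores_are_negated(self, cohort_factory):
        cohort = cohort_factory(
            {"tmt_a": [30.0, 60.0]}, [cog_entry("tmt_a", "lower_is_better")]
        )
        out = apply_directionality(cohort)
        np.testing.assert_array_equal(out.data["tmt_a"].to_numpy(), [-30.0, -60.0])

    def test_zero_burden_maps_to_zero(self, cohort_factory):
        cohort = cohort_factory(
            {"wm": [0.0, 1.0, 10.0]},
            [
                VariableEntry(
                    name="wm",
                    role="mri_global",
                    direction="lower_is_better",
                    transform="negate_log1p",
                )
            ],
        )
        out = apply_directionality(cohort)
        assert out.data["wm"].iloc[0] == 0.0
        np.testing.assert_allclose(
            out.data["wm"].to_numpy(), -np.log1p([0.0, 1.0, 10.0])
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        x1=st.floats(0.01, 1e4),
        gap=st.floats(0.01, 1e3),
        transform=st.sampled_from(["none", "log1p", "negate_log1p"]),
    )
    def test_monotone_higher_output_is_better(self, x1, gap, transform):
        """For any lower-is-better variable, a worse raw score always maps
        to a lower prepared score."""
        x2 = x1 + gap
        cohort = make_toy_two_values(x1, x2, transform)
        out = apply_directionality(cohort)
        v = out.data["v"].to_numpy()
        assert v[0] > v[1]

    def test_negative_log_input_fatal(self, cohort_factory):
        cohort = cohort_factory(
            {"wm": [-0.5, 1.0]},
            [cog_entry("wm", "lower_is_better", "log1p")],
        )
        with pytest.raises(PreprocessError, match="wm"):
            apply_directionality(cohort)

    def test_idempotent_after_first_pass(self, cohort_factory):
        cohort = cohort_factory(
            {"tmt_a": [30.0, 60.0]}, [cog_entry("tmt_a", "lower_is_better")]
        )
        once = apply_directionality(cohort)
        twice = apply_directionality(once)
        assert twice.data.equals(once.data)


def make_toy_two_values(x1, x2, transform):
    from conftest import make_cohort

    return make_cohort(
        {"v": [x1, x2]},
        [cog_entry("v", "lower_is_better", transform)],
    )


class TestTmtbImputation:
    def test_constant_ratio(self, cohort_factory):
        cohort = cohort_factory(
            {
                "tmt_a": [10, 20, 30, 40.0],
                "tmt_b": [20, 40, 60, np.nan],
                "dx": [1, 1, 1, 1.0],
            },
            [
                cog_entry("tmt_a", "lower_is_better"),
                cog_entry("tmt_b", "lower_is_better"),
                VariableEntry(name="dx", role="diagnosis"),
            ],
        )
        out = impute_tmtb(cohort, "tmt_a", "tmt_b", "dx")
        assert out.data["tmt_b"].iloc[3] == pytest.approx(80.0)

    def test_median_ratio_by_enumeration(self, cohort_factory):
        # ratios 1.5, 2.5, 2.0 -> median 2.0; subject with tmt_a=30 -> 60
        cohort = cohort_factory(
            {
                "tmt_a": [10, 10, 10, 30.0],
                "tmt_b": [15, 25, 20, np.nan],
                "dx": [1, 1, 1, 1.0],
            },
            [
                cog_entry("tmt_a", "lower_is_better"),
                cog_entry("tmt_b", "lower_is_better"),
                VariableEntry(name="dx", role="diagnosis"),
            ],
        )
        out = impute_tmtb(cohort, "tmt_a", "tmt_b", "dx")
        assert out.data["tmt_b"].iloc[3] == pytest.approx(60.0)

    def test_missing_both_stays_missing_and_groups_are_separate(self, cohort_factory):
        cohort = cohort_factory(
            {
                "tmt_a": [10, np.nan, 10.0, 20.0],
                "tmt_b": [20, np.nan, np.nan, np.nan],
                "dx": [1, 1, 1, 2.0],
            },
            [
                cog_entry("tmt_a", "lower_is_better"),
                cog_entry("tmt_b", "lower_is_better"),
                VariableEntry(name="dx", role="diagnosis"),
            ],
        )
        with pytest.warns(UserWarning, match="no complete"):
            out = impute_tmtb(cohort, "tmt_a", "tmt_b", "dx")
        assert np.isnan(out.data["tmt_b"].iloc[1])  # missing both
        assert out.data["tmt_b"].iloc[2] == pytest.approx(20.0)  # group 1 ratio 2
        assert np.isnan(out.data["tmt_b"].iloc[3])  # group 2 has no complete case


class TestSparsityExclusions:
    def make(self, cohort_factory, values):
        names = [f"c{j}" for j in range(values.shape[1])]
        return cohort_factory(
            {n: values[:, j] for j, n in enumerate(names)},
            [cog_entry(n) for n in names],
        )

    def test_subject_with_too_few_tests_excluded(self, cohort_factory):
        vals = np.ones((4, 5))
        vals[0, 2:] = np.nan  # subject 0 has only 2 tests
        cohort = self.make(cohort_factory, vals)
        out, plog = exclude_sparse(cohort)
        assert out.n == 3
        assert plog.steps[0].subjects_excluded == ["S1"]

    def test_variable_missing_boundary_is_strict(self, cohort_factory):
        # every subject keeps >= 3 tests, so only the variable rule acts
        vals = np.ones((10, 5))
        vals[:5, 1] = np.nan  # exactly 50% -> retained
        vals[4:, 2] = np.nan  # 60% -> dropped
        cohort = self.make(cohort_factory, vals)
        out, _ = exclude_sparse(cohort)
        assert out.n == 10
        assert "c1" in out.data.columns
        assert "c2" not in out.data.columns
        assert "c2" not in out.manifest

    def test_fully_observed_noop(self, cohort_factory):
        cohort = self.make(cohort_factory, np.ones((5, 4)))
        out, plog = exclude_sparse(cohort)
        assert out.n == 5 and plog.steps == []

    def test_all_variables_dropped_fatal(self, cohort_factory):
        vals = np.full((10, 3), np.nan)
        vals[:4, :] = 1.0  # 4 subjects keep 3 tests; vars 60% missing
        cohort = self.make(cohort_factory, vals)
        with pytest.raises(PreprocessError):
            exclude_sparse(cohort, min_tests=0)


class TestOutlierQC:
    def entries(self):
        return [
            VariableEntry(
                name="v", role="mri_volume", direction="higher_is_better"
            ),
            VariableEntry(name="dx", role="diagnosis"),
        ]

    def test_arithmetic_bounds(self, cohort_factory):
        # mean 2, sd ~4.47 -> bounds [-6.94, 10.94]: nothing removed
        cohort = cohort_factory(
            {"v": [0, 0, 0, 0, 10.0], "dx": [1] * 5}, self.entries()
        )
        out = qc_outliers(cohort, ["v"], "dx")
        assert not out.data["v"].isna().any()

    def test_clear_outlier_removed_boundary_kept(self, cohort_factory):
        # symmetric sample where +/-t sit exactly at mean +/- 2 sd:
        # [-1, 1] * 5 plus [-t, t] with t = sqrt(40/3)
        t = np.sqrt(40.0 / 3.0)
        base = np.array([-1.0, 1.0] * 5)
        vals = np.concatenate([base, [-t, t]])
        assert vals.max() == pytest.approx(vals.mean() + 2 * vals.std(ddof=1))
        cohort = cohort_factory({"v": vals, "dx": [1] * 12}, self.entries())
        out = qc_outliers(cohort, ["v"], "dx")
        assert not out.data["v"].isna().any()  # boundary values retained
        # nudging the extremes outward puts them strictly outside the band
        vals2 = np.concatenate([base, [-1.05 * t, 1.05 * t]])
        cohort2 = cohort_factory({"v": vals2, "dx": [1] * 12}, self.entries())
        out2 = qc_outliers(cohort2, ["v"], "dx")
        assert np.isnan(out2.data["v"].iloc[-1]) and np.isnan(out2.data["v"].iloc[-2])

    def test_all_equal_group_keeps_exact_values(self, cohort_factory):
        cohort = cohort_factory({"v": [3.0, 3, 3, 3], "dx": [1] * 4}, self.entries())
        out = qc_outliers(cohort, ["v"], "dx")
        np.testing.assert_array_equal(out.data["v"].to_numpy(), [3.0, 3, 3, 3])

    def test_small_group_untouched_with_warning(self, cohort_factory):
        cohort = cohort_factory({"v": [1.0, 100.0], "dx": [1, 1.0]}, self.entries())
        with pytest.warns(UserWarning, match="<3"):
            out = qc_outliers(cohort, ["v"], "dx")
        assert not out.data["v"].isna().any()


class TestSurfaceHoles:
    def test_arithmetic_oracle(self):
        flags = flag_surface_holes(np.array([1.0, 2, 3, 4, 100]))
        np.testing.assert_array_equal(flags, [False, False, False, False, True])

    def test_constant_vector_no_flags(self):
        assert not flag_surface_holes(np.array([5.0] * 6)).any()

    def test_threshold_value_not_flagged(self):
        x = np.array([1.0, 2, 3, 4, 5])
        med = np.median(x)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        flags = flag_surface_holes(np.append(x, med + 3 * iqr))
        assert not flags[-1]

    def test_needs_four_values(self):
        with pytest.raises(PreprocessError):
            flag_surface_holes(np.array([1.0, 2, 3]))


class TestPmm:
    def entries(self, names):
        return [cog_entry(n) for n in names]

    def test_no_missing_is_identity(self, cohort_factory, rng):
        vals = rng.standard_normal((20, 3))
        cohort = cohort_factory(
            {f"c{j}": vals[:, j] for j in range(3)}, self.entries(["c0", "c1", "c2"])
        )
        out = pmm_impute(cohort, ["c0", "c1", "c2"], ["c0", "c1", "c2"], seed=0)
        assert out.data.equals(cohort.data)

    def test_single_nearest_donor_hand_computed(self, cohort_factory):
        # y = 2*x exactly on donors; with k=1 the missing row at x=3.5 must
        # copy the donor with the nearest prediction: x=3 -> y=6
        x = [1.0, 2.0, 3.0, 5.0, 6.0, 3.4]
        y = [2.0, 4.0, 6.0, 10.0, 12.0, np.nan]
        cohort = cohort_factory({"x": x, "y": y}, self.entries(["x", "y"]))
        out = pmm_impute(cohort, ["y"], ["x", "y"], k_donors=1, cycles=1, seed=0)
        assert out.data["y"].iloc[5] == 6.0

    def test_deterministic_and_donor_valued(self, cohort_factory, rng):
        vals = rng.standard_normal((60, 3))
        mask = rng.random(60) < 0.25
        vals[mask, 2] = np.nan
        cols = {f"c{j}": vals[:, j].copy() for j in range(3)}
        names = ["c0", "c1", "c2"]
        a = pmm_impute(cohort_factory(cols, self.entries(names)), names, names, seed=5)
        b = pmm_impute(cohort_factory(cols, self.entries(names)), names, names, seed=5)
        c = pmm_impute(cohort_factory(cols, self.entries(names)), names, names, seed=6)
        assert a.data.equals(b.data)
        # different seed may differ, but only in originally-missing cells
        observed = ~np.isnan(vals[:, 2])
        np.testing.assert_array_equal(
            a.data["c2"].to_numpy()[observed], c.data["c2"].to_numpy()[observed]
        )
        # every imputed value equals some observed value of the variable
        imputed = a.data["c2"].to_numpy()[mask]
        assert np.isin(imputed, vals[observed, 2]).all()

    def test_zero_observed_target_fatal(self, cohort_factory):
        cohort = cohort_factory(
            {"x": [1.0, 2, 3], "y": [np.nan] * 3}, self.entries(["x", "y"])
        )
        with pytest.raises(PreprocessError, match="y"):
            pmm_impute(cohort, ["y"], ["x", "y"], seed=0)


class TestIcvAdjustment:
    def entries(self):
        return [
            VariableEntry(name="v", role="mri_volume", direction="higher_is_better"),
            VariableEntry(name="icv", role="mri_global", direction="higher_is_better"),
        ]

    def test_perfect_fit_becomes_constant_mean(self, cohort_factory, rng):
        icv = rng.normal(0, 1, 50)
        cohort = cohort_factory({"v": 2 * icv, "icv": icv}, self.entries())
        out = adjust_icv(cohort, ["v"], "icv")
        np.testing.assert_allclose(out.data["v"].to_numpy(), (2 * icv).mean(), atol=1e-10)

    def test_orthogonal_variable_unchanged(self, cohort_factory, rng):
        icv = rng.normal(0, 1, 64)
        v = rng.normal(0, 1, 64)
        # orthogonalize in-sample
        v = v - v.mean() - (np.cov(v, icv, ddof=1)[0, 1] / icv.var(ddof=1)) * (icv - icv.mean())
        v = v + 5.0
        cohort = cohort_factory({"v": v, "icv": icv}, self.entries())
        out = adjust_icv(cohort, ["v"], "icv")
        np.testing.assert_allclose(out.data["v"].to_numpy(), v, atol=1e-12)

    def test_residual_uncorrelated_and_mean_preserved(self, cohort_factory, rng):
        for _ in range(5):
            icv = rng.normal(0, 2, 80)
            v = 0.7 * icv + rng.normal(0, 1, 80) + 10
            cohort = cohort_factory({"v": v, "icv": icv}, self.entries())
            out = adjust_icv(cohort, ["v"], "icv")
            adj = out.data["v"].to_numpy()
            assert abs(np.corrcoef(adj, icv)[0, 1]) < 1e-10
            assert adj.mean() == pytest.approx(v.mean(), abs=1e-10)

    def test_constant_icv_fatal(self, cohort_factory):
        cohort = cohort_factory({"v": [1.0, 2, 3], "icv": [5.0, 5, 5]}, self.entries())
        with pytest.raises(PreprocessError, match="constant"):
            adjust_icv(cohort, ["v"], "icv")


class TestHarmonization:
    def entries(self):
        return [
            VariableEntry(name="v", role="mri_thickness", direction="higher_is_better"),
            VariableEntry(name="age", role="covariate"),
            VariableEntry(name="scanner", role="batch"),
        ]

    def _orthonormal_noise(self, rng, n, age):
        """Zero-mean noise orthogonal to [1, age], unit SD."""
        e = rng.standard_normal(n)
        D = np.column_stack([np.ones(n), age])
        e = e - D @ np.linalg.lstsq(D, e, rcond=None)[0]
        return e / e.std(ddof=1)

    def test_location_shift_removed(self, cohort_factory, rng):
        n = 40
        age = np.zeros(n)
        e = rng.standard_normal(n)
        e -= e.mean()
        batch = np.repeat([0.0, 1.0], n // 2)
        v = e + 0.5 * batch
        cohort = cohort_factory(
            {"v": v, "age": age + 70, "scanner": batch}, self.entries()
        )
        out = harmonize_batches(cohort, ["v"], "scanner", ["age"])
        h = out.data["v"].to_numpy()
        assert abs(h[batch == 0].mean() - h[batch == 1].mean()) < 1e-8

    def test_scale_difference_removed(self, cohort_factory, rng):
        n = 60
        age = rng.normal(70, 5, n)
        batch = np.repeat([0.0, 1.0], n // 2)
        e = np.concatenate(
            [
                self._orthonormal_noise(rng, n // 2, age[: n // 2]),
                2.0 * self._orthonormal_noise(rng, n // 2, age[n // 2:]),
            ]
        )
        cohort = cohort_factory({"v": e, "age": age, "scanner": batch}, self.entries())
        out = harmonize_batches(cohort, ["v"], "scanner", ["age"])
        h = out.data["v"].to_numpy()
        sd0 = h[batch == 0].std(ddof=1)
        sd1 = h[batch == 1].std(ddof=1)
        assert abs(sd0**2 - sd1**2) < 1e-6

    def test_protected_slope_preserved(self, cohort_factory, rng):
        n = 80
        age = rng.normal(70, 5, n)
        batch = np.repeat([0.0, 1.0], n // 2)
        e = np.concatenate(
            [
                1.0 * self._orthonormal_noise(rng, n // 2, age[: n // 2]),
                1.7 * self._orthonormal_noise(rng, n // 2, age[n // 2:]),
            ]
        )
        v = 0.1 * age + 0.4 * batch + e
        cohort = cohort_factory({"v": v, "age": age, "scanner": batch}, self.entries())
        out = harmonize_batches(cohort, ["v"], "scanner", ["age"])
        h = out.data["v"].to_numpy()
        D = np.column_stack([np.ones(n), age, batch])
        slope = np.linalg.lstsq(D, h, rcond=None)[0][1]
        assert slope == pytest.approx(0.1, abs=1e-8)
        for bv in (0.0, 1.0):
            resid = h[batch == bv] - D[batch == bv] @ np.linalg.lstsq(D, h, rcond=None)[0]
            assert abs(resid.mean()) < 1e-8

    def test_tiny_batch_fatal(self, cohort_factory, rng):
        v = rng.standard_normal(10)
        batch = np.array([0.0] * 8 + [1.0] * 2)
        cohort = cohort_factory(
            {"v": v, "age": np.ones(10) * 70, "scanner": batch}, self.entries()
        )
        with pytest.raises(PreprocessError, match="<=2"):
            harmonize_batches(cohort, ["v"], "scanner", ["age"])


class TestComposites:
    def entries(self, weights=(None, None)):
        return [
            VariableEntry(
                name="r1", role="mri_thickness", direction="higher_is_better",
                domain_tag="frontal", region_weight=weights[0],
            ),
            VariableEntry(
                name="r2", role="mri_thickness", direction="higher_is_better",
                domain_tag="frontal", region_weight=weights[1],
            ),
        ]

    def test_unweighted_mean(self, cohort_factory):
        cohort = cohort_factory({"r1": [2.0], "r2": [3.0]}, self.entries())
        out = compute_composites(cohort, {"comp": ["r1", "r2"]}, weighted=False)
        assert out.data["comp"].iloc[0] == pytest.approx(2.5)
        assert out.manifest.entry("comp").role == "mri_global"

    def test_weighted_mean(self, cohort_factory):
        cohort = cohort_factory({"r1": [2.0], "r2": [3.0]}, self.entries((1.0, 3.0)))
        out = compute_composites(cohort, {"comp": ["r1", "r2"]}, weighted=True)
        assert out.data["comp"].iloc[0] == pytest.approx(2.75)

    def test_single_region_identity_and_partial_members(self, cohort_factory):
        cohort = cohort_factory({"r1": [2.0, np.nan], "r2": [3.0, 4.0]}, self.entries())
        out = compute_composites(cohort, {"solo": ["r1"], "both": ["r1", "r2"]}, weighted=False)
        assert out.data["solo"].iloc[0] == 2.0
        assert out.data["both"].iloc[1] == pytest.approx(4.0)  # non-missing members only

    def test_empty_group_fatal(self, cohort_factory):
        cohort = cohort_factory({"r1": [2.0]}, self.entries()[:1])
        with pytest.raises(PreprocessError, match="empty"):
            compute_composites(cohort, {"comp": []}, weighted=False)


class TestGenotypeOrientation:
    def entries(self, orientation):
        return [
            VariableEntry(name="rs1", role="genotype", risk_orientation=orientation)
        ]

    def test_protective_reflected(self, cohort_factory):
        cohort = cohort_factory({"rs1": [0.0, 1, 2]}, self.entries("protective_coded"))
        out = orient_genotypes_to_risk(cohort)
        np.testing.assert_array_equal(out.data["rs1"].to_numpy(), [2.0, 1, 0])
        assert out.manifest.entry("rs1").risk_orientation == "risk_coded"

    def test_risk_coded_untouched_and_involution(self, cohort_factory):
        cohort = cohort_factory({"rs1": [0.0, 1, 2]}, self.entries("risk_coded"))
        out = orient_genotypes_to_risk(orient_genotypes_to_risk(cohort))
        np.testing.assert_array_equal(out.data["rs1"].to_numpy(), [0.0, 1, 2])

    def test_out_of_range_fatal(self, cohort_factory):
        cohort = cohort_factory({"rs1": [0.0, 3.0]}, self.entries("protective_coded"))
        with pytest.raises(PreprocessError, match="rs1"):
            orient_genotypes_to_risk(cohort)


class TestZscore:
    def test_three_values(self, cohort_factory):
        cohort = cohort_factory({"c": [1.0, 2, 3]}, [cog_entry("c")])
        out = zscore_reference(cohort, ["c"])
        np.testing.assert_allclose(out.data["c"].to_numpy(), [-1.0, 0, 1], atol=1e-12)

    def test_idempotent(self, cohort_factory, rng):
        cohort = cohort_factory({"c": rng.normal(3, 2, 30)}, [cog_entry("c")])
        once = zscore_reference(cohort, ["c"])
        twice = zscore_reference(once, ["c"])
        np.testing.assert_allclose(
            twice.data["c"].to_numpy(), once.data["c"].to_numpy(), atol=1e-12
        )

    def test_constant_fatal(self, cohort_factory):
        cohort = cohort_factory({"c": [2.0, 2, 2]}, [cog_entry("c")])
        with pytest.raises(PreprocessError, match="c"):
            zscore_reference(cohort, ["c"])


class TestChain:
    def test_rerun_is_noop_on_complete_data(self):
        """With no missing data, the chain applied to its own output changes
        nothing.  QC, composites and batch rescaling are held out: QC can
        re-flag boundary values, composites of standardized members are a
        different quantity, and batch-specific residual rescaling is only
        approximately idempotent."""
        from resilcca import PreprocessParams, preprocess_cohort, simulate_cohort
        from resilcca.synthetic import CohortSpec, SyntheticConfig

        cfg = SyntheticConfig(
            cohorts=[
                CohortSpec(
                    label="a", n=80, n_thickness=4, n_volumes=2, q_cog=5,
                    include_wm_hypo=True,
                )
            ],
            seed=3,
        )
        cohort, _ = simulate_cohort(cfg, 0)
        params = PreprocessParams(skip_qc=True, skip_composites=True)
        once, _ = preprocess_cohort(cohort, params, seed=0)
        twice, _ = preprocess_cohort(once, params, seed=0)
        np.testing.assert_allclose(
            twice.data.to_numpy(), once.data.to_numpy(), atol=1e-8
        )

    def test_harmonization_idempotent_for_pure_shift(self, cohort_factory, rng):
        """Once batch shifts are removed (equal residual scales), running the
        harmonizer again changes nothing."""
        n = 60
        age = rng.normal(70, 5, n)
        batch = np.repeat([0.0, 1.0], n // 2)
        helper = TestHarmonization()
        e = np.concatenate(
            [
                helper._orthonormal_noise(rng, n // 2, age[: n // 2]),
                helper._orthonormal_noise(rng, n // 2, age[n // 2:]),
            ]
        )
        v = 0.05 * age + 0.8 * batch + e
        entries = [
            VariableEntry(name="v", role="mri_thickness", direction="higher_is_better"),
            VariableEntry(name="age", role="covariate"),
            VariableEntry(name="scanner", role="batch"),
        ]
        cohort = cohort_factory({"v": v, "age": age, "scanner": batch}, entries)
        once = harmonize_batches(cohort, ["v"], "scanner", ["age"])
        twice = harmonize_batches(once, ["v"], "scanner", ["age"])
        np.testing.assert_allclose(
            twice.data["v"].to_numpy(), once.data["v"].to_numpy(), atol=1e-8
        )

    def test_row_count_changes_only_in_sparsity(self):
        from resilcca import PreprocessParams, preprocess_cohort, simulate_cohort
        from resilcca.synthetic import CohortSpec, SyntheticConfig

        cfg = SyntheticConfig(
            cohorts=[
                CohortSpec(
                    label="a", n=100, n_thickness=4, n_volumes=2, q_cog=5,
                    missing_cognition=0.05, missing_volume=0.05,
                )
            ],
            seed=4,
        )
        cohort, _ = simulate_cohort(cfg, 0)
        prep, _ = preprocess_cohort(
            cohort, PreprocessParams(skip_sparsity=True), seed=0
        )
        assert prep.n == cohort.n
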