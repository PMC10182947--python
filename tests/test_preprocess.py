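import numpy as np
import pandas as pd
import pytest

from mechtox import (
    GeneratorConfig,
    ValidationError,
    autoscale,
    between_batch_correct,
    blank_filter,
    exclude_low_protein,
    generate_study,
    interpolate_ic,
    qc_rsd,
    qcsvrc_correct,
    qcsvrc_correct_all,
    rsd_filter,
)
from mechtox.preprocess import Autoscaler

from conftest import make_table


def one_batch_study(small_design, small_signatures, **cfg_kw):
    from dataclasses import replace

    design = replace(small_design, n_batches=1)
    cfg = GeneratorConfig(n_features=200, seed=17, batch_scale_sd=0.0, **cfg_kw)
    return generate_study(design, small_signatures, cfg)


class TestQCSVRC:
    def test_zero_drift_zero_noise_is_identity(self, small_design,
                                               small_signatures):
        t = one_batch_study(small_design, small_signatures,
                            drift_amplitude=0.0, rsd_noise=0.0)
        out = qcsvrc_correct(t, batch=1)
        np.testing.assert_allclose(out.intensities.to_numpy(),
                                   t.intensities.to_numpy(), rtol=0, atol=0)

    def test_constant_qc_feature_passes_through_exactly(self):
        vals = np.ones((8, 2)) * [100.0, 50.0]
        vals[::2, 1] = 60.0  # feature F1 varies, F0 constant on QCs
        types = ["qc" if i % 2 == 0 else "control" for i in range(8)]
        t = make_table(vals, types=types)
        out = qcsvrc_correct(t, batch=1)
        np.testing.assert_array_equal(out.intensities["F0"], t.intensities["F0"])

    def test_planted_monotone_drift_reduces_qc_rsd(self, small_design,
                                                   small_signatures):
        t = one_batch_study(small_design, small_signatures, drift_amplitude=0.0)
        orders = t.samples["injection_order"].to_numpy(float)
        drift = 2.0 ** ((orders - 1) / (orders.max() - 1))  # 1x -> 2x across batch
        drifted = t.copy()
        drifted.intensities = t.intensities.mul(drift, axis=0)
        rsd_before = qc_rsd(drifted)
        out = qcsvrc_correct(drifted, batch=1)
        rsd_after = qc_rsd(out)
        assert (rsd_after < rsd_before).mean() >= 0.95

    def test_too_few_qcs_instructs_between_batch_mode(self):
        t = make_table(np.ones((4, 2)) * 10,
                       types=["qc", "control", "control", "control"])
        with pytest.raises(ValidationError, match="between-batch"):
            qcsvrc_correct(t, batch=1)

    def test_rerun_on_corrected_data_is_nearly_idempotent(self, small_design,
                                                          small_signatures):
        t = one_batch_study(small_design, small_signatures)
        once = qcsvrc_correct(t, batch=1)
        twice = qcsvrc_correct(once, batch=1)
        rel = np.abs(twice.intensities.to_numpy() / once.intensities.to_numpy() - 1)
        assert np.median(rel) < 0.05


class TestBetweenBatch:
    def test_single_batch_is_identity(self):
        vals = np.vstack([np.full(3, 10.0)] * 6)
        types = ["qc", "control", "qc", "control", "control", "qc"]
        t = make_table(vals, types=types)
        out = between_batch_correct(t)
        np.testing.assert_array_equal(out.intensities.to_numpy(), vals)

    def test_exact_threefold_shift_removed(self):
        base = np.array([[10.0, 20.0], [12.0, 18.0], [11.0, 19.0]])
        vals = np.vstack([base, 3.0 * base])
        t = make_table(
            vals,
            types=["qc", "control", "qc"] * 2,
            batch=[1, 1, 1, 2, 2, 2],
            injection_order=[1, 2, 3, 1, 2, 3],
        )
        out = between_batch_correct(t)
        np.testing.assert_allclose(out.intensities.to_numpy()[3:], base)

    def test_planted_batch_scale_reduces_between_batch_qc_variance(
        self, small_design, small_signatures
    ):
        cfg = GeneratorConfig(n_features=200, seed=23, batch_scale_sd=0.3)
        t = generate_study(small_design, small_signatures, cfg)

        def between_batch_var(tab):
            qc = tab.of_type("qc")
            means = qc.intensities.groupby(qc.samples["batch"]).mean()
            return np.log(means).var(axis=0, ddof=1)

        v_before = between_batch_var(t)
        out = between_batch_correct(t)
        v_after = between_batch_var(out)
        assert (v_after < v_before).mean() > 0.95

    def test_named_reference_sample_becomes_identical_across_batches(self):
        rng = np.random.default_rng(0)
        b1 = rng.uniform(10, 20, (3, 4))
        b2 = rng.uniform(10, 20, (3, 4)) * rng.uniform(0.5, 2.0, 4)
        t = make_table(
            np.vstack([b1, b2]),
            types=["qc", "control", "qc"] * 2,
            batch=[1, 1, 1, 2, 2, 2],
            injection_order=[1, 2, 3, 1, 2, 3],
            sample_ids=["r1", "s1", "q1", "r2", "s2", "q2"],
        )
        out = between_batch_correct(t, reference_qc={1: "r1", 2: "r2"})
        np.testing.assert_allclose(out.intensities.loc["r2"],
                                   out.intensities.loc["r1"])

    def test_missing_reference_names_batch(self):
        t = make_table(np.ones((2, 2)), types=["qc", "qc"], batch=[1, 2],
                       injection_order=[1, 1])
        with pytest.raises(ValidationError, match="batch 2"):
            between_batch_correct(t, reference_qc={1: "S0"})


class TestRSDFilter:
    def test_truth_table(self):
        # F0: QC [100,100,100] -> RSD 0, kept; F1: [100,200,300] -> sd=100,
        # mean=200, RSD 50 > 30 -> removed
        vals = np.array([[100.0, 100.0], [100.0, 200.0], [100.0, 300.0],
                         [150.0, 180.0]])
        t = make_table(vals, types=["qc", "qc", "qc", "control"])
        out, report = rsd_filter(t, threshold_pct=30.0)
        assert out.feature_ids == ["F0"]
        assert report.features_removed_rsd == {"F1"}

    def test_boundary_is_strict(self):
        # QC [70, 100, 130]: mean 100, sample sd exactly 30 -> RSD exactly
        # 30%, which is not strictly above the threshold, so the feature stays
        t = make_table(np.array([[70.0], [100.0], [130.0]]), types=["qc"] * 3)
        out, _ = rsd_filter(t, threshold_pct=30.0)
        assert out.n_features == 1

    def test_mostly_missing_qc_feature_removed(self):
        vals = np.array([[100.0, 100.0], [np.nan, 110.0], [np.nan, 90.0],
                         [100.0, 100.0]])
        t = make_table(vals, types=["qc", "qc", "qc", "control"])
        out, report = rsd_filter(t)
        assert "F0" in report.features_removed_missing_qc
        assert out.feature_ids == ["F1"]

    def test_no_qcs_is_an_error(self):
        t = make_table(np.ones((2, 2)), types=["control", "control"])
        with pytest.raises(ValidationError):
            rsd_filter(t)

    def test_default_synthetic_study_keeps_most_features(self, small_study):
        corrected = between_batch_correct(qcsvrc_correct_all(small_study))
        out, _ = rsd_filter(corrected)
        assert out.n_features >= 0.9 * small_study.n_features


class TestBlankFilter:
    def test_known_ratios(self):
        # ratios sample/blank: 1, 2.9, 3.0, 3.1, 10 -> exactly ratio >= 3 kept
        blank = np.full(5, 100.0)
        sample = np.array([100.0, 290.0, 300.0, 310.0, 1000.0])
        t = make_table(np.vstack([blank, sample, sample]),
                       types=["blank", "control", "control"])
        out, report = blank_filter(t, fold=3.0)
        assert out.feature_ids == ["F2", "F3", "F4"]
        assert report.features_removed_blank == {"F0", "F1"}

    def test_zero_blank_mean_keeps_feature(self):
        t = make_table(np.array([[0.0], [50.0]]), types=["blank", "control"])
        out, _ = blank_filter(t)
        assert out.n_features == 1

    def test_no_blanks_is_an_error(self):
        t = make_table(np.ones((2, 2)), types=["control", "control"])
        with pytest.raises(ValidationError):
            blank_filter(t)

    def test_synthetic_blank_background_features_are_removed(
        self, small_design, small_signatures
    ):
        # blanks sit at 5% of baseline, so every genuine feature passes 3x
        t = generate_study(small_design, small_signatures,
                           GeneratorConfig(n_features=200, seed=2))
        out, rep = blank_filter(t)
        assert out.n_features == 200
        assert not rep.features_removed_blank


class TestLowProteinExclusion:
    def test_below_one_third_of_baseline_removed(self):
        t = make_table(
            np.ones((4, 2)),
            types=["blank", "blank", "treated", "treated"],
            protein=[330.0, 330.0, 100.0, 120.0],
        )
        out, report = exclude_low_protein(t, baseline="blank")
        assert report.samples_removed_low_protein == {"S2"}  # 100 < 110
        assert "S2" not in out.sample_ids and "S3" in out.sample_ids

    def test_all_equal_protein_removes_nothing(self):
        t = make_table(np.ones((3, 1)), types=["blank", "treated", "treated"],
                       protein=[200.0, 200.0, 200.0])
        _, report = exclude_low_protein(t)
        assert not report.samples_removed_low_protein

    def test_missing_protein_lists_samples(self):
        t = make_table(np.ones((2, 1)), types=["blank", "treated"],
                       protein=[100.0, np.nan])
        with pytest.raises(ValidationError, match="S1"):
            exclude_low_protein(t)

    def test_planted_decline_matches_ground_truth(self):
        from mechtox import CompoundSpec, SignatureSpec, StudyDesign

        # fixed-ladder design reaching near-full cytotoxic activation at the
        # top concentration, with a strong protein decline planted
        comp = CompoundSpec("c", "OS", ic10=10.0, ic50=100.0)
        design = StudyDesign((comp,), n_batches=1,
                             replicates_per_condition=4,
                             design_kind="test_fixed",
                             concentrations_fixed=(1.0, 100.0, 1e4, 1e6))
        sig = SignatureSpec("OS", ("F0000",), (1,))
        cfg = GeneratorConfig(n_features=20, seed=5, protein_cv=0.0,
                              protein_decline=0.8)
        t = generate_study(design, [sig], cfg)
        _, report = exclude_low_protein(t, baseline="blank")
        act = t.samples["activation_general"]
        # protein = P0 (1 - 0.8 a) < P0/3  <=>  a > 5/6
        expected = set(t.samples.index[(t.samples["type"] == "treated")
                                       & (act > 5.0 / 6.0)])
        assert expected  # the planted cut is actually exercised
        assert report.samples_removed_low_protein == expected


class TestAutoscale:
    def test_simple_column(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        Z, mean, sd, dropped = autoscale(X)
        np.testing.assert_allclose(Z["a"], [-1.0, 0.0, 1.0])
        assert mean["a"] == 2.0 and sd["a"] == 1.0 and not dropped

    def test_constant_column_removed_and_reported(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        Z, _, _, dropped = autoscale(X)
        assert dropped == ["b"] and list(Z.columns) == ["a"]

    def test_normalization_identity_random_matrix(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(3, 2, (30, 8)))
        X.columns = [str(c) for c in X.columns]
        Z, _, _, _ = autoscale(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        assert np.abs(Z.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_scaler_reapplies_training_parameters(self):
        rng = np.random.default_rng(5)
        train = pd.DataFrame(rng.normal(0, 1, (20, 3)), columns=list("abc"))
        test = pd.DataFrame(rng.normal(5, 2, (10, 3)), columns=list("abc"))
        sc = Autoscaler().fit(train)
        Z = sc.transform(test)
        np.testing.assert_allclose(Z, (test - train.mean()) / train.std(ddof=1))

    def test_missing_training_feature_in_test_rejected(self):
        sc = Autoscaler().fit(pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]}))
        with pytest.raises(ValidationError, match="b"):
            sc.transform(pd.DataFrame({"a": [1.0]}))


class TestICInterpolation:
    def test_exact_anchor_points(self):
        dr = interpolate_ic([1, 10, 100, 1000], [1.0, 0.9, 0.5, 0.1])
        assert dr.ic10 == pytest.approx(10.0, rel=1e-9)
        assert dr.ic50 == pytest.approx(100.0, rel=1e-9)

    def test_symmetric_logistic_midpoint(self):
        conc = np.logspace(0, 4, 9)
        viab = 1 / (1 + (conc / 100.0))
        dr = interpolate_ic(conc, viab)
        assert dr.ic50 == pytest.approx(100.0, rel=1e-6)

    def test_noisy_curves_recover_ic50_within_15pct(self):
        rng = np.random.default_rng(8)
        conc = np.logspace(0, 4, 9)
        true = 1 / (1 + (conc / 100.0) ** 1.2)
        recovered = []
        for _ in range(50):
            noisy = np.clip(true * (1 + rng.normal(0, 0.05, conc.size)), 0, 1.2)
            try:
                recovered.append(interpolate_ic(conc, noisy).ic50)
            except ValidationError:
                continue
        assert abs(np.median(recovered) - 100.0) / 100.0 < 0.15

    def test_all_viable_and_all_dead_are_errors(self):
        with pytest.raises(ValidationError, match="all-viable"):
            interpolate_ic([1, 10, 100, 1000], [1.0, 1.0, 0.99, 0.98])
        with pytest.raises(ValidationError, match="all-dead"):
            interpolate_ic([1, 10, 100, 1000], [0.01, 0.0, 0.0, 0.0])

    def test_non_monotone_warns(self):
        with pytest.warns(UserWarning, match="not monotone"):
            interpolate_ic([1, 10, 100, 1000], [0.9, 0.5, 0.95, 0.1])

    def test_extrapolation_warns_and_flags(self):
        with pytest.warns(UserWarning, match="extrapolated"):
            dr = interpolate_ic([1, 10, 100, 1000], [0.85, 0.7, 0.5, 0.2])
        assert dr.extrapolated  # IC10 lies below the tested range


class TestFilterIdempotence:
    def test_filters_change_nothing_on_second_pass(self, small_study):
        corrected = between_batch_correct(qcsvrc_correct_all(small_study))
        once, _ = rsd_filter(corrected)
        once, _ = blank_filter(once)
        twice, rep1 = rsd_filter(once)
        twice, rep2 = blank_filter(twice)
        assert not rep1.features_removed_rsd
        assert not rep2.features_removed_blank
        pd.testing.assert_frame_equal(once.intensities, twice.intensities)
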