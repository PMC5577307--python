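import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy.stats import norm

from soaytel import (
    AmplificationCurve,
    DNASampleQC,
    PlateSummary,
    QPCRPlateSpec,
    compute_rtl,
    correct_baseline,
    dna_sample_qc,
    estimate_efficiency_and_cq,
    process_plates,
    sample_population,
    set_group_threshold,
    simulate_plates,
    study_design,
    triplicate_cv_qc,
    well_efficiency_qc,
)
from soaytel.errors import DomainError, InputError
from soaytel.qpcr import apply_dna_qc

CYCLES = np.arange(1, 51)


def make_curve(cq=20.0, eff=1.9, threshold=0.2, baseline=(0.0, 0.0), plateau=2.0,
               well="w1", role="sample", amplicon="TEL"):
    f0 = threshold * eff ** (-cq)
    f = baseline[0] + baseline[1] * CYCLES + np.minimum(f0 * eff**CYCLES, plateau)
    return AmplificationCurve("P1", well, "s1", amplicon, role, CYCLES,
                              np.maximum(f, 1e-9))


class TestBaselineCorrection:
    def test_pure_linear_baseline_corrects_to_zero(self):
        f = 0.05 + 0.002 * CYCLES
        curve = AmplificationCurve("P1", "w", "s", "TEL", "NTC", CYCLES, f)
        out = correct_baseline(curve, n_baseline_cycles=10)
        assert np.allclose(out.fluorescence, 0.0, atol=1e-12)

    def test_growth_phase_log_slope_recovers_efficiency(self):
        curve = make_curve(cq=25, eff=1.9, baseline=(0.04, 0.001))
        out = correct_baseline(curve, n_baseline_cycles=8)
        # regress log F on cycle well inside the exponential phase
        idx = (CYCLES >= 22) & (CYCLES <= 27)
        slope = np.polyfit(CYCLES[idx], np.log(out.fluorescence[idx]), 1)[0]
        assert np.exp(slope) == pytest.approx(1.9, abs=0.01)

    def test_negligible_early_signal_skips_correction(self):
        curve = make_curve(cq=20, eff=1.9, baseline=(0.0, 0.0))
        out = correct_baseline(curve, 6, negligible_level=0.02 * 0.2)
        assert out is curve

    def test_too_few_cycles_rejected(self):
        curve = make_curve()
        with pytest.raises(InputError):
            correct_baseline(curve, n_baseline_cycles=60)


class TestEfficiencyAndCq:
    def test_closed_form_recovery(self):
        # F = F0 * 2^c with F0 = T * 2^-20 crosses T exactly at cycle 20
        curve = make_curve(cq=20.0, eff=2.0, threshold=0.2)
        est = estimate_efficiency_and_cq(curve, 0.2)
        assert est.qc_pass
        assert est.efficiency == pytest.approx(2.0, abs=1e-6)
        assert est.cq == pytest.approx(20.0, abs=1e-6)

    @pytest.mark.parametrize("eff,cq", [(1.9, 18.0), (1.88, 24.5), (1.91, 15.2)])
    def test_generating_parameters_recovered(self, eff, cq):
        est = estimate_efficiency_and_cq(make_curve(cq=cq, eff=eff), 0.2)
        assert est.efficiency == pytest.approx(eff, abs=0.02)
        assert est.cq == pytest.approx(cq, abs=0.05)

    def test_ntc_flagged_non_amplifying(self):
        f = np.full(CYCLES.size, 1e-9)
        curve = AmplificationCurve("P1", "ntc", "NTC", "TEL", "NTC", CYCLES, f)
        est = estimate_efficiency_and_cq(curve, 0.2)
        assert not est.qc_pass
        assert est.reasons == ("non_amplifying",)
        assert np.isnan(est.cq)

    def test_threshold_within_window_span(self):
        est = estimate_efficiency_and_cq(make_curve(cq=20), 0.2)
        lo, hi = est.window
        assert lo <= est.cq <= hi


class TestGroupThreshold:
    def test_threshold_lies_in_every_window(self):
        curves = [make_curve(cq=cq, eff=1.9, well=f"w{i}")
                  for i, cq in enumerate([18.0, 19.0, 20.0, 21.0])]
        thr = set_group_threshold(curves, "TEL")
        for cv in curves:
            est = estimate_efficiency_and_cq(cv, thr)
            lo, hi = est.window
            f = cv.fluorescence
            span = (f[int(lo) - 1], f[int(hi) - 1])
            assert span[0] <= thr <= span[1]

    def test_deterministic(self):
        curves = [make_curve(cq=cq, well=f"w{i}") for i, cq in enumerate([18, 20, 22])]
        assert set_group_threshold(curves, "TEL") == set_group_threshold(curves, "TEL")

    def test_default_uses_first_six_plates(self):
        import inspect

        sig = inspect.signature(set_group_threshold)
        assert sig.parameters["first_k_plates"].default == 6

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            set_group_threshold([make_curve()], "B2M")


class TestTriplicateCV:
    @pytest.mark.parametrize(
        "cqs,cv,passed",
        [
            ((20.0, 20.0, 20.0), 0.0, True),
            ((20.0, 21.0, 22.0), 1 / 21, True),
            ((18.0, 21.0, 24.0), 3 / 21, False),
        ],
    )
    def test_cv_formula_and_cutoff(self, cqs, cv, passed):
        res = triplicate_cv_qc(cqs)
        assert res.value == pytest.approx(cv, abs=1e-12)
        assert res.passed is passed

    def test_missing_replicate_distinct_reason(self):
        res = triplicate_cv_qc((20.0, np.nan, 21.0))
        assert not res.passed
        assert res.reasons == ("missing_replicate",)

    @given(st_.floats(1.01, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_cv_scale_invariant(self, scale):
        base = triplicate_cv_qc((18.0, 20.0, 21.0)).value
        scaled = triplicate_cv_qc((18.0 * scale, 20.0 * scale, 21.0 * scale)).value
        assert scaled == pytest.approx(base, rel=1e-9)


class TestEfficiencyQC:
    @pytest.mark.parametrize(
        "eff,mean,passed",
        [(1.90, 1.90, True), (2.00, 1.90, False), (1.81, 1.90, True)],
    )
    def test_five_percent_band(self, eff, mean, passed):
        assert well_efficiency_qc(eff, mean).passed is passed

    def test_rejects_non_amplifying_efficiencies(self):
        with pytest.raises(DomainError):
            well_efficiency_qc(0.9, 1.9)


class TestDNASampleQC:
    def test_low_yield_immediately_rejected(self):
        res = dna_sample_qc(DNASampleQC("s", 19.0, 1.85, 2.0, 1))
        assert not res.passed and res.reasons == ("low_yield",)

    def test_boundaries_inclusive(self):
        assert dna_sample_qc(DNASampleQC("s", 50.0, 1.85, 2.0, 2)).passed
        assert dna_sample_qc(DNASampleQC("s", 20.0, 1.7, 1.8, 1)).passed

    def test_integrity_above_two_rejected(self):
        res = dna_sample_qc(DNASampleQC("s", 50.0, 1.85, 2.0, 3))
        assert not res.passed and "integrity" in res.reasons

    def test_invalid_integrity_score(self):
        with pytest.raises(InputError):
            dna_sample_qc(DNASampleQC("s", 50.0, 1.85, 2.0, 7))

    def test_reextraction_retry(self):
        records = [
            DNASampleQC("a", 15.0, 1.85, 2.0, 1),  # fails, first attempt
            DNASampleQC("a", 40.0, 1.85, 2.0, 1),  # re-extraction passes
            DNASampleQC("b", 15.0, 1.85, 2.0, 1),  # fails twice -> excluded
            DNASampleQC("b", 16.0, 1.85, 2.0, 1),
            DNASampleQC("c", 15.0, 1.85, 2.0, 1),  # one failure, retry pending
        ]
        out = apply_dna_qc(records).set_index("sample_id")
        assert out.loc["a", "accepted"] and out.loc["a", "final"]
        assert not out.loc["b", "accepted"] and out.loc["b", "final"]
        assert out.loc["b", "reason"] == "low_yield"
        assert not out.loc["c", "accepted"] and not out.loc["c", "final"]


class TestComputeRTL:
    def summary(self, et=1.9, eb=1.9, ct=20.0, cb=22.0):
        return PlateSummary("P1", et, eb, ct, cb)

    def test_self_normalisation(self):
        assert compute_rtl(20.0, 22.0, self.summary()) == 1.0

    def test_perfect_doubling_reduces_to_ddcq(self):
        s = self.summary(et=2.0, eb=2.0, ct=21.0, cb=22.0)
        assert compute_rtl(20.0, 22.0, s) == pytest.approx(2.0, rel=1e-12)

    def test_printed_plate_mean_efficiencies(self):
        # E_TEL = 1.91, E_B2M = 1.88, dCq_TEL = +0.5, dCq_B2M = -0.25
        s = PlateSummary("P1", 1.91, 1.88, 20.5, 21.75)
        rtl = compute_rtl(20.0, 22.0, s)
        assert rtl == pytest.approx(1.91**0.5 * 1.88**0.25, rel=1e-12)
        assert rtl == pytest.approx(1.618, abs=5e-4)

    def test_missing_calibrator_is_plate_error(self):
        with pytest.raises(InputError):
            compute_rtl(20.0, 22.0, PlateSummary("P1", 1.9, 1.9, np.nan, 22.0))

    def test_non_amplifying_efficiency_is_domain_error(self):
        with pytest.raises(DomainError):
            compute_rtl(20.0, 22.0, PlateSummary("P1", 0.99, 1.9, 20.0, 22.0))

    @given(st_.floats(-2.0, 2.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_amplicon_wide_cq_shift(self, delta):
        base = compute_rtl(20.0, 22.0, self.summary(ct=20.5, cb=21.75))
        shifted = compute_rtl(20.0 + delta, 22.0,
                              self.summary(ct=20.5 + delta, cb=21.75))
        assert shifted == pytest.approx(base, rel=1e-9)

    @given(st_.floats(0.05, 1.5))
    @settings(max_examples=25, deadline=None)
    def test_strictly_decreasing_in_sample_tel_cq(self, delta):
        s = self.summary(ct=20.5, cb=21.75)
        assert compute_rtl(20.0 + delta, 22.0, s) < compute_rtl(20.0, 22.0, s)


@pytest.fixture(scope="module")
def subpopulation():
    return sample_population(study_design(), seed=55).head(150)


class TestRoundTrip:
    def test_noiseless_round_trip_and_calibrator_identity(self, subpopulation):
        spec = QPCRPlateSpec(cq_noise_sd=0.0, fluor_noise_sd=0.0)
        sim = simulate_plates(subpopulation, spec, seed=2)
        rtl, _, _, exclusions = process_plates(sim.wells)
        assert exclusions == {}
        m = rtl[rtl.role == "sample"].merge(
            subpopulation[["sample_id", "rtl"]], on="sample_id",
            suffixes=("_est", "_true"),
        )
        assert len(m) == len(subpopulation)
        assert np.max(np.abs(m.rtl_est - m.rtl_true)) < 1e-6
        cal = rtl[rtl.role == "calibrator"]
        assert (cal.rtl == 1.0).all()

    def test_baseline_corrected_round_trip(self, subpopulation):
        spec = QPCRPlateSpec(
            cq_noise_sd=0.0, fluor_noise_sd=0.0,
            baseline_intercept=(0.01, 0.05), baseline_slope=(0.0, 0.002),
        )
        sim = simulate_plates(subpopulation, spec, seed=3)
        rtl, _, _, _ = process_plates(sim.wells)
        m = rtl[(rtl.role == "sample") & ~rtl.excluded].merge(
            subpopulation[["sample_id", "rtl"]], on="sample_id",
            suffixes=("_est", "_true"),
        )
        assert len(m) == len(subpopulation)
        relerr = np.abs(m.rtl_est / m.rtl_true - 1)
        assert relerr.max() < 0.02

    def test_cq_noise_error_matches_propagation(self, subpopulation):
        """Empirical RTL error under Cq noise agrees with direct error
        propagation of the RTL formula."""
        spec = QPCRPlateSpec(cq_noise_sd=0.1, fluor_noise_sd=0.0)
        sim = simulate_plates(subpopulation, spec, seed=4)
        rtl, _, _, _ = process_plates(sim.wells)
        m = rtl[(rtl.role == "sample") & ~rtl.excluded].merge(
            subpopulation[["sample_id", "rtl"]], on="sample_id",
            suffixes=("_est", "_true"),
        )
        # var(log RTL) from triplicate sample means (sd^2/3) and 6-well
        # calibrator means (sd^2/6), per amplicon
        var_log = (np.log(spec.e_tel) ** 2 + np.log(spec.e_b2m) ** 2) * (
            spec.cq_noise_sd**2 / 3 + spec.cq_noise_sd**2 / 6
        )
        sd = np.sqrt(var_log)
        predicted = norm.cdf(np.log(1.1) / sd) - norm.cdf(np.log(0.9) / sd)
        observed = (np.abs(m.rtl_est / m.rtl_true - 1) < 0.1).mean()
        mc = np.sqrt(predicted * (1 - predicted) / len(m))
        assert observed == pytest.approx(predicted, abs=3.5 * mc)

    def test_moderate_cq_noise_keeps_samples_within_ten_percent(self, subpopulation):
        spec = QPCRPlateSpec(cq_noise_sd=0.05, fluor_noise_sd=0.0)
        sim = simulate_plates(subpopulation, spec, seed=5)
        rtl, _, _, _ = process_plates(sim.wells)
        m = rtl[(rtl.role == "sample") & ~rtl.excluded].merge(
            subpopulation[["sample_id", "rtl"]], on="sample_id",
            suffixes=("_est", "_true"),
        )
        assert (np.abs(m.rtl_est / m.rtl_true - 1) < 0.1).mean() >= 0.95


class TestQCFilters:
    def test_injected_cv_corruption_excluded(self, subpopulation):
        spec = QPCRPlateSpec(cq_noise_sd=0.0, fluor_noise_sd=0.0,
                             corrupt_cv_fraction=0.3)
        sim = simulate_plates(subpopulation, spec, seed=6)
        n_corrupt = (
            sim.truth[(sim.truth.role == "sample") & (sim.truth.amplicon == "TEL")]
            .groupby("sample_id")["cq_nominal"].nunique() > 1
        ).sum()
        assert n_corrupt > 10
        rtl, _, _, exclusions = process_plates(sim.wells)
        assert exclusions.get("cv_tel", 0) == n_corrupt

    def test_qc_filters_order_independent(self, subpopulation):
        spec = QPCRPlateSpec(cq_noise_sd=0.08, fluor_noise_sd=0.01,
                             corrupt_cv_fraction=0.1)
        sim = simulate_plates(subpopulation, spec, seed=7)
        _, well_qc, _, _ = process_plates(sim.wells)
        w = well_qc[well_qc.role == "sample"]
        per_amp = w.groupby(["sample_id", "amplicon"])["cq"].apply(
            lambda c: not triplicate_cv_qc(c).passed
        )
        flags = (
            per_amp.groupby("sample_id").any().rename("cv_fail").to_frame()
            .join(w.groupby("sample_id")["eff_dev_fail"].any().rename("eff_fail"))
        )
        # the combined exclusion set is the same whichever filter runs first
        cv_then_eff = flags.cv_fail | flags.eff_fail
        eff_then_cv = flags.eff_fail | flags.cv_fail
        assert (cv_then_eff == eff_then_cv).all()
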