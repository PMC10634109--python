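"""Rate-constant estimation, QC filters and turnover classification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from turnover15n.synthetic import ProteinKineticParams, simulate_growth, simulate_protein_trajectory
from turnover15n.turnover import (
    C2_TIMES_H,
    aggregate_protein_ria,
    classify_turnover,
    compute_kd_steady,
    compute_ks_general,
    compute_ks_steady,
    estimate_steady_state,
    fit_fcp_model,
    fit_kd_transition,
    fit_kdil,
    fit_kloss,
    ks_timecourse_transition,
    qc_turnover,
)


def peptide_table(rows):
    return pd.DataFrame(rows, columns=["peptide_sequence", "protein_id", "replicate", "time_h", "ria"])


class TestAggregation:
    def test_single_covered_peptide_is_identity(self):
        rows = [("PEP", "P1", 1, t, 0.1 * t) for t in range(5)]
        out = aggregate_protein_ria(peptide_table(rows), min_timepoints=5)
        assert len(out) == 5
        assert np.allclose(out["ria"], [0.1 * t for t in range(5)])

    def test_under_covered_peptide_dropped(self):
        rows = [("PEP", "P1", 1, t, 0.1) for t in range(4)]  # 4 of 10 time points
        out = aggregate_protein_ria(peptide_table(rows), min_timepoints=5)
        assert out.empty

    def test_coverage_needs_one_replicate_only(self):
        rows = [("PEP", "P1", 1, t, 0.1) for t in range(5)]
        rows += [("PEP", "P1", 2, t, 0.2) for t in range(2)]  # sparse replicate kept
        out = aggregate_protein_ria(peptide_table(rows), min_timepoints=5)
        assert set(out["replicate"]) == {1, 2}

    def test_protein_ria_is_peptide_median(self):
        rows = [(f"PEP{i}", "P1", 1, t, r)
                for t in range(5)
                for i, r in enumerate([0.1, 0.2, 0.9])]
        out = aggregate_protein_ria(peptide_table(rows), min_timepoints=5)
        assert np.allclose(out["ria"], 0.2)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            aggregate_protein_ria(pd.DataFrame({"ria": [0.1]}))


class TestKloss:
    def test_exact_exponential_series(self):
        t_days = np.array([0, 1, 2, 3, 4], dtype=float)
        series = pd.DataFrame({
            "replicate": 1, "time_h": t_days * 24, "ria": 1 - np.exp(-0.2 * t_days),
        })
        [fit] = fit_kloss(series)
        assert fit.slope == pytest.approx(0.2, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_ria_zero_slope(self):
        series = pd.DataFrame({"replicate": 1, "time_h": [0, 24, 48], "ria": 0.3})
        [fit] = fit_kloss(series)
        assert fit.slope == 0.0

    def test_simulator_steady_state_slope(self):
        params = ProteinKineticParams.steady_state("P", 0.1, 0.25)
        traj = simulate_protein_trajectory(params, 0.25, [0, 24, 48, 72, 96])
        series = pd.DataFrame({"replicate": 1, "time_h": traj["time_h"], "ria": traj["ria"]})
        [fit] = fit_kloss(series)
        assert fit.slope == pytest.approx(0.35, abs=1e-6)

    def test_too_few_points_skipped(self):
        series = pd.DataFrame({"replicate": 1, "time_h": [0, 24], "ria": [0.1, 0.2]})
        assert fit_kloss(series) == []

    def test_saturated_ria_clipped_and_counted(self):
        series = pd.DataFrame({"replicate": 1, "time_h": [0, 24, 48], "ria": [0.5, 0.9, 1.0]})
        [fit] = fit_kloss(series)
        assert fit.n_clipped == 1
        assert math.isfinite(fit.slope)


class TestKdil:
    def test_closed_form_round_trip(self):
        t_h = np.array([0, 12, 24, 48, 96], dtype=float)
        growth = pd.DataFrame({
            "time_h": t_h, "replicate": 1, "weight_g": 0.2 * np.exp(0.3464 * t_h / 24),
        })
        assert fit_kdil(growth) == pytest.approx(0.3464, abs=1e-12)

    def test_constant_weights_zero(self):
        growth = pd.DataFrame({"time_h": [0, 24, 48], "replicate": 1, "weight_g": 0.5})
        assert fit_kdil(growth) == 0.0

    def test_noisy_recovery(self):
        growth = simulate_growth(0.2, 0.25, np.linspace(0, 96, 10), cv=0.05, seed=9,
                                 n_replicates=3)
        assert fit_kdil(growth) == pytest.approx(0.25, rel=0.10)

    def test_non_positive_weight_rejected(self):
        growth = pd.DataFrame({"time_h": [0, 24, 48], "replicate": 1,
                               "weight_g": [0.2, 0.0, 0.3]})
        with pytest.raises(ValueError, match="non-positive"):
            fit_kdil(growth)


class TestKdKs:
    def test_kd_is_kloss_minus_kdil(self):
        assert compute_kd_steady(0.35, 0.137) == pytest.approx(0.213)
        assert compute_kd_steady(0.2, 0.2) == 0.0

    def test_negative_kd_allowed_but_returned(self):
        assert compute_kd_steady(0.1, 0.3) < 0

    def test_ks_equals_kd_without_growth(self):
        # K_dil = 0 means FCP = 1, so synthesis just balances degradation
        assert compute_ks_steady(0.4, 0.0) == pytest.approx(0.4)
        assert compute_ks_general(0.4, 1.0, 2.0) == pytest.approx(0.4)

    def test_steady_equals_general_at_growth_fcp(self):
        kd, kdil, t = 0.1, 0.3, 2.0
        assert compute_ks_steady(kd, kdil, t) == pytest.approx(
            compute_ks_general(kd, math.exp(kdil * t), t), rel=1e-12
        )

    def test_pure_decay_gives_zero_ks(self):
        kd, t = 0.25, 2.0
        assert compute_ks_general(kd, math.exp(-kd * t), t) == pytest.approx(0.0, abs=1e-12)

    def test_small_kd_limit(self):
        # K_d -> 0+: K_s/A -> (exp(Kdil t) - 1) / t
        kdil, t = 0.3, 2.0
        probe = compute_ks_steady(1e-8, kdil, t)
        assert probe == pytest.approx((math.exp(kdil * t) - 1) / t, rel=1e-4)

    def test_kd_zero_rejected(self):
        with pytest.raises(ValueError, match="K_d = 0"):
            compute_ks_steady(0.0, 0.3)


class TestQC:
    def test_identical_slopes_pass(self):
        qc = qc_turnover([0.1, 0.1, 0.1], [0.9, 0.9, 0.9], "C1")
        assert qc.passed and qc.rstde_pct == pytest.approx(0, abs=1e-12)

    def test_rstde_filter(self):
        qc = qc_turnover([0.1, 0.2, 0.3], [0.9, 0.9, 0.9], "C1")
        assert qc.rstde_pct == pytest.approx(50.0)
        assert not qc.passed

    def test_negative_mean_fails_steady_conditions_only(self):
        slopes, r2s = [-0.06, -0.05, -0.04], [0.9, 0.9, 0.9]
        assert qc_turnover(slopes, r2s, "C1").reason == "negative K_loss"
        assert qc_turnover(slopes, r2s, "C3").reason == "negative K_loss"
        assert qc_turnover(slopes, r2s, "C2").passed  # negative K_d legitimate in C2

    def test_median_r2_filter(self):
        qc = qc_turnover([0.1, 0.1, 0.1], [0.4, 0.45, 0.9], "C1")
        assert not qc.passed and "R2" in qc.reason

    def test_single_replicate_fails(self):
        qc = qc_turnover([0.1], [0.9], "C1")
        assert not qc.passed and qc.reason == "insufficient replicates"

    def test_two_replicates_allowed(self):
        assert qc_turnover([0.1, 0.11], [0.9, 0.9], "C2").passed

    def test_order_independence(self):
        slopes, r2s = [0.12, 0.10, 0.14], [0.8, 0.95, 0.7]
        baseline = qc_turnover(slopes, r2s, "C1")
        for perm in itertools.permutations(range(3)):
            qc = qc_turnover([slopes[i] for i in perm], [r2s[i] for i in perm], "C1")
            assert (qc.passed, qc.reason) == (baseline.passed, baseline.reason)
            assert qc.rstde_pct == pytest.approx(baseline.rstde_pct)


class TestFCPModel:
    def test_flat_profile(self):
        model = fit_fcp_model({0: 1.0, 1: 1.0, 3: 1.0, 16: 1.0})
        assert (model.a, model.b, model.c) == pytest.approx((0, 0, 1), abs=1e-12)
        assert not model.responsive

    def test_rising_profile_fit_and_gate(self):
        fcp = {0: 1.0, 1: 1.2, 3: 1.8, 16: 2.6}
        model = fit_fcp_model(fcp)
        # least-squares oracle via the normal equations
        t = np.array([0, 1, 3, 16.0])
        y = np.array([1.0, 1.2, 1.8, 2.6])
        design = np.vstack([t**2, t, np.ones(4)]).T
        coef = np.linalg.lstsq(design, y, rcond=None)[0]
        assert (model.a, model.b, model.c) == pytest.approx(tuple(coef))
        assert model.responsive

    def test_depletion_gate(self):
        model = fit_fcp_model({0: 1.0, 1: 0.9, 3: 0.8, 16: 0.7})
        assert model.responsive  # below 0.75

    def test_missing_time_point_rejected(self):
        with pytest.raises(ValueError, match="missing median FCP"):
            fit_fcp_model({0: 1.0, 1: 1.2, 3: 1.8})


class TestTransition:
    def test_fcp_one_reduces_to_kloss_fit(self):
        t_days = np.array(C2_TIMES_H) / 24.0
        series = pd.DataFrame({
            "replicate": 1, "time_h": C2_TIMES_H, "ria": 1 - np.exp(-0.5 * t_days - 0.1),
        })
        flat = fit_fcp_model({0: 1.0, 1: 1.0, 3: 1.0, 16: 1.0})
        [via_eq7] = fit_kd_transition(series, flat)
        [via_eq2] = fit_kloss(series, times_h=C2_TIMES_H)
        assert via_eq7.slope == pytest.approx(via_eq2.slope, abs=1e-12)
        assert via_eq7.r2 == pytest.approx(via_eq2.r2, abs=1e-12)

    def test_simulator_round_trip_elevated_kd(self):
        # K_d jumps to 0.8/day over the transition window, noise-free
        kdil, kd0 = 0.25, 0.2
        params = ProteinKineticParams(
            "P", ((-1e9, kd0), (0.0, 0.8), (16.0, kd0)),
            ((-1e9, kd0 + kdil), (0.0, 0.15), (16.0, kd0 + kdil)),
        )
        times = sorted({-8.0, *C2_TIMES_H, 1.0, 3.0})
        traj = simulate_protein_trajectory(params, kdil, times).set_index("time_h")
        model = fit_fcp_model({t: traj.loc[t, "fcp"] for t in (0, 1, 3, 16)})
        assert model.responsive
        series = pd.DataFrame({
            "replicate": 1, "time_h": list(C2_TIMES_H),
            "ria": [traj.loc[t, "ria"] for t in C2_TIMES_H],
        })
        [fit] = fit_kd_transition(series, model)
        assert fit.slope == pytest.approx(0.8, abs=0.05)

    def test_ks_timecourse_constant_at_flat_fcp(self):
        flat = fit_fcp_model({0: 1.0, 1: 1.0, 3: 1.0, 16: 1.0})
        ks = ks_timecourse_transition(0.3, flat)
        assert set(ks) == {2.0, 4.0, 6.0, 8.0, 16.0}
        assert all(v == pytest.approx(0.3, abs=1e-9) for v in ks.values())

    def test_ks_series_matches_direct_formula(self):
        model = fit_fcp_model({0: 1.0, 1: 1.2, 3: 1.8, 16: 2.6})
        kd = 0.5
        ks = ks_timecourse_transition(kd, model)
        for t_h, value in ks.items():
            assert value == pytest.approx(
                compute_ks_general(kd, model.fcp_at(t_h), t_h / 24.0)
            )

    def test_ks_pulse_is_maximal_earliest(self):
        # synthesis burst right after elicitation, decaying over the window
        kdil, kd = 0.25, 0.3
        params = ProteinKineticParams(
            "P", ((-1e9, kd),),
            ((-1e9, kd + kdil), (0.0, 3.0), (4.0, 1.2), (8.0, kd + kdil)),
        )
        times = sorted({-8.0, *C2_TIMES_H, 1.0, 3.0})
        traj = simulate_protein_trajectory(params, kdil, times).set_index("time_h")
        model = fit_fcp_model({t: traj.loc[t, "fcp"] for t in (0, 1, 3, 16)})
        series = pd.DataFrame({
            "replicate": 1, "time_h": list(C2_TIMES_H),
            "ria": [traj.loc[t, "ria"] for t in C2_TIMES_H],
        })
        [fit] = fit_kd_transition(series, model)
        ks = ks_timecourse_transition(fit.slope, model)
        assert max(ks, key=ks.get) == 2.0


class TestClassification:
    @pytest.mark.parametrize(
        "kd,expected",
        [
            (0.01, "slow"), (0.0549, "slow"),
            (0.055, "intermediate"), (0.1, "intermediate"), (0.22, "intermediate"),
            (0.221, "fast"), (1.5, "fast"),
        ],
    )
    def test_boundaries(self, kd, expected):
        assert classify_turnover(kd) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_turnover(float("nan"))


class TestSteadyStateEstimate:
    def test_noise_free_recovery_and_class(self):
        kd, kdil = 0.1, 0.25
        params = ProteinKineticParams.steady_state("P", kd, kdil)
        rows = []
        for rep in (1, 2, 3):
            traj = simulate_protein_trajectory(params, kdil, [0, 24, 48, 72, 96])
            rows.append(pd.DataFrame({"replicate": rep, "time_h": traj["time_h"],
                                      "ria": traj["ria"]}))
        est = estimate_steady_state("P", pd.concat(rows), kdil, "C1")
        assert est.qc.passed
        assert est.kd == pytest.approx(kd, abs=1e-9)
        assert est.turnover_class == "intermediate"
        assert est.ks == pytest.approx(compute_ks_steady(kd, kdil), rel=1e-9)

    def test_failed_qc_blanks_estimates(self):
        series = pd.DataFrame({
            "replicate": [1] * 3 + [2] * 3 + [3] * 3,
            "time_h": [0, 24, 48] * 3,
            "ria": [0.1, 0.3, 0.5, 0.5, 0.3, 0.1, 0.1, 0.5, 0.2],
        })
        est = estimate_steady_state("P", series, 0.25, "C1")
        assert not est.qc.passed
        assert est.kd is None and est.ks is None and est.turnover_class is None
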