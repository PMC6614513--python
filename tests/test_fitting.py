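"""Quantile binning, multinomial likelihood, and per-subject fitting."""

import numpy as np
import pandas as pd
import pytest

from driftfit import (
    DDMParams,
    FitError,
    bias_check,
    bin_rts,
    ez_estimate,
    fit_all_models,
    fit_subject,
    hit_probability,
    mean_decision_time,
    multinomial_loglik,
    predictive_check,
)
from driftfit.conditions import CELLS
from driftfit.synth import default_scenario, generate_design, sample_cohort, simulate_subject


def _records_from_rts(rt_correct, rt_error=(), cell=("self", "high", "easy")):
    """Minimal single-cell trial table from explicit RT lists (seconds)."""
    rows = []
    for rt, cor in [(r, True) for r in rt_correct] + [(r, False) for r in rt_error]:
        rows.append(
            dict(subject=1, block=1, trial=len(rows) + 1, beneficiary=cell[0],
                 payoff=cell[1], difficulty=cell[2], direction="left",
                 iti_ms=1000, response="left" if cor else "right",
                 correct=cor, rt_ms=int(round(rt * 1000)), miss=False)
        )
    df = pd.DataFrame(rows)
    df["rt_ms"] = pd.array(df["rt_ms"], dtype="Int64")
    return df


class TestBinning:
    def test_quantile_bin_counts(self):
        # 100 distinct RTs at default quantiles -> (10, 20, 20, 20, 20, 10)
        rts = 0.95 + 0.4 * np.arange(100) / 100
        binned = bin_rts(_records_from_rts(rts))
        cell = binned.cells[("self", "high", "easy")]
        np.testing.assert_array_equal(cell.counts_upper, [10, 20, 20, 20, 20, 10])
        assert (np.diff(cell.edges_upper) > 0).all()

    def test_all_correct_cell_merges_error_side(self):
        binned = bin_rts(_records_from_rts(0.95 + 0.3 * np.random.default_rng(0).random(40)))
        cell = binned.cells[("self", "high", "easy")]
        assert cell.edges_lower.size == 0
        np.testing.assert_array_equal(cell.counts_lower, [0])

    def test_small_side_single_bin(self):
        binned = bin_rts(_records_from_rts(
            0.95 + 0.3 * np.random.default_rng(0).random(60),
            rt_error=[1.0, 1.1, 1.2],
        ))
        cell = binned.cells[("self", "high", "easy")]
        np.testing.assert_array_equal(cell.counts_lower, [3])

    def test_counts_conserved_on_simulated_subject(self, subject_records):
        binned = bin_rts(subject_records)
        for cell, b in binned.cells.items():
            assert b.counts_upper.sum() + b.counts_lower.sum() == b.n_scored
        assert binned.n_scored + binned.n_miss == len(subject_records)

    def test_tiny_cell_warns(self):
        with pytest.warns(UserWarning, match="merged"):
            bin_rts(_records_from_rts([1.0, 1.1, 1.2, 1.3, 1.4]))


class TestLikelihood:
    def test_generating_params_beat_perturbed(self, subject_records, subject_truth):
        binned = bin_rts(subject_records)
        ll_true = multinomial_loglik(subject_truth.params, binned)
        perturbed = {c: p.with_(v=p.v * 2.5) for c, p in subject_truth.params.items()}
        assert ll_true > multinomial_loglik(perturbed, binned)
        shifted = {c: p.with_(ter=p.ter - 0.3) for c, p in subject_truth.params.items()}
        assert ll_true > multinomial_loglik(shifted, binned)

    def test_trial_order_invariance(self, subject_records, subject_truth):
        shuffled = subject_records.sample(frac=1.0, random_state=5)
        ll1 = multinomial_loglik(subject_truth.params, bin_rts(subject_records))
        ll2 = multinomial_loglik(subject_truth.params, bin_rts(shuffled))
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    def test_single_bin_degenerate_value(self):
        # a 10-trial cell collapses to one bin per side: loglik = sum n_side ln P_side
        with pytest.warns(UserWarning):
            binned = bin_rts(_records_from_rts([1.0, 1.05, 1.1, 1.15, 1.2, 1.21],
                                               rt_error=[1.3, 1.31, 1.32, 1.4]))
        p = DDMParams(a=0.08, v=0.15, z=0.04, ter=0.9, s=0.1)
        p_up = hit_probability(p, "upper")
        expected = 6 * np.log(p_up) + 4 * np.log(1 - p_up)
        got = multinomial_loglik({("self", "high", "easy"): p}, binned)
        assert got == pytest.approx(expected, abs=1e-10)


class TestEZStart:
    def test_recovers_rough_magnitudes_from_analytic_moments(self):
        p = DDMParams(a=0.08, v=0.174, z=0.04, ter=0.9, s=0.1)
        pc = hit_probability(p, "upper")
        mrt = p.ter + mean_decision_time(p)
        a0, v0, t0 = ez_estimate(pc, 0.004, mrt, n=104, s=0.1)
        assert 0.3 * p.v < v0 < 3 * p.v
        assert 0.4 * p.a < a0 < 2.5 * p.a
        assert abs(t0 - p.ter) < 0.15


class TestFitSubject:
    def test_z_constraint_exact(self, subject_records):
        fit = fit_subject(subject_records, "v_free", starts=1)
        np.testing.assert_array_equal(fit.params["z"].to_numpy(), fit.params["a"].to_numpy() / 2.0)

    def test_vfree_recovers_generating_cells(self, subject_records, subject_truth):
        fit = fit_subject(subject_records, "v_free", starts=2)
        assert fit.converged
        est = fit.params
        true_a = subject_truth.params[CELLS[0]].a
        true_ter = subject_truth.params[CELLS[0]].ter
        assert est["a"].iloc[0] == pytest.approx(true_a, abs=0.01)
        assert est["ter"].iloc[0] == pytest.approx(true_ter, abs=0.02)
        for cell in CELLS:
            v_t = subject_truth.params[cell].v
            v_e = est.loc[cell, "v"]
            assert abs(np.log10(v_e) - np.log10(v_t)) < 0.35

    def test_bic_fields_consistent(self, subject_records):
        fit = fit_subject(subject_records, "v_free", starts=1)
        assert fit.k == 10
        assert fit.bic == pytest.approx(-2 * fit.loglik + fit.k * np.log(fit.n), abs=1e-9)
        assert fit.n == (~subject_records["miss"]).sum()

    def test_nesting_of_maximised_likelihoods(self, subject_records):
        fits = fit_all_models(subject_records, starts=1)
        ll = {m: f.loglik for m, f in fits.items()}
        tol = 1e-4
        assert ll["v_a_free"] >= ll["v_free"] - tol
        assert ll["v_ter_free"] >= ll["v_free"] - tol
        assert ll["full"] >= ll["v_a_free"] - tol
        assert ll["full"] >= ll["v_ter_free"] - tol
        assert fits["full"].k == 24
        assert fits["v_a_free"].k == fits["v_ter_free"].k == 17

    def test_millisecond_rt_guard(self, subject_records):
        broken = subject_records.copy()
        broken["rt_ms"] = broken["rt_ms"] * 1000  # double unit conversion
        with pytest.raises(FitError, match="milliseconds"):
            fit_subject(broken, "v_free")

    def test_seconds_rt_guard(self, subject_records):
        broken = subject_records.copy()
        broken["rt_ms"] = (broken["rt_ms"] / 1000).round().astype("Int64")  # seconds stored
        with pytest.raises(FitError):
            fit_subject(broken, "v_free")

    def test_multiple_subjects_rejected(self, subject_records):
        two = pd.concat([subject_records, subject_records.assign(subject=2)])
        with pytest.raises(FitError, match="single subject"):
            fit_subject(two, "v_free")


class TestBiasCheck:
    def test_symmetric_data_yields_central_start(self, subject_records):
        res = bias_check(subject_records, starts=1)
        assert abs(res["w_left"] - 0.5) < 0.08
        assert abs(res["w_right"] - 0.5) < 0.08
        for side in ("left", "right"):
            assert 0 < res[f"z_{side}"] < res[f"a_{side}"]

    def test_biased_start_detected(self):
        rng = np.random.default_rng(21)
        sc = default_scenario(z_frac=0.62, between_subject_sd=0.0)
        subj = sample_cohort(sc, 1, rng)[0]
        rec = simulate_subject(generate_design(rng), subj, rng)
        res = bias_check(rec, starts=1)
        assert res["w_right"] - res["w_left"] > 0.08
        assert res["w_right"] > 0.54
        assert res["w_left"] < 0.46


class TestPredictiveCheck:
    def test_accuracy_within_3se_and_deterministic(self, subject_records):
        fit = fit_subject(subject_records, "v_free", starts=1)
        sim1, sum1 = predictive_check(fit, subject_records, np.random.default_rng(3))
        sim2, sum2 = predictive_check(fit, subject_records, np.random.default_rng(3))
        pd.testing.assert_frame_equal(sum1, sum2)
        for _, row in sum1.iterrows():
            se = np.sqrt(row["acc_predicted"] * (1 - row["acc_predicted"]) / row["n"])
            assert abs(row["acc_observed"] - row["acc_predicted"]) < 3.5 * max(se, 0.01)
        # quantile discrepancies small when the model is the generator
        dq = sum1[[c for c in sum1 if c.startswith("d_rt_q")]].to_numpy(dtype=float)
        assert np.nanmedian(np.abs(dq)) < 60  # ms
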