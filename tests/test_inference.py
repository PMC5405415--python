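"""Estimators, trend-line algebra and the five case analyses."""

import numpy as np
import pytest

from kinetrans import (
    EffectiveConstants,
    EffectiveModelKind,
    FundamentalConstants,
    LifetimeSample,
    case1_tf_model_selection,
    case2_trend_lines,
    case3_case4_fret_predictions,
    estimate_rotational_constants,
    fit_adhesion_curve,
    fit_lifetimes,
    fit_sensorgram,
    fit_trend,
    make_ligand_panel,
    reduce_to_effective,
    sample_tf_lifetimes,
    ss_reaction_limited,
    synthesize_af_curve,
    synthesize_sensorgram,
)

TRANSPORT_2D = {
    "dimension": "2D", "d_plus": 1.0e4, "d_minus": 1.0e4,
    "e_plus": 400.0, "e_minus": 1.0e4,
}
# transport-limited 3D regime: e+ k+ >> d- (e- + k+) across the panel
TRANSPORT_3D = {
    "dimension": "3D", "d_plus": 1.0e5, "d_minus": 1.0e-4,
    "e_plus": 100.0, "e_minus": 10.0,
}


class TestFitLifetimes:
    def test_inverse_mean(self):
        sample = LifetimeSample(np.ones(4), k_off_eff=1.0, seed=0)
        assert fit_lifetimes(sample)["k_off"] == 1.0

    def test_mle_consistency(self):
        sample = sample_tf_lifetimes(2.0, 10_000, seed=21)
        fr = fit_lifetimes(sample)
        assert abs(fr["k_off"] - 2.0) <= 3 * fr.stderr["k_off"]

    def test_single_observation_flagged(self):
        fr = fit_lifetimes(LifetimeSample(np.array([0.5]), 2.0, 0))
        assert fr["k_off"] == 2.0
        assert any("unreliable" in f for f in fr.flags)


class TestFitSensorgram:
    EFF = EffectiveConstants(EffectiveModelKind("SS", "3D"), k_on=1e5, k_off=0.01)

    def test_noiseless_round_trip(self):
        sg = synthesize_sensorgram(self.EFF, 1e-6, 60.0, 300.0, 500, 100.0, 0.0, seed=0)
        fr = fit_sensorgram(sg)
        assert fr["k_on"] == pytest.approx(1e5, rel=1e-6)
        assert fr["k_off"] == pytest.approx(0.01, rel=1e-6)
        assert fr.converged

    def test_one_percent_noise_recovery(self):
        hits = 0
        for seed in range(20):
            sg = synthesize_sensorgram(self.EFF, 1e-6, 60.0, 300.0, 500, 100.0, 1.0, seed=seed)
            fr = fit_sensorgram(sg)
            ok = abs(fr["k_on"] / 1e5 - 1) < 0.05 and abs(fr["k_off"] / 0.01 - 1) < 0.05
            hits += ok
        assert hits >= 19

    def test_flat_zero_signal_flagged_degenerate(self):
        sg = synthesize_sensorgram(self.EFF, 0.0, 60.0, 300.0, 100, 100.0, 0.0, seed=0)
        fr = fit_sensorgram(sg)
        assert fr["k_on"] == 0.0 and not fr.converged
        assert any("degenerate" in f for f in fr.flags)


class TestFitAdhesion:
    EFF = EffectiveConstants(EffectiveModelKind("SS", "2D"), k_on=5.6e17, k_off=0.5)
    TS = [0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0]

    def test_large_cycle_limit_recovers_constants(self):
        c = synthesize_af_curve(self.EFF, 300, 300, 3.0, self.TS, 200_000, seed=30)
        fr = fit_adhesion_curve(c)
        assert abs(fr["K_a"] / self.EFF.K_a - 1) <= 0.02
        assert abs(fr["k_off"] / 0.5 - 1) <= 0.02

    def test_recovery_at_operating_cycle_count(self):
        hits = 0
        for seed in range(20):
            c = synthesize_af_curve(self.EFF, 300, 300, 3.0, self.TS, 2000, seed=100 + seed)
            fr = fit_adhesion_curve(c)
            hits += abs(fr["K_a"] / self.EFF.K_a - 1) < 0.1 and abs(fr["k_off"] / 0.5 - 1) < 0.1
        assert hits >= 18

    def test_all_zero_frequencies_non_identifiable(self):
        eff0 = EffectiveConstants(EffectiveModelKind("SS", "2D"), k_on=0.0, k_off=1.0)
        c = synthesize_af_curve(eff0, 50, 50, 3.0, self.TS, 100, seed=0)
        fr = fit_adhesion_curve(c)
        assert not fr.converged
        assert any("non-identifiable" in f for f in fr.flags)


class TestCase1:
    def test_pba_selected_when_binding_much_slower_than_rotation(self):
        panel = make_ligand_panel(6)
        verdict = case1_tf_model_selection(panel.constants(TRANSPORT_2D))
        assert verdict.conditions["pba_kplus_much_less_than_rotational_off"]
        assert not verdict.conditions["pbb_ligand_independent_e_minus_possible"]
        assert "PBA" in verdict.conclusion

    def test_pbb_requires_ligand_dependent_e_minus(self):
        panel = make_ligand_panel(6)
        verdict = case1_tf_model_selection(panel.constants(TRANSPORT_2D))
        # spread of the e- each ligand would need is the rejection evidence
        assert verdict.quantities["pbb_required_e_minus_relative_spread"] > 1.0

    def test_fast_binding_violates_pba_condition(self):
        fast = {**TRANSPORT_2D, "e_minus": 1.0}  # k+ / e- = O(1)
        panel = make_ligand_panel(3, k_plus_max=1.0)
        verdict = case1_tf_model_selection(panel.constants(fast))
        assert not verdict.conditions["pba_kplus_much_less_than_rotational_off"]


class TestCase2TrendLines:
    def test_af_effective_and_fundamental_slopes_identical(self):
        panel = make_ligand_panel(6)
        d = {l.constant: l for l in case2_trend_lines(panel, "AF", TRANSPORT_2D)}
        assert abs(d["k_on_eff"].slope - d["k_plus"].slope) <= 1e-10
        assert abs(d["k_off_eff"].slope - d["k_minus"].slope) <= 1e-10
        assert abs(d["K_a_eff"].slope - d["K_A"].slope) <= 1e-10

    def test_af_off_rate_line_unshifted_others_shift_by_log_KDE(self):
        panel = make_ligand_panel(6)
        d = {l.constant: l for l in case2_trend_lines(panel, "AF", TRANSPORT_2D)}
        K_D = TRANSPORT_2D["d_plus"] / TRANSPORT_2D["d_minus"]
        E = TRANSPORT_2D["e_plus"] / TRANSPORT_2D["e_minus"]
        shift = np.log10(K_D * E)
        assert abs(d["k_off_eff"].offset_from(d["k_minus"])) <= 1e-10
        assert d["k_on_eff"].offset_from(d["k_plus"]) == pytest.approx(shift, abs=1e-10)
        assert d["K_a_eff"].offset_from(d["K_A"]) == pytest.approx(shift, abs=1e-10)

    def test_spr_on_rate_ligand_independent_and_off_rate_mirrors_affinity(self):
        panel = make_ligand_panel(6)
        d = {l.constant: l for l in case2_trend_lines(panel, "SPR", TRANSPORT_3D)}
        assert abs(d["k_on_eff"].slope) <= 1e-6
        assert abs(d["k_off_eff"].slope + d["K_a_eff"].slope) <= 1e-10

    def test_degenerate_panel_rejected(self):
        panel = make_ligand_panel(3, fold_k_plus=1.0, fold_k_minus=1.0)
        with pytest.raises(ValueError, match="degenerate"):
            case2_trend_lines(panel, "AF", TRANSPORT_2D)


class TestCase3Case4:
    def test_equal_k_minus_separates_af_from_fret_off_rates(self):
        # same intrinsic off-rate, different affinities
        ligands = make_ligand_panel(
            4, fold_k_minus=1.0, fold_k_plus=1000.0, k_plus_max=5.0, k_minus_max=0.5
        )
        constants = ligands.constants(TRANSPORT_2D)
        af = [ss_reaction_limited(p) for p in constants]
        fret = [reduce_to_effective(p, EffectiveModelKind("FRET", "2D")) for p in constants]
        af_koff = np.array([e.k_off for e in af])
        fret_koff = np.array([e.k_off for e in fret])
        assert np.ptp(af_koff) == 0.0
        assert np.ptp(fret_koff) / fret_koff.mean() > 1.0

    def test_verdict_conditions_hold_on_default_panel(self):
        panel = make_ligand_panel(6)
        _, verdict = case3_case4_fret_predictions(panel, TRANSPORT_2D)
        assert all(verdict.conditions.values())
        assert verdict.quantities["max_affinity_ratio_relative_error"] <= 1e-10

    def test_affinity_ratio_tends_to_one_for_strong_binders(self):
        strong = make_ligand_panel(3, k_plus_max=1e4, k_minus_max=0.1, fold_k_plus=2.0,
                                   fold_k_minus=1.5)
        constants = strong.constants(TRANSPORT_2D)
        for p in constants:
            fret = reduce_to_effective(p, EffectiveModelKind("FRET", "2D"))
            ss = reduce_to_effective(p, EffectiveModelKind("SS", "2D"))
            assert fret.K_a / ss.K_a == pytest.approx(1.0, rel=1e-4)


class TestRotationalEstimate:
    E2D = 0.04
    SHARED = {
        "dimension": "2D", "d_plus": 1.0e4, "d_minus": 1.0e4,
        "e_plus": 0.04 * 1.0e4, "e_minus": 1.0e4,
    }

    def _panels(self, k_plus_max=0.05):
        # K_A stays below 1 so the affinity subtraction is well conditioned
        panel = make_ligand_panel(6, k_plus_max=k_plus_max, k_minus_max=0.5)
        constants = panel.constants(self.SHARED)
        fret = [reduce_to_effective(p, EffectiveModelKind("FRET", "2D")) for p in constants]
        af = [reduce_to_effective(p, EffectiveModelKind("SS", "2D")) for p in constants]
        return panel, fret, af

    def test_noiseless_recovery_of_E2D(self):
        _, fret, af = self._panels()
        est = estimate_rotational_constants(fret, af, K_D_2d=1.0)
        assert est.valid
        assert est.E_2d == pytest.approx(self.E2D, rel=1e-6)

    def test_large_K_A_panel_flagged_invalid(self):
        _, fret, af = self._panels(k_plus_max=50.0)
        est = estimate_rotational_constants(fret, af, K_D_2d=1.0)
        assert not est.valid
        assert "invalid-K_A-not-small" in est.flags

    def test_single_ligand_estimate_flagged(self):
        _, fret, af = self._panels()
        est = estimate_rotational_constants(fret[:1], af[:1], K_D_2d=1.0)
        assert est.E_2d == pytest.approx(self.E2D, rel=1e-6)
        assert "single-ligand-no-cross-consistency-check" in est.flags

    def test_E3D_recovered_from_matched_bulk_fret(self):
        E3D = 0.2
        panel, fret, af = self._panels()
        shared_3d = {
            "dimension": "3D", "d_plus": 1.0e5, "d_minus": 1.0e3,
            "e_plus": E3D * 5.0e3, "e_minus": 5.0e3,
        }
        fret3d = [
            reduce_to_effective(p, EffectiveModelKind("FRET", "3D"))
            for p in panel.constants(shared_3d)
        ]
        est = estimate_rotational_constants(fret, af, K_D_2d=1.0, fret3d=fret3d)
        assert est.E_3d == pytest.approx(E3D, rel=1e-6)

    def test_mismatched_panels_rejected(self):
        _, fret, af = self._panels()
        with pytest.raises(ValueError, match="same ligands"):
            estimate_rotational_constants(fret[:3], af, K_D_2d=1.0)


def test_trend_requires_two_ligands():
    with pytest.raises(ValueError, match=">= 2"):
        fit_trend(np.array([1.0]), np.array([1.0]), "x", "AF")
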