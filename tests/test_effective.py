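"""Effective models: closed forms, projections, inversion, reduction oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinetrans import (
    EffectiveConstants,
    EffectiveModelKind,
    FundamentalConstants,
    SpeciesState,
    invert_effective,
    project,
    project_state,
    reduce_to_effective,
    simulate_effective,
    simulate,
    ss_on_rate_bounds,
    validate_reduction,
)

KINDS_2D = [EffectiveModelKind(tag, "2D") for tag in ("PBA", "PBB", "FRET", "SS")]

rates = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False, allow_infinity=False)


def params_from(draw6, dimension="2D"):
    return FundamentalConstants(dimension, *draw6)


class TestClosedForms:
    @given(st.lists(rates, min_size=6, max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_pba_off_rate_is_the_fundamental_one(self, vals):
        p = params_from(vals)
        eff = reduce_to_effective(p, EffectiveModelKind("PBA", "2D"))
        assert eff.k_off == p.k_minus  # exact identity, no tolerance

    def test_pba_on_rate_small_E_approximation(self):
        # E^2D = 0.04 and k+ = 1/s: exact factor E/(1+E), within 4% of E k+
        p = FundamentalConstants("2D", 1.0, 1.0, 0.04, 1.0, 1.0, 1.0)
        eff = reduce_to_effective(p, EffectiveModelKind("PBA", "2D"))
        assert eff.k_on == pytest.approx(0.04 / 1.04, rel=1e-12)
        assert abs(eff.k_on - 0.04) / 0.04 < 0.04

    @given(st.lists(rates, min_size=6, max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_fret_vs_ss_affinity_ratio(self, vals):
        p = params_from(vals)
        fret = reduce_to_effective(p, EffectiveModelKind("FRET", "2D"))
        ss = reduce_to_effective(p, EffectiveModelKind("SS", "2D"))
        expected = (p.K_A + 1.0) / p.K_A
        assert fret.K_a / ss.K_a == pytest.approx(expected, rel=1e-10)

    @given(st.lists(rates, min_size=6, max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_ss_on_rate_harmonic_combination_of_bounds(self, vals):
        p = params_from(vals)
        eff = reduce_to_effective(p, EffectiveModelKind("SS", "2D"))
        reaction, transport = ss_on_rate_bounds(p)
        assert 1.0 / eff.k_on == pytest.approx(1.0 / reaction + 1.0 / transport, rel=1e-10)
        assert eff.k_on <= min(reaction, transport) * (1 + 1e-12)

    def test_ss_on_rate_approaches_each_bound_in_its_regime(self):
        base = dict(d_plus=1.0, d_minus=1.0, e_plus=1.0, e_minus=1.0, k_minus=1.0)
        slow_binding = FundamentalConstants("2D", k_plus=1e-6, **base)
        fast_binding = FundamentalConstants("2D", k_plus=1e6, **base)
        r, t = ss_on_rate_bounds(slow_binding)
        assert reduce_to_effective(slow_binding, EffectiveModelKind("SS", "2D")).k_on == pytest.approx(r, rel=1e-5)
        r, t = ss_on_rate_bounds(fast_binding)
        assert reduce_to_effective(fast_binding, EffectiveModelKind("SS", "2D")).k_on == pytest.approx(t, rel=1e-5)

    @pytest.mark.parametrize("tag", ["PBA", "SS"])
    def test_zero_binding_on_rate_gives_zero_effective_on_rate(self, tag):
        p = FundamentalConstants("2D", 1.0, 1.0, 1.0, 1.0, 0.0, 1.0)
        assert reduce_to_effective(p, EffectiveModelKind(tag, "2D")).k_on == 0.0

    def test_bulk_fret_3d_carries_pbb_constants(self):
        p = FundamentalConstants("3D", 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
        bulk = reduce_to_effective(p, EffectiveModelKind("FRET", "3D"))
        pbb = reduce_to_effective(p, EffectiveModelKind("PBB", "3D"))
        assert bulk.k_on == pbb.k_on and bulk.k_off == pbb.k_off

    def test_dimension_mismatch_rejected(self, balanced_params):
        with pytest.raises(ValueError, match="dimension"):
            reduce_to_effective(balanced_params, EffectiveModelKind("SS", "3D"))


class TestProjection:
    STATE = SpeciesState(R=1.0, L=1.0, RL_star=2.0, RL=3.0, C=4.0)

    def test_meta_state_definitions(self):
        fret = project_state(self.STATE, EffectiveModelKind("FRET", "2D"))
        assert fret == {"R_meta": 3.0, "L_meta": 3.0, "C_meta": 7.0}
        pba = project_state(self.STATE, EffectiveModelKind("PBA", "2D"))
        assert pba["RL_grouped"] == 5.0
        ss = project_state(self.STATE, EffectiveModelKind("SS", "2D"))
        assert ss["C"] == 4.0  # bound means chemically bound only
        pbb = project_state(self.STATE, EffectiveModelKind("PBB", "2D"))
        assert pbb["C_grouped"] == 7.0

    @pytest.mark.parametrize("kind", KINDS_2D, ids=lambda k: k.tag)
    def test_projection_preserves_receptor_mass(self, balanced_params, kind):
        traj = simulate(
            balanced_params,
            SpeciesState(1.0, 0.7, 0, 0, 0),
            np.linspace(0.1, 10, 30),
        )
        grouped = project(traj, kind)
        assert np.allclose(grouped.receptor_total(), traj.R_total, rtol=1e-12)


class TestInversion:
    @given(st.lists(rates, min_size=6, max_size=6))
    @settings(deadline=None, max_examples=40)
    def test_round_trip_recovers_determined_constants(self, vals):
        p = params_from(vals)
        known = {k: getattr(p, k) for k in ("d_plus", "d_minus", "e_plus", "e_minus")}
        for kind in KINDS_2D:
            eff = reduce_to_effective(p, kind)
            inv = invert_effective(eff, known)
            rebuilt = dict(known)
            rebuilt["k_plus"] = inv.values.get("k_plus", p.k_plus)
            if inv.is_determined("k_minus"):
                rebuilt["k_minus"] = inv["k_minus"]
            elif inv.is_determined("K_A"):
                rebuilt["k_minus"] = rebuilt["k_plus"] / inv["K_A"]
            else:
                rebuilt["k_minus"] = p.k_minus
            eff2 = reduce_to_effective(FundamentalConstants("2D", **rebuilt), kind)
            assert eff2.k_on == pytest.approx(eff.k_on, rel=1e-10)
            assert eff2.k_off == pytest.approx(eff.k_off, rel=1e-10)

    def test_pba_off_rate_inverts_exactly(self):
        kind = EffectiveModelKind("PBA", "2D")
        eff = EffectiveConstants(kind, k_on=0.02, k_off=0.37)
        inv = invert_effective(eff, {"E": 0.04})
        assert inv["k_minus"] == 0.37

    def test_fret_on_rate_carries_no_ligand_information(self, tf_regime_params):
        eff = reduce_to_effective(tf_regime_params, EffectiveModelKind("FRET", "2D"))
        inv = invert_effective(
            eff, {k: getattr(tf_regime_params, k) for k in ("d_plus", "d_minus", "e_minus")}
        )
        assert "k_plus" in inv.undetermined
        assert "k_minus" in inv.undetermined
        assert inv.is_determined("K_A")

    def test_ss_inversion_refuses_on_rate_at_transport_limit(self):
        kind = EffectiveModelKind("SS", "2D")
        known = dict(d_plus=1.0, d_minus=1.0, e_plus=1.0, e_minus=1.0)
        limit = 1.0 * 1.0 / (1.0 + 1.0)  # d+e+/(d-+e+)
        with pytest.raises(ValueError, match="transport limit"):
            invert_effective(EffectiveConstants(kind, k_on=limit * 1.01, k_off=0.1), known)


class TestEffectiveSimulation:
    def test_ss_zero_on_rate_keeps_bound_fraction_zero(self):
        eff = EffectiveConstants(EffectiveModelKind("SS", "2D"), k_on=0.0, k_off=1.0)
        out = simulate_effective(
            eff, {"R_unbound": 1.0, "L_unbound": 1.0, "C": 0.0}, np.linspace(0.1, 5, 20)
        )
        assert np.all(out["C"] == 0.0)

    def test_two_state_equilibrium_reproduces_effective_affinity(self):
        eff = EffectiveConstants(EffectiveModelKind("SS", "2D"), k_on=2.0, k_off=0.5)
        out = simulate_effective(
            eff, {"R_unbound": 1.0, "L_unbound": 2.0, "C": 0.0}, np.array([1.0, 400.0])
        )
        R, L, C = out["R_unbound"][-1], out["L_unbound"][-1], out["C"][-1]
        assert C / (R * L) == pytest.approx(eff.K_a, rel=1e-6)

    def test_fret_grouped_mass_conserved(self, balanced_params):
        eff = reduce_to_effective(balanced_params, EffectiveModelKind("FRET", "2D"))
        out = simulate_effective(
            eff, {"R_meta": 0.5, "L_meta": 0.4, "C_meta": 0.1}, np.linspace(0.1, 20, 40)
        )
        assert np.allclose(out["R_meta"] + out["C_meta"], 0.6, rtol=1e-8)


class TestReductionOracle:
    @pytest.mark.parametrize("kind", KINDS_2D, ids=lambda k: k.tag)
    def test_deviation_small_at_high_separation_and_decreasing(self, balanced_params, kind):
        devs = [
            validate_reduction(balanced_params, kind, s, R_total=1e-3, L_total=1e-3).max_relative_deviation
            for s in (10.0, 1000.0)
        ]
        assert devs[1] <= 1e-2
        assert devs[1] < devs[0]

    def test_frozen_binding_keeps_ss_system_unbound(self):
        p = FundamentalConstants("2D", 1.0, 1.2, 0.5, 0.9, 0.0, 0.6)
        rep = validate_reduction(p, EffectiveModelKind("SS", "2D"), 100.0, 1e-3, 1e-3)
        assert rep.per_species["C"] == 0.0
        assert rep.max_relative_deviation <= 1e-12  # integrator noise only

    def test_separation_factor_floor_enforced(self, balanced_params):
        with pytest.raises(ValueError, match="separation"):
            validate_reduction(balanced_params, KINDS_2D[0], 5.0)
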