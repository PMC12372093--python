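"""Spindle Ia/II hybrid filters: jump maps, flows, outputs, simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myospring.spindle import (
    HybridStateIa,
    HybridStateII,
    Regime,
    SpindleIaParams,
    SpindleIIParams,
    StimulusProfile,
    classify_regime,
    flow_ia,
    flow_ii,
    jump_ia,
    jump_ii,
    output_ia,
    output_ii,
    sat0,
    simulate_ia,
    simulate_ii,
)
from myospring.synthetic import ProtocolSpec, gen_stimulus

IA = SpindleIaParams()
II = SpindleIIParams()


def test_sat0_clips_only_negative_values():
    assert sat0(-5.0) == 0.0
    assert sat0(0.0) == 0.0
    assert sat0(2.167) == 2.167


class TestRegime:
    @pytest.mark.parametrize(
        "ldot, expected",
        [
            (0.5, Regime.LENGTHENING),
            (-0.5, Regime.SHORTENING),
            (1e-9, Regime.STATIC),
            (-1e-9, Regime.STATIC),
        ],
    )
    def test_classification(self, ldot, expected):
        assert classify_regime(ldot, 1e-6) is expected

    @given(st.floats(-10, 10, allow_nan=False))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_deadband_partition(self, ldot):
        r = classify_regime(ldot, 1e-3)
        if abs(ldot) <= 1e-3:
            assert r is Regime.STATIC
        else:
            assert r is (Regime.LENGTHENING if ldot > 0 else Regime.SHORTENING)

    def test_requires_positive_deadband(self):
        with pytest.raises(ValueError):
            classify_regime(0.0, 0.0)


class TestJumpMaps:
    def test_ia_regime_assignments(self):
        s = HybridStateIa(x=3.0, KL=7.15, p=3.858)
        short = jump_ia(s, Regime.SHORTENING, IA)
        assert (short.x, short.KL, short.p) == (3.0, 0.0, 85.0)
        lengthen = jump_ia(s, Regime.LENGTHENING, IA)
        assert (lengthen.x, lengthen.KL, lengthen.p) == (3.0, 7.15, 85.0)
        static = jump_ia(s, Regime.STATIC, IA)
        assert (static.x, static.KL, static.p) == (3.0, 0.0, 3.858)

    def test_ii_regime_assignments(self):
        s = HybridStateII(x=5.0, xi=1, p=85.0)
        assert jump_ii(s, Regime.SHORTENING, II) == HybridStateII(5.0, 0, 85.0)
        assert jump_ii(s, Regime.LENGTHENING, II) == HybridStateII(5.0, 1, 85.0)
        assert jump_ii(s, Regime.STATIC, II) == HybridStateII(5.0, 0, 2.858)

    @given(
        st.floats(0, 50, allow_nan=False),
        st.sampled_from(list(Regime)),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_state_continuous_and_jump_idempotent(self, x, regime):
        for state, jump in (
            (HybridStateIa(x=x, KL=0.0, p=85.0), jump_ia),
            (HybridStateII(x=x, xi=0, p=85.0), jump_ii),
        ):
            once = jump(state, regime)
            assert once.x == state.x  # x is continuous across every jump
            assert jump(once, regime) == once  # re-applying the regime is identity


class TestFlowsAndOutputs:
    def test_ia_flow_equilibrium(self):
        s = HybridStateIa(x=7.15 * 2.0, KL=7.15, p=85.0)
        assert flow_ia(s, 2.0) == 0.0

    def test_ia_static_decay_rate(self):
        s = HybridStateIa(x=1.0, KL=0.0, p=3.858)
        assert flow_ia(s, 5.0) == pytest.approx(-3.858)

    def test_ia_lengthening_drive(self):
        s = HybridStateIa(x=0.0, KL=7.15, p=85.0)
        assert flow_ia(s, 2.0) == pytest.approx(85.0 * 14.3)

    def test_ia_output_examples(self):
        assert output_ia(HybridStateIa(14.3, 7.15, 85.0), 0.5, 0.0, IA) == pytest.approx(16.875)
        # strong shortening saturates the primary afferent at zero
        assert output_ia(HybridStateIa(1.0, 0.0, 85.0), -2.0, 0.0, IA) == 0.0
        assert output_ia(HybridStateIa(0.0, 0.0, 3.858), 0.0, 1.0, IA) == pytest.approx(0.3514)

    def test_ii_flow_frozen_when_switch_off(self):
        s = HybridStateII(x=123.0, xi=0, p=85.0)
        assert flow_ii(s, 2.0, II) == 0.0

    def test_ii_flow_drive(self):
        s = HybridStateII(x=0.0, xi=1, p=85.0)
        assert flow_ii(s, 2.0, II) == pytest.approx(85.0 * 4.334 * 2.0)

    def test_ii_output_static_pathway(self):
        assert output_ii(HybridStateII(0.0, 0, 2.858), 3.0, 0.0, 0.0, II) == pytest.approx(2.167)
        # below the length offset the static pathway saturates at zero
        assert output_ii(HybridStateII(0.0, 0, 2.858), 2.0, 0.0, 0.0, II) == 0.0

    def test_ii_output_dynamic_pathway_gates_length_off(self):
        y = output_ii(HybridStateII(8.668, 1, 85.0), 2.0, 0.5, 0.0, II)
        assert y == pytest.approx(8.668 + 0.9184 * 0.5)

    def test_outputs_reject_negative_gamma(self):
        with pytest.raises(ValueError):
            output_ia(HybridStateIa(0.0, 0.0, 85.0), 0.0, -1.0, IA)


class TestStimulusProfile:
    def test_requires_increasing_time(self):
        with pytest.raises(ValueError):
            StimulusProfile(t=np.array([0.0, 0.0, 1.0]), L=np.zeros(3))

    def test_ldot_computed_when_missing(self):
        t = np.linspace(0, 1, 101)
        prof = StimulusProfile(t=t, L=2.0 + 0.5 * t)
        assert np.allclose(prof.Ldot, 0.5)

    def test_inconsistent_ldot_rejected(self):
        t = np.linspace(0, 1, 101)
        with pytest.raises(ValueError, match="inconsistent"):
            StimulusProfile(t=t, L=2.0 + 0.5 * t, Ldot=np.full_like(t, -0.5))


class TestSimulateIa:
    def test_static_decay_matches_closed_form(self):
        t = np.linspace(0.0, 2.0, 2001)
        prof = StimulusProfile(t=t, L=np.full_like(t, 3.0), Ldot=np.zeros_like(t))
        tr = simulate_ia(IA, prof, x0=10.0)
        assert np.allclose(tr.x, 10.0 * np.exp(-IA.p_slow * tr.t), atol=1e-6)
        assert np.allclose(tr.y, tr.x)

    def test_ramp_tracks_quasi_static_equilibrium(self):
        t = np.linspace(0.0, 4.0, 4001)
        prof = StimulusProfile(t=t, L=2.0 + 0.5 * t, Ldot=np.full_like(t, 0.5))
        tr = simulate_ia(IA, prof)
        # late in the ramp, y ~ KL*L(t) + KLdot*0.5 minus the constant tracking lag
        lag = IA.KL_on * 0.5 / IA.p_fast
        expect = IA.KL_on * (2.0 + 0.5 * tr.t[-1]) + IA.KLdot * 0.5 - lag
        assert tr.y[-1] == pytest.approx(expect, abs=1e-6)

    def test_ramp_hold_release_phases(self):
        prof = gen_stimulus(ProtocolSpec(ramp_rate=0.5, release_rate=1.0))
        tr = simulate_ia(IA, prof)
        assert np.all(tr.y >= 0.0)
        mode = np.array(tr.mode)
        ramp_peak = tr.y[mode == "lengthening"].max()
        hold = tr.y[(mode == "static") & (tr.t > 2.0) & (tr.t < 3.0)]
        # dynamic overshoot during the ramp, slow decay during the hold
        assert ramp_peak > hold.max()
        assert np.all(np.diff(hold) <= 1e-12)

    def test_hold_decay_recovers_slow_eigenvalue(self):
        prof = gen_stimulus(ProtocolSpec())
        tr = simulate_ia(IA, prof)
        mode = np.array(tr.mode)
        sel = (mode == "static") & (tr.t > 1.6) & (tr.t < 3.4) & (tr.y > 1e-8)
        slope = np.polyfit(tr.t[sel], np.log(tr.y[sel]), 1)[0]
        assert -slope == pytest.approx(IA.p_slow, rel=0.01)

    def test_release_saturates_output_at_zero(self):
        prof = gen_stimulus(ProtocolSpec(release_rate=2.0))
        tr = simulate_ia(IA, prof)
        mode = np.array(tr.mode)
        release = tr.y[mode == "shortening"]
        assert release.size > 0
        assert np.any(release == 0.0)

    def test_one_jump_per_regime_change(self):
        prof = gen_stimulus(ProtocolSpec())
        tr = simulate_ia(IA, prof)
        mode = np.array(tr.mode)
        changes = int(np.sum(mode[1:] != mode[:-1]))
        assert len(tr.jumps) == changes + 1  # + the initializing jump


class TestSimulateII:
    def test_constant_length_static_output(self):
        t = np.linspace(0.0, 1.0, 101)
        prof = StimulusProfile(t=t, L=np.full_like(t, 3.0), Ldot=np.zeros_like(t))
        tr = simulate_ii(II, prof)
        assert np.allclose(tr.y, II.KL * (3.0 - II.Lbar))
        assert np.allclose(tr.x, 0.0)

    def test_static_hold_output_constant_with_gamma(self):
        t = np.linspace(0.0, 1.0, 101)
        prof = StimulusProfile(
            t=t, L=np.full_like(t, 2.8), Ldot=np.zeros_like(t), gamma=20.0
        )
        tr = simulate_ii(II, prof)
        assert np.allclose(tr.y, sat0(II.KL * (2.8 - II.Lbar) + II.Kgamma * 20.0))

    def test_state_continuous_across_pathway_switches(self):
        prof = gen_stimulus(ProtocolSpec())
        tr = simulate_ii(II, prof)
        # x is frozen in static/shortening regimes and flows during the ramp;
        # its largest per-step change is bounded by the flow increment
        dt = np.diff(tr.t).max()
        bound = II.p_fast * II.KL * np.max(prof.L) * dt * 1.1
        assert np.max(np.abs(np.diff(tr.x))) <= bound
        assert np.all(tr.y >= 0.0)

    def test_flow_equilibrium_oracle_piecewise_constant(self):
        # lengthening segment with constant L: closed-form relaxation to KL*L
        t = np.linspace(0.0, 0.5, 501)
        eps = 1e-6
        prof = StimulusProfile(
            t=t, L=np.full_like(t, 3.0), Ldot=np.full_like(t, 2 * eps),
            consistency_rtol=None,
        )
        tr = simulate_ii(II, prof, x0=0.0)
        expect = II.KL * 3.0 * (1.0 - np.exp(-II.p_fast * tr.t))
        assert np.allclose(tr.x, expect, atol=1e-6)
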