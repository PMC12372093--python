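"""Antagonist eye plant: torque map, equilibria, redundancy, reconstruction."""

import warnings

import numpy as np
import pytest

from myospring.evaluation import ModelDomainWarning
from myospring.oculomotor import (
    ActivationPair,
    EyePlantParams,
    EyeState,
    SpindleCoupling,
    default_muscle_model,
    dynamics,
    equilibrium_angle,
    find_isotorque_pairs,
    joint_stiffness,
    muscle_lengths,
    reconstruct_angle,
    simulate,
    torque,
)
from myospring.spindle import SpindleIIParams
from myospring.synthetic import gen_activation_schedule


@pytest.fixture(scope="module")
def plant() -> EyePlantParams:
    return EyePlantParams()  # regenerated muscle model, Table-style constants


class TestGeometry:
    def test_neutral_lengths(self, plant):
        assert muscle_lengths(0.0, plant) == (0.5, 0.5)

    def test_linear_map(self, plant):
        L1, L2 = muscle_lengths(0.05, plant)
        assert (L1, L2) == (pytest.approx(0.45), pytest.approx(0.55))

    def test_antagonist_length_conservation(self, plant):
        for th in np.linspace(-0.1, 0.1, 11):
            L1, L2 = muscle_lengths(th, plant)
            assert L1 + L2 == pytest.approx(plant.L10 + plant.L20, rel=1e-14)

    def test_nonpositive_length_rejected(self, plant):
        with pytest.raises(ValueError):
            muscle_lengths(0.6, plant)

    def test_activation_pair_validation(self):
        with pytest.raises(ValueError):
            ActivationPair(1.2, 0.0)
        assert ActivationPair(0.7, 0.2).pps == (84.0, 24.0)


class TestTorque:
    def test_symmetric_activation_zero_torque(self, plant):
        for a in (0.0, 0.3, 0.6, 0.9):
            assert torque(a, a, 0.0, plant) == 0.0

    def test_agonist_dominance_sign(self, plant):
        assert torque(0.7, 0.2, 0.0, plant) > 0.0
        assert torque(0.2, 0.7, 0.0, plant) < 0.0

    def test_slack_muscles_no_torque(self, plant):
        assert torque(0.0, 0.0, 0.0, plant) == 0.0

    def test_equilibrium_is_zero_vector_field(self, plant):
        th = equilibrium_angle(0.7, 0.2, plant)
        dth, dom = dynamics(EyeState(theta=th, omega=0.0), 0.7, 0.2, plant)
        assert dth == 0.0
        assert abs(dom) < 1e-8


class TestEquilibrium:
    def test_symmetric_pairs_rest_at_zero(self, plant):
        assert equilibrium_angle(0.55, 0.55, plant) == 0.0

    def test_stronger_agonist_rotates_positive(self, plant):
        th = equilibrium_angle(0.7, 0.2, plant)
        assert 0.0 < th < 0.1

    def test_matches_long_time_simulation(self, plant):
        th_bisect = equilibrium_angle(0.7, 0.2, plant)
        sched = gen_activation_schedule("step", [(0.7, 0.2)], [0.0])
        traj = simulate(plant, sched, (0.0, 200.0), n_samples=200, with_spindles=False)
        assert traj.theta[-1] == pytest.approx(th_bisect, abs=1e-4)

    def test_damped_velocity_vanishes(self, plant):
        sched = gen_activation_schedule("step", [(0.7, 0.2)], [0.0])
        traj = simulate(plant, sched, (0.0, 200.0), n_samples=200, with_spindles=False)
        assert abs(traj.omega[-1]) < 1e-6


class TestSimulation:
    def test_saccade_profile_monotone_then_settled(self, plant):
        sched = gen_activation_schedule("step", [(0.7, 0.2)], [0.5], baseline=(0.4, 0.4))
        traj = simulate(plant, sched, (0.0, 30.0), n_samples=600, with_spindles=False)
        pre = traj.theta[traj.t < 0.5]
        assert np.allclose(pre, 0.0, atol=1e-10)
        post = traj.theta[traj.t >= 0.5]
        assert np.all(np.diff(post) >= -1e-9)  # overdamped rise, no oscillation

    def test_length_conservation_along_trajectory(self, plant):
        sched = gen_activation_schedule("step", [(0.7, 0.2)], [0.0])
        traj = simulate(plant, sched, (0.0, 5.0), n_samples=100, with_spindles=False)
        assert np.allclose(traj.L1 + traj.L2, plant.L10 + plant.L20, rtol=1e-14)

    def test_validity_box_warning(self, plant):
        # starting beyond the admissible angle leaves the spring validity box
        sched = gen_activation_schedule("step", [(0.0, 0.0)], [0.0])
        with pytest.warns(ModelDomainWarning, match="validity box"):
            simulate(plant, sched, (0.0, 1.0), n_samples=50,
                     state0=EyeState(theta=0.12), with_spindles=False)

    def test_spindle_channels_logged(self, plant):
        sched = gen_activation_schedule("step", [(0.7, 0.2)], [0.0])
        traj = simulate(plant, sched, (0.0, 2.0), n_samples=200)
        for ch in (traj.y_ia_1, traj.y_ii_1, traj.y_ia_2, traj.y_ii_2):
            assert ch is not None
            assert np.all(ch >= 0.0)
        # stretched antagonist drives its spindle II harder than the agonist's
        assert traj.y_ii_2[-1] > traj.y_ii_1[-1]


class TestStiffnessRedundancy:
    def test_cocontraction_raises_stiffness(self, plant):
        assert joint_stiffness(0.8, 0.8, 0.0, plant) > joint_stiffness(0.2, 0.2, 0.0, plant)

    def test_slack_plant_has_no_stiffness(self, plant):
        assert joint_stiffness(0.0, 0.0, 0.0, plant) == pytest.approx(0.0, abs=1e-9)

    def test_mirror_symmetry(self, plant):
        k1 = joint_stiffness(0.8, 0.5, 0.03, plant)
        k2 = joint_stiffness(0.5, 0.8, -0.03, plant)
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_isotorque_pairs_distinct_and_verified(self, plant):
        pairs = find_isotorque_pairs(0.02, 0.0, plant, 5)
        assert len(pairs) == 5
        for p in pairs:
            assert torque(p.a1, p.a2, 0.0, plant) == pytest.approx(0.02, abs=1e-8)
        a2s = [p.a2 for p in pairs]
        assert len(set(np.round(a2s, 6))) == 5

    def test_redundancy_spreads_joint_stiffness(self, plant):
        pairs = find_isotorque_pairs(0.02, 0.0, plant, 5)
        ks = [joint_stiffness(p.a1, p.a2, 0.0, plant) for p in pairs]
        assert (max(ks) - min(ks)) / max(ks) > 0.10

    def test_unattainable_torque_raises(self, plant):
        with pytest.raises(ValueError):
            find_isotorque_pairs(50.0, 0.0, plant, 3)


class TestAngleReconstruction:
    @staticmethod
    def _static_outputs(theta, plant):
        sp = SpindleIIParams()
        L1, L2 = muscle_lengths(theta, plant)
        y = lambda L: max(0.0, sp.KL * (plant.coupling.to_spindle(L) - sp.Lbar))
        return y(L1), y(L2)

    def test_zero_angle(self, plant):
        y1, y2 = self._static_outputs(0.0, plant)
        th, ok, res = reconstruct_angle(0.0, y1, 0.0, y2, plant, true_theta=0.0)
        assert ok and th == pytest.approx(0.0, abs=1e-12)

    def test_exact_inversion(self, plant):
        y1, y2 = self._static_outputs(0.05, plant)
        th, ok, res = reconstruct_angle(0.0, y1, 0.0, y2, plant, true_theta=0.05)
        assert ok
        assert th == pytest.approx(0.05, abs=1e-9)
        assert abs(res) < 1e-9

    def test_saturated_outputs_unobservable(self, plant):
        th, ok, res = reconstruct_angle(0.0, 0.0, 0.0, 1.0, plant)
        assert not ok and np.isnan(th)

    def test_unequal_neutral_lengths_rejected(self):
        plant = EyePlantParams(L10=0.5, L20=0.6)
        with pytest.raises(ValueError):
            reconstruct_angle(0.0, 1.0, 0.0, 1.0, plant)


def test_default_muscle_model_is_cached():
    assert default_muscle_model() is default_muscle_model()


def test_spindle_coupling_round_trip():
    c = SpindleCoupling(scale=4.0, offset=1.0)
    assert c.to_muscle(c.to_spindle(0.5)) == pytest.approx(0.5, rel=1e-14)
    with pytest.raises(ValueError):
        SpindleCoupling(scale=0.0)
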