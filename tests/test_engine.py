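"""Toy MD engine: energies, forces, coordinates, pulling and work accounting."""

import dataclasses
import math

import numpy as np
import pytest

from smdfe.engine import (
    ACCEL_CONV,
    COULOMB_KCAL,
    IntegrationError,
    PullingProtocol,
    ReactionCoordinate,
    ToySystem,
    forces,
    potential_energy,
    rc_value_and_gradient,
    run_pull,
    run_pull_ensemble,
    system_from_dict,
)


def lj_pair(r, A=1.0, B=1.0):
    return ToySystem(
        masses=[12.0, 12.0],
        charges=[0.0, 0.0],
        positions=[[0.0, 0.0, 0.0], [r, 0.0, 0.0]],
        lj_pairs={(0, 1): (A, B)},
    )


def random_cluster(seed=0):
    """Four atoms with LJ, charges, a bond and an angle: exercises every term."""
    rng = np.random.default_rng(seed)
    return ToySystem(
        masses=[12.0, 16.0, 1.0, 14.0],
        charges=[0.4, -0.4, 0.1, -0.1],
        positions=rng.uniform(-1.5, 1.5, (4, 3)) + np.arange(4)[:, None] * 2.0,
        lj_pairs={(0, 1): (5e3, 50.0), (0, 3): (1e3, 20.0), (2, 3): (200.0, 5.0)},
        bonds=[(0, 2, 300.0, 1.1)],
        angles=[(1, 0, 2, 40.0, math.radians(109.5))],
    )


class TestPotentialEnergy:
    def test_lj_minimum_closed_form(self):
        # minimum of A/r¹² − B/r⁶ sits at r = (2A/B)^(1/6) with depth −B²/(4A)
        assert potential_energy(lj_pair(2 ** (1 / 6))) == pytest.approx(-0.25, abs=1e-12)

    def test_lj_minimum_location_by_scan(self):
        rs = np.linspace(0.9, 2.0, 4001)
        energies = [potential_energy(lj_pair(r)) for r in rs]
        assert rs[int(np.argmin(energies))] == pytest.approx(2 ** (1 / 6), abs=1e-3)

    def test_coulomb_value(self):
        sys_ = ToySystem(
            masses=[1.0, 1.0],
            charges=[1.0, -1.0],
            positions=[[0, 0, 0], [COULOMB_KCAL / 100.0, 0, 0]],
        )
        assert potential_energy(sys_) == pytest.approx(-100.0, abs=1e-9)

    def test_single_atom_zero(self):
        sys_ = ToySystem(masses=[12.0], charges=[0.0], positions=[[1, 2, 3]])
        assert potential_energy(sys_) == 0.0

    def test_coincident_nonbonded_pair_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            potential_energy(lj_pair(0.0))

    def test_bonded_pairs_excluded_from_nonbonded(self):
        bonded = ToySystem(
            masses=[12.0, 12.0],
            charges=[1.0, 1.0],
            positions=[[0, 0, 0], [1.0, 0, 0]],
            lj_pairs={(0, 1): (10.0, 10.0)},
            bonds=[(0, 1, 100.0, 1.0)],
        )
        # at the bond rest length only the (excluded) LJ/Coulomb terms differ
        assert potential_energy(bonded) == pytest.approx(0.0, abs=1e-12)


class TestForces:
    def test_zero_net_force_at_lj_minimum(self):
        F = forces(lj_pair(2 ** (1 / 6)))
        assert np.abs(F).max() < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_forces_match_finite_differences(self, seed):
        system = random_cluster(seed)
        x0 = system.positions.copy()
        F = forces(system)
        h = 1e-6
        num = np.zeros_like(F)
        for i in range(x0.shape[0]):
            for k in range(3):
                xp, xm = x0.copy(), x0.copy()
                xp[i, k] += h
                xm[i, k] -= h
                num[i, k] = -(potential_energy(system, xp) - potential_energy(system, xm)) / (2 * h)
        scale = max(np.abs(F).max(), 1.0)
        assert np.abs(F - num).max() / scale < 1e-5

    def test_newtons_third_law_and_translation_invariance(self):
        F = forces(random_cluster(3))
        assert np.abs(F.sum(axis=0)).max() < 1e-9
        pair = forces(lj_pair(1.5))
        assert pair[0] == pytest.approx(-pair[1])


class TestReactionCoordinate:
    def test_distance_three_four_five(self):
        rc = ReactionCoordinate("distance", (0, 1))
        x = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        value, grad = rc_value_and_gradient(rc, x)
        assert value == pytest.approx(5.0)
        # per-atom gradients are unit vectors
        assert np.linalg.norm(grad[0]) == pytest.approx(1.0)
        assert np.linalg.norm(grad[1]) == pytest.approx(1.0)

    def test_difference_vanishes_by_symmetry(self):
        rc = ReactionCoordinate("distance_difference", (0, 1, 2))
        x = np.array([[0.0, 1.0, 0], [-2.0, 0, 0], [2.0, 0, 0]])
        assert rc.value(x) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("kind, atoms", [("distance", (0, 1)), ("distance_difference", (0, 1, 2))])
    def test_gradient_matches_finite_differences(self, kind, atoms):
        rng = np.random.default_rng(7)
        rc = ReactionCoordinate(kind, atoms)
        for _ in range(5):
            x = rng.uniform(-3, 3, (3, 3))
            _, grad = rc_value_and_gradient(rc, x)
            h = 1e-7
            for i in range(3):
                for k in range(3):
                    xp, xm = x.copy(), x.copy()
                    xp[i, k] += h
                    xm[i, k] -= h
                    num = (rc.value(xp) - rc.value(xm)) / (2 * h)
                    assert grad[i, k] == pytest.approx(num, abs=1e-6)

    def test_coincident_atoms_rejected(self):
        rc = ReactionCoordinate("distance", (0, 1))
        with pytest.raises(ValueError, match="coincident"):
            rc.value(np.zeros((2, 3)))

    def test_bad_kind_and_indices_rejected(self):
        with pytest.raises(ValueError):
            ReactionCoordinate("angle", (0, 1, 2))
        with pytest.raises(ValueError):
            ReactionCoordinate("distance", (1, 1))


def well_system():
    """Mobile particle bound to a fixed anchor by a harmonic bond."""
    return ToySystem(
        masses=[16.0, 12.0],
        charges=[0.0, 0.0],
        positions=[[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]],
        bonds=[(0, 1, 5.0, 2.0)],
        fixed=[True, False],
    )


def well_protocol(**kw):
    base = dict(
        rc=ReactionCoordinate("distance", (1, 0)),
        lambda_start=2.0,
        lambda_end=3.0,
        n_steps=200,
        k_spring=10.0,
        dt=0.5,
        gamma=1.0,
        T=298.15,
        seed=4,
    )
    base.update(kw)
    return PullingProtocol(**base)


class TestRunPull:
    def test_zero_spring_zero_work(self):
        traj = run_pull(well_system(), well_protocol(k_spring=0.0))
        assert traj.final_work == 0.0
        assert len(traj.work) == 201

    def test_constant_schedule_zero_work(self):
        traj = run_pull(well_system(), well_protocol(lambda_end=2.0))
        assert traj.final_work == pytest.approx(0.0, abs=1e-12)

    def test_records_are_complete(self):
        traj = run_pull(well_system(), well_protocol(n_steps=50))
        for arr in (traj.time, traj.lam, traj.xi, traj.restraint_energy, traj.work):
            assert len(arr) == 51
        assert traj.work[0] == 0.0
        assert traj.lam[0] == 2.0 and traj.lam[-1] == 3.0

    def test_deterministic_given_seed(self):
        a = run_pull(well_system(), well_protocol())
        b = run_pull(well_system(), well_protocol())
        assert np.array_equal(a.xi, b.xi) and a.final_work == b.final_work

    def test_matches_velocity_verlet_oracle(self):
        """γ=0, T=0: BAOAB reduces to plain Newtonian velocity Verlet."""
        protocol = well_protocol(gamma=0.0, T=0.0, n_steps=400)
        traj = run_pull(well_system(), protocol)

        # independent 1-D velocity-Verlet integration of the same forces
        k_bond, r0, k_s, m = 5.0, 2.0, 10.0, 12.0
        lam = np.linspace(2.0, 3.0, 401)
        x, v = 2.0, 0.0
        xi_oracle = [x]
        acc = lambda x_, l_: (-2 * k_bond * (x_ - r0) - k_s * (x_ - l_)) * ACCEL_CONV / m
        a = acc(x, lam[0])
        dt = 0.5
        for n in range(400):
            x = x + dt * v + 0.5 * dt * dt * a
            a_new = acc(x, lam[n + 1])
            v = v + 0.5 * dt * (a + a_new)
            a = a_new
            xi_oracle.append(x)
        assert np.abs(traj.xi - np.array(xi_oracle)).max() < 1e-6

    def test_blowup_raises_with_step_index(self):
        # absurd timestep on a stiff bond diverges immediately
        protocol = well_protocol(dt=500.0, gamma=0.0, T=0.0, k_spring=400.0, n_steps=2000)
        with pytest.raises(IntegrationError, match="step"):
            run_pull(well_system(), protocol)


class TestWorkAccounting:
    def test_static_spring_stretch_closed_form(self):
        """Frozen coordinate: W = Σ −k(ξ0 − λ_mid)Δλ = ½kL² for ξ0 = λ_start."""
        frozen = ToySystem(
            masses=[16.0, 16.0],
            charges=[0.0, 0.0],
            positions=[[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]],
            fixed=[True, True],
        )
        L, k = 1.5, 8.0
        protocol = well_protocol(
            lambda_start=2.0, lambda_end=2.0 + L, k_spring=k, n_steps=300, T=0.0
        )
        traj = run_pull(frozen, protocol)
        assert traj.final_work == pytest.approx(0.5 * k * L**2, abs=k * L * (L / 300))

    def test_reversed_schedule_static_work(self):
        frozen = ToySystem(
            masses=[16.0, 16.0],
            charges=[0.0, 0.0],
            positions=[[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]],
            fixed=[True, True],
        )
        # static work is a state function ½k[(ξ0−λ)²]: schedules symmetric
        # about the frozen coordinate give equal work, and a reversed
        # schedule gives the exact negative
        sym_f = run_pull(frozen, well_protocol(lambda_start=2.5, lambda_end=3.5, k_spring=6.0))
        sym_r = run_pull(frozen, well_protocol(lambda_start=3.5, lambda_end=2.5, k_spring=6.0))
        assert sym_f.final_work == pytest.approx(sym_r.final_work, abs=1e-10)
        fwd = run_pull(frozen, well_protocol(lambda_start=3.0, lambda_end=4.0, k_spring=6.0))
        rev = run_pull(frozen, well_protocol(lambda_start=4.0, lambda_end=3.0, k_spring=6.0))
        assert fwd.final_work == pytest.approx(-rev.final_work, abs=1e-10)
        assert fwd.final_work == pytest.approx(0.5 * 6.0 * 1.0**2, rel=1e-2)


class TestEnsemble:
    def test_single_replica_matches_run_pull_with_derived_seed(self):
        system, protocol = well_system(), well_protocol()
        sample = run_pull_ensemble(system, protocol, n_replicas=1, seed=99)
        derived = int(np.random.SeedSequence(99).generate_state(1)[0])
        direct = run_pull(system, dataclasses.replace(protocol, seed=derived))
        assert sample.works[0] == direct.final_work

    def test_master_seed_determinism(self):
        a = run_pull_ensemble(well_system(), well_protocol(), 5, seed=7)
        b = run_pull_ensemble(well_system(), well_protocol(), 5, seed=7)
        assert np.array_equal(a.works, b.works)

    def test_replicas_differ(self):
        sample = run_pull_ensemble(well_system(), well_protocol(), 5, seed=7)
        assert len(set(sample.works)) == 5


class TestConservation:
    def test_energy_drift_microcanonical(self):
        """γ=0, T=0, no restraint: total energy drift ≤ 1e-4 relative, 1e4 steps."""
        # gentle LJ oscillation (r_min ≈ 2.01 Å, period ≈ 370 fs) so the
        # symplectic energy-error band sits well below the tolerance
        system = ToySystem(
            masses=[12.0, 12.0],
            charges=[0.0, 0.0],
            positions=[[0.0, 0.0, 0.0], [2.1, 0.0, 0.0]],
            lj_pairs={(0, 1): (1e3, 30.0)},
        )
        protocol = PullingProtocol(
            rc=ReactionCoordinate("distance", (0, 1)),
            lambda_start=1.0,
            lambda_end=1.0,
            n_steps=10_000,
            k_spring=0.0,
            dt=0.5,
            gamma=0.0,
            T=0.0,
            seed=0,
        )
        traj = run_pull(system, protocol, record_energy=True)
        total = traj.total_energy
        assert np.abs(total - total[0]).max() / abs(total[0]) <= 1e-4


class TestSystemFromDict:
    def test_round_trip_construction(self):
        cfg = {
            "atoms": [
                {"element": "O", "mass": 16.0, "charge": -0.3, "fixed": True},
                {"element": "H", "mass": 1.0, "charge": 0.3},
            ],
            "positions": [[0, 0, 0], [1.0, 0, 0]],
            "lj_pairs": [{"i": 0, "j": 1, "A": 100.0, "B": 10.0}],
        }
        system = system_from_dict(cfg)
        assert system.n_atoms == 2
        assert system.fixed.tolist() == [True, False]
        assert system.lj_pairs[(0, 1)] == (100.0, 10.0)

    def test_invalid_masses_rejected(self):
        with pytest.raises(ValueError):
            ToySystem(masses=[0.0], charges=[0.0], positions=[[0, 0, 0]])

    def test_negative_lj_rejected(self):
        with pytest.raises(ValueError):
            ToySystem(
                masses=[1.0, 1.0],
                charges=[0.0, 0.0],
                positions=[[0, 0, 0], [1, 0, 0]],
                lj_pairs={(0, 1): (-1.0, 1.0)},
            )
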