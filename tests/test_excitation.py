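import numpy as np
import pytest

from modexcite.dynamics import DynamicsState, initialize_velocities, kinetic_energy
from modexcite.excitation import (
    ExcitationConfig,
    ExcitationDirection,
    ReplicaState,
    SaturationError,
    diversity_filter,
    displace_along,
    inject_kinetic_energy,
    maybe_update_direction,
    run_campaign,
    run_excitation_cycle,
    run_replica,
    sample_direction,
)
from modexcite.structure import rmsd


@pytest.fixture
def fast_config():
    return ExcitationConfig(n_excitations=3, t_exc=0.02)


def make_state(structure, temp=300.0, seed=0):
    return DynamicsState(
        structure.coords.copy(),
        initialize_velocities(structure.masses, temp, seed),
        temperature_target=temp,
        friction=1.0,
    )


class TestSampleDirection:
    def test_single_mode_subspace(self, modeset):
        rng = np.random.default_rng(0)
        idx = [modeset.n_zero]
        d = sample_direction(modeset, idx, rng)
        mode = modeset.eigenvectors[:, idx[0]]
        overlap = abs(np.dot(d.vector, mode))
        assert overlap == pytest.approx(1.0, abs=1e-12)

    def test_weight_covariance_isotropic(self, modeset, selected_modes):
        rng = np.random.default_rng(1)
        w = np.array(
            [
                sample_direction(modeset, selected_modes, rng).mode_weights
                for _ in range(10_000)
            ]
        )
        cov = w.T @ w / w.shape[0]
        assert np.allclose(cov, np.eye(4) / 4.0, atol=0.05 / 4)

    def test_unit_norm_every_draw(self, modeset, selected_modes):
        rng = np.random.default_rng(2)
        for _ in range(100):
            d = sample_direction(modeset, selected_modes, rng)
            assert abs(np.linalg.norm(d.vector) - 1.0) <= 1e-10

    def test_zero_mode_rejected(self, modeset):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="zero"):
            sample_direction(modeset, [0], rng)

    def test_empty_rejected(self, modeset):
        with pytest.raises(ValueError):
            sample_direction(modeset, [], np.random.default_rng(0))


class TestDisplaceAlong:
    def test_null_displacement(self, structure, modeset, selected_modes):
        d = sample_direction(modeset, selected_modes, np.random.default_rng(4))
        out = displace_along(structure, d, 0.0)
        assert np.array_equal(out.coords, structure.coords)

    def test_exact_target_rmsd(self, structure, modeset, selected_modes):
        rng = np.random.default_rng(5)
        for _ in range(5):
            d = sample_direction(modeset, selected_modes, rng)
            out = displace_along(structure, d, 1.0)
            assert rmsd(out.coords, structure.coords) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_translation_shifts_every_atom(self, structure):
        n = structure.n_atoms
        # mass-weighted uniform +x translation on equal masses
        vec = np.zeros((n, 3))
        vec[:, 0] = 1.0
        d = ExcitationDirection(vec.ravel())
        out = displace_along(structure, d, 1.0)
        shift = out.coords - structure.coords
        assert np.allclose(shift[:, 0], 1.0, atol=1e-9)
        assert np.allclose(shift[:, 1:], 0.0, atol=1e-12)

    def test_negative_target_rejected(self, structure, modeset, selected_modes):
        d = sample_direction(modeset, selected_modes, np.random.default_rng(6))
        with pytest.raises(ValueError):
            displace_along(structure, d, -1.0)


class TestDiversityFilter:
    def test_empty_accepted_vacuous(self, structure, modeset, selected_modes):
        d = sample_direction(modeset, selected_modes, np.random.default_rng(7))
        assert diversity_filter(d, [], structure, ExcitationConfig()) is True

    def test_duplicate_rejected(self, structure, modeset, selected_modes):
        d = sample_direction(modeset, selected_modes, np.random.default_rng(8))
        assert diversity_filter(d, [d], structure, ExcitationConfig()) is False

    def test_matches_bruteforce_oracle(self, structure, modeset, selected_modes):
        """Sequential filter decisions equal an independent re-implementation."""
        rng = np.random.default_rng(9)
        config = ExcitationConfig()
        candidates = [
            sample_direction(modeset, selected_modes, rng) for _ in range(200)
        ]

        # oracle: precompute every displaced structure, then greedy scan
        displaced = [
            displace_along(structure, c, config.filter_displacement).coords
            for c in candidates
        ]
        oracle_accepted: list[int] = []
        oracle_decisions = []
        for i, di in enumerate(displaced):
            ok = all(
                rmsd(di, displaced[j]) > config.filter_rmsd_min
                for j in oracle_accepted
            )
            oracle_decisions.append(ok)
            if ok:
                oracle_accepted.append(i)

        accepted: list = []
        decisions = []
        for c in candidates:
            ok = diversity_filter(c, accepted, structure, config)
            decisions.append(ok)
            if ok:
                accepted.append(c)
        assert decisions == oracle_decisions


class TestInjectKineticEnergy:
    def test_null_injection(self, structure, modeset, selected_modes):
        d = sample_direction(modeset, selected_modes, np.random.default_rng(10))
        state = make_state(structure, seed=10)
        out = inject_kinetic_energy(state, d, 0.0, structure.masses)
        assert np.array_equal(out.velocities, state.velocities)

    def test_exact_energy_increment(self, structure, modeset, selected_modes):
        rng = np.random.default_rng(11)
        for seed in range(5):
            d = sample_direction(modeset, selected_modes, rng)
            state = make_state(structure, seed=seed)
            ke0 = kinetic_energy(state.velocities, structure.masses)
            out = inject_kinetic_energy(state, d, 1.25, structure.masses)
            ke1 = kinetic_energy(out.velocities, structure.masses)
            assert ke1 - ke0 == pytest.approx(1.25, rel=1e-9)

    def test_from_rest_closed_form(self, structure, modeset, selected_modes):
        from modexcite.constants import KCAL_MOL_IN_AMU_A2_PS2

        d = sample_direction(modeset, selected_modes, np.random.default_rng(12))
        state = DynamicsState(structure.coords, np.zeros_like(structure.coords))
        delta_e = 2.0
        out = inject_kinetic_energy(state, d, delta_e, structure.masses)
        # mass-weighted speed alpha = sqrt(2 dE) in amu^1/2 A/ps units
        mw_speed = np.linalg.norm(
            np.sqrt(structure.masses)[:, None] * out.velocities
        )
        assert mw_speed == pytest.approx(
            np.sqrt(2 * delta_e * KCAL_MOL_IN_AMU_A2_PS2), rel=1e-12
        )


class TestExcitationCycle:
    def test_no_perturbation_fixed_point(self, modeset, selected_modes):
        from modexcite.synthetic import SyntheticSpec, make_two_domain_system

        # lj_eps=0 puts the generated coordinates at an exact minimum
        s, p = make_two_domain_system(SyntheticSpec(lj_eps=0.0))
        d = sample_direction(modeset, selected_modes, np.random.default_rng(13))
        config = ExcitationConfig(delta_E=0.0, n_excitations=1, t_exc=0.02)
        state = DynamicsState(
            s.coords.copy(),
            np.zeros_like(s.coords),
            temperature_target=0.0,
            friction=0.0,
        )
        replica = ReplicaState(d, s.coords.copy(), masses=s.masses)
        state, _ = run_excitation_cycle(s, p, state, replica, config, seed=0)
        assert np.allclose(replica.conformations[0], s.coords, atol=1e-9)

    def test_segment_duration(self, structure, params, modeset, selected_modes):
        d = sample_direction(modeset, selected_modes, np.random.default_rng(14))
        config = ExcitationConfig(n_excitations=1)  # default t_exc = 0.2 ps
        state = make_state(structure, seed=14)
        replica = ReplicaState(d, structure.coords.copy(), masses=structure.masses)
        _, frames = run_excitation_cycle(structure, params, state, replica, config, seed=1)
        assert frames.shape[0] * config.dt == pytest.approx(0.2)

    def test_mean_projection_positive(self, structure, params, modeset, selected_modes):
        """Injection biases motion along the excitation direction."""
        rng = np.random.default_rng(15)
        projections = []
        for trial in range(10):
            d = sample_direction(modeset, selected_modes, rng)
            config = ExcitationConfig(n_excitations=5, t_exc=0.02)
            state = make_state(structure, seed=trial)
            replica = ReplicaState(d, structure.coords.copy(), masses=structure.masses)
            for c in range(config.n_excitations):
                state, _ = run_excitation_cycle(
                    structure, params, state, replica, config, seed=100 + c
                )
            projections.append(replica.last_projection)
        assert np.mean(projections) > 0


class TestMaybeUpdateDirection:
    def make_replica(self, structure, direction, projection, angle):
        replica = ReplicaState(
            direction,
            structure.coords.copy(),
            masses=structure.masses,
        )
        replica.last_projection = projection
        replica.last_angle_deg = angle
        replica.last_segment_mean = structure.coords + 0.1
        replica.current_coords = structure.coords + 0.2
        replica.log.append({"updated": False})
        return replica

    @pytest.mark.parametrize(
        "projection,angle,expected",
        [(0.6, 75.0, True), (0.6, 45.0, False), (0.4, 75.0, False)],
    )
    def test_trigger_boundary(
        self, structure, modeset, selected_modes, projection, angle, expected
    ):
        d = sample_direction(modeset, selected_modes, np.random.default_rng(16))
        replica = self.make_replica(structure, d, projection, angle)
        _, updated = maybe_update_direction(replica, ExcitationConfig())
        assert updated is expected

    def test_updated_direction_is_mean_displacement(
        self, structure, modeset, selected_modes
    ):
        d = sample_direction(modeset, selected_modes, np.random.default_rng(17))
        replica = self.make_replica(structure, d, 0.6, 75.0)
        old_start = replica.segment_start_coords.copy()
        diff = replica.last_segment_mean - old_start
        expected = (np.sqrt(structure.masses)[:, None] * diff).ravel()
        expected /= np.linalg.norm(expected)
        _, updated = maybe_update_direction(replica, ExcitationConfig())
        assert updated
        assert np.allclose(replica.current_direction.vector, expected, atol=1e-12)
        assert np.array_equal(replica.segment_start_coords, replica.current_coords)
        assert replica.current_direction.mode_weights is None

    def test_no_history_error(self, structure, modeset, selected_modes):
        d = sample_direction(modeset, selected_modes, np.random.default_rng(18))
        replica = ReplicaState(d, structure.coords.copy(), masses=structure.masses)
        with pytest.raises(RuntimeError, match="history"):
            maybe_update_direction(replica, ExcitationConfig())

    def test_never_triggers_at_180_degrees(self, structure, modeset, selected_modes):
        """Angles cannot exceed 180 deg, so the condition is unsatisfiable."""
        config = ExcitationConfig(adapt_max_angle=180.0)
        d = sample_direction(modeset, selected_modes, np.random.default_rng(19))
        for angle in [0.0, 60.0, 90.0, 179.0, 180.0]:
            replica = self.make_replica(structure, d, 5.0, angle)
            _, updated = maybe_update_direction(replica, config)
            assert not updated


class TestRunReplica:
    def test_single_cycle(self, structure, params, modeset, selected_modes, fast_config):
        d = sample_direction(modeset, selected_modes, np.random.default_rng(20))
        config = ExcitationConfig(n_excitations=1, t_exc=0.02)
        replica = run_replica(
            structure, params, make_state(structure, seed=20), d, config, seed=20
        )
        assert len(replica.conformations) == 1
        assert replica.excitation_count == 1

    def test_determinism(self, structure, params, modeset, selected_modes, fast_config):
        d = sample_direction(modeset, selected_modes, np.random.default_rng(21))
        r1 = run_replica(
            structure, params, make_state(structure, seed=21), d, fast_config, seed=21
        )
        r2 = run_replica(
            structure, params, make_state(structure, seed=21), d, fast_config, seed=21
        )
        assert np.array_equal(
            np.array(r1.conformations), np.array(r2.conformations)
        )

    def test_injection_bookkeeping_every_cycle(
        self, structure, params, modeset, selected_modes, fast_config
    ):
        d = sample_direction(modeset, selected_modes, np.random.default_rng(22))
        replica = run_replica(
            structure, params, make_state(structure, seed=22), d, fast_config, seed=22
        )
        for event in replica.log:
            assert event["delta_ke"] == pytest.approx(
                fast_config.delta_E, rel=1e-9
            )


class TestRunCampaign:
    def test_minimal_campaign(self, system, modeset, selected_modes):
        s, p = system
        config = ExcitationConfig(n_excitations=1, t_exc=0.02)
        result = run_campaign(s, p, modeset, selected_modes, 1, config, seed=0)
        assert result.total_conformations == 1

    def test_bookkeeping_identity(self, system, modeset, selected_modes):
        s, p = system
        config = ExcitationConfig(n_excitations=7)
        result = run_campaign(
            s, p, modeset, selected_modes, 3, config, seed=1, dry_run=True
        )
        assert result.total_conformations == 3 * 7

    def test_dry_run_paper_scale_bookkeeping(self, system, modeset, selected_modes):
        s, p = system
        config = ExcitationConfig(n_excitations=200)
        result = run_campaign(
            s, p, modeset, selected_modes, 183, config, seed=2, dry_run=True
        )
        assert result.total_conformations == 36_600

    def test_accepted_directions_satisfy_filter_posthoc(
        self, system, modeset, selected_modes
    ):
        s, p = system
        config = ExcitationConfig(n_excitations=1, t_exc=0.02)
        result = run_campaign(
            s,
            p,
            modeset,
            selected_modes,
            5,
            config,
            seed=3,
            dry_run=True,
            apply_diversity_filter=True,
        )
        displaced = [
            displace_along(s, d, config.filter_displacement).coords
            for d in result.directions
        ]
        for i in range(len(displaced)):
            for j in range(i + 1, len(displaced)):
                assert rmsd(displaced[i], displaced[j]) > config.filter_rmsd_min

    def test_saturation_error(self, system, modeset, selected_modes):
        s, p = system
        # only ~2 directions can be this different in a 4-mode subspace
        config = ExcitationConfig(
            n_excitations=1, filter_rmsd_min=1.99, candidate_cap_factor=5
        )
        with pytest.raises(SaturationError, match="acceptance rate"):
            run_campaign(
                s,
                p,
                modeset,
                selected_modes,
                10,
                config,
                seed=4,
                dry_run=True,
                apply_diversity_filter=True,
            )

    def test_invalid_replica_count(self, system, modeset, selected_modes):
        s, p = system
        with pytest.raises(ValueError):
            run_campaign(s, p, modeset, selected_modes, 0, ExcitationConfig(), seed=0)
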