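"""Kinetic excitation along adaptively updated normal-mode combinations.

The sampling loop: draw a random unit combination of selected low-frequency
modes, keep it only if the structure displaced 1 A along it differs enough
(RMSD) from the structures displaced along previously accepted directions,
then repeatedly (a) inject a fixed amount of kinetic energy along the
current direction, (b) run a short Langevin segment, (c) store the end
conformation, and (d) update the direction when the system has moved far
enough along it but the realized displacement has swung away from it by more
than a threshold angle.

Directions live in mass-weighted coordinates (where the modes are
orthonormal); conversion to Cartesian displacement/velocity space divides by
sqrt(m_i) per atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import KCAL_MOL_IN_AMU_A2_PS2
from .dynamics import (
    DynamicsState,
    ForceFieldParams,
    initialize_velocities,
    kinetic_energy,
    run_langevin,
)
from .modes import ModeSet
from .structure import Structure, rmsd

__all__ = [
    "ExcitationDirection",
    "ExcitationConfig",
    "ReplicaState",
    "CampaignResult",
    "SaturationError",
    "sample_direction",
    "displace_along",
    "diversity_filter",
    "inject_kinetic_energy",
    "run_excitation_cycle",
    "maybe_update_direction",
    "run_replica",
    "run_campaign",
]


class SaturationError(RuntimeError):
    """Direction sampling could not produce enough diverse candidates."""


@dataclass
class ExcitationDirection:
    """Unit-norm direction over all atom coordinates, mass-weighted metric.

    ``mode_weights`` holds the combination coefficients at sampling time and
    is ``None`` after an adaptive update.
    """

    vector: np.ndarray
    mode_weights: np.ndarray | None = None
    id: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float).ravel()
        nrm = np.linalg.norm(v)
        if nrm == 0.0:
            raise ValueError("zero direction vector")
        if abs(nrm - 1.0) > 1e-10:
            v = v / nrm
        self.vector = v

    def cartesian_displacement(self, masses: np.ndarray) -> np.ndarray:
        """Unnormalized Cartesian displacement field, shape (N, 3)."""
        return (self.vector.reshape(-1, 3)) / np.sqrt(masses)[:, None]

    def cartesian_unit(self, masses: np.ndarray) -> np.ndarray:
        """Unit Cartesian displacement direction, shape (N, 3)."""
        dx = self.cartesian_displacement(masses)
        return dx / np.linalg.norm(dx)


@dataclass(frozen=True)
class ExcitationConfig:
    """All numeric parameters of the excitation protocol."""

    delta_E: float = 1.25  # kcal/mol injected per excitation
    t_exc: float = 0.2  # ps per excitation-relaxation segment
    n_excitations: int = 200  # segments per replica
    filter_displacement: float = 1.0  # A displacement used by the filter
    filter_rmsd_min: float = 1.15  # A minimum pairwise displaced RMSD
    adapt_min_displacement: float = 0.5  # A along the direction
    adapt_max_angle: float = 60.0  # degrees
    dt: float = 0.002  # ps integration step
    temperature: float = 300.0  # K
    friction: float = 1.0  # ps^-1
    segment_stride: int = 1  # frame stride inside a segment
    candidate_cap_factor: int = 100

    def __post_init__(self) -> None:
        for name in (
            "delta_E",
            "t_exc",
            "n_excitations",
            "filter_displacement",
            "filter_rmsd_min",
            "adapt_min_displacement",
            "dt",
        ):
            if getattr(self, name) <= 0 and name != "delta_E":
                raise ValueError(f"{name} must be positive")
        if self.delta_E < 0:
            raise ValueError("delta_E must be >= 0")
        if not (0.0 < self.adapt_max_angle <= 180.0):
            raise ValueError("adapt_max_angle must be in (0, 180]")

    @property
    def steps_per_segment(self) -> int:
        return max(1, int(round(self.t_exc / self.dt)))


@dataclass
class ReplicaState:
    """Per-replica adaptive state and bookkeeping."""

    current_direction: ExcitationDirection
    segment_start_coords: np.ndarray
    excitation_count: int = 0
    update_count: int = 0
    conformations: list = field(default_factory=list)
    log: list = field(default_factory=list)
    # last-segment displacement record consumed by maybe_update_direction
    last_projection: float | None = None
    last_angle_deg: float | None = None
    last_segment_mean: np.ndarray | None = None
    current_coords: np.ndarray | None = None
    masses: np.ndarray | None = None


@dataclass
class CampaignResult:
    replicas: list
    directions: list
    config: ExcitationConfig
    n_candidates_drawn: int

    @property
    def total_conformations(self) -> int:
        return sum(len(r.conformations) for r in self.replicas)

    def all_conformations(self) -> np.ndarray:
        return np.array(
            [c for r in self.replicas for c in r.conformations]
        )


# ---------------------------------------------------------------------------


def sample_direction(
    modes: ModeSet,
    mode_indices,
    rng: np.random.Generator,
    replica_id: int = 0,
) -> ExcitationDirection:
    """Uniform random unit combination of the selected modes.

    Weights are drawn uniformly on the unit hypersphere of the selected-mode
    subspace (signs included); the resulting vector is unit-norm in the
    mass-weighted metric because the modes are orthonormal there.
    """
    idx = np.asarray(mode_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("mode_indices must be nonempty")
    if np.any(idx < modes.n_zero):
        raise ValueError("rigid-body (zero) modes cannot be excited")
    w = rng.standard_normal(idx.size)
    w /= np.linalg.norm(w)
    vec = modes.eigenvectors[:, idx] @ w
    return ExcitationDirection(vec, mode_weights=w, id=replica_id)


def displace_along(
    structure: Structure,
    direction: ExcitationDirection,
    target_rmsd: float,
) -> Structure:
    """Move the structure along the direction to an exact all-atom RMSD."""
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be >= 0")
    if target_rmsd == 0.0:
        return structure.copy()
    dx = direction.cartesian_displacement(structure.masses)
    unit_rmsd = np.sqrt(np.mean(np.sum(dx * dx, axis=1)))
    if unit_rmsd == 0.0:
        raise ValueError("direction has zero Cartesian displacement")
    return structure.with_coords(structure.coords + (target_rmsd / unit_rmsd) * dx)


def diversity_filter(
    candidate: ExcitationDirection,
    accepted: list,
    structure: Structure,
    config: ExcitationConfig,
) -> bool:
    """Greedy acceptance: displace the structure ``filter_displacement`` A
    along the candidate and along every accepted direction; accept iff the
    minimum RMSD between the candidate-displaced structure and each
    accepted-displaced structure exceeds ``filter_rmsd_min``.

    An empty accepted list accepts vacuously.
    """
    if not accepted:
        return True
    cand_coords = displace_along(structure, candidate, config.filter_displacement).coords
    for d in accepted:
        other = displace_along(structure, d, config.filter_displacement).coords
        if rmsd(cand_coords, other) <= config.filter_rmsd_min:
            return False
    return True


def inject_kinetic_energy(
    state: DynamicsState,
    direction: ExcitationDirection,
    delta_E: float,
    masses: np.ndarray,
) -> DynamicsState:
    """Add a velocity increment along the direction raising the kinetic
    energy by exactly ``delta_E`` kcal/mol.

    With the increment dv_i = alpha * q_i / sqrt(m_i) and unit mass-weighted
    q, the KE change (in amu A^2/ps^2) is alpha*b + alpha^2/2 where b is the
    mass-weighted velocity projection on q; the positive root of the
    quadratic is taken, reinforcing motion along +q.
    """
    if delta_E < 0:
        raise ValueError("delta_E must be >= 0")
    if delta_E == 0.0:
        return replace(state, velocities=state.velocities.copy())
    m = np.asarray(masses, dtype=float)
    q = direction.vector.reshape(-1, 3)
    sqrt_m = np.sqrt(m)[:, None]
    b = float(np.sum(sqrt_m * state.velocities * q))
    c = delta_E * KCAL_MOL_IN_AMU_A2_PS2
    disc = b * b + 2.0 * c
    alpha = -b + np.sqrt(disc)
    if alpha <= 0:  # cannot occur for delta_E > 0
        raise RuntimeError("no positive injection root")
    v_new = state.velocities + alpha * q / sqrt_m
    return replace(state, velocities=v_new)


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    cosv = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosv)))


def run_excitation_cycle(
    structure: Structure,
    params: ForceFieldParams,
    state: DynamicsState,
    replica: ReplicaState,
    config: ExcitationConfig,
    seed: int,
) -> tuple[DynamicsState, "np.ndarray"]:
    """One excitation-relaxation segment.

    Injects ``delta_E`` along the replica's current direction, runs
    ``t_exc`` of Langevin dynamics, stores the end conformation and records
    the displacement data (projection onto the direction and deviation angle,
    both measured from ``segment_start_coords``) used by the adaptation rule.
    Returns the new dynamics state and the segment frames.
    """
    if replica.excitation_count >= config.n_excitations:
        raise RuntimeError("replica already exhausted")
    ke_before = kinetic_energy(state.velocities, structure.masses)
    state = inject_kinetic_energy(
        state, replica.current_direction, config.delta_E, structure.masses
    )
    ke_after = kinetic_energy(state.velocities, structure.masses)
    traj, state = run_langevin(
        structure,
        params,
        state,
        n_steps=config.steps_per_segment,
        dt=config.dt,
        seed=seed,
        stride=config.segment_stride,
    )
    u = replica.current_direction.cartesian_unit(structure.masses).ravel()
    net = (state.coords - replica.segment_start_coords).ravel()
    projection = float(np.dot(net, u))
    angle = _angle_deg(net, u)

    replica.conformations.append(state.coords.copy())
    replica.excitation_count += 1
    replica.last_projection = projection
    replica.last_angle_deg = angle
    replica.last_segment_mean = traj.frames.mean(axis=0)
    replica.current_coords = state.coords.copy()
    replica.log.append(
        {
            "cycle": replica.excitation_count,
            "delta_ke": ke_after - ke_before,
            "projection": projection,
            "angle_deg": angle,
            "updated": False,
        }
    )
    return state, traj.frames


def maybe_update_direction(
    replica: ReplicaState,
    config: ExcitationConfig,
) -> tuple[ReplicaState, bool]:
    """Adaptive direction update.

    Triggers iff the recorded displacement along the direction is at least
    ``adapt_min_displacement`` AND the recorded deviation angle exceeds
    ``adapt_max_angle``.  The new direction is the (mass-weighted,
    normalized) difference between the mean position over the last segment
    and the segment start; the segment start then resets to the current
    coordinates.
    """
    if replica.last_projection is None or replica.last_angle_deg is None:
        raise RuntimeError("no displacement history recorded for this replica")
    trigger = (
        replica.last_projection >= config.adapt_min_displacement
        and replica.last_angle_deg > config.adapt_max_angle
    )
    if not trigger:
        return replica, False
    if replica.last_segment_mean is None or replica.current_coords is None:
        raise RuntimeError("missing segment coordinates for direction update")
    diff = replica.last_segment_mean - replica.segment_start_coords
    masses = replica.masses if replica.masses is not None else np.ones(diff.shape[0])
    q = (np.sqrt(masses)[:, None] * diff).ravel()
    nrm = np.linalg.norm(q)
    if nrm == 0.0:
        return replica, False
    replica.current_direction = ExcitationDirection(
        q / nrm, mode_weights=None, id=replica.current_direction.id
    )
    replica.segment_start_coords = replica.current_coords.copy()
    replica.update_count += 1
    if replica.log:
        replica.log[-1]["updated"] = True
    return replica, True


def run_replica(
    structure: Structure,
    params: ForceFieldParams,
    start: DynamicsState,
    direction: ExcitationDirection,
    config: ExcitationConfig,
    seed: int,
) -> ReplicaState:
    """Run a full excitation-relaxation replica with adaptation checks after
    every segment.  Deterministic under a fixed seed."""
    replica = ReplicaState(
        current_direction=direction,
        segment_start_coords=start.coords.copy(),
        masses=structure.masses,
    )
    state = start
    rng = np.random.default_rng(seed)
    for cycle in range(config.n_excitations):
        seg_seed = int(rng.integers(0, 2**31 - 1))
        try:
            state, _ = run_excitation_cycle(
                structure, params, state, replica, config, seg_seed
            )
        except Exception as exc:
            raise RuntimeError(
                f"replica {direction.id} failed at cycle {cycle + 1}"
            ) from exc
        maybe_update_direction(replica, config)
    return replica


def run_campaign(
    structure: Structure,
    params: ForceFieldParams,
    modes: ModeSet,
    mode_indices,
    n_replicas: int,
    config: ExcitationConfig,
    seed: int,
    dry_run: bool = False,
    apply_diversity_filter: bool | None = None,
    start_state: DynamicsState | None = None,
) -> CampaignResult:
    """Run (or dry-run) a multi-replica excitation campaign.

    Candidate directions are drawn until ``n_replicas`` pass the diversity
    filter, capped at ``candidate_cap_factor * n_replicas`` draws.  In
    ``dry_run`` mode no dynamics is integrated: each replica stores
    ``n_excitations`` frozen copies of the start coordinates, exercising
    campaign bookkeeping only, and the diversity filter defaults to off
    (bookkeeping does not depend on direction diversity).
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    if apply_diversity_filter is None:
        apply_diversity_filter = not dry_run
    rng = np.random.default_rng(seed)
    accepted: list[ExcitationDirection] = []
    cap = config.candidate_cap_factor * n_replicas
    drawn = 0
    while len(accepted) < n_replicas:
        if drawn >= cap:
            raise SaturationError(
                f"accepted {len(accepted)}/{n_replicas} directions after "
                f"{drawn} draws (acceptance rate {len(accepted) / drawn:.3f})"
            )
        cand = sample_direction(modes, mode_indices, rng, replica_id=len(accepted))
        drawn += 1
        if not apply_diversity_filter or diversity_filter(
            cand, accepted, structure, config
        ):
            accepted.append(cand)

    replicas = []
    if dry_run:
        for d in accepted:
            r = ReplicaState(
                current_direction=d,
                segment_start_coords=structure.coords,
                excitation_count=config.n_excitations,
                conformations=[structure.coords] * config.n_excitations,
            )
            replicas.append(r)
    else:
        if start_state is None:
            v0 = initialize_velocities(structure.masses, config.temperature, seed)
            start_state = DynamicsState(
                coords=structure.coords.copy(),
                velocities=v0,
                temperature_target=config.temperature,
                friction=config.friction,
            )
        for i, d in enumerate(accepted):
            replicas.append(
                run_replica(
                    structure,
                    params,
                    replace(start_state, coords=start_state.coords.copy(),
                            velocities=start_state.velocities.copy()),
                    d,
                    config,
                    seed=seed + 7919 * (i + 1),
                )
            )
    return CampaignResult(replicas, accepted, config, drawn)
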