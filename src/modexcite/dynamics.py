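"""Toy force field, staged minimization, and Langevin dynamics.

Potential terms (physics convention, 1/2 prefactors):

* bonds:   1/2 k (r - r0)^2
* angles:  1/2 k (theta - theta0)^2
* LJ:      eps [ (rmin/r)^12 - 2 (rmin/r)^6 ] * S(r)
* Coulomb: C q_i q_j / (eps_r * r) * S(r)
* optional harmonic positional restraint 1/2 k |r - ref|^2

where S(r) is the CHARMM-style switching polynomial, identically 1 below
``switch_on`` and identically 0 at and beyond ``switch_off``.  Switching is
applied to both LJ and Coulomb (no Ewald at this scale).  Forces are the
exact negative gradient of the implemented energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

from .constants import COULOMB_CONSTANT, KB, KCAL_MOL_IN_AMU_A2_PS2
from .structure import Structure
from .trajectory import Trajectory

__all__ = [
    "ForceFieldParams",
    "DynamicsState",
    "MinimizationStage",
    "MinimizationSchedule",
    "EnergyResult",
    "MinimizationResult",
    "DivergenceError",
    "BlowUpError",
    "potential_energy",
    "minimize",
    "run_langevin",
    "kinetic_energy",
    "kinetic_temperature",
    "initialize_velocities",
    "standard_restrained_schedule",
    "network_spring_params",
]


class DivergenceError(RuntimeError):
    """Minimization produced a non-finite energy."""


class BlowUpError(RuntimeError):
    """Dynamics produced non-finite coordinates."""


@dataclass
class ForceFieldParams:
    """Parameters of the bead force field.

    ``bonds`` is (nb, 2) int; ``angles`` is (na, 3) int with the central atom
    in the middle.  Nonbonded 1-2 and 1-3 pairs are excluded automatically.
    """

    bonds: np.ndarray
    bond_k: np.ndarray
    bond_r0: np.ndarray
    angles: np.ndarray
    angle_k: np.ndarray
    angle_theta0: np.ndarray
    charges: np.ndarray
    lj_eps: np.ndarray
    lj_rmin_half: np.ndarray
    dielectric: float = 1.0
    switch_on: float = 10.0
    switch_off: float = 12.0
    coulomb_constant: float = COULOMB_CONSTANT
    restraint_k: float = 0.0
    restraint_ref: np.ndarray | None = None
    _excluded: set = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        self.bond_k = np.asarray(self.bond_k, dtype=float).reshape(-1)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=float).reshape(-1)
        self.angles = np.asarray(self.angles, dtype=int).reshape(-1, 3)
        self.angle_k = np.asarray(self.angle_k, dtype=float).reshape(-1)
        self.angle_theta0 = np.asarray(self.angle_theta0, dtype=float).reshape(-1)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_eps = np.asarray(self.lj_eps, dtype=float)
        self.lj_rmin_half = np.asarray(self.lj_rmin_half, dtype=float)
        if self.switch_on >= self.switch_off:
            raise ValueError("switch_on must be < switch_off")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        if self.restraint_ref is not None:
            self.restraint_ref = np.asarray(self.restraint_ref, dtype=float)
        pairs = {tuple(sorted(b)) for b in self.bonds.tolist()}
        pairs |= {tuple(sorted((a[0], a[2]))) for a in self.angles.tolist()}
        self._excluded = pairs

    @property
    def n_atoms(self) -> int:
        return self.charges.shape[0]

    def excluded_pairs(self) -> set:
        return self._excluded

    def nonbonded_pairs(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle pair list with 1-2/1-3 exclusions removed (cached)."""
        cache = getattr(self, "_nb_cache", None)
        if cache is not None and cache[0] == n:
            return cache[1], cache[2]
        iu, ju = np.triu_indices(n, 1)
        if self._excluded:
            keep = np.fromiter(
                (
                    (a, b) not in self._excluded
                    for a, b in zip(iu.tolist(), ju.tolist())
                ),
                dtype=bool,
                count=iu.size,
            )
            iu, ju = iu[keep], ju[keep]
        object.__setattr__(self, "_nb_cache", (n, iu, ju))
        return iu, ju

    def with_restraint(self, k: float, ref: np.ndarray | None) -> "ForceFieldParams":
        return replace(self, restraint_k=float(k), restraint_ref=ref)


@dataclass
class DynamicsState:
    """Coordinates/velocities plus thermostat settings."""

    coords: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    temperature_target: float = 300.0
    friction: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        if self.coords.shape != self.velocities.shape:
            raise ValueError("coords/velocities shape mismatch")
        if not (np.all(np.isfinite(self.coords)) and np.all(np.isfinite(self.velocities))):
            raise ValueError("non-finite state")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")


@dataclass(frozen=True)
class MinimizationStage:
    method: str  # "sd" | "cg"
    steps: int
    restraint_k: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("sd", "cg"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.steps <= 0:
            raise ValueError("steps must be positive")
        if self.restraint_k < 0:
            raise ValueError("restraint_k must be >= 0")


MinimizationSchedule = list  # list[MinimizationStage]


def standard_restrained_schedule() -> list[MinimizationStage]:
    """Staged schedule: restrained steepest descent with force constants
    10, 1, 0.1 kcal/mol/A^2 decreased every 500 steps, 200 conjugate-gradient
    steps at 0.1, then unrestrained (100 sd + 200 cg)."""
    return [
        MinimizationStage("sd", 500, 10.0),
        MinimizationStage("sd", 500, 1.0),
        MinimizationStage("sd", 500, 0.1),
        MinimizationStage("cg", 200, 0.1),
        MinimizationStage("sd", 100, 0.0),
        MinimizationStage("cg", 200, 0.0),
    ]


def network_spring_params(
    structure: Structure,
    cutoff: float = 12.0,
    k: float = 1.0,
) -> ForceFieldParams:
    """Pure network-spring force field: harmonic bonds of stiffness ``k``
    between all bead pairs within ``cutoff``, at their current separations.

    No angles, charges or LJ — its Hessian at the input coordinates equals
    the anisotropic-network Hessian with gamma = k.
    """
    x = structure.coords
    n = structure.n_atoms
    iu, ju = np.triu_indices(n, 1)
    d = np.linalg.norm(x[iu] - x[ju], axis=1)
    contact = d < cutoff
    bonds = np.column_stack([iu[contact], ju[contact]])
    return ForceFieldParams(
        bonds=bonds,
        bond_k=np.full(bonds.shape[0], float(k)),
        bond_r0=d[contact],
        angles=np.empty((0, 3), dtype=int),
        angle_k=np.empty(0),
        angle_theta0=np.empty(0),
        charges=np.zeros(n),
        lj_eps=np.zeros(n),
        lj_rmin_half=np.full(n, 2.0),
    )


@dataclass
class EnergyResult:
    total: float
    terms: dict
    forces: np.ndarray


def _switch(r2: np.ndarray, ron: float, roff: float) -> tuple[np.ndarray, np.ndarray]:
    """CHARMM switching function and d(S)/dr, as functions of r^2 and r."""
    ron2, roff2 = ron * ron, roff * roff
    denom = (roff2 - ron2) ** 3
    a = roff2 - r2
    b = roff2 + 2.0 * r2 - 3.0 * ron2
    s = np.where(r2 <= ron2, 1.0, np.where(r2 >= roff2, 0.0, a * a * b / denom))
    r = np.sqrt(r2)
    dsdr = np.where(
        (r2 > ron2) & (r2 < roff2), 12.0 * r * a * (ron2 - r2) / denom, 0.0
    )
    return s, dsdr


def potential_energy(
    structure: Structure,
    params: ForceFieldParams,
    coords: np.ndarray | None = None,
) -> EnergyResult:
    """Total potential energy, per-term breakdown, and exact forces."""
    x = structure.coords if coords is None else np.asarray(coords, dtype=float)
    x = x.reshape(-1, 3)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    n = x.shape[0]
    forces = np.zeros_like(x)
    terms = {"bond": 0.0, "angle": 0.0, "lj": 0.0, "coulomb": 0.0, "restraint": 0.0}

    if params.bonds.shape[0]:
        i, j = params.bonds[:, 0], params.bonds[:, 1]
        d = x[i] - x[j]
        r = np.linalg.norm(d, axis=1)
        dr = r - params.bond_r0
        terms["bond"] = float(0.5 * np.sum(params.bond_k * dr * dr))
        fpair = (-params.bond_k * dr / r)[:, None] * d  # force on i
        np.add.at(forces, i, fpair)
        np.add.at(forces, j, -fpair)

    if params.angles.shape[0]:
        ai, aj, ak = params.angles[:, 0], params.angles[:, 1], params.angles[:, 2]
        u = x[ai] - x[aj]
        v = x[ak] - x[aj]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cos_t = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.sqrt(np.clip(1.0 - cos_t * cos_t, 1e-12, None))
        dtheta = theta - params.angle_theta0
        terms["angle"] = float(0.5 * np.sum(params.angle_k * dtheta * dtheta))
        coef = (-params.angle_k * dtheta)[:, None]  # -dE/dtheta
        dthe_di = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
        dthe_dk = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
        fi = coef * dthe_di
        fk = coef * dthe_dk
        np.add.at(forces, ai, fi)
        np.add.at(forces, ak, fk)
        np.add.at(forces, aj, -(fi + fk))

    # nonbonded: all pairs except 1-2/1-3 exclusions, within switch_off
    if n > 1:
        iu, ju = params.nonbonded_pairs(n)
        if iu.size:
            d = x[iu] - x[ju]
            r2 = np.sum(d * d, axis=1)
            within = r2 < params.switch_off**2
            iu, ju, d, r2 = iu[within], ju[within], d[within], r2[within]
        if iu.size:
            if np.any(r2 < 1e-12):
                bad = int(np.argmin(r2))
                raise ValueError(
                    f"nonbonded singularity: atoms {iu[bad]} and {ju[bad]} overlap"
                )
            r = np.sqrt(r2)
            s, dsdr = _switch(r2, params.switch_on, params.switch_off)

            eps = np.sqrt(params.lj_eps[iu] * params.lj_eps[ju])
            rmin = params.lj_rmin_half[iu] + params.lj_rmin_half[ju]
            sr6 = (rmin / r) ** 6
            e_lj = eps * (sr6 * sr6 - 2.0 * sr6)
            de_lj = eps * 12.0 * (sr6 - sr6 * sr6) / r  # dE/dr

            qq = (
                params.coulomb_constant
                * params.charges[iu]
                * params.charges[ju]
                / params.dielectric
            )
            e_cl = qq / r
            de_cl = -qq / r2

            terms["lj"] = float(np.sum(e_lj * s))
            terms["coulomb"] = float(np.sum(e_cl * s))
            dudr = (de_lj + de_cl) * s + (e_lj + e_cl) * dsdr
            fpair = (-dudr / r)[:, None] * d
            np.add.at(forces, iu, fpair)
            np.add.at(forces, ju, -fpair)

    if params.restraint_k > 0.0:
        ref = params.restraint_ref
        if ref is None:
            raise ValueError("restraint_k > 0 requires restraint_ref")
        dx = x - ref
        terms["restraint"] = float(0.5 * params.restraint_k * np.sum(dx * dx))
        forces -= params.restraint_k * dx

    total = float(sum(terms.values()))
    return EnergyResult(total, terms, forces)


# ---------------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------------

@dataclass
class StageLog:
    method: str
    steps_run: int
    restraint_k: float
    energy_start: float
    energy_end: float


@dataclass
class MinimizationResult:
    coords: np.ndarray
    stages: list


def _sd_stage(fun_grad, x0: np.ndarray, steps: int) -> np.ndarray:
    """Steepest descent with backtracking; energy never increases."""
    x = x0.copy()
    e, g = fun_grad(x)
    step = 0.01
    for k in range(steps):
        gnorm = np.max(np.abs(g))
        if gnorm < 1e-12:
            break
        trial = x - step * g / gnorm
        e_new, g_new = fun_grad(trial)
        if not np.isfinite(e_new):
            raise DivergenceError(f"non-finite energy at sd step {k}")
        if e_new <= e:
            x, e, g = trial, e_new, g_new
            step *= 1.2
        else:
            step *= 0.5
    return x


def minimize(
    structure: Structure,
    params: ForceFieldParams,
    schedule: list,
    coords: np.ndarray | None = None,
) -> MinimizationResult:
    """Run the staged minimization.

    Positional restraints in each stage act toward the coordinates passed in
    (the minimization input), as in a heavy-atom restrained relaxation.
    """
    if not schedule:
        raise ValueError("empty minimization schedule")
    x = (structure.coords if coords is None else np.asarray(coords, float)).copy()
    ref = x.copy()
    logs = []
    for si, stage in enumerate(schedule):
        p = params.with_restraint(stage.restraint_k, ref) if stage.restraint_k > 0 else params

        def fun_grad(flat_or_arr):
            arr = np.asarray(flat_or_arr, dtype=float).reshape(-1, 3)
            res = potential_energy(structure, p, arr)
            return res.total, -res.forces

        e_start = fun_grad(x)[0]
        if not np.isfinite(e_start):
            raise DivergenceError(f"non-finite energy entering stage {si}")
        if stage.method == "sd":
            x = _sd_stage(fun_grad, x, stage.steps)
        else:  # cg

            def fun(flat):
                return fun_grad(flat)[0]

            def jac(flat):
                return fun_grad(flat)[1].ravel()

            out = scipy.optimize.minimize(
                fun,
                x.ravel(),
                jac=jac,
                method="CG",
                options={"maxiter": stage.steps, "gtol": 1e-10},
            )
            x = out.x.reshape(-1, 3)
        e_end = fun_grad(x)[0]
        if not np.isfinite(e_end):
            raise DivergenceError(f"non-finite energy in stage {si} ({stage.method})")
        logs.append(StageLog(stage.method, stage.steps, stage.restraint_k, e_start, e_end))
    return MinimizationResult(x, logs)


# ---------------------------------------------------------------------------
# Langevin dynamics (BAOAB)
# ---------------------------------------------------------------------------

def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in kcal/mol from velocities in A/ps and masses in amu."""
    v = np.asarray(velocities, dtype=float).reshape(-1, 3)
    m = np.asarray(masses, dtype=float)
    return float(0.5 * np.sum(m[:, None] * v * v) / KCAL_MOL_IN_AMU_A2_PS2)


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature (K), 3N degrees of freedom."""
    n = np.asarray(velocities).reshape(-1, 3).shape[0]
    return 2.0 * kinetic_energy(velocities, masses) / (3.0 * n * KB)


def initialize_velocities(
    masses: np.ndarray, temperature: float, seed: int
) -> np.ndarray:
    """Maxwell-Boltzmann velocities at the target temperature."""
    m = np.asarray(masses, dtype=float)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB * temperature * KCAL_MOL_IN_AMU_A2_PS2 / m)
    return sigma[:, None] * rng.standard_normal((m.size, 3))


def run_langevin(
    structure: Structure,
    params: ForceFieldParams,
    state: DynamicsState,
    n_steps: int,
    dt: float = 0.002,
    seed: int = 0,
    stride: int = 1,
) -> tuple[Trajectory, DynamicsState]:
    """BAOAB Langevin integration.

    With friction 0 the O-step is the identity and the scheme reduces to
    velocity Verlet.  Frames are stored every ``stride`` steps (after the
    step); deterministic under a fixed seed.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    m = structure.masses[:, None]
    x = state.coords.copy()
    v = state.velocities.copy()
    gamma = state.friction
    kt = KB * state.temperature_target * KCAL_MOL_IN_AMU_A2_PS2
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    else:
        c1, c2 = 1.0, 0.0
    sigma_v = np.sqrt(kt / m)

    frames = []
    f = potential_energy(structure, params, x).forces
    acc_scale = KCAL_MOL_IN_AMU_A2_PS2 / m
    for step in range(n_steps):
        v = v + 0.5 * dt * f * acc_scale  # B
        x = x + 0.5 * dt * v  # A
        if c2 > 0.0:
            v = c1 * v + c2 * sigma_v * rng.standard_normal(v.shape)  # O
        else:
            v = c1 * v
        x = x + 0.5 * dt * v  # A
        if not np.all(np.isfinite(x)):
            raise BlowUpError(f"non-finite coordinates at step {step}")
        f = potential_energy(structure, params, x).forces
        v = v + 0.5 * dt * f * acc_scale  # B
        if (step + 1) % stride == 0:
            frames.append(x.copy())
    if not frames:
        frames.append(x.copy())
    traj = Trajectory(np.array(frames), dt * stride)
    new_state = DynamicsState(
        coords=x,
        velocities=v,
        time=state.time + n_steps * dt,
        temperature_target=state.temperature_target,
        friction=state.friction,
    )
    return traj, new_state
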