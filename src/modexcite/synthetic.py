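"""Synthetic two-domain bead systems and validation trajectories.

The generator emulates a compact globular domain (the "core") with a
flexible tail that terminates in an ideal helix — one bead per residue,
contiguous numbering 1..(n_core + n_tail).  The tail attaches to the core
bead placed at the +z pole of the (slightly anisotropic) core ellipsoid, so
the tail initially extends away from the core along +z.

Bond/angle equilibrium values are taken from the generated geometry, so the
bonded part of the force field is exactly at its minimum for the generated
coordinates.  Tail bonds and angles are softer than core ones by
construction (the tail is the flexible element); the core is additionally
cross-linked by a network of stiff springs between nearby beads so it moves
as a quasi-rigid body under dynamics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .constants import DEFAULT_BEAD_MASS
from .dynamics import ForceFieldParams
from .structure import Structure
from .trajectory import Trajectory

__all__ = [
    "SyntheticSpec",
    "InvalidSpecError",
    "make_two_domain_system",
    "make_gaussian_trajectory",
]

#: relative axis scalings of the core ellipsoid; chosen so the three
#: principal moments of inertia are distinct by at least ~5% relative gap.
_CORE_AXIS_SCALES = (1.0, 0.85, 0.70)

#: bead spacing (A) of the straight pre-helix part of the tail.
_TAIL_SPACING = 3.8

#: helix radius (A) and twist per bead (degrees), alpha-helix-like.
_HELIX_RADIUS = 2.3
_HELIX_TWIST_DEG = 100.0


class InvalidSpecError(ValueError):
    """Raised when a SyntheticSpec violates its invariants."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Blueprint of a synthetic two-domain system.

    ``helix_range`` is an inclusive (lo, hi) residue-number range inside the
    tail; ``None`` selects the last min(8, n_tail) tail residues.
    ``charges`` is an optional per-bead array of elementary charges.
    """

    n_core: int = 40
    n_tail: int = 12
    helix_range: tuple[int, int] | None = None
    core_radius: float = 11.0
    tail_rise: float = 1.5
    bond_k: float = 100.0
    tail_bond_k: float = 10.0
    angle_k: float = 10.0
    tail_angle_k: float = 1.0
    core_link_cutoff: float = 8.0
    charges: tuple | None = None
    lj_eps: float = 0.05
    lj_rmin_half: float = 2.0
    bead_mass: float = DEFAULT_BEAD_MASS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core < 4:
            raise InvalidSpecError("n_core must be >= 4 (non-collinear core)")
        if self.n_tail < 1:
            raise InvalidSpecError("n_tail must be >= 1")
        if self.tail_bond_k > self.bond_k:
            raise InvalidSpecError("tail_bond_k must not exceed bond_k")
        if self.core_radius <= 0 or self.tail_rise <= 0:
            raise InvalidSpecError("core_radius and tail_rise must be positive")
        lo, hi = self.resolved_helix_range()
        tail_lo, tail_hi = self.n_core + 1, self.n_core + self.n_tail
        if not (tail_lo <= lo <= hi <= tail_hi):
            raise InvalidSpecError(
                f"helix_range {lo}:{hi} outside tail residues {tail_lo}:{tail_hi}"
            )
        if self.charges is not None and len(self.charges) != self.n_atoms:
            raise InvalidSpecError("charges length must equal n_core + n_tail")

    @property
    def n_atoms(self) -> int:
        return self.n_core + self.n_tail

    def resolved_helix_range(self) -> tuple[int, int]:
        if self.helix_range is not None:
            return (int(self.helix_range[0]), int(self.helix_range[1]))
        n_helix = min(8, self.n_tail)
        return (self.n_core + self.n_tail - n_helix + 1, self.n_core + self.n_tail)

    # plain-config round trip -------------------------------------------------
    def to_json(self, path) -> None:
        d = asdict(self)
        d["charges"] = None if self.charges is None else list(self.charges)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("helix_range") is not None:
            d["helix_range"] = tuple(d["helix_range"])
        if d.get("charges") is not None:
            d["charges"] = tuple(d["charges"])
        return cls(**d)


def _fibonacci_ellipsoid(n: int, radius: float, seed: int) -> np.ndarray:
    """Quasi-uniform points on an anisotropically scaled sphere.

    A tiny seeded jitter breaks any residual symmetry without affecting the
    moment-of-inertia gaps.
    """
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    pts *= radius * np.array(_CORE_AXIS_SCALES)
    rng = np.random.default_rng(seed)
    pts += 0.05 * rng.standard_normal(pts.shape)
    return pts


def make_two_domain_system(spec: SyntheticSpec) -> tuple[Structure, ForceFieldParams]:
    """Build the bead structure and its force-field parameters.

    Deterministic: identical specs (same seed) give identical output.
    """
    n_core, n_tail = spec.n_core, spec.n_tail
    n = spec.n_atoms

    core = _fibonacci_ellipsoid(n_core, spec.core_radius, spec.seed)
    # anchor = core bead with the largest z; reorder it to be the last core
    # bead so the chain runs ... core -> anchor -> tail.
    anchor_local = int(np.argmax(core[:, 2]))
    order = np.concatenate(
        [np.arange(n_core)[np.arange(n_core) != anchor_local], [anchor_local]]
    )
    core = core[order]
    anchor = core[-1]

    helix_lo, helix_hi = spec.resolved_helix_range()
    coords = np.zeros((n, 3))
    coords[:n_core] = core
    t_phase = 0.0
    z_cursor = anchor[2]
    for t in range(n_tail):
        resid = n_core + 1 + t
        if resid < helix_lo:
            # gently coiled stalk along +z; a perfectly straight stalk would
            # leave zero-energy perpendicular motions in the network model
            z_cursor += _TAIL_SPACING
            phase = np.deg2rad(120.0) * (t + 1)
            coords[n_core + t] = np.array(
                [
                    anchor[0] + 1.2 * np.cos(phase),
                    anchor[1] + 1.2 * np.sin(phase),
                    z_cursor,
                ]
            )
        else:  # ideal helix, axis along +z through the anchor's x-y position
            k = resid - helix_lo
            if k == 0:
                z_cursor += _TAIL_SPACING
            else:
                z_cursor += spec.tail_rise
            t_phase = np.deg2rad(_HELIX_TWIST_DEG) * k
            coords[n_core + t] = np.array(
                [
                    anchor[0] + _HELIX_RADIUS * np.cos(t_phase),
                    anchor[1] + _HELIX_RADIUS * np.sin(t_phase),
                    z_cursor,
                ]
            )

    # steric sanity
    diffs = coords[:, None, :] - coords[None, :, :]
    dists = np.sqrt(np.sum(diffs * diffs, axis=-1))
    np.fill_diagonal(dists, np.inf)
    if dists.min() < 1.0:
        raise InvalidSpecError(
            f"generated beads closer than 1.0 A (min {dists.min():.2f} A); "
            "increase core_radius or spacing"
        )

    charges = np.zeros(n) if spec.charges is None else np.asarray(spec.charges, float)
    structure = Structure.from_beads(
        coords,
        masses=spec.bead_mass,
        charges=charges,
        lj_eps=spec.lj_eps,
        lj_rmin_half=spec.lj_rmin_half,
    )

    # chain bonds; tail stiffness applies to any bond touching a tail bead
    bonds, bond_k = [], []
    for i in range(n - 1):
        bonds.append((i, i + 1))
        bond_k.append(spec.tail_bond_k if (i + 1) >= n_core else spec.bond_k)
    # core cross-links: stiff springs between nearby core beads
    for i in range(n_core):
        for j in range(i + 2, n_core):
            if dists[i, j] < spec.core_link_cutoff:
                bonds.append((i, j))
                bond_k.append(spec.bond_k)
    bonds = np.array(bonds, dtype=int)
    bond_k = np.array(bond_k, dtype=float)
    bond_r0 = np.linalg.norm(coords[bonds[:, 0]] - coords[bonds[:, 1]], axis=1)

    angles, angle_k = [], []
    for i in range(n - 2):
        angles.append((i, i + 1, i + 2))
        angle_k.append(spec.tail_angle_k if (i + 2) >= n_core else spec.angle_k)
    angles = np.array(angles, dtype=int)
    angle_k = np.array(angle_k, dtype=float)
    u = coords[angles[:, 0]] - coords[angles[:, 1]]
    v = coords[angles[:, 2]] - coords[angles[:, 1]]
    cos_t = np.sum(u * v, axis=1) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    theta0 = np.arccos(np.clip(cos_t, -1.0, 1.0))

    params = ForceFieldParams(
        bonds=bonds,
        bond_k=bond_k,
        bond_r0=bond_r0,
        angles=angles,
        angle_k=angle_k,
        angle_theta0=theta0,
        charges=charges,
        lj_eps=structure.lj_eps,
        lj_rmin_half=structure.lj_rmin_half,
    )
    return structure, params


def make_gaussian_trajectory(
    structure: Structure,
    per_atom_sd,
    n_frames: int,
    seed: int = 0,
) -> Trajectory:
    """Reference coordinates plus i.i.d. zero-mean Gaussian displacements.

    ``per_atom_sd`` (scalar or per-atom, A) is the standard deviation of each
    Cartesian coordinate, so the 3-D positional variance of atom i is
    3*sd_i^2.  Used as an analysis fixture: RMSF has the closed form sd*sqrt(3).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    sd = np.broadcast_to(np.asarray(per_atom_sd, dtype=float), (structure.n_atoms,))
    if np.any(sd < 0):
        raise ValueError("per_atom_sd must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_frames, structure.n_atoms, 3)) * sd[None, :, None]
    return Trajectory(structure.coords[None, :, :] + noise, dt=1.0)
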