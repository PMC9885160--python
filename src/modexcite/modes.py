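"""Mass-weighted normal modes: network/numerical Hessians, diagonalization,
per-mode fluctuation contributions and mode selection.

Mode math is done in the A / amu / kcal-per-mol unit system; eigenvalues of
the mass-weighted Hessian are in kcal/mol/A^2/amu.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .constants import KB
from .dynamics import ForceFieldParams, potential_energy
from .structure import AtomSelection, Structure

__all__ = [
    "ENMConfig",
    "ModeSet",
    "build_enm_hessian",
    "build_numerical_hessian",
    "diagonalize",
    "mode_rmsf_contributions",
    "select_modes",
]


@dataclass(frozen=True)
class ENMConfig:
    """Anisotropic-network-model settings: uniform springs of stiffness
    ``gamma`` between all bead pairs within ``cutoff``."""

    cutoff: float = 12.0
    gamma: float = 1.0
    tol_zero: float = 1e-8

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class ModeSet:
    """Eigenpairs of the mass-weighted Hessian.

    ``eigenvectors`` columns are orthonormal in the mass-weighted metric
    (i.e. plain-orthonormal as stored); ``eigenvalues`` ascend and the first
    ``n_zero`` are the rigid-body null modes.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    masses: np.ndarray
    n_zero: int

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(np.diff(self.eigenvalues) < -1e-10):
            raise ValueError("eigenvalues must be sorted ascending")

    @property
    def n_atoms(self) -> int:
        return self.masses.size

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    def nonzero_mode_indices(self) -> np.ndarray:
        return np.arange(self.n_zero, self.n_modes)

    def frequencies(self) -> np.ndarray:
        """sqrt(eigenvalue) for positive eigenvalues, 0 for null modes."""
        return np.sqrt(np.clip(self.eigenvalues, 0.0, None))

    def save(self, path) -> None:
        np.savez(
            path,
            eigenvalues=self.eigenvalues,
            eigenvectors=self.eigenvectors,
            masses=self.masses,
            n_zero=np.array([self.n_zero]),
        )

    @classmethod
    def load(cls, path) -> "ModeSet":
        with np.load(path) as z:
            return cls(
                z["eigenvalues"], z["eigenvectors"], z["masses"], int(z["n_zero"][0])
            )


def build_enm_hessian(structure: Structure, config: ENMConfig) -> np.ndarray:
    """Anisotropic-network Hessian (3N x 3N, kcal/mol/A^2).

    Off-diagonal 3x3 block for a contact pair is -gamma * rhat rhat^T; the
    diagonal blocks are minus the sum of the row's off-diagonal blocks, so
    every row sums to zero (translation invariance).
    """
    x = structure.coords
    n = structure.n_atoms
    if n < 2:
        raise ValueError("need at least 2 atoms")
    h = np.zeros((3 * n, 3 * n))
    iu, ju = np.triu_indices(n, 1)
    d = x[iu] - x[ju]
    r = np.linalg.norm(d, axis=1)
    contact = r < config.cutoff
    if not np.any(contact):
        warnings.warn("no pairs within ENM cutoff: Hessian is zero")
        return h
    for i, j, dij, rij in zip(
        iu[contact], ju[contact], d[contact], r[contact]
    ):
        rhat = dij / rij
        block = -config.gamma * np.outer(rhat, rhat)
        h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] += block
        h[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] += block
        h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        h[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return h


def build_numerical_hessian(
    structure: Structure,
    params: ForceFieldParams,
    delta: float = 1e-4,
    gradient_warn_threshold: float = 1e-4,
    symmetrize: bool = True,
) -> np.ndarray:
    """Hessian of the toy potential by central differences of the analytic
    gradient, symmetrized as (H + H^T)/2 unless ``symmetrize`` is False.

    Warns if the starting gradient norm exceeds ``gradient_warn_threshold``
    (kcal/mol/A): modes are only meaningful near a minimum.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    x0 = structure.coords.copy()
    n3 = x0.size
    g0 = -potential_energy(structure, params, x0).forces
    gnorm = float(np.max(np.abs(g0)))
    if gnorm > gradient_warn_threshold:
        warnings.warn(
            f"structure not at a minimum (max |gradient| = {gnorm:.3g} "
            "kcal/mol/A); numerical modes may be unreliable"
        )
    h = np.empty((n3, n3))
    flat = x0.ravel()
    for k in range(n3):
        xp = flat.copy()
        xp[k] += delta
        gp = -potential_energy(structure, params, xp.reshape(-1, 3)).forces.ravel()
        xm = flat.copy()
        xm[k] -= delta
        gm = -potential_energy(structure, params, xm.reshape(-1, 3)).forces.ravel()
        h[:, k] = (gp - gm) / (2.0 * delta)
    return 0.5 * (h + h.T) if symmetrize else h


def diagonalize(
    hessian: np.ndarray,
    masses: np.ndarray,
    tol_zero: float = 1e-8,
    symmetry_tol: float = 1e-6,
) -> ModeSet:
    """Eigendecomposition of M^{-1/2} H M^{-1/2}."""
    h = np.asarray(hessian, dtype=float)
    m = np.asarray(masses, dtype=float)
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    scale = max(1.0, float(np.max(np.abs(h))))
    if np.max(np.abs(h - h.T)) > symmetry_tol * scale:
        raise ValueError("Hessian is not symmetric within tolerance")
    h = 0.5 * (h + h.T)
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(m), 3)
    mw = h * np.outer(inv_sqrt_m, inv_sqrt_m)
    evals, evecs = scipy.linalg.eigh(mw)
    n_zero = int(np.sum(np.abs(evals) <= tol_zero))
    return ModeSet(evals, evecs, m, n_zero)


def mode_rmsf_contributions(modes: ModeSet, temperature: float) -> np.ndarray:
    """Per-mode, per-atom thermal RMSF (A), shape (n_modes, n_atoms).

    Mode k contributes positional variance kB*T/lambda_k * |a_{k,i}|^2 / m_i
    to atom i (summed over the atom's three components); rigid-body null
    modes contribute exactly zero.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    n_modes, n_atoms = modes.n_modes, modes.n_atoms
    var = np.zeros((n_modes, n_atoms))
    comp2 = modes.eigenvectors.T.reshape(n_modes, n_atoms, 3) ** 2
    amp2 = comp2.sum(axis=2) / modes.masses[None, :]
    nz = modes.nonzero_mode_indices()
    var[nz] = (KB * temperature / modes.eigenvalues[nz])[:, None] * amp2[nz]
    return np.sqrt(var)


def select_modes(
    modes: ModeSet,
    region: AtomSelection,
    k: int,
    pool: int = 20,
    temperature: float = 300.0,
) -> np.ndarray:
    """Pick the ``k`` modes with the largest summed RMSF over ``region``.

    Candidates are the lowest ``pool`` nonzero-frequency modes; the result
    is sorted by frequency (mode index), ties broken by lower index.
    """
    if len(region) == 0:
        raise ValueError("empty region selection")
    nz = modes.nonzero_mode_indices()
    if k > nz.size:
        raise ValueError(f"k={k} exceeds the {nz.size} nonzero modes")
    candidates = nz[: min(pool, nz.size)]
    rmsf = mode_rmsf_contributions(modes, temperature)
    scores = rmsf[np.ix_(candidates, region.indices)].sum(axis=1)
    # stable sort keeps lower mode index first among ties
    order = np.argsort(-scores, kind="stable")[:k]
    return np.sort(candidates[order])
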