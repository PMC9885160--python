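"""Trajectory analyses: RMSF, RMSD series, anchor/inertia frame transforms,
center-of-mass tracking of the tail helix, residue-pair interaction-energy
maps, and sampling-coverage statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .dynamics import ForceFieldParams, _switch
from .structure import AtomSelection, Structure, kabsch, rmsd
from .trajectory import Trajectory

__all__ = [
    "FrameTransform",
    "COMTrack",
    "InteractionMap",
    "DegenerateInertiaError",
    "rmsf",
    "rmsd_series",
    "build_anchor_frame",
    "com_track",
    "interaction_map",
    "coverage_stats",
]


class DegenerateInertiaError(ValueError):
    """The two largest principal moments are equal within tolerance, leaving
    the frame's z-axis undefined; pass an explicit axis instead."""


@dataclass(frozen=True)
class FrameTransform:
    """Anchored orthonormal frame: p -> rotation @ (p - origin).

    Rows of ``rotation`` are the frame's x, y, z axes in lab coordinates.
    """

    origin: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        o = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation rows must be orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("frame must be right-handed")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "origin", o)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=float) - self.origin) @ self.rotation.T


@dataclass
class COMTrack:
    """Per-frame helix center of mass in the anchored frame."""

    xyz: np.ndarray  # (n_frames, 3)
    anchor_index: int
    helix_indices: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite COM track")

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self.xyz)), "x": self.x, "y": self.y, "z": self.z}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class InteractionMap:
    """Trajectory-mean residue-pair nonbonded energies (kcal/mol).

    ``total`` = ``electrostatic`` + ``vdw`` elementwise; rows are labeled by
    the residues of set A, columns by set B (author numbering).
    """

    total: np.ndarray
    electrostatic: np.ndarray
    vdw: np.ndarray
    resids_a: np.ndarray
    resids_b: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.total, self.electrostatic + self.vdw, atol=1e-10):
            raise ValueError("total must equal electrostatic + vdw")

    def to_dataframe(self, component: str = "total") -> pd.DataFrame:
        mat = getattr(self, component)
        return pd.DataFrame(mat, index=self.resids_a, columns=self.resids_b)

    def to_csv(self, path, component: str = "total") -> None:
        self.to_dataframe(component).to_csv(path)

    def ranked_contacts(self, n: int = 10) -> pd.DataFrame:
        """Strongest (most negative) residue-pair energies."""
        flat = self.total.ravel()
        order = np.argsort(flat)[:n]
        ia, ib = np.unravel_index(order, self.total.shape)
        return pd.DataFrame(
            {
                "resid_a": self.resids_a[ia],
                "resid_b": self.resids_b[ib],
                "energy": flat[order],
            }
        )


# ---------------------------------------------------------------------------


def rmsf(
    trajectory: Trajectory,
    selection: AtomSelection,
    reference: str = "mean",
) -> np.ndarray:
    """Per-atom RMSF (A) over the selection after best-fit superposition.

    ``reference`` is ``"frame0"`` or ``"mean"`` (two-pass: fit to frame 0,
    recompute the mean, refit to it).
    """
    if trajectory.n_frames < 2:
        raise ValueError("need at least 2 frames for RMSF")
    if reference not in ("mean", "frame0"):
        raise ValueError("reference must be 'mean' or 'frame0'")
    idx = selection.indices
    frames = trajectory.frames[:, idx, :]
    ref = frames[0]
    fitted = np.empty_like(frames)
    for f in range(frames.shape[0]):
        fitted[f] = kabsch(frames[f], ref).apply(frames[f])
    if reference == "mean":
        ref = fitted.mean(axis=0)
        for f in range(frames.shape[0]):
            fitted[f] = kabsch(frames[f], ref).apply(frames[f])
    mean = fitted.mean(axis=0)
    var = np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0)
    return np.sqrt(var)


def rmsd_series(
    trajectory: Trajectory,
    reference: np.ndarray,
    selection: AtomSelection,
    plateau_window: int = 20,
    plateau_slope_tol: float = 1e-3,
) -> tuple[np.ndarray, int | None]:
    """Per-frame best-fit RMSD to the reference over the selection.

    The plateau detector fits a line to each trailing window of the series
    and reports the first frame index at which the window slope (A/frame)
    drops below ``plateau_slope_tol`` in magnitude and stays below it for
    the remainder; returns ``None`` if never.
    """
    idx = selection.indices
    ref = np.asarray(reference, dtype=float)[idx]
    series = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        mob = trajectory.frames[f, idx, :]
        series[f] = rmsd(kabsch(mob, ref).apply(mob), ref)

    plateau = None
    n = series.size
    if n >= plateau_window:
        t = np.arange(plateau_window, dtype=float)
        t -= t.mean()
        denom = np.sum(t * t)
        slopes = np.full(n, np.inf)
        for end in range(plateau_window, n + 1):
            w = series[end - plateau_window : end]
            slopes[end - 1] = abs(np.sum(t * (w - w.mean())) / denom)
        below = slopes <= plateau_slope_tol
        # first index from which the criterion holds for good
        for f in range(n):
            if below[f:].all() and below[f]:
                plateau = max(0, f - plateau_window + 1)
                break
    if np.allclose(series, series[0], atol=1e-12):
        plateau = 0
    return series, plateau


def _inertia_tensor(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    com = np.average(coords, axis=0, weights=masses)
    d = coords - com
    r2 = np.sum(d * d, axis=1)
    eye = np.eye(3)
    return np.einsum("i,ijk->jk", masses, r2[:, None, None] * eye) - np.einsum(
        "i,ij,ik->jk", masses, d, d
    )


def build_anchor_frame(
    coords: np.ndarray,
    masses: np.ndarray,
    anchor_index: int,
    domain_indices: np.ndarray,
    degeneracy_tol: float = 1e-6,
) -> FrameTransform:
    """Anchored inertia frame of a structure snapshot.

    Origin = anchor atom position.  z = principal axis of the domain's
    inertia tensor with the LARGEST moment, signed to point from the domain
    center of mass toward the anchor ("away from the domain").  x = the
    middle principal axis (orthogonal to z by symmetry of the tensor), signed
    deterministically by the first domain atom's offset; y = z cross x.
    """
    coords = np.asarray(coords, dtype=float)
    dom = np.asarray(domain_indices, dtype=int)
    if dom.size < 3:
        raise ValueError("domain selection needs >= 3 atoms")
    m = np.asarray(masses, dtype=float)[dom]
    pts = coords[dom]
    inertia = _inertia_tensor(pts, m)
    moments, axes = np.linalg.eigh(inertia)  # ascending
    if (moments[2] - moments[1]) <= degeneracy_tol * max(moments[2], 1e-30):
        raise DegenerateInertiaError(
            f"two largest moments nearly equal ({moments[1]:.6g}, "
            f"{moments[2]:.6g}); choose the z-axis explicitly"
        )
    com = np.average(pts, axis=0, weights=m)
    z = axes[:, 2]
    away = coords[anchor_index] - com
    if np.dot(z, away) < 0:
        z = -z
    x = axes[:, 1]
    # deterministic sign for x: align with the first domain atom's offset
    for probe in range(dom.size):
        p = pts[probe] - com
        p -= np.dot(p, z) * z
        if np.linalg.norm(p) > 1e-8:
            if np.dot(x, p) < 0:
                x = -x
            break
    y = np.cross(z, x)
    rotation = np.vstack([x, y, z])
    return FrameTransform(origin=coords[anchor_index], rotation=rotation)


def com_track(
    trajectory: Trajectory,
    masses: np.ndarray,
    anchor_index: int,
    domain_indices: np.ndarray,
    helix_indices: np.ndarray,
) -> COMTrack:
    """Helix center of mass per frame, in the frame's own anchored inertia
    coordinate system (rebuilt every frame).

    z > 0 means the helix COM lies on the anchor side of the domain
    ("away"); z < 0 means it has approached past the domain center plane.
    """
    m_all = np.asarray(masses, dtype=float)
    helix = np.asarray(helix_indices, dtype=int)
    mh = m_all[helix]
    out = np.empty((trajectory.n_frames, 3))
    for f in range(trajectory.n_frames):
        coords = trajectory.frames[f]
        try:
            tf = build_anchor_frame(coords, m_all, anchor_index, domain_indices)
        except DegenerateInertiaError as exc:
            raise DegenerateInertiaError(f"frame {f}: {exc}") from exc
        com = np.average(coords[helix], axis=0, weights=mh)
        out[f] = tf.apply(com)
    return COMTrack(out, anchor_index, helix)


def interaction_map(
    trajectory: Trajectory,
    structure: Structure,
    set_a: AtomSelection,
    set_b: AtomSelection,
    params: ForceFieldParams,
    stride: int = 1,
) -> InteractionMap:
    """Trajectory-mean residue-pair nonbonded energies between two disjoint
    atom sets: switched Coulomb plus switched Lennard-Jones, using the
    simulation's own nonbonded parameters and truncation.  Pairs excluded by
    the force field (1-2/1-3) contribute zero.
    """
    ia = set_a.indices
    ib = set_b.indices
    if np.intersect1d(ia, ib).size:
        raise ValueError("set_a and set_b must be disjoint")
    res_a = np.unique(structure.resids[ia])
    res_b = np.unique(structure.resids[ib])
    pos_a = {r: i for i, r in enumerate(res_a)}
    pos_b = {r: i for i, r in enumerate(res_b)}
    row = np.array([pos_a[r] for r in structure.resids[ia]])
    col = np.array([pos_b[r] for r in structure.resids[ib]])

    excl = params.excluded_pairs()
    pair_ok = np.array(
        [
            [tuple(sorted((int(a), int(b)))) not in excl for b in ib]
            for a in ia
        ]
    )

    qq = (
        params.coulomb_constant
        * np.outer(params.charges[ia], params.charges[ib])
        / params.dielectric
    )
    eps = np.sqrt(np.outer(params.lj_eps[ia], params.lj_eps[ib]))
    rmin = params.lj_rmin_half[ia][:, None] + params.lj_rmin_half[ib][None, :]

    elec = np.zeros((res_a.size, res_b.size))
    vdw = np.zeros_like(elec)
    frames = trajectory.frames[::stride]
    for coords in frames:
        d = coords[ia][:, None, :] - coords[ib][None, :, :]
        r2 = np.sum(d * d, axis=-1)
        r = np.sqrt(r2)
        s, _ = _switch(r2, params.switch_on, params.switch_off)
        s = s * pair_ok
        e_cl = np.divide(qq, r, out=np.zeros_like(qq), where=r > 0) * s
        sr6 = (rmin / np.where(r > 0, r, np.inf)) ** 6
        e_lj = eps * (sr6 * sr6 - 2.0 * sr6) * s
        np.add.at(elec, (row[:, None], col[None, :]), e_cl)
        np.add.at(vdw, (row[:, None], col[None, :]), e_lj)
    n_frames = len(frames)
    elec /= n_frames
    vdw /= n_frames
    return InteractionMap(elec + vdw, elec, vdw, res_a, res_b)


@dataclass
class CoverageStats:
    hull_area: float
    radius_of_gyration: float
    extent_x: tuple[float, float]
    extent_y: tuple[float, float]
    n_points: int


def coverage_stats(track: COMTrack) -> CoverageStats:
    """Dispersion summaries of the (x, y) COM point cloud.

    Hull area is 0 for fewer than 3 distinct points or collinear sets.
    """
    pts = np.column_stack([track.x, track.y])
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    uniq = np.unique(pts, axis=0)
    area = 0.0
    if uniq.shape[0] >= 3:
        try:
            area = float(ConvexHull(uniq).volume)  # 2-D "volume" is area
        except QhullError:
            area = 0.0  # collinear
    center = pts.mean(axis=0)
    rgyr = float(np.sqrt(np.mean(np.sum((pts - center) ** 2, axis=1))))
    return CoverageStats(
        hull_area=area,
        radius_of_gyration=rgyr,
        extent_x=(float(pts[:, 0].min()), float(pts[:, 0].max())),
        extent_y=(float(pts[:, 1].min()), float(pts[:, 1].max())),
        n_points=pts.shape[0],
    )
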