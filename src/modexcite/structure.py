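"""Structures, PDB I/O, atom selection, superposition and segment grafting.

A :class:`Structure` is a flat, array-backed record of atoms (one bead per
residue in the synthetic systems, but nothing here assumes that).  Residue
numbers are 1-based author numbering and all residue ranges are inclusive on
both ends.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import DEFAULT_BEAD_MASS

__all__ = [
    "Structure",
    "AtomSelection",
    "RigidTransform",
    "PDBParseError",
    "SelectionError",
    "GraftResult",
    "read_pdb",
    "write_pdb",
    "select",
    "superpose",
    "graft_segment",
    "kabsch",
    "rmsd",
]


class PDBParseError(ValueError):
    """Raised for malformed or unsupported PDB records."""


class SelectionError(ValueError):
    """Raised for syntactically invalid selection expressions."""


@dataclass
class Structure:
    """Array-backed molecular structure.

    All per-atom arrays share the same length N; ``coords`` has shape (N, 3).
    """

    names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    lj_eps: np.ndarray
    lj_rmin_half: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        self.names = np.asarray(self.names, dtype="U4")
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype="U4")
        self.chains = np.asarray(self.chains, dtype="U1")
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_eps = np.asarray(self.lj_eps, dtype=float)
        self.lj_rmin_half = np.asarray(self.lj_rmin_half, dtype=float)
        for arr, label in [
            (self.names, "names"),
            (self.resids, "resids"),
            (self.resnames, "resnames"),
            (self.chains, "chains"),
            (self.masses, "masses"),
            (self.charges, "charges"),
            (self.lj_eps, "lj_eps"),
            (self.lj_rmin_half, "lj_rmin_half"),
        ]:
            if arr.shape[0] != n:
                raise ValueError(f"{label} length {arr.shape[0]} != {n} atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        keys = list(zip(self.chains, self.resids, self.names))
        if len(set(keys)) != n:
            raise ValueError("(chain, resid, atom name) triplets must be unique")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Structure":
        return Structure(
            names=self.names.copy(),
            resids=self.resids.copy(),
            resnames=self.resnames.copy(),
            chains=self.chains.copy(),
            coords=self.coords.copy(),
            masses=self.masses.copy(),
            charges=self.charges.copy(),
            lj_eps=self.lj_eps.copy(),
            lj_rmin_half=self.lj_rmin_half.copy(),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float).copy())

    def subset(self, indices: np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            names=self.names[idx],
            resids=self.resids[idx],
            resnames=self.resnames[idx],
            chains=self.chains[idx],
            coords=self.coords[idx],
            masses=self.masses[idx],
            charges=self.charges[idx],
            lj_eps=self.lj_eps[idx],
            lj_rmin_half=self.lj_rmin_half[idx],
        )

    @classmethod
    def from_beads(
        cls,
        coords: np.ndarray,
        resids: np.ndarray | None = None,
        masses: np.ndarray | float = DEFAULT_BEAD_MASS,
        charges: np.ndarray | float = 0.0,
        lj_eps: np.ndarray | float = 0.0,
        lj_rmin_half: np.ndarray | float = 2.0,
        chain: str = "A",
        resname: str = "BEA",
        name: str = "CA",
    ) -> "Structure":
        """Build a one-atom-per-residue bead structure."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = coords.shape[0]
        if resids is None:
            resids = np.arange(1, n + 1)
        return cls(
            names=np.full(n, name),
            resids=np.asarray(resids, dtype=int),
            resnames=np.full(n, resname),
            chains=np.full(n, chain),
            coords=coords,
            masses=np.broadcast_to(np.asarray(masses, float), (n,)).copy(),
            charges=np.broadcast_to(np.asarray(charges, float), (n,)).copy(),
            lj_eps=np.broadcast_to(np.asarray(lj_eps, float), (n,)).copy(),
            lj_rmin_half=np.broadcast_to(np.asarray(lj_rmin_half, float), (n,)).copy(),
        )


@dataclass(frozen=True)
class AtomSelection:
    """Sorted, unique atom indices into a Structure."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("selection indices must be 1-D")
        if idx.size and (np.any(np.diff(idx) <= 0)):
            raise ValueError("selection indices must be strictly ascending")
        if idx.size and idx.min() < 0:
            raise ValueError("negative selection index")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)

    def __iter__(self):
        return iter(self.indices)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(r) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthogonal")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


# ---------------------------------------------------------------------------
# PDB I/O (fixed columns; only ATOM/HETATM/MODEL/ENDMDL/TER/END are honoured)
# ---------------------------------------------------------------------------

def read_pdb(path) -> Structure:
    """Parse ATOM/HETATM records from a PDB file.

    Keeps the first altloc of each atom; insertion codes are rejected.
    Masses/charges/LJ parameters are not present in PDB and are filled with
    bead defaults.
    """
    names, resids, resnames, chains, xyz = [], [], [], [], []
    seen_altloc: dict[tuple, str] = {}
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {lineno}: truncated ATOM record")
            name = line[12:16].strip()
            altloc = line[16]
            resname = line[17:20].strip()
            chain = line[21].strip() or "A"
            icode = line[26]
            if icode != " ":
                raise PDBParseError(
                    f"line {lineno}: insertion codes are not supported"
                )
            try:
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: {exc}") from exc
            key = (chain, resid, name)
            if key in seen_altloc:
                continue  # keep first altloc only
            seen_altloc[key] = altloc
            names.append(name)
            resids.append(resid)
            resnames.append(resname)
            chains.append(chain)
            xyz.append((x, y, z))
            n_records += 1
    if n_records == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    n = n_records
    return Structure(
        names=np.array(names),
        resids=np.array(resids),
        resnames=np.array(resnames),
        chains=np.array(chains),
        coords=np.array(xyz),
        masses=np.full(n, DEFAULT_BEAD_MASS),
        charges=np.zeros(n),
        lj_eps=np.zeros(n),
        lj_rmin_half=np.full(n, 2.0),
    )


def _format_atom_line(i: int, s: Structure, serial: int) -> str:
    name = s.names[i]
    # PDB column convention: 1-3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{'':1s}{s.resnames[i]:<3s} "
        f"{s.chains[i]:1s}{s.resids[i]:4d}    "
        f"{s.coords[i, 0]:8.3f}{s.coords[i, 1]:8.3f}{s.coords[i, 2]:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}\n"
    )


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure as fixed-column ATOM records."""
    with open(path, "w") as fh:
        for i in range(structure.n_atoms):
            fh.write(_format_atom_line(i, structure, serial=i + 1))
        fh.write("END\n")


def write_multimodel_pdb(structure: Structure, frames: np.ndarray, path) -> None:
    """Write trajectory frames as a multi-model PDB."""
    frames = np.asarray(frames, dtype=float)
    with open(path, "w") as fh:
        for m, frame in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            s = structure.with_coords(frame)
            for i in range(s.n_atoms):
                fh.write(_format_atom_line(i, s, serial=i + 1))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selection grammar:
#   expr   := term ("or" term)*
#   term   := factor ("and" factor)*
#   factor := "(" expr ")" | "not" factor | "resid" ranges | "name" names | "all"
#   ranges := range ("," range)*       range := INT | INT ":" INT
#   names  := WORD ("," WORD)*
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|,|:|[A-Za-z_][A-Za-z0-9_*']*|-?\d+|\S")


class _Parser:
    def __init__(self, text: str, structure: Structure):
        self.tokens = _TOKEN_RE.findall(text)
        self.pos = 0
        self.s = structure

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def expect(self, tok: str):
        got = self.next()
        if got != tok:
            raise SelectionError(f"expected {tok!r}, got {got!r}")

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens at {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.next()
        if tok == "(":
            mask = self.expr()
            self.expect(")")
            return mask
        if tok == "not":
            return ~self.factor()
        if tok == "all":
            return np.ones(self.s.n_atoms, dtype=bool)
        if tok == "resid":
            return self.resid_ranges()
        if tok == "name":
            return self.name_list()
        raise SelectionError(f"unexpected token {tok!r}")

    def resid_ranges(self) -> np.ndarray:
        mask = np.zeros(self.s.n_atoms, dtype=bool)
        while True:
            tok = self.next()
            try:
                lo = int(tok)
            except ValueError:
                raise SelectionError(f"expected residue number, got {tok!r}")
            hi = lo
            if self.peek() == ":":
                self.next()
                tok = self.next()
                try:
                    hi = int(tok)
                except ValueError:
                    raise SelectionError(f"expected residue number, got {tok!r}")
            mask |= (self.s.resids >= lo) & (self.s.resids <= hi)
            if self.peek() == ",":
                self.next()
                continue
            return mask

    def name_list(self) -> np.ndarray:
        mask = np.zeros(self.s.n_atoms, dtype=bool)
        while True:
            tok = self.next()
            if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_*']*", tok):
                raise SelectionError(f"invalid atom name {tok!r}")
            mask |= self.s.names == tok
            if self.peek() == ",":
                self.next()
                continue
            return mask


def select(structure: Structure, spec: str) -> AtomSelection:
    """Evaluate a selection expression against a structure.

    The grammar supports inclusive residue ranges (``resid 1:172``), atom
    name filters (``name CA``), ``and``/``or``/``not`` and parentheses.  An
    empty match is legal.
    """
    if not spec or not spec.strip():
        raise SelectionError("empty selection expression")
    mask = _Parser(spec, structure).parse()
    return AtomSelection(np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares optimal proper rigid transform mapping mobile -> reference.

    det(rotation) = +1 is enforced by flipping the smallest singular vector in
    the reflection branch.
    """
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(reference, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    if p.shape[0] < 3:
        raise ValueError("need at least 3 atoms for a rigid fit")
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, sing, vt = np.linalg.svd(h)
    if sing[1] < 1e-12 * max(sing[0], 1.0):
        raise ValueError("degenerate fit: selection is (near-)collinear")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qc - rot @ pc
    return RigidTransform(rot, trans)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no-fit) RMSD between coordinate arrays of equal shape."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def superpose(
    mobile: Structure,
    reference: Structure,
    selection: AtomSelection | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the transform and the post-fit RMSD over the selection.
    """
    idx = selection.indices if selection is not None else np.arange(mobile.n_atoms)
    if idx.size and idx.max() >= min(mobile.n_atoms, reference.n_atoms):
        raise ValueError("selection index out of range")
    pm = mobile.coords[idx]
    pr = reference.coords[idx]
    tf = kabsch(pm, pr)
    return tf, rmsd(tf.apply(pm), pr)


# ---------------------------------------------------------------------------
# Segment grafting
# ---------------------------------------------------------------------------

@dataclass
class GraftResult:
    structure: Structure
    overlap_rmsd: float
    junction_distance: float | None
    transform: RigidTransform = field(repr=False, default=None)


def _resid_range_indices(s: Structure, resid_range: tuple[int, int]) -> np.ndarray:
    lo, hi = resid_range
    return np.flatnonzero((s.resids >= lo) & (s.resids <= hi))


def graft_segment(
    base: Structure,
    donor: Structure,
    overlap_resids: tuple[int, int],
    graft_resids: tuple[int, int] | None,
) -> GraftResult:
    """Complete ``base`` with residues from ``donor``.

    The donor is rigidly superposed onto the base over ``overlap_resids``
    (atoms matched by (resid, atom name)); atoms of ``graft_resids`` are then
    copied, transformed, into the result.  The result is sorted by residue
    number.  ``graft_resids=None`` means an empty graft.
    """
    idx_base = _resid_range_indices(base, overlap_resids)
    idx_donor = _resid_range_indices(donor, overlap_resids)
    if idx_base.size == 0 or idx_donor.size == 0:
        raise ValueError(
            f"overlap residues {overlap_resids[0]}:{overlap_resids[1]} missing "
            "from base or donor"
        )
    # match overlap atoms across structures by (resid, name)
    key_base = {(base.resids[i], base.names[i]): i for i in idx_base}
    pairs = [
        (key_base[(donor.resids[j], donor.names[j])], j)
        for j in idx_donor
        if (donor.resids[j], donor.names[j]) in key_base
    ]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 matched overlap atoms")
    bi = np.array([p[0] for p in pairs])
    dj = np.array([p[1] for p in pairs])
    tf = kabsch(donor.coords[dj], base.coords[bi])
    fit_rmsd = rmsd(tf.apply(donor.coords[dj]), base.coords[bi])

    if graft_resids is None:
        return GraftResult(base.copy(), fit_rmsd, None, tf)

    idx_graft = _resid_range_indices(donor, graft_resids)
    if idx_graft.size == 0:
        raise ValueError(
            f"graft residues {graft_resids[0]}:{graft_resids[1]} absent from donor"
        )
    clash = set(base.resids) & set(donor.resids[idx_graft])
    if clash:
        raise ValueError(f"graft residues already present in base: {sorted(clash)}")

    grafted = donor.subset(idx_graft)
    grafted = grafted.with_coords(tf.apply(grafted.coords))
    merged = Structure(
        names=np.concatenate([base.names, grafted.names]),
        resids=np.concatenate([base.resids, grafted.resids]),
        resnames=np.concatenate([base.resnames, grafted.resnames]),
        chains=np.concatenate([base.chains, grafted.chains]),
        coords=np.concatenate([base.coords, grafted.coords]),
        masses=np.concatenate([base.masses, grafted.masses]),
        charges=np.concatenate([base.charges, grafted.charges]),
        lj_eps=np.concatenate([base.lj_eps, grafted.lj_eps]),
        lj_rmin_half=np.concatenate([base.lj_rmin_half, grafted.lj_rmin_half]),
    )
    order = np.lexsort((merged.resids,))
    merged = merged.subset(order)

    # junction geometry: last base residue below the graft vs first grafted
    graft_lo = int(grafted.resids.min())
    below = base.resids[base.resids < graft_lo]
    junction = None
    if below.size:
        last_base = int(below.max())
        a = merged.coords[merged.resids == last_base].mean(axis=0)
        b = merged.coords[merged.resids == graft_lo].mean(axis=0)
        junction = float(np.linalg.norm(a - b))
    return GraftResult(merged, fit_rmsd, junction, tf)
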