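"""Coordinate I/O and superposition primitives.

Wraps gemmi for PDB/mmCIF reading and exposes a small, explicit object
model (:class:`StructureModel` / :class:`ResidueView`) tailored to the
descriptor layer: author residue numbering is authoritative (residue
labels such as Pro2, K/R242, Y244, Gly240/Gly249 refer to full-length
hNEIL1 numbering), alternate locations are resolved to a single conformer
at parse time, hydrogens are dropped (the X-ray models carry none; all
geometry downstream is heavy-atom based), and waters are separated from
the polymer.

A minimal PDB writer (ATOM/HETATM records, 3-decimal coordinates) is
included for generating plain-text fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ResidueView",
    "read_structure",
    "write_pdb",
    "select_residue",
    "superpose",
    "RigidTransform",
]

WATER_NAMES = {"HOH", "WAT", "H2O"}


class StructureParseError(ValueError):
    """File could not be parsed as a coordinate file."""


class MissingAtomError(KeyError):
    """A named atom is absent from a residue."""


class MissingResidueError(KeyError):
    """A residue lookup (chain, author number) found nothing."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: coordinates must be finite 3-vectors")


@dataclass
class Residue:
    chain: str
    number: int  # author numbering
    name: str
    atoms: list[Atom] = field(default_factory=list)
    is_water: bool = False

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise MissingAtomError(
            f"residue {self.chain}/{self.name}{self.number} has no atom {name!r}; "
            f"available: {[a.name for a in self.atoms]}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Heavy-atom coordinates, optionally restricted to named atoms."""
        if names is None:
            return np.array([a.pos for a in self.atoms])
        return np.array([self.atom(n).pos for n in names])


@dataclass
class StructureModel:
    """One coordinate set: polymer/hetero residues plus separated waters."""

    identifier: str
    residues: list[Residue] = field(default_factory=list)
    waters: list[Residue] = field(default_factory=list)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    def residue(self, chain: str, number: int) -> Residue:
        for r in self.residues:
            if r.chain == chain and r.number == number:
                return r
        avail = sorted({rr.number for rr in self.residues if rr.chain == chain})
        raise MissingResidueError(
            f"no residue {number} in chain {chain!r} of {self.identifier}; "
            f"available numbers: {avail}"
        )

    def has_residue(self, chain: str, number: int) -> bool:
        return any(r.chain == chain and r.number == number for r in self.residues)

    def all_atoms(self) -> Iterable[tuple[Residue, Atom]]:
        for r in (*self.residues, *self.waters):
            for a in r.atoms:
                yield r, a

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in (*self.residues, *self.waters))

    def transformed(self, transform: "RigidTransform") -> "StructureModel":
        """A deep copy with the rigid transform applied to every atom."""
        out = StructureModel(self.identifier)
        for group_in, group_out in ((self.residues, out.residues), (self.waters, out.waters)):
            for r in group_in:
                rr = Residue(r.chain, r.number, r.name, [], r.is_water)
                for a in r.atoms:
                    rr.atoms.append(
                        Atom(a.name, a.element, transform.apply(a.pos), a.occupancy, a.altloc)
                    )
                group_out.append(rr)
        return out

    def ca_positions(self, chain: str | None = None) -> dict[int, np.ndarray]:
        """Author residue number -> Calpha position for one (or any) chain."""
        out = {}
        for r in self.residues:
            if chain is not None and r.chain != chain:
                continue
            if r.has_atom("CA"):
                out[r.number] = r.atom("CA").pos
        return out


@dataclass(frozen=True)
class ResidueView:
    """Read-only convenience view over one residue of a StructureModel."""

    residue: Residue

    @property
    def name(self) -> str:
        return self.residue.name

    @property
    def number(self) -> int:
        return self.residue.number

    @property
    def chain(self) -> str:
        return self.residue.chain

    def atom(self, name: str) -> Atom:
        return self.residue.atom(name)

    def coords(self, names: Sequence[str] | None = None) -> np.ndarray:
        return self.residue.coords(names)

    def heavy_coords(self) -> np.ndarray:
        return self.residue.coords()


def read_structure(path, fmt: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``fmt`` is one of ``{"pdb", "mmcif", "auto"}``.  The first model of
    the file is used.  Alternate locations are resolved by keeping the
    highest-occupancy conformer (ties broken by altloc letter order);
    hydrogens are dropped; residues named HOH/WAT/H2O become waters.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise ValueError(f"unknown format {fmt!r}; expected pdb, mmcif or auto")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no model")
    model = st[0]
    out = StructureModel(identifier=st.name or path.stem)
    for chain in model:
        for res in chain:
            is_water = res.name.upper() in WATER_NAMES
            rr = Residue(
                chain=chain.name,
                number=res.seqid.num,
                name=res.name,
                is_water=is_water,
            )
            for atom in _resolve_altlocs(res):
                if atom.element.is_hydrogen:
                    continue
                rr.atoms.append(
                    Atom(
                        name=atom.name,
                        element=atom.element.name,
                        pos=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                        altloc=atom.altloc or "",
                    )
                )
            if not rr.atoms:
                continue
            (out.waters if is_water else out.residues).append(rr)
    if out.n_atoms() == 0:
        raise StructureParseError(f"{path}: empty model (no atoms)")
    return out


def _resolve_altlocs(res: "gemmi.Residue"):
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        key_new = (-atom.occ, atom.altloc or "~")
        key_old = (-prev.occ, prev.altloc or "~")
        if key_new < key_old:
            by_name[atom.name] = atom
    return by_name.values()


def write_pdb(model: StructureModel, path) -> None:
    """Write a minimal PDB file (ATOM/HETATM, 3-decimal coordinates)."""
    lines = []
    serial = 1
    for group, hetero in ((model.residues, False), (model.waters, True)):
        for r in group:
            record = "HETATM" if (hetero or _is_het(r)) else "ATOM  "
            for a in r.atoms:
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"{record}{serial:5d} {name:<4.4s} {r.name:<3.3s} {r.chain:1.1s}"
                    f"{r.number:4d}    {a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
                )
                serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "DA", "DC", "DG", "DT", "DU", "A", "C", "G", "U",
}


def _is_het(r: Residue) -> bool:
    return r.name.upper() not in _STANDARD_RESIDUES


def select_residue(model: StructureModel, chain: str, resnum: int) -> ResidueView:
    """View over one residue addressed by chain id and author number."""
    return ResidueView(model.residue(chain, resnum))


@dataclass(frozen=True)
class RigidTransform:
    """x -> R x + t rigid-body transform."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    @property
    def angle_deg(self) -> float:
        """Magnitude of the rotation in degrees."""
        return float(np.degrees(Rotation.from_matrix(self.rotation).magnitude()))

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


class GeometryError(ValueError):
    """Degenerate geometry (too few or collinear points)."""


def superpose(
    mobile_xyz, reference_xyz
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch) of paired coordinates.

    ``mobile_xyz`` and ``reference_xyz`` are (n, 3) arrays of paired
    positions, n >= 3 and non-collinear.  Returns the transform that maps
    mobile onto reference and the post-fit RMSD over the selection.
    """
    P = np.asarray(mobile_xyz, dtype=float)
    Q = np.asarray(reference_xyz, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"paired (n, 3) arrays required, got {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise GeometryError(f"need >= 3 paired atoms, got {len(P)}")
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - Pc, Q - Qc
    if _collinear(P0) or _collinear(Q0):
        raise GeometryError("selection is collinear; superposition underdetermined")
    rot, rssd = Rotation.align_vectors(Q0, P0)
    R = rot.as_matrix()
    t = Qc - R @ Pc
    rmsd = float(rssd / math.sqrt(len(P)))
    return RigidTransform(R, t), rmsd


def _collinear(centered: np.ndarray, tol: float = 1e-8) -> bool:
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def superpose_models(
    mobile: StructureModel,
    reference: StructureModel,
    pairs: Sequence[tuple[tuple[str, int, str], tuple[str, int, str]]] | None = None,
    chain: str | None = None,
) -> tuple[RigidTransform, float]:
    """Superpose two models over an atom-pair selection.

    ``pairs`` lists ((chain, resnum, atom), (chain, resnum, atom))
    correspondences; when omitted, all shared Calpha atoms of ``chain``
    (or the whole model) are paired by author residue number.
    """
    if pairs is None:
        ca_m = mobile.ca_positions(chain)
        ca_r = reference.ca_positions(chain)
        shared = sorted(set(ca_m) & set(ca_r))
        P = np.array([ca_m[i] for i in shared])
        Q = np.array([ca_r[i] for i in shared])
    else:
        P = np.array([mobile.residue(c, n).atom(a).pos for (c, n, a), _ in pairs])
        Q = np.array([reference.residue(c, n).atom(a).pos for _, (c, n, a) in pairs])
    if len(P) < 3:
        raise GeometryError(f"need >= 3 paired atoms, got {len(P)}")
    return superpose(P, Q)
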