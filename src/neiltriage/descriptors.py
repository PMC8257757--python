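"""Geometric descriptors of the hNEIL1 lesion-recognition loop.

The loop (Gly240–Gly249 in full-length numbering) carries two probe
residues whose positions relative to the flipped base operationalize the
three recognition states:

* ``d242`` — minimum distance from the terminal side-chain nitrogen(s) of
  residue 242 (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2) to any heavy atom of
  the flipped base.  ~3.0 A in the activated (242-in) conformers, where a
  tautomerization-dependent hydrogen bond forms; >9 A in the apo loop.
* ``d244`` — distance between the ring centroid of residue 244 (Tyr) and
  the base ring centroid; ~3.4–3.8 A when Tyr244 stacks on the base in
  the quarantine (244-in) conformation.
* a heavy-atom hydrogen-bond flag for the 242–base contact (donor–
  acceptor distance criterion only; crystallographic models carry no
  hydrogens, so no angle term is applied);
* a loop rotation angle about the Gly240–Gly249 Calpha hinge relative to
  a reference conformer (~40 degrees between apo and base-bound loops);
* solvation-shell water counts around the base (default 5 A shell) and
  the per-distance-bin desolvation difference dN_water between 242-in
  and 244-in ensembles.

Descriptors whose required atoms are missing (e.g. the loop segment was
unbuildable in the density) are returned as not-available (None/NaN)
with an explanatory flag, never silently imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .structio import MissingAtomError, ResidueView, StructureModel, superpose

__all__ = [
    "LoopDescriptor",
    "TERMINAL_NITROGENS",
    "RING_ATOMS_RESIDUE",
    "BASE_RING_ATOMS",
    "compute_d242",
    "compute_d244",
    "detect_tautomer_hbond",
    "loop_rotation_angle",
    "count_shell_waters",
    "delta_n_water",
    "compute_descriptors",
    "descriptors_to_frame",
    "write_descriptor_csv",
    "read_descriptor_csv",
]

#: Terminal side-chain nitrogen atoms probing the flipped base, per
#: residue type at position 242 (wild-type Lys, RNA-edited Arg, R242H).
TERMINAL_NITROGENS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}

#: Aromatic-ring atom names for residue 244 (and common substitutions).
RING_ATOMS_RESIDUE = {
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
_PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")

#: Heterocycle ring atoms per nucleotide / lesion residue name.  Lesions
#: handled here keep the pyrimidine ring skeleton (Tg, DHU, DHT, 5-OHU and
#: the non-cleavable FDHU mimic); hydantoin lesions (Sp, Gh) have
#: rearranged rings and fall back to all base heavy atoms, flagged.
BASE_RING_ATOMS = {
    "DT": _PYRIMIDINE_RING,
    "DC": _PYRIMIDINE_RING,
    "DU": _PYRIMIDINE_RING,
    "T": _PYRIMIDINE_RING,
    "C": _PYRIMIDINE_RING,
    "U": _PYRIMIDINE_RING,
    "TG": _PYRIMIDINE_RING,
    "DHU": _PYRIMIDINE_RING,
    "DHT": _PYRIMIDINE_RING,
    "5OU": _PYRIMIDINE_RING,
    "OHU": _PYRIMIDINE_RING,
    "FDU": _PYRIMIDINE_RING,
    "DA": _PURINE_RING,
    "DG": _PURINE_RING,
    "A": _PURINE_RING,
    "G": _PURINE_RING,
}

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
_SUGAR_PHOSPHATE = {"P", "OP1", "OP2", "OP3"}


class DescriptorNotAvailable(ValueError):
    """Raised internally when required atoms are missing; callers of the
    high-level API receive a NaN descriptor with a reason flag instead."""


@dataclass
class LoopDescriptor:
    """Per-structure/snapshot geometric summary of the recognition loop.

    Distances in angstrom; ``rotation_deg`` in [0, 180] when available.
    Not-available values are ``None`` and listed in ``not_available``
    together with the reason.
    """

    source: str = ""
    d242: float | None = None
    d244: float | None = None
    hbond_242_base: bool | None = None
    hbond_distance: float | None = None
    rotation_deg: float | None = None
    n_waters_shell: int | None = None
    not_available: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("d242", "d244", "hbond_distance"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.rotation_deg is not None and not 0 <= self.rotation_deg <= 180:
            raise ValueError(f"rotation_deg must lie in [0, 180], got {self.rotation_deg}")


def _base_heavy_coords(base: ResidueView) -> np.ndarray:
    """Heavy atoms of the base moiety: no sugar (primed names), no phosphate."""
    coords = [
        a.pos
        for a in base.residue.atoms
        if "'" not in a.name and a.name not in _SUGAR_PHOSPHATE
    ]
    if not coords:
        raise DescriptorNotAvailable(f"base residue {base.name}{base.number} has no base heavy atoms")
    return np.array(coords)


def _terminal_nitrogen_coords(res242: ResidueView) -> np.ndarray:
    """Probe atoms of residue 242 (see TERMINAL_NITROGENS; fallbacks below)."""
    res = res242.residue
    side = [a for a in res.atoms if a.name not in _BACKBONE_ATOMS]
    if not side or all(a.name in ("CB",) for a in side):
        raise DescriptorNotAvailable(
            f"residue {res.name}{res.number}: side chain truncated, no probe atoms"
        )
    names = TERMINAL_NITROGENS.get(res.name.upper())
    if names is not None:
        coords = [res.atom(n).pos for n in names if res.has_atom(n)]
        if not coords:
            raise DescriptorNotAvailable(
                f"residue {res.name}{res.number}: terminal nitrogen(s) {names} missing"
            )
        return np.array(coords)
    # unknown residue type: any side-chain N, else all side-chain heavy atoms
    n_atoms = [a.pos for a in side if a.element.upper() == "N"]
    if n_atoms:
        return np.array(n_atoms)
    return np.array([a.pos for a in side])


def compute_d242(model: StructureModel, loop_chain: str, base: ResidueView, resnum: int = 242) -> float:
    """Minimum terminal-N(242) to base heavy-atom distance, angstrom."""
    res = ResidueView(model.residue(loop_chain, resnum))
    probes = _terminal_nitrogen_coords(res)
    targets = _base_heavy_coords(base)
    d = np.linalg.norm(probes[:, None, :] - targets[None, :, :], axis=2)
    return float(d.min())


def _ring_centroid(view: ResidueView, ring_names: Sequence[str], what: str) -> tuple[np.ndarray, bool]:
    """Mean position of the ring atoms; falls back to all heavy atoms."""
    res = view.residue
    present = [n for n in ring_names if res.has_atom(n)]
    if len(present) == len(ring_names):
        return res.coords(present).mean(axis=0), False
    raise DescriptorNotAvailable(f"{what}: ring atoms incomplete ({present} of {list(ring_names)})")


def compute_d244(
    model: StructureModel, loop_chain: str, base: ResidueView, resnum: int = 244
) -> tuple[float, bool]:
    """Residue-244 ring centroid to base ring centroid distance.

    Returns ``(distance, fallback_flag)``; the flag is True when either
    centroid had to fall back from the canonical ring-atom set (non-
    aromatic residue 244 -> side-chain centroid; unknown lesion -> all
    base heavy atoms).
    """
    res = ResidueView(model.residue(loop_chain, resnum))
    fallback = False
    ring_names = RING_ATOMS_RESIDUE.get(res.name.upper())
    if ring_names is not None:
        try:
            c_res, _ = _ring_centroid(res, ring_names, f"residue {res.name}{resnum}")
        except DescriptorNotAvailable:
            c_res, fallback = _side_chain_centroid(res), True
    else:
        c_res, fallback = _side_chain_centroid(res), True

    base_ring = BASE_RING_ATOMS.get(base.name.upper())
    if base_ring is not None and all(base.residue.has_atom(n) for n in base_ring):
        c_base = base.residue.coords(base_ring).mean(axis=0)
    else:
        c_base = _base_heavy_coords(base).mean(axis=0)
        fallback = True
    return float(np.linalg.norm(c_res - c_base)), fallback


def _side_chain_centroid(view: ResidueView) -> np.ndarray:
    side = [a.pos for a in view.residue.atoms if a.name not in _BACKBONE_ATOMS]
    if not side:
        raise DescriptorNotAvailable(
            f"residue {view.name}{view.number}: no side-chain atoms for centroid"
        )
    return np.mean(side, axis=0)


def detect_tautomer_hbond(
    model: StructureModel,
    base: ResidueView,
    loop_chain: str,
    resnum: int = 242,
    cutoff: float = 3.5,
) -> tuple[bool, float]:
    """Heavy-atom hydrogen-bond test between residue 242 and the base.

    Minimum distance between the terminal nitrogen(s) of residue 242 and
    the nitrogen/oxygen atoms of the base heterocycle; the flag is True
    when that distance is <= ``cutoff`` (inclusive; default 3.5 A, the
    observed activated-state contact is ~3.0 A).  Distance-only
    criterion — no donor-hydrogen angle term, as the models carry no
    hydrogens.
    """
    res = ResidueView(model.residue(loop_chain, resnum))
    probes = _terminal_nitrogen_coords(res)
    acceptors = [
        a.pos
        for a in base.residue.atoms
        if "'" not in a.name
        and a.name not in _SUGAR_PHOSPHATE
        and a.element.upper() in ("N", "O")
    ]
    if not acceptors:
        raise DescriptorNotAvailable(
            f"base {base.name}{base.number}: no heterocycle N/O acceptor atoms"
        )
    acceptors = np.array(acceptors)
    d = np.linalg.norm(probes[:, None, :] - acceptors[None, :, :], axis=2)
    dmin = float(d.min())
    return dmin <= cutoff, dmin


def loop_rotation_angle(
    model: StructureModel,
    reference: StructureModel,
    chain: str | None = None,
    hinge: tuple[int, int] = (240, 249),
    apex: int = 244,
) -> float:
    """Loop rotation (degrees) about the Gly240–Gly249 Calpha hinge.

    The mobile model is first superposed on the reference over all shared
    Calpha atoms outside the loop span; the loop plane of each structure
    is taken through (Calpha hinge-start, Calpha apex, Calpha hinge-end)
    and the rotation is the angle between the two apex directions after
    projecting out the hinge-axis component.  Symmetric in its arguments
    and returned in [0, 180].
    """
    lo, hi = min(hinge), max(hinge)
    ca_m = model.ca_positions(chain)
    ca_r = reference.ca_positions(chain)
    for num in (*hinge, apex):
        if num not in ca_m or num not in ca_r:
            raise DescriptorNotAvailable(f"Calpha of residue {num} missing in one structure")
    core = sorted(n for n in set(ca_m) & set(ca_r) if not lo <= n <= hi)
    if len(core) >= 3:
        transform, _ = superpose(
            np.array([ca_m[n] for n in core]), np.array([ca_r[n] for n in core])
        )
        ca_m = {n: transform.apply(p) for n, p in ca_m.items()}

    def apex_perp(ca: dict[int, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        axis = ca[hi] - ca[lo]
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise DescriptorNotAvailable("hinge Calpha atoms coincide")
        axis = axis / norm
        v = ca[apex] - ca[lo]
        return axis, v - np.dot(v, axis) * axis

    axis_m, vm = apex_perp(ca_m)
    axis_r, vr = apex_perp(ca_r)
    nm, nr = np.linalg.norm(vm), np.linalg.norm(vr)
    if nm < 1e-9 or nr < 1e-9:
        raise DescriptorNotAvailable("loop apex lies on the hinge axis; rotation undefined")
    cosang = np.clip(np.dot(vm / nm, vr / nr), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def count_shell_waters(model: StructureModel, base: ResidueView, radius: float = 5.0) -> int:
    """Number of water oxygens within ``radius`` of any base heavy atom."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if radius == 0 or not model.waters:
        return 0
    targets = _base_heavy_coords(base)
    count = 0
    for w in model.waters:
        for a in w.atoms:
            if a.element.upper() != "O":
                continue
            if np.linalg.norm(targets - a.pos, axis=1).min() <= radius:
                count += 1
    return count


def delta_n_water(ensemble_A, ensemble_Q, bin_edges) -> np.ndarray:
    """Per-distance-bin desolvation difference dN_water.

    ``ensemble_A`` / ``ensemble_Q`` are lists of per-snapshot water
    distances (to the base) for the 242-in and 244-in ensembles.  Each
    snapshot's distances are histogrammed on ``bin_edges``; the result is
    mean count per bin in A minus mean count per bin in Q — the number of
    waters shed per bin when the loop transits from 242-in to 244-in.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be a strictly increasing 1D sequence")
    if len(ensemble_A) == 0 or len(ensemble_Q) == 0:
        raise ValueError("both ensembles must be non-empty")

    def mean_counts(ensemble) -> np.ndarray:
        counts = np.array(
            [np.histogram(np.asarray(d, dtype=float), bins=edges)[0] for d in ensemble]
        )
        return counts.mean(axis=0)

    return mean_counts(ensemble_A) - mean_counts(ensemble_Q)


def compute_descriptors(
    model: StructureModel,
    loop_chain: str,
    base: ResidueView,
    reference: StructureModel | None = None,
    hbond_cutoff: float = 3.5,
    shell_radius: float = 5.0,
    source: str | None = None,
) -> LoopDescriptor:
    """All descriptors for one structure; missing pieces become NA flags."""
    desc = LoopDescriptor(source=source if source is not None else model.identifier)
    try:
        desc.d242 = compute_d242(model, loop_chain, base)
    except (DescriptorNotAvailable, KeyError) as exc:
        desc.not_available["d242"] = str(exc)
    try:
        desc.d244, _ = compute_d244(model, loop_chain, base)
    except (DescriptorNotAvailable, KeyError) as exc:
        desc.not_available["d244"] = str(exc)
    try:
        desc.hbond_242_base, desc.hbond_distance = detect_tautomer_hbond(
            model, base, loop_chain, cutoff=hbond_cutoff
        )
    except (DescriptorNotAvailable, KeyError) as exc:
        desc.not_available["hbond_242_base"] = str(exc)
    if reference is not None:
        try:
            desc.rotation_deg = loop_rotation_angle(model, reference, chain=loop_chain)
        except (DescriptorNotAvailable, KeyError) as exc:
            desc.not_available["rotation_deg"] = str(exc)
    try:
        desc.n_waters_shell = count_shell_waters(model, base, radius=shell_radius)
    except (DescriptorNotAvailable, KeyError) as exc:
        desc.not_available["n_waters_shell"] = str(exc)
    return desc


_CSV_COLUMNS = [
    "source",
    "d242",
    "d244",
    "hbond_242_base",
    "hbond_distance",
    "rotation_deg",
    "n_waters_shell",
]


def descriptors_to_frame(descriptors: Sequence[LoopDescriptor]) -> pd.DataFrame:
    rows = []
    for d in descriptors:
        rows.append({c: getattr(d, c) for c in _CSV_COLUMNS})
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_descriptor_csv(descriptors: Sequence[LoopDescriptor], path) -> None:
    """One row per structure/snapshot; not-available encoded as empty cell."""
    descriptors_to_frame(descriptors).to_csv(path, index=False)


def read_descriptor_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"d242", "d244"} - set(df.columns)
    if missing:
        raise ValueError(f"descriptor CSV missing required columns: {sorted(missing)}")
    return df
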