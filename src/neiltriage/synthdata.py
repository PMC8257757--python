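"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators:

* :func:`gen_conformational_ensemble` — descriptor snapshots from a
  three-component Gaussian mixture over (d242, d244) whose component
  weights are Boltzmann-consistent with supplied per-state free energies,
  emulating an equilibrated conformational ensemble of the recognition
  loop.  Truth labels are retained for oracle tests.
* :func:`gen_timecourse_dataset` — single-turnover cleavage time-courses
  whose true k_obs per (variant, substrate) row follows the auto-
  inhibition law k_obs = k_cat / (1 + exp(dG/RT)), sampled on the
  standard 13-point schedule with additive Gaussian noise.
* :func:`gen_toy_structure` — minimal plain-text coordinate models
  realizing the three loop conformations with descriptor values placed
  exactly (242-in: d242 = 3.0 A; 244-in: d244 = 3.6 A; apo: both probes
  >= 9 A and the loop rotated 40 degrees about the 240–249 hinge).
  Idealized geometry (planar hexagonal rings, straight-line side-chain
  fill-in): these are descriptor fixtures, not chemically valid models.
* :func:`gen_solvation_shell` — Poisson-distributed waters placed
  uniformly in a distance shell around the flipped base, plus a fixed
  far-field set, for testing water-counting and desolvation analyses.

All generators are deterministic under a fixed seed; multi-part outputs
derive per-part substreams from the master seed via numpy SeedSequence
spawning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import STANDARD_TIMES_MIN, simulate_timecourse
from .states import STATE_LABELS
from .structio import Atom, Residue, StructureModel, write_pdb
from .thermo import R_KCAL, T_DEFAULT, TwoStateModel, apparent_kcat

__all__ = [
    "DEFAULT_CENTROIDS",
    "EnsembleSpec",
    "KineticsSpec",
    "ToyStructureParams",
    "gen_conformational_ensemble",
    "gen_timecourse_dataset",
    "gen_toy_structure",
    "gen_solvation_shell",
]

#: Default generating centroids, matching the packaged classifier
#: references (angstrom, (d242, d244)).
DEFAULT_CENTROIDS: dict[str, tuple[float, float]] = {
    "apo": (12.0, 10.0),
    "in242": (3.0, 8.0),
    "in244": (8.0, 3.5),
}

_DEFAULT_COV = ((0.25, 0.0), (0.0, 0.25))  # sd 0.5 A per axis


@dataclass
class EnsembleSpec:
    """Three-component metastable ensemble specification.

    Component weights come either from explicit ``weights`` (must sum to
    1) or from Boltzmann factors exp(-G_s/RT) of ``free_energies``
    (kcal/mol; states omitted there get weight 0).
    """

    n: int = 1000
    centroids: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CENTROIDS)
    )
    covariances: Mapping[str, Sequence[Sequence[float]]] | None = None
    free_energies: Mapping[str, float] | None = None
    weights: Mapping[str, float] | None = None
    T: float = T_DEFAULT
    seed: int | None = None

    @classmethod
    def from_file(cls, path) -> "EnsembleSpec":
        """Load a spec from a YAML/JSON mapping of the field names."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def resolved_weights(self) -> dict[str, float]:
        if self.weights is not None:
            w = {s: float(self.weights.get(s, 0.0)) for s in STATE_LABELS}
            total = sum(w.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"explicit weights must sum to 1, got {total}")
            return w
        if self.free_energies is None:
            raise ValueError("spec needs either free_energies or weights")
        RT = R_KCAL * self.T
        boltz = {
            s: math.exp(-float(self.free_energies[s]) / RT) if s in self.free_energies else 0.0
            for s in STATE_LABELS
        }
        Z = sum(boltz.values())
        if Z == 0:
            raise ValueError("all Boltzmann weights are zero")
        return {s: b / Z for s, b in boltz.items()}

    def resolved_cov(self, state: str) -> np.ndarray:
        cov = np.asarray(
            (self.covariances or {}).get(state, _DEFAULT_COV), dtype=float
        )
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError(f"covariance for {state!r} must be symmetric 2x2")
        eig = np.linalg.eigvalsh(cov)
        if np.any(eig < 0):
            raise ValueError(f"covariance for {state!r} is not positive semi-definite")
        return cov


def gen_conformational_ensemble(spec: EnsembleSpec) -> pd.DataFrame:
    """Sample a labelled (d242, d244) ensemble from the mixture spec.

    Returns a DataFrame with columns ``d242, d244, true_label``; the
    empirical label counts are multinomial draws from the Boltzmann
    weights, so population-derived free energies recover the generating
    ones within statistical error.
    """
    if spec.n < 1:
        raise ValueError("n must be >= 1")
    weights = spec.resolved_weights()
    rng = np.random.default_rng(spec.seed)
    labels_idx = rng.choice(3, size=spec.n, p=[weights[s] for s in STATE_LABELS])
    d = np.empty((spec.n, 2))
    for i, state in enumerate(STATE_LABELS):
        mask = labels_idx == i
        k = int(mask.sum())
        if k == 0:
            continue
        cov = spec.resolved_cov(state)
        mu = np.asarray(spec.centroids[state], dtype=float)
        if np.allclose(cov, 0):
            d[mask] = mu  # degenerate limiting case: all samples at centroid
        else:
            d[mask] = rng.multivariate_normal(mu, cov, size=k, method="svd")
    df = pd.DataFrame({"d242": d[:, 0], "d244": d[:, 1]})
    df["true_label"] = np.array(STATE_LABELS)[labels_idx]
    return df


@dataclass
class KineticsSpec:
    """Single-turnover dataset specification.

    ``params`` rows: (variant, substrate, k_cat, dG_conf, dG_chem); the
    true observed rate per row is k_cat * p_A(dG_conf + dG_chem) at
    temperature ``T``.  Default assay design follows the standard
    single-turnover protocol (substrate duplex at 20 nM with 10-fold
    enzyme excess) sampled on the 13-point schedule.
    """

    params: pd.DataFrame
    T: float = T_DEFAULT
    times: np.ndarray = field(default_factory=lambda: STANDARD_TIMES_MIN.copy())
    noise_sd: float = 0.02
    replicates: int = 3
    amplitude: float = 0.9
    seed: int | None = None

    @classmethod
    def from_file(cls, path) -> "KineticsSpec":
        """Load a spec from YAML/JSON; ``params`` is a list of row mappings."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["params"] = pd.DataFrame(data["params"])
        if "times" in data:
            data["times"] = np.asarray(data["times"], dtype=float)
        return cls(**data)

    def __post_init__(self) -> None:
        required = {"variant", "substrate", "k_cat", "dG_conf", "dG_chem"}
        missing = required - set(self.params.columns)
        if missing:
            raise ValueError(f"params table missing columns: {sorted(missing)}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        t = np.asarray(self.times, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")


def gen_timecourse_dataset(
    spec: KineticsSpec, csv_path=None, truth_path=None
) -> tuple[pd.DataFrame, dict]:
    """Generate a time-course table plus a ground-truth sidecar.

    Returns ``(data, truth)``: ``data`` has columns time_min,
    fraction_product, replicate, variant, substrate; ``truth`` maps
    ``"variant:substrate"`` to the generating parameters including the
    true k_obs.  Optionally writes both to ``csv_path`` /
    ``truth_path``.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(len(spec.params) * spec.replicates)
    frames = []
    truth: dict[str, dict] = {}
    i = 0
    for _, row in spec.params.iterrows():
        m = TwoStateModel(
            k_cat=float(row["k_cat"]),
            dG_conf=float(row["dG_conf"]),
            dG_chem=float(row["dG_chem"]),
            T=spec.T,
        )
        k_true = apparent_kcat(m)
        key = f"{row['variant']}:{row['substrate']}"
        truth[key] = {
            "variant": str(row["variant"]),
            "substrate": str(row["substrate"]),
            "k_cat": m.k_cat,
            "dG_conf": m.dG_conf,
            "dG_chem": m.dG_chem,
            "T": spec.T,
            "A": spec.amplitude,
            "k_obs_true": k_true,
            "noise_sd": spec.noise_sd,
            "replicates": spec.replicates,
        }
        for rep in range(spec.replicates):
            tc = simulate_timecourse(
                A=spec.amplitude,
                k_obs=k_true,
                times=spec.times,
                noise_sd=spec.noise_sd,
                seed=np.random.default_rng(seeds[i]),
                replicate=rep,
                variant=str(row["variant"]),
                substrate=str(row["substrate"]),
            )
            frames.append(tc.to_frame())
            i += 1
    data = pd.concat(frames, ignore_index=True)
    if csv_path is not None:
        data.to_csv(csv_path, index=False, float_format="%.10g")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)
    return data, truth


# ---------------------------------------------------------------------------
# Toy coordinate fixtures
# ---------------------------------------------------------------------------

_RING_RADIUS = 1.39  # idealized aromatic ring, angstrom
_HINGE_Y = 8.0
_LOOP_BULGE = 6.0


@dataclass
class ToyStructureParams:
    """Target descriptor values for the toy conformers (angstrom/degrees)."""

    d242_in: float = 3.0  # 242-in: terminal N to base contact
    d244_in: float = 3.6  # 244-in: stacking centroid separation
    d244_out: float = 8.0  # 242-in: Tyr244 swung-out centroid distance
    d242_out: float = 8.61  # 244-in: displaced residue-242 probe distance
    apo_distance: float = 10.6  # apo: both probes at least this far
    apo_rotation_deg: float = 40.0  # apo loop rotation about the hinge

    def __post_init__(self) -> None:
        for name in ("d242_in", "d244_in", "d244_out", "d242_out", "apo_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.apo_rotation_deg < 180:
            raise ValueError("apo_rotation_deg must lie in (0, 180)")
        if self.d242_in >= self.d242_out:
            raise ValueError("242-in contact must be shorter than the displaced distance")


def _hexagon(center: np.ndarray, normal: str = "z", phase: float = 0.0) -> np.ndarray:
    """Six vertices of a planar hexagon of the idealized ring radius."""
    ang = np.radians(np.arange(6) * 60.0 + phase)
    ring = np.stack(
        [_RING_RADIUS * np.cos(ang), _RING_RADIUS * np.sin(ang), np.zeros(6)], axis=1
    )
    return ring + np.asarray(center, dtype=float)


def _base_residue() -> Residue:
    """Flipped pyrimidine-like base: hexagonal ring at the origin, z=0."""
    # ring order starting at N3, which sits at the phase-0 vertex
    # (+1.39, 0, 0); its outward in-plane direction is +x
    names = ["N3", "C4", "C5", "C6", "N1", "C2"]
    elements = ["N", "C", "C", "C", "N", "C"]
    coords = _hexagon(np.zeros(3), phase=0.0)
    res = Residue(chain="B", number=5, name="DU")
    for name, el, pos in zip(names, elements, coords):
        res.atoms.append(Atom(name=name, element=el, pos=pos))
    return res


def _rotate_about_axis(points: np.ndarray, origin: np.ndarray, axis: np.ndarray, deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(deg) * axis)
    return rot.apply(points - origin) + origin


def gen_toy_structure(
    state: str, params: ToyStructureParams | None = None, path=None
) -> StructureModel:
    """Minimal coordinate model realizing one loop conformation.

    The model holds a flipped pyrimidine-like base (chain B, ring in the
    z = 0 plane at the origin), a protein chain A with core Calpha atoms
    (residues 225–239 and 250–260, identical across states), the loop
    Calpha trace 240–249, a Lys242 side chain and a Tyr244 ring placed so
    the computed descriptors hit the ``params`` targets exactly:

    * ``in242`` — Lys242 NZ exactly ``d242_in`` (3.0 A) from base N3,
      Tyr244 ring centroid at ``d244_out`` (8.0 A);
    * ``in244`` — Tyr244 ring stacked ``d244_in`` (3.6 A) over the base
      centroid, Lys242 NZ displaced beyond 7 A;
    * ``apo`` — both probes >= 9 A away and the loop Calpha trace rotated
      ``apo_rotation_deg`` (40 degrees) about the Calpha240–Calpha249
      axis relative to the bound template.

    When ``path`` is given the model is also written as a PDB file.
    """
    if state not in STATE_LABELS:
        raise ValueError(f"state must be one of {STATE_LABELS}, got {state!r}")
    p = params or ToyStructureParams()

    model = StructureModel(identifier=f"toy-{state}")
    base = _base_residue()
    model.residues.append(base)
    base_coords = np.array([a.pos for a in base.atoms])
    base_centroid = base_coords.mean(axis=0)  # origin
    n3 = base.atom("N3").pos

    # core Calpha scaffold, identical in every state (non-collinear)
    for num in (*range(225, 240), *range(250, 261)):
        x = (num - 244.5) * 1.5
        ca = np.array([x, 15.0 + 3.0 * math.sin(num * 0.7), 3.0 * math.cos(num * 0.7)])
        res = Residue(chain="A", number=num, name="GLY")
        res.atoms.append(Atom(name="CA", element="C", pos=ca))
        model.residues.append(res)

    # hinge + loop Calpha trace (bound template: arc bulging toward the base)
    h1 = np.array([-4.5, _HINGE_Y, 0.0])
    h2 = np.array([4.5, _HINGE_Y, 0.0])
    loop_ca = {240: h1, 249: h2}
    for num in range(241, 249):
        frac = (num - 240) / 9.0
        pos = h1 + frac * (h2 - h1)
        loop_ca[num] = pos - np.array([0.0, _LOOP_BULGE * math.sin(math.pi * frac), 0.0])
    if state == "apo":
        nums = list(range(241, 249))
        pts = np.array([loop_ca[n] for n in nums])
        pts = _rotate_about_axis(pts, h1, h2 - h1, p.apo_rotation_deg)
        loop_ca.update({n: q for n, q in zip(nums, pts)})

    residue_names = {
        240: "GLY", 241: "SER", 242: "LYS", 243: "GLY", 244: "TYR",
        245: "GLY", 246: "SER", 247: "GLY", 248: "GLY", 249: "GLY",
    }
    loop_residues = {}
    for num in range(240, 250):
        res = Residue(chain="A", number=num, name=residue_names[num])
        res.atoms.append(Atom(name="CA", element="C", pos=loop_ca[num]))
        model.residues.append(res)
        loop_residues[num] = res

    # --- residue-242 probe (Lys NZ) ---------------------------------------
    out_n3 = (n3 - base_centroid) / np.linalg.norm(n3 - base_centroid)
    if state == "in242":
        nz = n3 + p.d242_in * out_n3
    elif state == "in244":
        nz = n3 + p.d242_out * out_n3  # swung out along the same contact vector
    else:  # apo: fully displaced, solvent-exposed
        nz = base_centroid + np.array([0.0, -(p.apo_distance + _RING_RADIUS), 1.0])
    lys = loop_residues[242]
    # straight-line fill-in CB..CE between Calpha and the probe nitrogen
    for i, name in enumerate(("CB", "CG", "CD", "CE"), start=1):
        lys.atoms.append(
            Atom(name=name, element="C", pos=loop_ca[242] + (i / 5.0) * (nz - loop_ca[242]))
        )
    lys.atoms.append(Atom(name="NZ", element="N", pos=nz))

    # --- residue-244 ring (Tyr) -------------------------------------------
    if state == "in244":
        ring_center = base_centroid + np.array([0.0, 0.0, p.d244_in])
    elif state == "in242":
        ring_center = base_centroid + p.d244_out * np.array(
            [math.cos(math.radians(110)), math.sin(math.radians(110)), 0.0]
        )
    else:
        ring_center = base_centroid + np.array([3.0, -(p.apo_distance + 1.0), 4.0])
    tyr = loop_residues[244]
    ring = _hexagon(ring_center, phase=15.0)
    for name, pos in zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), ring):
        tyr.atoms.append(Atom(name=name, element="C", pos=pos))
    tyr.atoms.append(Atom(name="CB", element="C", pos=ring_center + np.array([0.0, 0.0, 1.5])))

    _check_toy_targets(state, model, p)
    if path is not None:
        write_pdb(model, path)
    return model


def _check_toy_targets(state: str, model: StructureModel, p: ToyStructureParams) -> None:
    """Construction self-check: infeasible parameter combinations error out."""
    from .descriptors import compute_d242, compute_d244
    from .structio import ResidueView

    base = ResidueView(model.residue("B", 5))
    d242 = compute_d242(model, "A", base)
    d244, _ = compute_d244(model, "A", base)
    if state == "in242":
        ok = math.isclose(d242, p.d242_in, abs_tol=1e-9) and math.isclose(
            d244, p.d244_out, abs_tol=1e-9
        )
    elif state == "in244":
        ok = math.isclose(d244, p.d244_in, abs_tol=1e-9) and d242 >= 7.0
    else:
        ok = d242 >= 9.0 and d244 >= 9.0
    if not ok:
        raise ValueError(
            f"infeasible toy-structure parameters for state {state!r}: "
            f"got d242={d242:.3f}, d244={d244:.3f} with {p}"
        )


def gen_solvation_shell(
    base_model: StructureModel,
    expected_in_shell: float,
    shell: tuple[float, float] = (2.5, 5.0),
    seed: int | None = None,
    n_far: int = 4,
    path=None,
) -> tuple[StructureModel, int]:
    """Add a Poisson water shell around the flipped base.

    Draws K ~ Poisson(``expected_in_shell``) water oxygens placed
    uniformly (by rejection) at minimum base-heavy-atom distance within
    ``shell`` = (r_min, r_max], plus ``n_far`` fixed far-field waters
    strictly outside r_max.  Returns the augmented model and the in-shell
    bookkeeping count K, which equals
    ``count_shell_waters(model, base, radius=r_max)`` by construction.
    """
    r_min, r_max = shell
    if expected_in_shell < 0:
        raise ValueError("expected_in_shell must be non-negative")
    if not 0 <= r_min < r_max:
        raise ValueError(f"need 0 <= r_min < r_max, got {shell}")
    base = base_model.residue("B", 5) if base_model.has_residue("B", 5) else base_model.residues[0]
    targets = np.array([a.pos for a in base.atoms])
    center = targets.mean(axis=0)
    rng = np.random.default_rng(seed)
    k = int(rng.poisson(expected_in_shell))

    model = base_model.transformed(_identity_transform())
    placed = 0
    extent = float(np.ptp(targets, axis=0).max())
    half = r_max + extent
    while placed < k:
        pts = center + rng.uniform(-half, half, size=(max(4 * (k - placed), 32), 3))
        dmin = np.linalg.norm(
            targets[None, :, :] - pts[:, None, :], axis=2
        ).min(axis=1)
        for pt in pts[(r_min < dmin) & (dmin <= r_max)]:
            if placed >= k:
                break
            model.waters.append(_water(900 + placed, pt))
            placed += 1
    for j in range(n_far):
        ang = 2 * math.pi * j / max(n_far, 1)
        pt = center + (r_max + 2.5 + extent) * np.array(
            [math.cos(ang), math.sin(ang), 0.3]
        )
        model.waters.append(_water(950 + j, pt))
    if path is not None:
        write_pdb(model, path)
    return model, k


def _water(number: int, pos: np.ndarray) -> Residue:
    res = Residue(chain="W", number=number, name="HOH", is_water=True)
    res.atoms.append(Atom(name="O", element="O", pos=pos))
    return res


def _identity_transform():
    from .structio import RigidTransform

    return RigidTransform.identity()
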