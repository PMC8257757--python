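"""Metastable-state classification and population thermodynamics.

Conformational snapshots of the hNEIL1 lesion-recognition loop are reduced
to two distances — ``d242`` (residue-242 terminal N to flipped base) and
``d244`` (residue-244 ring centroid to base ring centroid) — and assigned
to one of three metastable states seen crystallographically:

* ``apo``    — encounter state, loop displaced from the base;
* ``in242``  — activated state, residue 242 hydrogen-bonded to the base;
* ``in244``  — quarantine state, Tyr244 stacked on the base.

State populations over an equilibrium ensemble convert to a free-energy
difference between the activated and quarantine states via
dG = RT ln(p_quarantine / p_activated), the inverse of
:func:`neiltriage.thermo.activated_fraction` restricted to the two
catalysis-relevant states.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .thermo import R_KCAL, T_DEFAULT

__all__ = [
    "STATE_LABELS",
    "StateReference",
    "StateAssignment",
    "EnsembleSummary",
    "Zone",
    "StateClassifier",
    "ZoneFinder",
    "default_references",
    "load_references",
    "classify_snapshot",
    "find_metastable_zones",
    "state_populations",
    "delta_g_from_populations",
]

#: Canonical label order; also the deterministic tie-break order.
STATE_LABELS = ("apo", "in242", "in244")


@dataclass(frozen=True)
class StateReference:
    """Reference centroid of one metastable state in (d242, d244) space."""

    label: str
    centroid: tuple[float, float]  # (d242, d244), angstrom
    scale: tuple[float, float] = (1.0, 1.0)  # per-axis divisor

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.label!r}; expected one of {STATE_LABELS}")
        if any(s <= 0 for s in self.scale):
            raise ValueError("per-axis scales must be positive")


@dataclass(frozen=True)
class StateAssignment:
    """Result of classifying one snapshot: winning label, distances, margin."""

    label: str
    distances: dict[str, float]
    margin: float


@dataclass(frozen=True)
class EnsembleSummary:
    """State counts/fractions over an ensemble plus the derived dG.

    ``dG`` is the activated-minus-quarantine free energy (kcal/mol),
    positive when the quarantine state (in244) dominates; ``dG_se`` its
    binomial-propagation standard error.  Unclassifiable snapshots are
    excluded from fractions and reported in ``n_unclassifiable``.
    """

    counts: dict[str, int]
    fractions: dict[str, float]
    n_total: int
    n_unclassifiable: int
    dG: float
    dG_se: float
    T: float

    def __post_init__(self) -> None:
        if self.n_total > 0:
            assert abs(sum(self.fractions.values()) - 1.0) < 1e-12
            assert sum(self.counts.values()) == self.n_total


def default_references() -> list[StateReference]:
    """The packaged reference centroids (see data/default_centroids.yaml)."""
    text = resources.files("neiltriage.data").joinpath("default_centroids.yaml").read_text()
    return _refs_from_mapping(yaml.safe_load(text))


def load_references(path) -> list[StateReference]:
    """Load reference centroids from a YAML/JSON mapping file.

    Expected form: ``{label: {d242: x, d244: y}}`` for the three labels.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _refs_from_mapping(data)


def _refs_from_mapping(data: Mapping) -> list[StateReference]:
    refs = []
    for label in STATE_LABELS:
        if label not in data:
            raise ValueError(f"centroid file missing state {label!r}")
        entry = data[label]
        refs.append(StateReference(label, (float(entry["d242"]), float(entry["d244"]))))
    return refs


def _validate_references(refs: Sequence[StateReference]) -> list[StateReference]:
    if len(refs) != 3:
        raise ValueError(f"need exactly 3 state references, got {len(refs)}")
    labels = [r.label for r in refs]
    if sorted(labels) != sorted(STATE_LABELS):
        raise ValueError(f"references must carry labels {STATE_LABELS}, got {labels}")
    cents = {r.label: tuple(r.centroid) for r in refs}
    for a in STATE_LABELS:
        for b in STATE_LABELS:
            if a < b and cents[a] == cents[b]:
                raise ValueError(f"centroids of {a!r} and {b!r} coincide")
    # canonical order
    return sorted(refs, key=lambda r: STATE_LABELS.index(r.label))


class StateClassifier:
    """Nearest-centroid assignment of snapshots to the three loop states.

    Euclidean distance in (optionally per-axis scaled) (d242, d244) space;
    exact ties broken deterministically by label order apo < in242 < in244.

    Follows the scikit-learn estimator protocol: ``fit`` either accepts
    the references given at construction or, when labelled training data
    are passed, learns per-state mean centroids from them.

    Parameters
    ----------
    references : sequence of StateReference, optional
        Three reference centroids.  Default: the packaged crystallographic
        operational centroids.
    """

    def __init__(self, references: Sequence[StateReference] | None = None):
        self.references = references

    def get_params(self, deep: bool = True) -> dict:
        return {"references": self.references}

    def set_params(self, **params) -> "StateClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "StateClassifier":
        """Fix the reference centroids.

        With ``X, y`` given (descriptor array of shape (n, 2) and state
        labels), centroids are the per-state means of ``X``; otherwise the
        constructor's (or packaged default) references are used.
        """
        if X is not None and y is not None:
            X = np.asarray(X, dtype=float)
            y = np.asarray(y)
            refs = []
            for label in STATE_LABELS:
                mask = y == label
                if not mask.any():
                    raise ValueError(f"no training snapshots labelled {label!r}")
                refs.append(StateReference(label, tuple(X[mask].mean(axis=0))))
            self.references_ = _validate_references(refs)
        else:
            refs = self.references if self.references is not None else default_references()
            self.references_ = _validate_references(refs)
        self.centroids_ = np.array([r.centroid for r in self.references_])
        self.scales_ = np.array([r.scale for r in self.references_])
        self.classes_ = np.array(STATE_LABELS)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "references_"):
            raise RuntimeError("classifier is not fitted; call fit() first")

    def _distances(self, X: np.ndarray) -> np.ndarray:
        # scaled Euclidean distance to each centroid; shape (n, 3)
        diff = (X[:, None, :] - self.centroids_[None, :, :]) / self.scales_[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    def predict(self, X) -> np.ndarray:
        """Nearest-centroid labels for descriptor rows (n, 2)."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != 2:
            raise ValueError(f"expected (n, 2) descriptor array, got shape {X.shape}")
        # argmin takes the first minimum, which is the tie-break order
        idx = np.argmin(self._distances(X), axis=1)
        return self.classes_[idx]

    def assign(self, d242: float, d244: float) -> StateAssignment:
        """Classify a single snapshot, reporting distances and margin."""
        self._check_fitted()
        if d242 is None or d244 is None or not (np.isfinite(d242) and np.isfinite(d244)):
            raise UnclassifiableSnapshotError(
                f"descriptors not available (d242={d242}, d244={d244})"
            )
        dists = self._distances(np.array([[d242, d244]]))[0]
        win = int(np.argmin(dists))
        margin = float(np.partition(dists, 1)[1] - dists[win])
        return StateAssignment(
            label=str(self.classes_[win]),
            distances={lbl: float(d) for lbl, d in zip(self.classes_, dists)},
            margin=margin,
        )


class UnclassifiableSnapshotError(ValueError):
    """Snapshot lacks the descriptors needed for state assignment."""


def classify_snapshot(descriptor, references: Sequence[StateReference] | None = None) -> StateAssignment:
    """Nearest-centroid state call for one descriptor snapshot.

    ``descriptor`` is anything with ``d242``/``d244`` attributes or keys
    (a :class:`~neiltriage.descriptors.LoopDescriptor`, a mapping, or a
    2-sequence).  Not-available descriptors raise
    :class:`UnclassifiableSnapshotError`.
    """
    d242, d244 = _extract_d(descriptor)
    return StateClassifier(references).fit().assign(d242, d244)


def _extract_d(descriptor) -> tuple[float, float]:
    if hasattr(descriptor, "d242"):
        return descriptor.d242, descriptor.d244
    if isinstance(descriptor, Mapping):
        return descriptor["d242"], descriptor["d244"]
    d242, d244 = descriptor
    return d242, d244


@dataclass(frozen=True)
class Zone:
    """One detected metastable zone of the 2D descriptor landscape."""

    mode_cell: tuple[float, float]  # (d242, d244) of the densest cell centre
    population: int  # snapshots in the zone's cells
    n_cells: int
    peak_density: float  # fraction of the modal landscape density


class ZoneFinder:
    """Density-based detection of metastable zones in (d242, d244) space.

    Histograms the ensemble on a regular grid and keeps connected
    components (4-connectivity) of cells whose count is at least
    ``min_density`` times the modal cell count; each component is one
    zone, reported with its densest cell and total membership, sorted by
    population (descending), ties by mode-cell coordinates.

    Parameters
    ----------
    bin_width : float
        Grid spacing in angstrom (both axes), default 0.5.
    min_density : float
        Fraction of the modal cell density a cell must reach to belong to
        a zone, default 0.2.
    """

    def __init__(self, bin_width: float = 0.5, min_density: float = 0.2):
        self.bin_width = bin_width
        self.min_density = min_density

    def get_params(self, deep: bool = True) -> dict:
        return {"bin_width": self.bin_width, "min_density": self.min_density}

    def set_params(self, **params) -> "ZoneFinder":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X) -> "ZoneFinder":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"expected (n, 2) descriptor array, got shape {X.shape}")
        if len(X) == 0:
            raise ValueError("empty ensemble")
        if not 0 < self.min_density <= 1:
            raise ValueError("min_density must be in (0, 1]")
        w = self.bin_width
        lo = np.floor(X.min(axis=0) / w) * w
        hi = np.ceil(X.max(axis=0) / w) * w + w  # at least one bin per axis
        xedges = np.arange(lo[0], hi[0] + w / 2, w)
        yedges = np.arange(lo[1], hi[1] + w / 2, w)
        H, xedges, yedges = np.histogram2d(X[:, 0], X[:, 1], bins=[xedges, yedges])
        n_cells = H.size
        if len(X) < n_cells:
            warnings.warn(
                f"ensemble size {len(X)} below grid cell count {n_cells}; "
                "zone detection may fragment",
                stacklevel=2,
            )
        threshold = self.min_density * H.max()
        mask = H >= threshold
        labels, n_zones = ndimage.label(mask)  # 4-connectivity default
        zones = []
        xc = (xedges[:-1] + xedges[1:]) / 2
        yc = (yedges[:-1] + yedges[1:]) / 2
        for z in range(1, n_zones + 1):
            cells = labels == z
            pop = int(H[cells].sum())
            # densest cell of this zone
            masked = np.where(cells, H, -1)
            i, j = np.unravel_index(np.argmax(masked), H.shape)
            zones.append(
                Zone(
                    mode_cell=(float(xc[i]), float(yc[j])),
                    population=pop,
                    n_cells=int(cells.sum()),
                    peak_density=float(H[i, j] / H.max()),
                )
            )
        zones.sort(key=lambda zn: (-zn.population, zn.mode_cell))
        self.zones_ = zones
        self.histogram_ = H
        self.xedges_ = xedges
        self.yedges_ = yedges
        return self


def find_metastable_zones(
    ensemble, bin_width: float = 0.5, min_density: float = 0.2
) -> list[Zone]:
    """Detect high-population zones of an ensemble of descriptors.

    ``ensemble`` is an (n, 2) array, a DataFrame with d242/d244 columns,
    or an iterable of objects with those attributes.
    """
    X = _ensemble_to_array(ensemble)
    return ZoneFinder(bin_width=bin_width, min_density=min_density).fit(X).zones_


def _ensemble_to_array(ensemble) -> np.ndarray:
    if isinstance(ensemble, pd.DataFrame):
        return ensemble[["d242", "d244"]].to_numpy(dtype=float)
    if isinstance(ensemble, np.ndarray):
        return np.asarray(ensemble, dtype=float)
    rows = []
    for item in ensemble:
        rows.append(_extract_d(item))
    return np.asarray(rows, dtype=float)


def state_populations(
    ensemble,
    references: Sequence[StateReference] | None = None,
    T: float = T_DEFAULT,
) -> EnsembleSummary:
    """Classify an ensemble and summarize state populations and dG.

    Snapshots with missing (NaN) descriptors are excluded and counted as
    unclassifiable.  dG (activated minus quarantine, kcal/mol) and its
    standard error come from :func:`delta_g_from_populations` applied to
    the in242/in244 counts.
    """
    if isinstance(ensemble, pd.DataFrame):
        X = ensemble[["d242", "d244"]].to_numpy(dtype=float)
    else:
        X = _ensemble_to_array(ensemble)
    ok = np.isfinite(X).all(axis=1)
    n_bad = int((~ok).sum())
    X = X[ok]
    if len(X) == 0:
        raise ValueError("no classifiable snapshots in ensemble")
    labels = StateClassifier(references).fit().predict(X)
    counts = {lbl: int((labels == lbl).sum()) for lbl in STATE_LABELS}
    n = len(X)
    fractions = {lbl: counts[lbl] / n for lbl in STATE_LABELS}
    if counts["in242"] == 0 and counts["in244"] == 0:
        dG, dG_se = math.nan, math.nan  # all-apo ensemble: dG undefined
    else:
        dG, dG_se = delta_g_from_populations(
            fractions["in242"],
            fractions["in244"],
            T,
            counts=(counts["in242"], counts["in244"]),
        )
    return EnsembleSummary(
        counts=counts,
        fractions=fractions,
        n_total=n,
        n_unclassifiable=n_bad,
        dG=dG,
        dG_se=dG_se,
        T=T,
    )


def delta_g_from_populations(
    p_activated: float,
    p_quarantine: float,
    T: float = T_DEFAULT,
    counts: tuple[int, int] | None = None,
):
    """Free energy (kcal/mol) of activated vs quarantine from populations.

    dG = RT ln(p_quarantine / p_activated) — positive when the quarantine
    state dominates, the inverse of
    :func:`neiltriage.thermo.activated_fraction` for a two-state system.

    A zero population yields an infinite-dG marker (``±inf``), not an
    exception.  When per-state ``counts`` (n_activated, n_quarantine) are
    supplied, the returned pair is (dG, standard error) with
    SE = RT * sqrt(1/n_A + 1/n_Q) from binomial propagation of the
    ln-ratio; otherwise (dG, nan).
    """
    if not T > 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    if p_activated < 0 or p_quarantine < 0:
        raise ValueError("populations must be non-negative")
    RT = R_KCAL * T
    if p_activated == 0 and p_quarantine == 0:
        raise ValueError("both state populations are zero")
    if p_activated == 0:
        return math.inf, math.nan
    if p_quarantine == 0:
        return -math.inf, math.nan
    dG = RT * math.log(p_quarantine / p_activated)
    se = math.nan
    if counts is not None:
        nA, nQ = counts
        if nA > 0 and nQ > 0:
            se = RT * math.sqrt(1.0 / nA + 1.0 / nQ)
    return dG, se
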