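"""Two-state auto-inhibition rate law for hNEIL1 substrate triage.

hNEIL1 binds a flipped base in one of two competing modes: an *activated*
(242-in) state that is catalytically competent, and a *quarantine* (244-in)
state that sequesters the base and blocks catalysis.  With the binding step
pre-equilibrated, only the activated fraction of the enzyme-substrate
complex turns over, so the apparent single-turnover rate constant is

    k~_cat = k_cat / (1 + exp(dG / RT)),        dG = dG_conf + dG_chem

where ``dG`` is the free energy of the activated state relative to the
quarantine state (positive when quarantine dominates), decomposed into a
loop-conformation term (``dG_conf``, the "structural check": desolvation
and stacking on transiting 244-in -> 242-in) and a tautomerization term
(``dG_chem``, the "chemical check": the hydrogen bond between residue 242
and the flipped base).

Units are fixed throughout: kcal/mol for free energies, minutes for rates,
kelvin for temperature.  Infinite ``dG`` values are legal and represent the
pure-quarantine (+inf -> activated fraction 0) and pure-activated
(-inf -> fraction 1) limits.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "R_KCAL",
    "T_DEFAULT",
    "TwoStateModel",
    "total_dG",
    "activated_fraction",
    "apparent_kcat",
    "overall_rate",
    "discrimination_ratio",
    "triage_report",
    "TriageReport",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.98720425e-3

#: Default absolute temperature (K) used when none is supplied.
T_DEFAULT = 298.15


class UndefinedFreeEnergyError(ValueError):
    """Raised when dG_conf and dG_chem are opposing infinities."""


@dataclass(frozen=True)
class TwoStateModel:
    """Parameters of the two-state (activated vs quarantine) rate law.

    Parameters
    ----------
    k_cat : float
        Intrinsic glycosylase rate constant of the activated state, min^-1.
        Must be positive.
    dG_conf : float
        Loop-conformation free energy (244-in -> 242-in), kcal/mol.
        May be ``±inf``.
    dG_chem : float
        Tautomerization ("chemical check") free energy, kcal/mol.
        May be ``±inf``.
    T : float
        Absolute temperature in kelvin, default 298.15.
    """

    k_cat: float
    dG_conf: float = 0.0
    dG_chem: float = 0.0
    T: float = T_DEFAULT

    def __post_init__(self) -> None:
        if not self.k_cat > 0:
            raise ValueError(f"k_cat must be positive, got {self.k_cat}")
        if not self.T > 0:
            raise ValueError(f"temperature must be positive, got {self.T} K")
        for name in ("dG_conf", "dG_chem"):
            v = getattr(self, name)
            if math.isnan(v):
                raise ValueError(f"{name} is NaN")

    @property
    def RT(self) -> float:
        """Thermal energy RT in kcal/mol."""
        return R_KCAL * self.T


def total_dG(m: TwoStateModel) -> float:
    """Total activated-vs-quarantine free energy: dG_conf + dG_chem.

    Opposing infinities (one component +inf, the other -inf) have no
    defined sum and raise :class:`UndefinedFreeEnergyError`.
    """
    a, b = m.dG_conf, m.dG_chem
    if math.isinf(a) and math.isinf(b) and (a > 0) != (b > 0):
        raise UndefinedFreeEnergyError(
            "dG_conf and dG_chem are opposing infinities; total dG undefined"
        )
    return a + b


def activated_fraction(dG, T: float = T_DEFAULT):
    """Equilibrium fraction of the ES complex in the activated state.

    p_A = 1 / (1 + exp(dG / RT)); strictly decreasing in dG, with
    p_A(0) = 1/2 and the exact limits p_A(+inf) = 0, p_A(-inf) = 1.

    Accepts scalars or arrays of dG (kcal/mol).
    """
    if not T > 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    dG = np.asarray(dG, dtype=float)
    RT = R_KCAL * T
    # scipy.special.expit(-x) = 1/(1+e^x) without overflow for large |x|
    from scipy.special import expit

    p = expit(-dG / RT)
    return float(p) if p.ndim == 0 else p


def apparent_kcat(m: TwoStateModel) -> float:
    """Apparent rate constant k~_cat = k_cat * p_A(dG_conf + dG_chem)."""
    return m.k_cat * activated_fraction(total_dG(m), m.T)


def overall_rate(m: TwoStateModel, ES_total: float) -> float:
    """Overall reaction rate r = k~_cat * [ES] (concentration per minute).

    ``ES_total`` is the total equilibrium ES concentration in whatever
    concentration unit the caller uses; the rate carries that unit / min.
    """
    if ES_total < 0:
        raise ValueError(f"ES_total must be non-negative, got {ES_total}")
    return apparent_kcat(m) * ES_total


def discrimination_ratio(m_damage: TwoStateModel, m_normal: TwoStateModel) -> float:
    """Ratio of apparent rate constants, damage over normal substrate.

    Quantifies the extra substrate discrimination the quarantine state
    buys: identical intrinsic k_cat but a more positive dG for the normal
    base suppresses its apparent rate.  Returns ``inf`` when the normal
    substrate's apparent rate is exactly zero.
    """
    if m_damage.T != m_normal.T:
        warnings.warn(
            f"models compared at different temperatures "
            f"({m_damage.T} K vs {m_normal.T} K)",
            stacklevel=2,
        )
    num = apparent_kcat(m_damage)
    den = apparent_kcat(m_normal)
    if den == 0.0:
        return math.inf
    return num / den


@dataclass
class TriageReport:
    """Per-(variant, substrate) summary of the two-state rate law.

    ``table`` has one row per input model with columns
    variant, substrate, k_cat, dG_conf, dG_chem, dG, T,
    activated_fraction, apparent_kcat; ``ratios`` holds every ordered
    pairwise apparent-k_cat quotient.
    """

    table: pd.DataFrame
    ratios: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "table": self.table.to_dict(orient="records"),
            "ratios": self.ratios.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def triage_report(params: pd.DataFrame) -> TriageReport:
    """Build a :class:`TriageReport` from a parameter table.

    ``params`` needs columns ``variant, substrate, k_cat, dG_conf,
    dG_chem`` and optionally ``T`` (default 298.15 K).
    """
    required = {"variant", "substrate", "k_cat", "dG_conf", "dG_chem"}
    missing = required - set(params.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    rows = []
    for _, r in params.iterrows():
        T = float(r["T"]) if "T" in params.columns and not pd.isna(r.get("T")) else T_DEFAULT
        m = TwoStateModel(
            k_cat=float(r["k_cat"]),
            dG_conf=float(r["dG_conf"]),
            dG_chem=float(r["dG_chem"]),
            T=T,
        )
        dG = total_dG(m)
        rows.append(
            {
                "variant": r["variant"],
                "substrate": r["substrate"],
                "k_cat": m.k_cat,
                "dG_conf": m.dG_conf,
                "dG_chem": m.dG_chem,
                "dG": dG,
                "T": m.T,
                "activated_fraction": activated_fraction(dG, m.T),
                "apparent_kcat": apparent_kcat(m),
            }
        )
    table = pd.DataFrame(rows)
    pairs = []
    for i, a in table.iterrows():
        for j, b in table.iterrows():
            if i == j:
                continue
            den = b["apparent_kcat"]
            ratio = math.inf if den == 0 else a["apparent_kcat"] / den
            pairs.append(
                {
                    "numerator": f"{a['variant']}:{a['substrate']}",
                    "denominator": f"{b['variant']}:{b['substrate']}",
                    "ratio": ratio,
                }
            )
    return TriageReport(table=table, ratios=pd.DataFrame(pairs))
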