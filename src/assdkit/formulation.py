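"""Composition arithmetic for drug-salt-polymer systems and simulation boxes.

Covers the bookkeeping needed to plan a supersaturated drug / oligomer /
counterion simulation box: oligomer masses from repeat units, drug:oligomer
and counterion:drug mass ratios, salt-pair counts for a target molarity,
electroneutrality accounting, uniform residual-charge redistribution,
supersaturation folds from a dose scenario, and seeded random insertion of
molecule centres with a minimum-image separation guarantee.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .gcontrib import formula_mass

__all__ = [
    "AVOGADRO",
    "MonomerUnit",
    "OligomerSpec",
    "BoxPlan",
    "DoseScenario",
    "MassRatio",
    "PackingError",
    "oligomer_mass",
    "drug_oligomer_mass_ratio",
    "counterion_mass_ratio",
    "ions_for_molarity",
    "neutralizing_ions",
    "box_ion_counts",
    "redistribute_charge",
    "supersaturation_ratio",
    "random_insertion",
    "celecoxib_unit",
    "pvpva_34mer",
    "hpmcas_15mer",
]

AVOGADRO = 6.02214076e23

#: Masses (Da) of the reference species as printed in the source study.
CELECOXIB_MASS_DA = 381.3
PVPVA_34MER_MASS_DA = 3375.5
HPMCAS_15MER_MASS_DA = 3691.5

#: M-grade HPMCAS substituent occupancies (fraction of substituent positions).
HPMCAS_SUBSTITUENT_FRACTIONS: Mapping[str, float] = {
    "methoxy": 0.644,
    "hydroxypropoxy": 0.089,
    "acetyl": 0.111,
    "succinate": 0.089,
    "hydroxyl": 0.067,
}


class PackingError(RuntimeError):
    """Random insertion exhausted its attempts."""

    def __init__(self, placed: int, requested: int, attempts: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed {placed} of {requested} molecules within {attempts} attempts"
        )


@dataclass(frozen=True)
class MonomerUnit:
    """A repeat unit (or a single molecule treated as one)."""

    name: str
    mass: float                  # Da
    formula: str | None = None
    net_charge: int = 0          # elementary charges

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"{self.name}: mass must be positive")
        if self.formula is not None:
            expected = formula_mass(self.formula)
            if abs(expected - self.mass) > 0.05:
                raise ValueError(
                    f"{self.name}: mass {self.mass} Da inconsistent with formula "
                    f"{self.formula} ({expected:.3f} Da)"
                )


@dataclass(frozen=True)
class OligomerSpec:
    """An oligomer as counted repeat units plus an end-group mass correction."""

    name: str
    units: tuple[tuple[MonomerUnit, int], ...]
    terminal_adjustment: float = 0.0       # Da
    substituent_fractions: Mapping[str, float] | None = None
    net_charge: int = 0                    # elementary charges

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError(f"{self.name}: oligomer has no units")
        for unit, count in self.units:
            if count < 1:
                raise ValueError(f"{self.name}: unit {unit.name} count < 1")
        if self.substituent_fractions is not None:
            total = sum(self.substituent_fractions.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"{self.name}: substituent fractions sum to {total}, expected 1"
                )


def oligomer_mass(spec: OligomerSpec) -> float:
    """Total oligomer mass: sum of count * unit mass, plus the end correction."""
    return sum(count * unit.mass for unit, count in spec.units) + spec.terminal_adjustment


@dataclass(frozen=True)
class MassRatio:
    """A normalized mass ratio, kept unrounded with a 2-decimal display value."""

    value: float

    @property
    def rounded(self) -> float:
        return round(self.value, 2)

    def as_one_to(self) -> str:
        return f"1:{self.rounded:.2f}"


def drug_oligomer_mass_ratio(n_drug: int, m_drug: float, m_olig: float) -> MassRatio:
    """Drug:oligomer mass ratio 1:x with x = m_olig / (n_drug * m_drug)."""
    if n_drug <= 0:
        raise ValueError("n_drug must be positive")
    if m_drug <= 0 or m_olig <= 0:
        raise ValueError("masses must be positive")
    return MassRatio(m_olig / (n_drug * m_drug))


def counterion_mass_ratio(ion_mass: float, m_drug: float) -> float:
    """Counterion:drug mass ratio x:1 at 1:1 stoichiometry (x = ion/drug)."""
    if ion_mass <= 0 or m_drug <= 0:
        raise ValueError("masses must be positive")
    return ion_mass / m_drug


def ions_for_molarity(edges: Sequence[float], molarity: float) -> int:
    """Salt ion pairs giving the target molarity in an orthorhombic box.

    ``round(V * c * N_A)`` with the box volume from the edge lengths in
    Angstrom (1 A^3 = 1e-27 L); nearest-integer rounding.
    """
    ex, ey, ez = edges
    if min(ex, ey, ez) <= 0:
        raise ValueError("box edges must be positive")
    if molarity < 0:
        raise ValueError("molarity must be >= 0")
    volume_l = ex * ey * ez * 1e-27
    return int(round(volume_l * molarity * AVOGADRO))


def neutralizing_ions(solute_charges: Sequence[float]) -> int:
    """Monovalent cations needed to neutralize the net negative solute charge."""
    total = sum(solute_charges)
    if total > 1e-9:
        raise ValueError(
            "net positive solute charge is unsupported (anion planning only)"
        )
    return int(round(abs(total)))


def box_ion_counts(
    solute_charges: Sequence[float], salt_pairs: int
) -> tuple[int, int]:
    """(n_Na, n_Cl) = (neutralizing cations + salt pairs, salt pairs)."""
    if salt_pairs < 0:
        raise ValueError("salt_pairs must be >= 0")
    return neutralizing_ions(solute_charges) + salt_pairs, salt_pairs


def redistribute_charge(
    per_atom_charges: Sequence[float], target_total: float = 0.0
) -> np.ndarray:
    """Shift every atomic charge equally so the total equals ``target_total``.

    This is the residual-charge correction applied when capped monomer charge
    sets leave an oligomer with a small non-integer net charge; the uniform
    shift preserves all charge differences between atoms.
    """
    charges = np.asarray(per_atom_charges, dtype=float)
    if charges.size == 0:
        raise ValueError("empty charge list")
    shift = (target_total - charges.sum()) / charges.size
    out = charges + shift
    # remove any residual floating-point drift on the total
    out[-1] += target_total - out.sum()
    return out


@dataclass(frozen=True)
class DoseScenario:
    """An oral dose dissolving in a fixed fluid volume."""

    dose: float                    # mg
    fluid_volume: float            # mL
    equilibrium_solubility: float  # mg/L

    def __post_init__(self) -> None:
        if min(self.dose, self.fluid_volume, self.equilibrium_solubility) <= 0:
            raise ValueError("all dose-scenario fields must be strictly positive")


def supersaturation_ratio(scenario: DoseScenario) -> float:
    """Fold supersaturation: (dose / fluid volume, as mg/L) / solubility.

    Report to 3 significant figures when printing; the unrounded value is
    returned.
    """
    concentration = scenario.dose / (scenario.fluid_volume / 1000.0)  # mg/L
    return concentration / scenario.equilibrium_solubility


def round_sig(value: float, figures: int = 3) -> float:
    """Round to a number of significant figures (reporting helper)."""
    if value == 0:
        return 0.0
    magnitude = math.floor(math.log10(abs(value)))
    return round(value, figures - 1 - magnitude)


@dataclass(frozen=True)
class BoxPlan:
    """Composition of one simulation box (counts recorded, not predicted)."""

    edges: tuple[float, float, float]       # Angstrom
    n_drug: int
    drug_state: Literal["neutral", "anionic"]
    n_Na: int
    n_Cl: int
    oligomer: OligomerSpec | None = None
    n_water: int = 0
    target_molarity: float = 0.0

    def __post_init__(self) -> None:
        if min(self.edges) <= 0:
            raise ValueError("box edges must be positive")
        if min(self.n_drug, self.n_Na, self.n_Cl, self.n_water) < 0:
            raise ValueError("counts must be >= 0")
        drug_charge = -self.n_drug if self.drug_state == "anionic" else 0
        olig_charge = self.oligomer.net_charge if self.oligomer else 0
        if drug_charge + olig_charge + self.n_Na - self.n_Cl != 0:
            raise ValueError(
                "box is not electroneutral: solute charge "
                f"{drug_charge + olig_charge}, n_Na {self.n_Na}, n_Cl {self.n_Cl}"
            )

    def to_dict(self) -> dict:
        return {
            "edges": list(self.edges),
            "n_drug": self.n_drug,
            "drug_state": self.drug_state,
            "oligomer": None if self.oligomer is None else self.oligomer.name,
            "n_water": self.n_water,
            "n_Na": self.n_Na,
            "n_Cl": self.n_Cl,
            "target_molarity": self.target_molarity,
        }


def plan_box(
    edges: Sequence[float],
    n_drug: int,
    drug_state: Literal["neutral", "anionic"],
    oligomer: OligomerSpec | None = None,
    molarity: float = 0.01,
    n_water: int = 0,
) -> BoxPlan:
    """Build an electroneutral box plan for the requested composition."""
    salt = ions_for_molarity(edges, molarity)
    charges = [-1.0] * n_drug if drug_state == "anionic" else []
    if oligomer is not None and oligomer.net_charge:
        charges.append(float(oligomer.net_charge))
    n_na, n_cl = box_ion_counts(charges, salt)
    return BoxPlan(
        edges=tuple(float(e) for e in edges),  # type: ignore[arg-type]
        n_drug=n_drug,
        drug_state=drug_state,
        n_Na=n_na,
        n_Cl=n_cl,
        oligomer=oligomer,
        n_water=n_water,
        target_molarity=molarity,
    )


def random_insertion(
    n_molecules: int,
    edges: Sequence[float],
    min_separation: float,
    seed: int,
    max_attempts: int = 10000,
) -> np.ndarray:
    """Place molecule centres uniformly in the box, all pairwise minimum-image
    distances at least ``min_separation``; deterministic for a given seed.

    Returns an (n, 3) array of centres; raises :class:`PackingError` with the
    achieved count when the attempt budget is exhausted.
    """
    if n_molecules < 1:
        raise ValueError("need at least one molecule")
    box = np.asarray(edges, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_molecules:
        if attempts >= max_attempts:
            raise PackingError(len(placed), n_molecules, max_attempts)
        attempts += 1
        candidate = rng.random(3) * box
        ok = True
        for other in placed:
            delta = candidate - other
            delta -= box * np.round(delta / box)
            if float(np.linalg.norm(delta)) < min_separation:
                ok = False
                break
        if ok:
            placed.append(candidate)
    return np.array(placed)


# ---------------------------------------------------------------------------
# Reference fixtures
# ---------------------------------------------------------------------------

def celecoxib_unit() -> MonomerUnit:
    """Celecoxib as a single unit (C17H14F3N3O2S, 381.4 Da)."""
    return MonomerUnit("celecoxib", formula_mass("C17H14F3N3O2S"), "C17H14F3N3O2S")


def pvpva_34mer() -> OligomerSpec:
    """The model PVP-VA 34-mer: 18 vinylpyrrolidone + 16 vinyl acetate units.

    The end-group correction is calibrated so the total matches the reported
    3375.5 Da (the raw two-H-terminated sum is ~3378.0 Da; the exact end
    groups of the reference model are unstated).
    """
    vp = MonomerUnit("vinylpyrrolidone", formula_mass("C6H9NO"), "C6H9NO")
    va = MonomerUnit("vinyl_acetate", formula_mass("C4H6O2"), "C4H6O2")
    raw = 18 * vp.mass + 16 * va.mass
    return OligomerSpec(
        "pvpva_34mer",
        units=((vp, 18), (va, 16)),
        terminal_adjustment=PVPVA_34MER_MASS_DA - raw,
        net_charge=0,
    )


def hpmcas_15mer() -> OligomerSpec:
    """The model M-grade HPMCAS 15-mer with averaged substituent occupancy.

    45 substituent positions carry methoxy/hydroxypropoxy/acetyl/succinate/
    free-hydroxyl groups in the M-grade proportions; the ~4 succinates are
    deprotonated, giving the oligomer a net charge of -4.  The end-group
    correction is calibrated to the reported 3691.5 Da.
    """
    core = formula_mass("C6H10O5")  # anhydroglucose
    additions = {
        "methoxy": formula_mass("CH2"),          # -H +CH3
        "hydroxypropoxy": formula_mass("C3H6O"),
        "acetyl": formula_mass("C2H2O"),
        "succinate": formula_mass("C4H4O3"),     # deprotonated succinoyl
        "hydroxyl": 0.0,
    }
    fractions = HPMCAS_SUBSTITUENT_FRACTIONS
    avg_mass = core + 3 * sum(fractions[k] * additions[k] for k in fractions)
    unit = MonomerUnit("hpmcas_avg_monomer", avg_mass)
    raw = 15 * avg_mass
    return OligomerSpec(
        "hpmcas_15mer",
        units=((unit, 15),),
        terminal_adjustment=HPMCAS_15MER_MASS_DA - raw,
        substituent_fractions=fractions,
        net_charge=-4,
    )
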