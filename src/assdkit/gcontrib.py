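"""Group-contribution miscibility screening for drug-polymer dispersions.

Implements the Fedors and Hoftyzer-Van Krevelen (HVK) group-contribution
estimates of the Hildebrand/Hansen solubility parameter, the solubility
parameter mismatch between a drug and a polymer, the lattice Flory-Huggins
interaction parameter computed from that mismatch, and the conventional
miscibility verdict (mismatch below 7 MPa^1/2).

The Fedors method estimates the cohesive energy density from additive
vaporization-energy and molar-volume increments::

    delta = sqrt(E_v / V_m),   E_v = sum_i n_i dEv_i,   V_m = sum_i n_i V_i

with ``delta`` in MPa^1/2 (1 J/cm^3 == 1 MPa).  The HVK method splits the
parameter into dispersion, polar and hydrogen-bonding components::

    delta_d = sum(F_d) / V_m
    delta_p = sqrt(sum(F_p^2)) / V_m
    delta_h = sqrt(sum(E_h) / V_m)
    delta^2 = delta_d^2 + delta_p^2 + delta_h^2

The Flory-Huggins parameter follows from the mean-parameter mismatch::

    chi = V_site * (delta_drug - delta_polymer)^2 / (R T)

where ``V_site`` is the lattice-site volume, conventionally the drug's
Fedors molar volume.
"""

from __future__ import annotations

import csv
import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

__all__ = [
    "GAS_CONSTANT",
    "MISCIBILITY_THRESHOLD",
    "GroupEntry",
    "GroupContributionTable",
    "Decomposition",
    "SolubilityProfile",
    "MiscibilityReport",
    "UnknownGroupError",
    "fedors_delta",
    "hvk_delta",
    "polymer_delta",
    "delta_mismatch",
    "flory_huggins_chi",
    "assess_miscibility",
    "load_default_table",
    "load_reference_decompositions",
    "parse_formula",
    "formula_mass",
]

#: Gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: Conventional miscibility threshold on the solubility-parameter mismatch,
#: MPa^1/2.  Strict: a mismatch equal to the threshold is judged immiscible.
MISCIBILITY_THRESHOLD = 7.0

# Standard atomic weights (Da) for the elements that occur in the shipped
# fixtures plus common pharmaceutical heteroatoms.
ATOMIC_MASSES: Mapping[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "K": 39.098, "Br": 79.904, "I": 126.904,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownGroupError(KeyError):
    """A decomposition references a group absent from the active table."""


def parse_formula(formula: str) -> Counter:
    """Parse a Hill-style molecular formula (e.g. ``C17H14F3N3O2S``)."""
    counts: Counter = Counter()
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = match.end()
        element, number = match.groups()
        if element not in ATOMIC_MASSES:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] += int(number) if number else 1
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def formula_mass(formula: str) -> float:
    """Molecular mass in Da from a molecular formula."""
    return sum(ATOMIC_MASSES[el] * n for el, n in parse_formula(formula).items())


@dataclass(frozen=True)
class GroupEntry:
    """One row of a group-contribution table.

    ``dEv``/``V`` feed the Fedors method, ``Fd``/``Fp``/``Eh``/``V`` the HVK
    method; ``V`` may be negative for branch or correction entries.
    """

    name: str
    formula: str | None = None
    dEv: float | None = None   # J/mol
    V: float | None = None     # cm^3/mol
    Fd: float | None = None    # (J cm^3)^0.5 / mol
    Fp: float | None = None    # (J cm^3)^0.5 / mol
    Eh: float | None = None    # J/mol

    def __post_init__(self) -> None:
        if self.Eh is not None and self.Eh < 0:
            raise ValueError(f"group {self.name!r}: Eh must be >= 0")
        for attr in ("dEv", "V", "Fd", "Fp", "Eh"):
            value = getattr(self, attr)
            if value is not None and not math.isfinite(value):
                raise ValueError(f"group {self.name!r}: {attr} must be finite")

    def require(self, *attrs: str) -> None:
        for attr in attrs:
            if getattr(self, attr) is None:
                raise ValueError(
                    f"group {self.name!r} lacks the {attr!r} coefficient required here"
                )


class GroupContributionTable:
    """Lookup table of :class:`GroupEntry` rows keyed by group name."""

    def __init__(self, entries: Iterable[GroupEntry]):
        self._entries: dict[str, GroupEntry] = {}
        for entry in entries:
            if entry.name in self._entries:
                raise ValueError(f"duplicate group {entry.name!r}")
            self._entries[entry.name] = entry

    def __getitem__(self, name: str) -> GroupEntry:
        try:
            return self._entries[name]
        except KeyError:
            raise UnknownGroupError(
                f"group {name!r} does not resolve in the active table"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def names(self) -> list[str]:
        return list(self._entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupContributionTable":
        """Load a delimited table (columns name, formula, dEv, V, Fd, Fp, Eh)."""
        entries = []
        with open(path, newline="") as handle:
            rows = (row for row in handle if not row.lstrip().startswith("#"))
            for record in csv.DictReader(rows):
                def num(key: str) -> float | None:
                    raw = (record.get(key) or "").strip()
                    return float(raw) if raw else None

                entries.append(
                    GroupEntry(
                        name=record["name"].strip(),
                        formula=(record.get("formula") or "").strip() or None,
                        dEv=num("dEv"), V=num("V"),
                        Fd=num("Fd"), Fp=num("Fp"), Eh=num("Eh"),
                    )
                )
        return cls(entries)


def _data_path(name: str) -> Path:
    return Path(resources.files("assdkit").joinpath("data", name))  # type: ignore[arg-type]


def load_default_table() -> GroupContributionTable:
    """The shipped Fedors + HVK coefficient table."""
    return GroupContributionTable.from_csv(_data_path("group_contributions.csv"))


@dataclass(frozen=True)
class Decomposition:
    """A molecule's functional-group inventory.

    Counts are positive; fractional counts express averaged repeat units
    (e.g. a cellulose monomer with fractional substituent occupancies), in
    which case no atom balance is defined and ``formula`` should be ``None``.
    """

    molecule_id: str
    groups: tuple[tuple[str, float], ...]
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError(f"{self.molecule_id}: empty decomposition")
        for name, count in self.groups:
            if not count > 0:
                raise ValueError(
                    f"{self.molecule_id}: group {name!r} has non-positive count {count}"
                )

    @classmethod
    def from_mapping(
        cls, molecule_id: str, groups: Mapping[str, float], formula: str | None = None
    ) -> "Decomposition":
        return cls(molecule_id, tuple(groups.items()), formula)

    def check_atom_balance(self, table: GroupContributionTable) -> None:
        """Verify that summed group formulas equal the molecular formula.

        Only available for integer-count decompositions with a formula.
        """
        if self.formula is None:
            raise ValueError(f"{self.molecule_id}: no molecular formula recorded")
        total: Counter = Counter()
        for name, count in self.groups:
            entry = table[name]
            if abs(count - round(count)) > 1e-9:
                raise ValueError(
                    f"{self.molecule_id}: fractional count for {name!r}; "
                    "atom balance undefined"
                )
            if entry.formula:
                for el, n in parse_formula(entry.formula).items():
                    total[el] += n * int(round(count))
        expected = parse_formula(self.formula)
        if total != expected:
            raise ValueError(
                f"{self.molecule_id}: group formulas sum to "
                f"{dict(total)} but molecular formula is {dict(expected)}"
            )

    def molar_mass(self) -> float:
        if self.formula is None:
            raise ValueError(f"{self.molecule_id}: no molecular formula recorded")
        return formula_mass(self.formula)


def load_reference_decompositions() -> dict[str, Decomposition]:
    """The shipped drug / repeat-unit decompositions, atom-balance checked."""
    with open(_data_path("decompositions.json")) as handle:
        raw = json.load(handle)
    table = load_default_table()
    out = {}
    for molecule_id, payload in raw.items():
        if molecule_id.startswith("_"):
            continue
        decomp = Decomposition.from_mapping(
            molecule_id, payload["groups"], payload.get("formula")
        )
        if decomp.formula is not None:
            decomp.check_atom_balance(table)
        out[molecule_id] = decomp
    return out


@dataclass(frozen=True)
class SolubilityProfile:
    """Solubility parameter of one species by one method (all deltas MPa^1/2)."""

    method: Literal["fedors", "hvk"]
    delta: float
    Vm: float                      # cm^3/mol
    Ev: float | None = None        # J/mol (Fedors only)
    delta_d: float | None = None
    delta_p: float | None = None
    delta_h: float | None = None

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not self.Vm > 0:
            raise ValueError("Vm must be > 0")
        if self.method == "hvk":
            comps = (self.delta_d, self.delta_p, self.delta_h)
            if any(c is None for c in comps):
                raise ValueError("hvk profile requires delta_d, delta_p, delta_h")
            ssq = sum(c * c for c in comps)  # type: ignore[operator]
            if abs(ssq - self.delta**2) > 1e-9 * max(self.delta**2, 1.0):
                raise ValueError("delta^2 != delta_d^2 + delta_p^2 + delta_h^2")


def _accumulate(
    decomp: Decomposition, table: GroupContributionTable, attrs: Sequence[str]
) -> dict[str, float]:
    sums = {attr: 0.0 for attr in attrs}
    sums["Fp2"] = 0.0
    for name, count in decomp.groups:
        entry = table[name]
        for attr in attrs:
            entry.require(attr)
            value = getattr(entry, attr)
            sums[attr] += count * value
            if attr == "Fp":
                # The polar term sums squared per-group contributions before
                # the square root; counts weight the squared contributions.
                sums["Fp2"] += count * value * value
    return sums


def fedors_delta(
    decomp: Decomposition, table: GroupContributionTable | None = None
) -> SolubilityProfile:
    """Fedors cohesive-energy-density estimate of the solubility parameter."""
    table = table if table is not None else load_default_table()
    sums = _accumulate(decomp, table, ("dEv", "V"))
    Ev, Vm = sums["dEv"], sums["V"]
    if not Vm > 0:
        raise ValueError(f"{decomp.molecule_id}: summed molar volume {Vm} <= 0")
    return SolubilityProfile("fedors", math.sqrt(Ev / Vm), Vm, Ev=Ev)


def hvk_delta(
    decomp: Decomposition, table: GroupContributionTable | None = None
) -> SolubilityProfile:
    """Hoftyzer-Van Krevelen three-component solubility parameter."""
    table = table if table is not None else load_default_table()
    sums = _accumulate(decomp, table, ("Fd", "Fp", "Eh", "V"))
    Vm = sums["V"]
    if not Vm > 0:
        raise ValueError(f"{decomp.molecule_id}: summed molar volume {Vm} <= 0")
    delta_d = sums["Fd"] / Vm
    delta_p = math.sqrt(sums["Fp2"]) / Vm
    delta_h = math.sqrt(sums["Eh"] / Vm)
    delta = math.sqrt(delta_d**2 + delta_p**2 + delta_h**2)
    return SolubilityProfile(
        "hvk", delta, Vm, delta_d=delta_d, delta_p=delta_p, delta_h=delta_h
    )


def polymer_delta(
    units: Sequence[tuple[Decomposition, float]],
    table: GroupContributionTable | None = None,
    method: Literal["fedors", "hvk"] = "fedors",
    fractions: Literal["mass", "mole"] = "mass",
) -> SolubilityProfile:
    """Solubility parameter of a copolymer from its repeat units.

    Group counts of the units are pooled into one average repeat unit and the
    chosen method applied once.  With ``fractions="mass"`` (the default) the
    weights are mass fractions, converted to mole proportions via each unit's
    molar mass so that e.g. a 6:4 VP:VA mass ratio pools mole-proportionally;
    with ``fractions="mole"`` the weights are used as mole proportions
    directly (they need not sum to 1 in that mode).
    """
    if not units:
        raise ValueError("empty unit list")
    table = table if table is not None else load_default_table()
    weights = [w for _, w in units]
    if any(w <= 0 for w in weights):
        raise ValueError("unit weights must be positive")
    if fractions == "mass":
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"mass fractions sum to {sum(weights)}, expected 1")
        moles = [w / decomp.molar_mass() for (decomp, _), w in zip(units, weights)]
    else:
        moles = list(weights)
    total = sum(moles)
    pooled: dict[str, float] = {}
    for (decomp, _), n in zip(units, moles):
        for name, count in decomp.groups:
            pooled[name] = pooled.get(name, 0.0) + count * n / total
    ids = "+".join(decomp.molecule_id for decomp, _ in units)
    avg = Decomposition.from_mapping(f"avg({ids})", pooled)
    op = fedors_delta if method == "fedors" else hvk_delta
    return op(avg, table)


def delta_mismatch(
    drug: tuple[SolubilityProfile, SolubilityProfile],
    polymer: tuple[SolubilityProfile, SolubilityProfile],
) -> float:
    """|mean delta(drug) - mean delta(polymer)| with means over the two methods."""
    mean_drug = (drug[0].delta + drug[1].delta) / 2.0
    mean_poly = (polymer[0].delta + polymer[1].delta) / 2.0
    return abs(mean_drug - mean_poly)


def flory_huggins_chi(
    delta_drug: float, delta_polymer: float, V_site: float, T: float = 298.15
) -> float:
    """Flory-Huggins chi from the solubility-parameter mismatch.

    ``chi = V_site (delta_drug - delta_polymer)^2 / (R T)``; with deltas in
    MPa^1/2 and ``V_site`` in cm^3/mol the numerator is already J/mol
    (MPa cm^3/mol == J/mol).
    """
    if not V_site > 0:
        raise ValueError("V_site must be > 0")
    if not T > 0:
        raise ValueError("T must be > 0")
    return V_site * (delta_drug - delta_polymer) ** 2 / (GAS_CONSTANT * T)


def assess_miscibility(mismatch: float) -> Literal["miscible", "not_miscible"]:
    """Verdict from the mismatch: miscible iff strictly below 7 MPa^1/2."""
    if mismatch < 0:
        raise ValueError("mismatch must be >= 0")
    return "miscible" if mismatch < MISCIBILITY_THRESHOLD else "not_miscible"


@dataclass(frozen=True)
class MiscibilityReport:
    """Drug-polymer miscibility summary (the shape of a screening-table row)."""

    delta_drug: float       # mean over methods, MPa^1/2
    delta_polymer: float    # mean over methods, MPa^1/2
    delta_mismatch: float   # MPa^1/2
    chi: float
    V_site: float           # cm^3/mol
    T: float                # K
    verdict: Literal["miscible", "not_miscible"]

    def __post_init__(self) -> None:
        if self.delta_mismatch < 0:
            raise ValueError("delta_mismatch must be >= 0")
        if self.chi < 0:
            raise ValueError("chi must be >= 0")
        if (self.chi == 0) != (self.delta_mismatch == 0):
            raise ValueError("chi == 0 iff delta_mismatch == 0")


def miscibility_report(
    drug: tuple[SolubilityProfile, SolubilityProfile],
    polymer: tuple[SolubilityProfile, SolubilityProfile],
    V_site: float | None = None,
    T: float = 298.15,
) -> MiscibilityReport:
    """Assemble the full report for one drug-polymer pair.

    ``V_site`` defaults to the drug's Fedors molar volume, the choice that is
    consistent with inverting the chi definition on the reference systems.
    """
    if V_site is None:
        fed = drug[0] if drug[0].method == "fedors" else drug[1]
        V_site = fed.Vm
    mean_drug = (drug[0].delta + drug[1].delta) / 2.0
    mean_poly = (polymer[0].delta + polymer[1].delta) / 2.0
    mismatch = abs(mean_drug - mean_poly)
    chi = flory_huggins_chi(mean_drug, mean_poly, V_site, T)
    return MiscibilityReport(
        delta_drug=mean_drug,
        delta_polymer=mean_poly,
        delta_mismatch=mismatch,
        chi=chi,
        V_site=V_site,
        T=T,
        verdict=assess_miscibility(mismatch),
    )
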