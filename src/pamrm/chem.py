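"""Elemental-composition arithmetic and monoisotopic m/z computation for
glycerophospholipids.

All masses are monoisotopic and pinned to the constant table below so that
every derived value in the test suite is reproducible bit-for-bit.  Ion m/z
values include electron-mass bookkeeping: an anion gains one electron mass,
a cation loses one.  Printed m/z values follow the two-decimal *truncation*
convention used on unit-resolution triple-quadrupole instruments (671.4657
prints as "671.46", not "671.47").
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_DOWN
from typing import Mapping, Optional, Tuple

__all__ = [
    "ATOMIC_MASSES",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ElementalComposition",
    "AcylChain",
    "LipidClass",
    "LipidSpecies",
    "AdductDef",
    "ADDUCTS",
    "composition_of_species",
    "species_composition",
    "monoisotopic_mass",
    "adduct_mz",
    "acyl_anion_mz",
    "free_fatty_acid_composition",
    "format_mz",
]

#: Monoisotopic atomic masses (Da).  C-12 is exactly 12 by definition;
#: the others are IUPAC 2005 values rounded to 8 decimals.
ATOMIC_MASSES: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "D": 2.01410178,
    "O": 15.99491462,
    "P": 30.97376151,
    "N": 14.00307401,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Li": 7.01600344,
}

ELECTRON_MASS: float = 0.00054858
PROTON_MASS: float = ATOMIC_MASSES["H"] - ELECTRON_MASS

#: Mass shift per H -> D substitution.
DEUTERIUM_SHIFT: float = ATOMIC_MASSES["D"] - ATOMIC_MASSES["H"]

_HILL_ORDER = ("C", "H", "D", "N", "O", "P", "Na", "K", "Li")


@dataclass(frozen=True)
class ElementalComposition:
    """A multiset of atoms plus an integer charge.

    Counts are non-negative; subtracting more atoms than present raises
    ``ValueError``.  Addition and subtraction are element-wise; charge adds.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {}
        for element, count in self.counts.items():
            if element not in ATOMIC_MASSES:
                raise ValueError(f"unsupported element {element!r}")
            if not isinstance(count, int):
                raise TypeError(f"count for {element} must be an integer")
            if count < 0:
                raise ValueError(f"negative count for {element}: {count}")
            if count > 0:
                clean[element] = count
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return ElementalComposition(merged, self.charge + other.charge)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            remaining = merged.get(element, 0) - count
            if remaining < 0:
                raise ValueError(
                    f"cannot remove {count} {element} from composition with "
                    f"{merged.get(element, 0)}"
                )
            merged[element] = remaining
        return ElementalComposition(merged, self.charge - other.charge)

    def replace_charge(self, charge: int) -> "ElementalComposition":
        return ElementalComposition(dict(self.counts), charge)

    @property
    def formula(self) -> str:
        """Hill-style formula string, e.g. ``C37H69O8P``."""
        parts = []
        for element in _HILL_ORDER:
            count = self[element]
            if count == 1:
                parts.append(element)
            elif count > 1:
                parts.append(f"{element}{count}")
        return "".join(parts) or "empty"

    def __str__(self) -> str:  # pragma: no cover - convenience
        if self.charge:
            sign = "+" if self.charge > 0 else "-"
            return f"{self.formula}[{abs(self.charge)}{sign}]"
        return self.formula


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic mass in Da, with electron bookkeeping for ions."""
    mass = sum(ATOMIC_MASSES[el] * n for el, n in comp.counts.items())
    return mass - comp.charge * ELECTRON_MASS


@dataclass(frozen=True)
class AcylChain:
    """A fatty acyl chain ``c:d``, optionally deuterated (e.g. 16:0D31)."""

    carbons: int
    double_bonds: int = 0
    n_deuterium: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"acyl chain needs >= 1 carbon, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")
        ffa_hydrogens = 2 * self.carbons - 2 * self.double_bonds
        if ffa_hydrogens < 1:
            raise ValueError(
                f"chain {self.carbons}:{self.double_bonds} has no free-acid hydrogens"
            )
        if not 0 <= self.n_deuterium <= ffa_hydrogens:
            raise ValueError(
                f"n_deuterium={self.n_deuterium} exceeds the {ffa_hydrogens} "
                f"hydrogens of the {self.carbons}:{self.double_bonds} free acid"
            )

    @classmethod
    def parse(cls, text: str) -> "AcylChain":
        """Parse shorthand like ``18:1`` or ``16:0D31``."""
        body, _, deut = text.strip().partition("D")
        c_str, _, d_str = body.partition(":")
        try:
            return cls(int(c_str), int(d_str or 0), int(deut) if deut else 0)
        except ValueError as exc:
            raise ValueError(f"cannot parse acyl chain {text!r}") from exc

    def __str__(self) -> str:
        base = f"{self.carbons}:{self.double_bonds}"
        return f"{base}D{self.n_deuterium}" if self.n_deuterium else base

    @property
    def sort_key(self) -> Tuple[int, int, int]:
        return (self.carbons, self.double_bonds, self.n_deuterium)


def free_fatty_acid_composition(chain: AcylChain) -> ElementalComposition:
    """Neutral free fatty acid C_c H_{2c-2d} O2 (deuterium substituted)."""
    hydrogens = 2 * chain.carbons - 2 * chain.double_bonds - chain.n_deuterium
    counts = {"C": chain.carbons, "H": hydrogens, "O": 2}
    if chain.n_deuterium:
        counts["D"] = chain.n_deuterium
    return ElementalComposition(counts)


def acyl_anion_composition(chain: AcylChain) -> ElementalComposition:
    """The [RCOO]- carboxylate anion: the free acid minus one proton."""
    hydrogens = 2 * chain.carbons - 2 * chain.double_bonds - 1 - chain.n_deuterium
    if hydrogens < 0:
        raise ValueError(f"chain {chain} cannot lose a proton")
    counts = {"C": chain.carbons, "H": hydrogens, "O": 2}
    if chain.n_deuterium:
        counts["D"] = chain.n_deuterium
    return ElementalComposition(counts, charge=-1)


def acyl_anion_mz(chain: AcylChain) -> float:
    """m/z of the diagnostic fatty acyl carboxylate anion [RCOO]-."""
    return monoisotopic_mass(acyl_anion_composition(chain))


class LipidClass(enum.Enum):
    PA = "PA"
    LPA = "LPA"
    PC = "PC"
    LPC = "LPC"
    PE = "PE"
    LPE = "LPE"
    PS = "PS"
    LPS = "LPS"
    PG = "PG"
    LPG = "LPG"
    PI = "PI"
    LPI = "LPI"

    @property
    def is_lyso(self) -> bool:
        return self.value.startswith("L")

    @property
    def diacyl_parent(self) -> "LipidClass":
        return LipidClass(self.value[1:]) if self.is_lyso else self


# Head-group atom deltas relative to the PA backbone (signed, validated to be
# pure additions).  The diacyl PA skeleton is C_{m+3} H_{2m-2n+5} O8 P; other
# classes differ by the atoms of their head group.
HEAD_GROUP_DELTAS: Mapping[LipidClass, Mapping[str, int]] = {
    LipidClass.PA: {},
    LipidClass.PC: {"C": 5, "H": 11, "N": 1},
    LipidClass.PE: {"C": 2, "H": 5, "N": 1},
    LipidClass.PS: {"C": 3, "H": 5, "N": 1, "O": 2},
    LipidClass.PG: {"C": 3, "H": 6, "O": 2},
    LipidClass.PI: {"C": 6, "H": 10, "O": 5},
}


def composition_of_species(
    lipid_class: LipidClass | str, m: int, n: int
) -> ElementalComposition:
    """Neutral composition of a (lyso-)glycerophospholipid sum composition.

    For PA the generalized formula is C_{m+3} H_{2m-2n+5} O8 P, with ``m``
    total acyl carbons and ``n`` total double bonds; the lyso form is
    C_{m+3} H_{2m-2n+7} O7 P.  Other classes apply their head-group delta
    on top of the (L)PA skeleton.
    """
    if isinstance(lipid_class, str):
        try:
            lipid_class = LipidClass(lipid_class)
        except ValueError:
            raise ValueError(f"unknown lipid class {lipid_class!r}") from None
    min_carbons = 1 if lipid_class.is_lyso else 2
    if m < min_carbons:
        raise ValueError(
            f"{lipid_class.value} needs at least {min_carbons} acyl carbons, got m={m}"
        )
    if n < 0:
        raise ValueError(f"total double bonds must be >= 0, got n={n}")
    if lipid_class.is_lyso:
        hydrogens = 2 * m - 2 * n + 7
        oxygens = 7
    else:
        hydrogens = 2 * m - 2 * n + 5
        oxygens = 8
    if hydrogens <= 0:
        raise ValueError(
            f"impossible composition: {lipid_class.value} {m}:{n} implies "
            f"{hydrogens} hydrogens"
        )
    skeleton = ElementalComposition({"C": m + 3, "H": hydrogens, "O": oxygens, "P": 1})
    delta = HEAD_GROUP_DELTAS[lipid_class.diacyl_parent]
    if not delta:
        return skeleton
    return skeleton + ElementalComposition(dict(delta))


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species at sum-composition or resolved-chain level.

    ``chains`` is an sn-ordered ``(sn1, sn2)`` pair when the acyl chains are
    resolved, a single-element tuple for lyso species, and ``None`` for a
    sum-composition-only species.
    """

    lipid_class: LipidClass
    total_carbons: int
    total_double_bonds: int
    chains: Optional[Tuple[AcylChain, ...]] = None

    def __post_init__(self) -> None:
        if self.chains is not None:
            expected = 1 if self.lipid_class.is_lyso else 2
            if len(self.chains) != expected:
                raise ValueError(
                    f"{self.lipid_class.value} species must have {expected} chains"
                )
            if sum(c.carbons for c in self.chains) != self.total_carbons:
                raise ValueError("chain carbons do not sum to total_carbons")
            if sum(c.double_bonds for c in self.chains) != self.total_double_bonds:
                raise ValueError("chain double bonds do not sum to total_double_bonds")
        # validates the m/n combination
        composition_of_species(self.lipid_class, self.total_carbons, self.total_double_bonds)

    @classmethod
    def from_chains(
        cls, lipid_class: LipidClass | str, *chains: AcylChain
    ) -> "LipidSpecies":
        if isinstance(lipid_class, str):
            lipid_class = LipidClass(lipid_class)
        return cls(
            lipid_class,
            sum(c.carbons for c in chains),
            sum(c.double_bonds for c in chains),
            tuple(chains),
        )

    @classmethod
    def parse(cls, text: str) -> "LipidSpecies":
        """Parse ``PA(34:2)``, ``PA 34:2``, ``PA:34:2`` or ``PA(16:0/18:1)``."""
        text = text.strip()
        if "(" in text:
            cls_str, _, rest = text.partition("(")
            body = rest.rstrip(")")
        elif ":" in text and text.count(":") >= 2:
            cls_str, body = text.split(":", 1)
        else:
            cls_str, _, body = text.partition(" ")
        lipid_class = LipidClass(cls_str.strip())
        if "/" in body:
            chains = tuple(AcylChain.parse(part) for part in body.split("/"))
            return cls.from_chains(lipid_class, *chains)
        chain = AcylChain.parse(body)
        return cls(lipid_class, chain.carbons, chain.double_bonds)

    @property
    def name(self) -> str:
        if self.chains is not None:
            inner = "/".join(str(c) for c in self.chains)
        else:
            inner = f"{self.total_carbons}:{self.total_double_bonds}"
        return f"{self.lipid_class.value}({inner})"

    @property
    def sum_composition(self) -> Tuple[int, int]:
        return (self.total_carbons, self.total_double_bonds)

    @property
    def n_deuterium(self) -> int:
        if self.chains is None:
            return 0
        return sum(c.n_deuterium for c in self.chains)

    def __str__(self) -> str:
        return self.name


def species_composition(species: LipidSpecies) -> ElementalComposition:
    """Neutral composition of a species, applying chain deuteration."""
    comp = composition_of_species(
        species.lipid_class, species.total_carbons, species.total_double_bonds
    )
    n_d = species.n_deuterium
    if n_d:
        comp = comp - ElementalComposition({"H": n_d})
        comp = comp + ElementalComposition({"D": n_d})
    return comp


@dataclass(frozen=True)
class AdductDef:
    """An ionizing adduct: a signed atom delta plus the resulting charge."""

    name: str
    delta: Mapping[str, int]
    charge: int

    def apply(self, neutral: ElementalComposition) -> ElementalComposition:
        if neutral.charge != 0:
            raise ValueError("adducts apply to neutral compositions")
        gains = {el: n for el, n in self.delta.items() if n > 0}
        losses = {el: -n for el, n in self.delta.items() if n < 0}
        comp = neutral
        if gains:
            comp = comp + ElementalComposition(gains)
        if losses:
            try:
                comp = comp - ElementalComposition(losses)
            except ValueError as exc:
                raise ValueError(
                    f"adduct {self.name} removes atoms absent from {neutral.formula}"
                ) from exc
        return comp.replace_charge(self.charge)


#: The nine built-in adducts, in the order they appear in MS1 tables.
ADDUCTS: Mapping[str, AdductDef] = {
    a.name: a
    for a in (
        AdductDef("[M+H]+", {"H": 1}, +1),
        AdductDef("[M+H-H2O]+", {"H": -1, "O": -1}, +1),
        AdductDef("[M+NH4]+", {"N": 1, "H": 4}, +1),
        AdductDef("[M+Na]+", {"Na": 1}, +1),
        AdductDef("[M+K]+", {"K": 1}, +1),
        AdductDef("[M+Li]+", {"Li": 1}, +1),
        AdductDef("[M-H]-", {"H": -1}, -1),
        AdductDef("[M+HCO2]-", {"C": 1, "H": 1, "O": 2}, -1),
        AdductDef("[M+CH3CO2]-", {"C": 2, "H": 3, "O": 2}, -1),
    )
}


def adduct_mz(neutral: ElementalComposition, adduct: AdductDef | str) -> float:
    """m/z of an adduct ion of a neutral composition (|z| = 1 built-ins)."""
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ValueError(f"unknown adduct {adduct!r}") from None
    ion = adduct.apply(neutral)
    return monoisotopic_mass(ion) / abs(ion.charge)


def species_mz(species: LipidSpecies, adduct: AdductDef | str = "[M-H]-") -> float:
    """Convenience: adduct m/z of a species (deuteration included)."""
    return adduct_mz(species_composition(species), adduct)


def format_mz(x: float, places: int = 2) -> str:
    """Truncated (not rounded) decimal representation, e.g. 671.4657 -> '671.46'."""
    if x < 0:
        raise ValueError("m/z must be non-negative")
    if not math.isfinite(x):
        raise ValueError("m/z must be finite")
    quantum = Decimal(1).scaleb(-places)
    return str(Decimal(repr(x)).quantize(quantum, rounding=ROUND_DOWN))
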