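"""MS1 species/adduct tables, MS/MS fragment tables, sum-composition chain
decomposition, and MRM transition-list design."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import (
    ADDUCTS,
    AcylChain,
    LipidClass,
    LipidSpecies,
    acyl_anion_mz,
    adduct_mz,
    composition_of_species,
    format_mz,
    monoisotopic_mass,
)

__all__ = [
    "ChainSpace",
    "DEFAULT_PANEL_CHAINS",
    "MRMTransition",
    "TransitionOverflowError",
    "decompose_sum_composition",
    "build_ms1_table",
    "build_msms_table",
    "build_transition_list",
    "write_table",
]

#: Curated fatty acyl chains used as the default search space for transition
#: design.  These are the acyl chains commonly reported in insect and
#: mammalian glycerophospholipids plus the odd-carbon chains used by internal
#: standards; the set is deliberately NOT a full (carbon x double-bond) grid,
#: because chains such as 20:2 or 14:0 paired with rare partners would inflate
#: candidate lists with biologically implausible pairs.
DEFAULT_PANEL_CHAINS: Tuple[AcylChain, ...] = tuple(
    AcylChain(c, d)
    for c, d in (
        (12, 0), (13, 0),
        (14, 0), (14, 1), (14, 2),
        (15, 0),
        (16, 0), (16, 1), (16, 2),
        (17, 0),
        (18, 0), (18, 1), (18, 2), (18, 3),
        (20, 0), (20, 4),
        (22, 6),
    )
)


@dataclass(frozen=True)
class ChainSpace:
    """The search space of candidate acyl chains.

    Either a (min_carbons..max_carbons) x (0..max_db_per_chain) grid, or an
    explicit ``allowed_chains`` list which overrides the grid entirely.
    """

    min_carbons: int = 12
    max_carbons: int = 22
    allow_odd_carbons: bool = True
    max_db_per_chain: int = 6
    allowed_chains: Optional[FrozenSet[AcylChain]] = None

    def __post_init__(self) -> None:
        if self.min_carbons < 0 or self.max_carbons < 0:
            raise ValueError("carbon bounds must be >= 0")
        if self.min_carbons > self.max_carbons:
            raise ValueError("min_carbons must be <= max_carbons")
        if self.max_db_per_chain < 0:
            raise ValueError("max_db_per_chain must be >= 0")
        if self.allowed_chains is not None:
            object.__setattr__(self, "allowed_chains", frozenset(self.allowed_chains))

    @classmethod
    def default_panel(cls) -> "ChainSpace":
        """The documented default space for MRM design (curated chain list)."""
        return cls(allowed_chains=frozenset(DEFAULT_PANEL_CHAINS))

    @classmethod
    def from_chains(cls, chains: Iterable[AcylChain]) -> "ChainSpace":
        return cls(allowed_chains=frozenset(chains))

    def __contains__(self, chain: AcylChain) -> bool:
        if self.allowed_chains is not None:
            return AcylChain(chain.carbons, chain.double_bonds) in self.allowed_chains
        if not self.min_carbons <= chain.carbons <= self.max_carbons:
            return False
        if chain.double_bonds > self.max_db_per_chain:
            return False
        if not self.allow_odd_carbons and chain.carbons % 2:
            return False
        return True

    def chains(self) -> Iterator[AcylChain]:
        """All chains in the space, sorted by (carbons, double bonds)."""
        if self.allowed_chains is not None:
            yield from sorted(self.allowed_chains, key=lambda c: c.sort_key)
            return
        for carbons in range(self.min_carbons, self.max_carbons + 1):
            if not self.allow_odd_carbons and carbons % 2:
                continue
            for db in range(self.max_db_per_chain + 1):
                try:
                    yield AcylChain(carbons, db)
                except ValueError:
                    continue


ChainPair = Tuple[AcylChain, AcylChain]


def decompose_sum_composition(
    m: int, n: int, space: Optional[ChainSpace] = None
) -> List[ChainPair]:
    """All unordered chain pairs (c1:d1, c2:d2) with c1+c2=m and d1+d2=n.

    Pairs are returned with the lexicographically smaller chain first and the
    list sorted by (c1, d1, c2, d2); sn order is decided downstream from
    fragment intensities, not here.
    """
    if m < 0 or n < 0:
        raise ValueError("m and n must be >= 0")
    space = space if space is not None else ChainSpace()
    pairs = set()
    for chain1 in space.chains():
        c2 = m - chain1.carbons
        d2 = n - chain1.double_bonds
        if c2 < 1 or d2 < 0:
            continue
        try:
            chain2 = AcylChain(c2, d2)
        except ValueError:
            continue
        if chain2 not in space:
            continue
        pair = tuple(sorted((chain1, chain2), key=lambda c: c.sort_key))
        pairs.add(pair)
    return sorted(pairs, key=lambda p: p[0].sort_key + p[1].sort_key)


def build_ms1_table(
    lipid_class: LipidClass | str,
    m_range: Tuple[int, int],
    n_range: Tuple[int, int],
    space: Optional[ChainSpace] = None,
) -> pd.DataFrame:
    """One row per (m, n) with formula, neutral mass and nine adduct m/z.

    Full-precision columns are paired with two-decimal truncated display
    columns.  Rows whose sum composition has no chain-pair decomposition in
    ``space`` (or an impossible hydrogen count) are flagged ``valid=False``.
    """
    if isinstance(lipid_class, str):
        lipid_class = LipidClass(lipid_class)
    m_lo, m_hi = m_range
    n_lo, n_hi = n_range
    if m_lo > m_hi or n_lo > n_hi:
        raise ValueError("empty m or n range")
    space = space if space is not None else ChainSpace()
    rows = []
    for m, n in itertools.product(range(m_lo, m_hi + 1), range(n_lo, n_hi + 1)):
        row = {
            "species": f"{lipid_class.value}({m}:{n})",
            "m": m,
            "n": n,
        }
        try:
            comp = composition_of_species(lipid_class, m, n)
        except ValueError:
            row.update({"formula": None, "neutral_mass": np.nan, "valid": False,
                        "n_chain_pairs": 0})
            for adduct_name in ADDUCTS:
                row[adduct_name] = np.nan
                row[f"{adduct_name} (2dp)"] = None
            rows.append(row)
            continue
        row["formula"] = comp.formula
        row["neutral_mass"] = monoisotopic_mass(comp)
        for adduct_name, adduct in ADDUCTS.items():
            try:
                mz = adduct_mz(comp, adduct)
            except ValueError:
                mz = np.nan
            row[adduct_name] = mz
            row[f"{adduct_name} (2dp)"] = format_mz(mz) if np.isfinite(mz) else None
        if lipid_class.is_lyso:
            n_pairs = sum(1 for c in space.chains()
                          if c.carbons == m and c.double_bonds == n)
        else:
            n_pairs = len(decompose_sum_composition(m, n, space))
        row["n_chain_pairs"] = n_pairs
        row["valid"] = n_pairs > 0
        rows.append(row)
    return pd.DataFrame(rows)


def build_msms_table(
    chain: AcylChain,
    lipid_class: LipidClass | str = LipidClass.PA,
    space: Optional[ChainSpace] = None,
) -> pd.DataFrame:
    """Fragment masses diagnostic of one acyl chain in negative mode.

    Rows: the chain's carboxylate anion [RCOO]-; the lyso-species [M-H]-
    that remains when the complementary chain is lost; and, for every
    complementary chain in the space, the diacyl precursor [M-H]- that would
    yield those fragments.
    """
    if isinstance(lipid_class, str):
        lipid_class = LipidClass(lipid_class)
    if lipid_class.is_lyso:
        raise ValueError("fragment tables are built for diacyl classes")
    space = space if space is not None else ChainSpace()
    lyso_class = LipidClass("L" + lipid_class.value)

    rows = [
        {
            "fragment_type": "acyl_anion",
            "chain": str(chain),
            "complement": None,
            "mz": acyl_anion_mz(chain),
        },
        {
            "fragment_type": "lyso_[M-H]-",
            "chain": str(chain),
            "complement": None,
            "mz": adduct_mz(
                composition_of_species(lyso_class, chain.carbons, chain.double_bonds),
                "[M-H]-",
            ),
        },
    ]
    for comp_chain in space.chains():
        m = chain.carbons + comp_chain.carbons
        n = chain.double_bonds + comp_chain.double_bonds
        rows.append(
            {
                "fragment_type": "precursor_[M-H]-",
                "chain": str(chain),
                "complement": str(comp_chain),
                "mz": adduct_mz(composition_of_species(lipid_class, m, n), "[M-H]-"),
            }
        )
    df = pd.DataFrame(rows)
    df["mz (2dp)"] = df["mz"].map(format_mz)
    return df


@dataclass(frozen=True)
class MRMTransition:
    """A Q1/Q3 pair monitoring one acyl chain of one sum composition."""

    q1_mz: float
    q3_mz: float
    sum_composition: Tuple[int, int]
    diagnostic_chain: AcylChain
    dwell_ms: float = 30.0
    collision_energy_eV: float = 39.0
    shared_fragment: bool = False
    lipid_class: LipidClass = LipidClass.PA

    def __post_init__(self) -> None:
        if not self.q1_mz > self.q3_mz > 0:
            raise ValueError(
                f"require q1 > q3 > 0, got q1={self.q1_mz}, q3={self.q3_mz}"
            )
        m, n = self.sum_composition
        chain = self.diagnostic_chain
        if chain.carbons > m or chain.double_bonds > n:
            raise ValueError(
                f"chain {chain} does not fit inside sum composition {m}:{n}"
            )

    @property
    def name(self) -> str:
        m, n = self.sum_composition
        return (
            f"{self.lipid_class.value}({m}:{n}) "
            f"{format_mz(self.q1_mz)}-{format_mz(self.q3_mz)} ({self.diagnostic_chain})"
        )


class TransitionOverflowError(ValueError):
    """Raised when a panel needs more MRM transitions than the instrument cap."""

    def __init__(self, count: int, max_transitions: int):
        self.count = count
        self.max_transitions = max_transitions
        super().__init__(
            f"panel requires {count} transitions, exceeding the maximum of "
            f"{max_transitions}; supply a priority list to truncate"
        )


def build_transition_list(
    species: Sequence[LipidSpecies | Tuple[int, int]],
    space: Optional[ChainSpace] = None,
    max_transitions: int = 75,
    dwell_ms: float = 30.0,
    collision_energy_eV: float = 39.0,
    priority: Optional[Sequence[Tuple[int, int]]] = None,
) -> List[MRMTransition]:
    """Design the negative-mode MRM panel for a list of sum compositions.

    One transition per (species, candidate chain): Q1 is the species [M-H]-
    and Q3 the chain's carboxylate anion.  A chain occurring in more than one
    candidate pair of the same species is flagged ``shared_fragment``.  Counts
    above ``max_transitions`` raise :class:`TransitionOverflowError` unless a
    priority ordering of sum compositions is supplied.
    """
    if not species:
        raise ValueError("empty species panel")
    space = space if space is not None else ChainSpace.default_panel()

    sum_comps: List[Tuple[int, int]] = []
    lipid_class = LipidClass.PA
    for item in species:
        if isinstance(item, LipidSpecies):
            sum_comps.append(item.sum_composition)
            lipid_class = item.lipid_class
        else:
            sum_comps.append((int(item[0]), int(item[1])))
    if len(set(sum_comps)) != len(sum_comps):
        dupes = sorted({s for s in sum_comps if sum_comps.count(s) > 1})
        raise ValueError(f"duplicate species in panel: {dupes}")

    per_species: List[Tuple[Tuple[int, int], List[MRMTransition]]] = []
    for m, n in sum_comps:
        q1 = adduct_mz(composition_of_species(lipid_class, m, n), "[M-H]-")
        pairs = decompose_sum_composition(m, n, space)
        chain_uses: dict = {}
        for pair in pairs:
            for chain in set(pair):
                chain_uses[chain] = chain_uses.get(chain, 0) + 1
        transitions = [
            MRMTransition(
                q1_mz=q1,
                q3_mz=acyl_anion_mz(chain),
                sum_composition=(m, n),
                diagnostic_chain=chain,
                dwell_ms=dwell_ms,
                collision_energy_eV=collision_energy_eV,
                shared_fragment=uses > 1,
                lipid_class=lipid_class,
            )
            for chain, uses in sorted(chain_uses.items(), key=lambda kv: kv[0].sort_key)
        ]
        per_species.append(((m, n), transitions))

    total = sum(len(t) for _, t in per_species)
    if total > max_transitions:
        if priority is None:
            raise TransitionOverflowError(total, max_transitions)
        order = {tuple(p): i for i, p in enumerate(priority)}
        per_species.sort(key=lambda item: order.get(item[0], len(order)))
        result: List[MRMTransition] = []
        for _, transitions in per_species:
            if len(result) + len(transitions) > max_transitions:
                break
            result.extend(transitions)
        return result
    return [t for _, transitions in per_species for t in transitions]


def transitions_to_frame(transitions: Sequence[MRMTransition]) -> pd.DataFrame:
    """Flatten a transition list into the combined-database table layout."""
    rows = []
    for t in transitions:
        m, n = t.sum_composition
        rows.append(
            {
                "species": f"{t.lipid_class.value}({m}:{n})",
                "m": m,
                "n": n,
                "q1_mz": t.q1_mz,
                "q3_mz": t.q3_mz,
                "q1 (2dp)": format_mz(t.q1_mz),
                "q3 (2dp)": format_mz(t.q3_mz),
                "diagnostic_chain": str(t.diagnostic_chain),
                "dwell_ms": t.dwell_ms,
                "collision_energy_eV": t.collision_energy_eV,
                "shared_fragment": t.shared_fragment,
            }
        )
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a table as CSV, TSV or xlsx based on the file extension."""
    path_str = str(path)
    if path_str.endswith(".xlsx"):
        df.to_excel(path_str, index=False)
    elif path_str.endswith(".tsv"):
        df.to_csv(path_str, sep="\t", index=False)
    else:
        df.to_csv(path_str, index=False)
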