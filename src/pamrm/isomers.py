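"""sn-1/sn-2 positional isomer assignment from EPI fragment intensities and
MRM co-elution.

The interpretive rules, in order:

1. every candidate acyl chain of a sum composition is matched to the nearest
   spectrum peak within an m/z tolerance; a match below 1% of the base peak
   counts as absent;
2. a candidate chain *pair* is accepted iff both of its chains are present
   (a single fragment suffices for a self-pair such as 18:1/18:1);
3. within an accepted pair, the chain with the more intense carboxylate anion
   is placed at sn-1; intensities equal within a relative tolerance leave the
   sn order ambiguous;
4. accepted pairs sharing a present fragment are ambiguous at the pair level
   unless retention-time evidence separates them; co-elution of a pair's two
   transitions confirms the assignment, contradictory apexes withdraw it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import AcylChain, LipidClass, LipidSpecies, acyl_anion_mz
from .database import ChainPair, ChainSpace, decompose_sum_composition
from .spectra import Chromatogram, EPISpectrum, integrate_peak

__all__ = [
    "Confidence",
    "FragmentMatch",
    "IsomerAssignment",
    "match_fragments",
    "resolve_pairs",
    "assign_sn_positions",
    "confirm_by_coelution",
    "identify_species",
]

DEFAULT_MZ_TOL = 0.3  # Da; unit-resolution Q3
DEFAULT_ABSENCE_FRAC = 0.01  # of base peak
DEFAULT_EQUALITY_TOL = 0.2  # relative intensity difference
DEFAULT_RT_TOL = 0.1  # minutes


class Confidence(enum.Enum):
    RESOLVED = "resolved"
    SN_AMBIGUOUS = "sn_ambiguous"
    PAIR_AMBIGUOUS = "pair_ambiguous"


_CONFIDENCE_RANK = {
    Confidence.RESOLVED: 0,
    Confidence.SN_AMBIGUOUS: 1,
    Confidence.PAIR_AMBIGUOUS: 2,
}


def _worst(a: Confidence, b: Confidence) -> Confidence:
    return a if _CONFIDENCE_RANK[a] >= _CONFIDENCE_RANK[b] else b


@dataclass(frozen=True)
class FragmentMatch:
    chain: AcylChain
    present: bool
    mz_theory: float
    mz_observed: Optional[float] = None
    mz_error: Optional[float] = None
    intensity: float = 0.0


@dataclass(frozen=True)
class IsomerAssignment:
    """A (possibly sn-ordered) diacyl assignment with its evidence."""

    species: LipidSpecies
    confidence: Confidence
    fragment_matches: Tuple[FragmentMatch, ...] = ()
    rt_apexes: Tuple[float, ...] = ()
    rt_confirmed: Optional[bool] = None  # None: no / incomplete XIC evidence
    collision_energy_eV: Optional[float] = None

    @property
    def chains(self) -> Tuple[AcylChain, AcylChain]:
        assert self.species.chains is not None
        return self.species.chains  # type: ignore[return-value]


def match_fragments(
    spectrum: EPISpectrum,
    candidates: Sequence[ChainPair],
    mz_tol: float = DEFAULT_MZ_TOL,
    absence_frac: float = DEFAULT_ABSENCE_FRAC,
) -> Dict[AcylChain, FragmentMatch]:
    """Match each distinct candidate chain to its carboxylate anion peak.

    The nearest peak within ``mz_tol`` (closed interval) is taken; a chain
    with no peak, or whose best peak is below ``absence_frac`` of the base
    peak, is marked absent.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be > 0")
    if not candidates:
        return {}
    if len(spectrum) == 0:
        raise ValueError("cannot match fragments in an empty spectrum")

    base = spectrum.base_peak_intensity
    chains = sorted({c for pair in candidates for c in pair},
                    key=lambda c: c.sort_key)
    matches: Dict[AcylChain, FragmentMatch] = {}
    for chain in chains:
        theory = acyl_anion_mz(chain)
        errors = np.abs(spectrum.mz - theory)
        idx = int(np.argmin(errors))
        # closed interval with a float-safety epsilon: a peak exactly at the
        # tolerance boundary is matched
        if errors[idx] <= mz_tol + 1e-9 and \
                spectrum.intensities[idx] >= absence_frac * base:
            matches[chain] = FragmentMatch(
                chain=chain,
                present=True,
                mz_theory=theory,
                mz_observed=float(spectrum.mz[idx]),
                mz_error=float(spectrum.mz[idx] - theory),
                intensity=float(spectrum.intensities[idx]),
            )
        else:
            matches[chain] = FragmentMatch(chain=chain, present=False,
                                           mz_theory=theory)
    return matches


def resolve_pairs(
    matches: Dict[AcylChain, FragmentMatch],
    candidates: Sequence[ChainPair],
    lipid_class: LipidClass = LipidClass.PA,
) -> List[IsomerAssignment]:
    """Accept candidate pairs whose chains are both present; flag pairs that
    share a present fragment with another accepted pair."""
    accepted: List[ChainPair] = []
    for pair in sorted(set(candidates),
                       key=lambda p: p[0].sort_key + p[1].sort_key):
        if all(matches.get(chain, FragmentMatch(chain, False, 0.0)).present
               for chain in set(pair)):
            accepted.append(pair)

    assignments = []
    for pair in accepted:
        shared = any(
            other is not pair and set(pair) & set(other) for other in accepted
        )
        confidence = Confidence.PAIR_AMBIGUOUS if shared else Confidence.RESOLVED
        species = LipidSpecies.from_chains(lipid_class, *pair)
        evidence = tuple(matches[c] for c in sorted(set(pair),
                                                    key=lambda c: c.sort_key))
        assignments.append(
            IsomerAssignment(species=species, confidence=confidence,
                             fragment_matches=evidence)
        )
    return assignments


def assign_sn_positions(
    assignment: IsomerAssignment,
    matches: Dict[AcylChain, FragmentMatch],
    equality_tol: float = DEFAULT_EQUALITY_TOL,
    collision_energy_eV: Optional[float] = 39.0,
) -> IsomerAssignment:
    """Order the chains: the more intense carboxylate anion goes to sn-1.

    Intensities within ``equality_tol`` relative difference leave the order
    ambiguous (chains are then sorted canonically for determinism).
    """
    chain_a, chain_b = assignment.chains
    if chain_a == chain_b:
        return replace(assignment, collision_energy_eV=collision_energy_eV)

    intensity_a = matches[chain_a].intensity
    intensity_b = matches[chain_b].intensity
    top = max(intensity_a, intensity_b)
    confidence = assignment.confidence
    if top <= 0 or abs(intensity_a - intensity_b) / top <= equality_tol:
        confidence = _worst(confidence, Confidence.SN_AMBIGUOUS)
        ordered = tuple(sorted((chain_a, chain_b), key=lambda c: c.sort_key))
    elif intensity_a > intensity_b:
        ordered = (chain_a, chain_b)
    else:
        ordered = (chain_b, chain_a)

    species = LipidSpecies.from_chains(assignment.species.lipid_class, *ordered)
    return replace(assignment, species=species, confidence=confidence,
                   collision_energy_eV=collision_energy_eV)


def _apex_of(xic: Chromatogram) -> Optional[float]:
    peak = integrate_peak(xic)
    return None if peak.not_detected else peak.rt_apex_min


def confirm_by_coelution(
    assignments: Sequence[IsomerAssignment],
    xics: Sequence[Chromatogram],
    rt_tol_min: float = DEFAULT_RT_TOL,
    q1_tol: float = 0.5,
    q3_tol: float = DEFAULT_MZ_TOL,
) -> List[IsomerAssignment]:
    """Attach retention-time evidence from per-transition XICs.

    An assignment is confirmed when the apexes of its chains' transitions
    agree within ``rt_tol_min``; contradictory apexes withdraw the assignment
    to ``pair_ambiguous``.  Missing XICs leave the confidence unchanged with
    ``rt_confirmed=None``.
    """
    confirmed = []
    for assignment in assignments:
        from .chem import species_mz

        q1 = species_mz(
            LipidSpecies(assignment.species.lipid_class,
                         assignment.species.total_carbons,
                         assignment.species.total_double_bonds)
        )
        apexes = []
        complete = True
        for chain in dict.fromkeys(assignment.chains):  # unique, order kept
            q3 = acyl_anion_mz(chain)
            candidates = [
                x for x in xics
                if abs(x.q1_mz - q1) <= q1_tol and abs(x.q3_mz - q3) <= q3_tol
            ]
            if not candidates:
                complete = False
                continue
            chain_apexes = [_apex_of(x) for x in candidates]
            chain_apexes = [a for a in chain_apexes if a is not None]
            if not chain_apexes:
                complete = False
                continue
            # nearest apex to the EPI retention time if several XICs match
            apexes.append(min(chain_apexes))
        if not complete or not apexes:
            confirmed.append(replace(assignment, rt_apexes=tuple(apexes),
                                     rt_confirmed=None))
            continue
        coeluting = (max(apexes) - min(apexes)) <= rt_tol_min
        if coeluting:
            confirmed.append(replace(assignment, rt_apexes=tuple(apexes),
                                     rt_confirmed=True))
        else:
            confirmed.append(
                replace(assignment, rt_apexes=tuple(apexes), rt_confirmed=False,
                        confidence=Confidence.PAIR_AMBIGUOUS)
            )
    return confirmed


def identify_species(
    spectrum: EPISpectrum,
    sum_composition: Tuple[int, int],
    space: Optional[ChainSpace] = None,
    mz_tol: float = DEFAULT_MZ_TOL,
    absence_frac: float = DEFAULT_ABSENCE_FRAC,
    equality_tol: float = DEFAULT_EQUALITY_TOL,
    xics: Optional[Sequence[Chromatogram]] = None,
    rt_tol_min: float = DEFAULT_RT_TOL,
    lipid_class: LipidClass = LipidClass.PA,
    collision_energy_eV: Optional[float] = 39.0,
) -> List[IsomerAssignment]:
    """Full interpretation of one EPI spectrum: match, resolve, order, confirm."""
    m, n = sum_composition
    candidates = decompose_sum_composition(m, n, space)
    if not candidates:
        return []
    matches = match_fragments(spectrum, candidates, mz_tol, absence_frac)
    assignments = resolve_pairs(matches, candidates, lipid_class)
    assignments = [
        assign_sn_positions(a, matches, equality_tol, collision_energy_eV)
        for a in assignments
    ]
    if xics is not None:
        assignments = confirm_by_coelution(assignments, xics, rt_tol_min,
                                           q3_tol=mz_tol)
    return assignments
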