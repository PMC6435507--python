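"""End-to-end glue: from raw chromatograms/spectra to identified species and
quantified amounts."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import LipidClass, acyl_anion_mz, composition_of_species, adduct_mz
from .database import ChainSpace
from .isomers import IsomerAssignment, identify_species
from .quant import SampleMeta, quantify_species
from .spectra import Chromatogram, EPISpectrum, integrate_peak

__all__ = [
    "infer_sum_composition",
    "process_run",
    "quantify_runs",
]


def infer_sum_composition(
    q1_mz: float,
    lipid_class: LipidClass = LipidClass.PA,
    tol: float = 0.005,
    m_range: Tuple[int, int] = (20, 50),
    n_range: Tuple[int, int] = (0, 12),
) -> Optional[Tuple[int, int]]:
    """Invert a [M-H]- precursor m/z to its (m, n) sum composition."""
    best = None
    best_err = tol
    for m in range(m_range[0], m_range[1] + 1):
        for n in range(n_range[0], n_range[1] + 1):
            try:
                mz = adduct_mz(composition_of_species(lipid_class, m, n), "[M-H]-")
            except ValueError:
                continue
            err = abs(mz - q1_mz)
            if err <= best_err:
                best, best_err = (m, n), err
    return best


def _merge_spectra(spectra: Sequence[EPISpectrum]) -> EPISpectrum:
    """Concatenate the fragment peaks of co-precursor EPI spectra."""
    mz = np.concatenate([s.mz for s in spectra])
    intensity = np.concatenate([s.intensities for s in spectra])
    reference = max(spectra, key=lambda s: s.base_peak_intensity)
    return EPISpectrum(reference.precursor_mz, reference.retention_time_min,
                       mz, intensity)


def process_run(
    chromatograms: Sequence[Chromatogram],
    spectra: Sequence[EPISpectrum],
    space: Optional[ChainSpace] = None,
    mz_tol: float = 0.3,
    rt_tol_min: float = 0.1,
    precursor_tol: float = 0.02,
    lipid_class: LipidClass = LipidClass.PA,
) -> Tuple[List[IsomerAssignment], pd.DataFrame]:
    """Identify species in one LC-MS run and integrate their transitions.

    EPI spectra sharing a precursor (within ``precursor_tol``) are merged
    and interpreted against the chain decomposition of the inferred sum
    composition; each accepted assignment is quantified as the summed peak
    area of its chains' transitions.

    Returns (assignments, areas) where areas has columns species, area,
    rt_apex_min, confidence.
    """
    space = space if space is not None else ChainSpace.default_panel()

    # group EPI spectra by precursor m/z
    groups: List[Tuple[float, List[EPISpectrum]]] = []
    for spectrum in sorted(spectra, key=lambda s: s.precursor_mz):
        if groups and abs(spectrum.precursor_mz - groups[-1][0]) <= precursor_tol:
            groups[-1][1].append(spectrum)
        else:
            groups.append((spectrum.precursor_mz, [spectrum]))

    area_by_transition: Dict[Tuple[float, float], float] = {}
    apex_by_transition: Dict[Tuple[float, float], float] = {}
    for chrom in chromatograms:
        peak = integrate_peak(chrom)
        key = (round(chrom.q1_mz, 3), round(chrom.q3_mz, 3))
        area_by_transition[key] = area_by_transition.get(key, 0.0) + peak.area
        apex_by_transition[key] = peak.rt_apex_min

    assignments: List[IsomerAssignment] = []
    rows = []
    for precursor, members in groups:
        sum_comp = infer_sum_composition(precursor, lipid_class,
                                         tol=precursor_tol)
        if sum_comp is None:
            continue
        merged = _merge_spectra(members)
        xics = [c for c in chromatograms
                if abs(c.q1_mz - precursor) <= precursor_tol]
        found = identify_species(merged, sum_comp, space=space, mz_tol=mz_tol,
                                 xics=xics, rt_tol_min=rt_tol_min,
                                 lipid_class=lipid_class)
        for assignment in found:
            area = 0.0
            apexes = []
            for chain in dict.fromkeys(assignment.chains):
                q3 = acyl_anion_mz(chain)
                for key, value in area_by_transition.items():
                    if abs(key[0] - precursor) <= precursor_tol and \
                            abs(key[1] - q3) <= mz_tol:
                        area += value
                        apexes.append(apex_by_transition[key])
            rows.append(
                {
                    "species": assignment.species.name,
                    "area": area,
                    "rt_apex_min": float(np.median(apexes)) if apexes else np.nan,
                    "confidence": assignment.confidence.value,
                }
            )
            assignments.append(assignment)
    return assignments, pd.DataFrame(
        rows, columns=["species", "area", "rt_apex_min", "confidence"]
    )


def quantify_runs(
    runs: Dict[str, Tuple[Sequence[Chromatogram], Sequence[EPISpectrum]]],
    meta: Sequence[SampleMeta],
    standard: Optional[str] = None,
    space: Optional[ChainSpace] = None,
    **process_kwargs,
) -> Tuple[pd.DataFrame, Dict[str, List[IsomerAssignment]]]:
    """Process every sample and quantify against the internal standard.

    Returns (quant table, per-sample assignments).
    """
    from .quant import DEFAULT_STANDARD

    standard = standard or DEFAULT_STANDARD
    all_assignments: Dict[str, List[IsomerAssignment]] = {}
    area_frames = []
    for sample_id, (chromatograms, spectra) in runs.items():
        assignments, areas = process_run(chromatograms, spectra, space=space,
                                         **process_kwargs)
        all_assignments[sample_id] = assignments
        areas = areas.copy()
        areas["sample_id"] = sample_id
        area_frames.append(areas)
    area_table = pd.concat(area_frames, ignore_index=True)
    quant = quantify_species(area_table[["sample_id", "species", "area"]],
                             meta, standard=standard)
    return quant, all_assignments
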