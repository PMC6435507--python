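"""Ground-truth PA mixtures and simulated MRM/EPI acquisitions.

Chromatographic model: one Gaussian elution peak per species per run, with
the apex drawn once per species and shared across that species' transitions
(encoding co-elution), default sigma 0.05 min.  EPI fragment intensities
carry an sn-1/sn-2 bias: before noise, the sn-1 carboxylate anion is
``sn_bias`` times the sn-2 anion (default 1.7).  Internal-standard species
are always included in every simulated sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import AcylChain, LipidClass, LipidSpecies, acyl_anion_mz, species_mz
from .database import DEFAULT_PANEL_CHAINS, ChainSpace
from .quant import DEFAULT_STANDARD, SECONDARY_STANDARD, SampleMeta
from .spectra import (
    Chromatogram,
    EPISpectrum,
    write_chromatograms_csv,
    write_mzml,
    write_spectra_csv,
)

__all__ = [
    "SimNoise",
    "GroundTruth",
    "RunData",
    "SimulatedRun",
    "INTERNAL_STANDARDS",
    "build_default_panel",
    "restoration_design",
    "make_ground_truth",
    "simulate_run",
    "truth_quant_table",
    "write_run",
]

#: Internal-standard species spiked into every simulated sample (pmol).
INTERNAL_STANDARDS: Mapping[str, float] = {
    DEFAULT_STANDARD: 10.0,
    SECONDARY_STANDARD: 10.0,
}

_IS_SPECIES = {
    DEFAULT_STANDARD: LipidSpecies.from_chains(
        LipidClass.PA, AcylChain(17, 0), AcylChain(14, 1)
    ),
    SECONDARY_STANDARD: LipidSpecies.from_chains(
        LipidClass.PA, AcylChain(12, 0), AcylChain(13, 0)
    ),
}

#: Even-carbon chains used to build natural panels (odd-carbon chains are
#: reserved for internal standards, so panel and standard sum compositions
#: can never collide).
_PANEL_CHAINS = tuple(
    c for c in DEFAULT_PANEL_CHAINS if c.carbons % 2 == 0
)


@dataclass(frozen=True)
class SimNoise:
    intensity_cv: float = 0.0
    mz_sigma_da: float = 0.0
    rt_jitter_min: float = 0.0

    def __post_init__(self) -> None:
        if min(self.intensity_cv, self.mz_sigma_da, self.rt_jitter_min) < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class GroundTruth:
    """A resolved-species panel plus per-sample true amounts."""

    panel: List[LipidSpecies]
    amounts: pd.DataFrame  # sample_id, group, replicate, species, amount_pmol
    samples: List[SampleMeta]
    seed: int


@dataclass
class RunData:
    chromatograms: List[Chromatogram]
    spectra: List[EPISpectrum]


@dataclass
class SimulatedRun:
    truth: GroundTruth
    runs: Dict[str, RunData]
    noise: SimNoise
    sn_bias: float
    seed: int


def build_default_panel(n_species: int = 39) -> List[LipidSpecies]:
    """A deterministic panel of resolved diacyl PA species.

    Pairs are drawn from the even-carbon curated chain list; within any one
    sum composition no two selected species share an acyl chain, so the
    positional-isomer interpreter can resolve every member unambiguously.
    The smaller chain (by carbons, then double bonds) is placed at sn-1.
    """
    candidates = []
    for i, chain1 in enumerate(_PANEL_CHAINS):
        for chain2 in _PANEL_CHAINS[i:]:
            m = chain1.carbons + chain2.carbons
            n = chain1.double_bonds + chain2.double_bonds
            if not 28 <= m <= 40:
                continue
            candidates.append((m, n, chain1, chain2))
    candidates.sort(key=lambda item: (item[0], item[1],
                                      item[2].sort_key, item[3].sort_key))
    chosen: List[LipidSpecies] = []
    used_chains: Dict[Tuple[int, int], set] = {}
    for m, n, chain1, chain2 in candidates:
        key = (m, n)
        used = used_chains.setdefault(key, set())
        if chain1 in used or chain2 in used:
            continue
        used.update({chain1, chain2})
        chosen.append(LipidSpecies.from_chains(LipidClass.PA, chain1, chain2))
        if len(chosen) == n_species:
            return chosen
    raise ValueError(
        f"cannot build a panel of {n_species} species (got {len(chosen)})"
    )


def restoration_design(
    panel: Sequence[LipidSpecies],
    n_reduced: int = 30,
    n_restored: int = 16,
    mutant_factor: float = 0.3,
    groups: Tuple[str, str, str] = ("WT", "mutant", "rescue"),
) -> Tuple[Dict[str, Dict[str, float]], List[str], List[str]]:
    """Three-group rescue design with per-species effect multipliers.

    The first ``n_reduced`` panel species are reduced to ``mutant_factor`` of
    wild type in the mutant; the first ``n_restored`` of those return to the
    wild-type level in the rescue group while the rest stay at the mutant
    level.  Returns (multipliers, reduced_species, restored_species).
    """
    if n_restored > n_reduced or n_reduced > len(panel):
        raise ValueError("need n_restored <= n_reduced <= panel size")
    wt_name, mutant_name, rescue_name = groups
    names = [sp.name for sp in panel]
    reduced = names[:n_reduced]
    restored = names[:n_restored]
    multipliers = {
        wt_name: {name: 1.0 for name in names},
        mutant_name: {
            name: (mutant_factor if name in reduced else 1.0) for name in names
        },
        rescue_name: {
            name: (
                1.0
                if name in restored or name not in reduced
                else mutant_factor
            )
            for name in names
        },
    }
    return multipliers, reduced, restored


def make_ground_truth(
    panel: Sequence[LipidSpecies],
    group_multipliers: Mapping[str, Mapping[str, float]],
    base_amounts: Optional[Mapping[str, float]] = None,
    n_replicates: int = 3,
    replicate_cv: float = 0.0,
    total_phosphate_nmol: float = 5.0,
    is_amounts: Mapping[str, float] = INTERNAL_STANDARDS,
    seed: int = 0,
) -> GroundTruth:
    """Draw per-sample true amounts for every species under a group design.

    ``base_amounts`` (pmol at wild-type level) default to a deterministic
    log-spread between 0.5 and 6 pmol, inside the verified linear range.
    Replicate-to-replicate biological variation is multiplicative with
    coefficient of variation ``replicate_cv``.
    """
    rng = np.random.default_rng(seed)
    names = [sp.name for sp in panel]
    if base_amounts is None:
        levels = np.geomspace(0.5, 6.0, num=len(names))
        base_amounts = dict(zip(names, levels))
    rows = []
    samples = []
    for group, multipliers in group_multipliers.items():
        for replicate in range(1, n_replicates + 1):
            sample_id = f"{group}_{replicate}"
            samples.append(
                SampleMeta(
                    sample_id=sample_id,
                    group=group,
                    replicate=replicate,
                    is_amounts=dict(is_amounts),
                    total_phosphate_nmol=total_phosphate_nmol,
                )
            )
            for name in names:
                mean = base_amounts[name] * multipliers.get(name, 1.0)
                noise = 1.0 + replicate_cv * rng.standard_normal()
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "replicate": replicate,
                        "species": name,
                        "amount_pmol": max(mean * noise, 0.0),
                    }
                )
    amounts = pd.DataFrame(rows)
    return GroundTruth(panel=list(panel), amounts=amounts, samples=samples,
                       seed=seed)


def truth_quant_table(truth: GroundTruth) -> pd.DataFrame:
    """The ground-truth amounts in the quantitation-table layout."""
    phosphate = {m.sample_id: m.total_phosphate_nmol for m in truth.samples}
    df = truth.amounts.copy()
    df["amount_per_phosphate"] = df.apply(
        lambda row: row["amount_pmol"] / phosphate[row["sample_id"]], axis=1
    )
    return df


def _sn_fractions(species: LipidSpecies, sn_bias: float) -> List[Tuple[AcylChain, float]]:
    assert species.chains is not None
    sn1, sn2 = species.chains
    if sn1 == sn2:
        return [(sn1, 1.0)]
    return [(sn1, sn_bias / (1.0 + sn_bias)), (sn2, 1.0 / (1.0 + sn_bias))]


def simulate_run(
    truth: GroundTruth,
    noise: SimNoise = SimNoise(),
    sn_bias: float = 1.7,
    seed: Optional[int] = None,
    rt_window: Tuple[float, float] = (8.6, 10.4),
    sigma_min: float = 0.05,
    dt_min: float = 0.004,
    response_per_pmol: float = 1.0e4,
) -> SimulatedRun:
    """Simulate MRM XICs and EPI spectra for every sample of a ground truth.

    Per species and sample: a Gaussian XIC peak for each diagnostic
    transition, all sharing one apex (area proportional to amount, split
    ``sn_bias`` : 1 between the sn-1 and sn-2 transitions), plus an EPI
    spectrum at the apex whose sn-1 fragment is ``sn_bias`` times the sn-2
    fragment before noise.  Internal standards are always included.
    """
    if sn_bias <= 1.0:
        raise ValueError("sn_bias must be > 1")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    standards = [
        (_IS_SPECIES[name], name) for name in sorted(INTERNAL_STANDARDS)
        if name in {m for s in truth.samples for m in s.is_amounts}
    ]
    all_species = [(sp, sp.name) for sp in truth.panel] + standards
    for sp, _ in all_species:
        if sp.chains is None:
            raise ValueError(f"panel species {sp.name} must have resolved chains")

    # deterministic base retention times, spread over the window
    lo, hi = rt_window
    margin = 0.1 * (hi - lo)
    n_total = len(all_species)
    base_rt = {
        name: lo + margin + (hi - lo - 2 * margin) * (i + 0.5) / n_total
        for i, (_, name) in enumerate(
            sorted(all_species, key=lambda item: item[1])
        )
    }
    times = np.arange(lo, hi + dt_min / 2, dt_min)

    amounts_by_sample = {
        sample_id: dict(zip(sub["species"], sub["amount_pmol"]))
        for sample_id, sub in truth.amounts.groupby("sample_id")
    }

    runs: Dict[str, RunData] = {}
    norm = sigma_min * np.sqrt(2.0 * np.pi)
    for meta in truth.samples:
        amounts = dict(amounts_by_sample.get(meta.sample_id, {}))
        for name, pmol in meta.is_amounts.items():
            amounts[name] = pmol

        signal: Dict[Tuple[float, float], np.ndarray] = {}
        spectra: List[EPISpectrum] = []
        for species, name in all_species:
            amount = amounts.get(name, 0.0)
            if amount <= 0:
                continue
            apex = base_rt[name] + noise.rt_jitter_min * rng.standard_normal()
            q1 = species_mz(
                LipidSpecies(species.lipid_class, species.total_carbons,
                             species.total_double_bonds)
            )
            peak_mz: List[float] = []
            peak_intensity: List[float] = []
            for chain, fraction in _sn_fractions(species, sn_bias):
                q3 = acyl_anion_mz(chain)
                scale = max(1.0 + noise.intensity_cv * rng.standard_normal(), 0.0)
                area = amount * response_per_pmol * fraction * scale
                trace = (area / norm) * np.exp(
                    -0.5 * ((times - apex) / sigma_min) ** 2
                )
                key = (round(q1, 4), round(q3, 4))
                signal[key] = signal.get(key, 0.0) + trace
                epi_scale = max(
                    1.0 + noise.intensity_cv * rng.standard_normal(), 0.0
                )
                peak_mz.append(q3 + noise.mz_sigma_da * rng.standard_normal())
                peak_intensity.append(amount * fraction * epi_scale * 1000.0)
            spectra.append(
                EPISpectrum(
                    precursor_mz=q1,
                    retention_time_min=apex,
                    mz=np.array(peak_mz),
                    intensities=np.array(peak_intensity),
                )
            )

        chromatograms = [
            Chromatogram(q1, q3, times.copy(), trace)
            for (q1, q3), trace in sorted(signal.items())
        ]
        spectra.sort(key=lambda s: (s.precursor_mz, s.retention_time_min))
        runs[meta.sample_id] = RunData(chromatograms=chromatograms,
                                       spectra=spectra)
    return SimulatedRun(truth=truth, runs=runs, noise=noise, sn_bias=sn_bias,
                        seed=seed)


def write_run(
    sim: SimulatedRun, outdir: str | Path, format: str = "csv"
) -> List[Path]:
    """Write one chromatogram + spectrum file per sample plus a metadata
    table; the RNG seed is recorded in every output."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_header = f"# seed={sim.seed}\n"
    written = []
    meta_rows = []
    for meta in sim.truth.samples:
        run = sim.runs[meta.sample_id]
        if format == "mzml":
            path = outdir / f"{meta.sample_id}.mzML"
            write_mzml(path, run.chromatograms, run.spectra)
            written.append(path)
        elif format == "csv":
            chrom_path = outdir / f"{meta.sample_id}_chromatograms.csv"
            spec_path = outdir / f"{meta.sample_id}_spectra.csv"
            write_chromatograms_csv(run.chromatograms, chrom_path)
            write_spectra_csv(run.spectra, spec_path)
            for path in (chrom_path, spec_path):
                content = path.read_text()
                path.write_text(seed_header + content)
            written.extend([chrom_path, spec_path])
        else:
            raise ValueError(f"unknown format {format!r}")
        row = {
            "sample_id": meta.sample_id,
            "group": meta.group,
            "replicate": meta.replicate,
            "total_phosphate_nmol": meta.total_phosphate_nmol,
            "seed": sim.seed,
        }
        for name, pmol in meta.is_amounts.items():
            row[f"is_pmol[{name}]"] = pmol
        meta_rows.append(row)
    meta_path = outdir / "samples.csv"
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)
    written.append(meta_path)
    return written
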