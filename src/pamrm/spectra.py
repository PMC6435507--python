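"""Chromatogram / product-ion spectrum containers, file IO, and peak
integration.

The CSV dialects are deliberately simple and self-describing:

* chromatogram CSV — header ``q1_mz,q3_mz,rt_min,intensity``; one row per
  chromatogram point, grouped by (q1_mz, q3_mz).
* spectrum CSV — header ``precursor_mz,rt_min,mz,intensity``; one row per
  fragment peak, grouped by (precursor_mz, rt_min).

Retention times are minutes everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import _mzml
from .database import MRMTransition

__all__ = [
    "Chromatogram",
    "EPISpectrum",
    "PeakArea",
    "read_spectra",
    "read_chromatograms_csv",
    "read_spectra_csv",
    "write_chromatograms_csv",
    "write_spectra_csv",
    "write_mzml",
    "integrate_peak",
]

logger = logging.getLogger(__name__)

CHROM_CSV_COLUMNS = ["q1_mz", "q3_mz", "rt_min", "intensity"]
SPECTRUM_CSV_COLUMNS = ["precursor_mz", "rt_min", "mz", "intensity"]


@dataclass(frozen=True)
class Chromatogram:
    """An extracted/recorded ion chromatogram for one MRM transition."""

    q1_mz: float
    q3_mz: float
    times: np.ndarray
    intensities: np.ndarray
    transition: Optional[MRMTransition] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        if times.shape != intensities.shape or times.ndim != 1:
            raise ValueError("times and intensities must be 1-D arrays of equal length")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(intensities < 0):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class EPISpectrum:
    """A product-ion (EPI) spectrum attached to a precursor and a retention
    time."""

    precursor_mz: float
    retention_time_min: float
    mz: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        if mz.shape != intensities.shape or mz.ndim != 1:
            raise ValueError("mz and intensities must be 1-D arrays of equal length")
        if np.any(intensities < 0):
            raise ValueError("intensities must be >= 0")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensities", intensities[order])

    @property
    def peaks(self) -> List[Tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensities.tolist()))

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensities.max()) if len(self.intensities) else 0.0

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class PeakArea:
    """An integrated chromatographic peak (area in intensity x minutes)."""

    q1_mz: float
    q3_mz: float
    rt_apex_min: float
    area: float
    height: float
    fwhm_min: float
    not_detected: bool = False
    transition: Optional[MRMTransition] = None


# ---------------------------------------------------------------------------
# IO

def read_chromatograms_csv(path: Union[str, Path]) -> List[Chromatogram]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CHROM_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"chromatogram CSV {path!r} lacks columns {missing}")
    chroms = []
    for (q1, q3), group in df.groupby(["q1_mz", "q3_mz"], sort=True):
        group = group.sort_values("rt_min")
        chroms.append(
            Chromatogram(float(q1), float(q3), group["rt_min"].to_numpy(),
                         group["intensity"].to_numpy())
        )
    if not chroms:
        raise ValueError(f"empty chromatogram CSV {path!r}")
    return chroms


def read_spectra_csv(path: Union[str, Path]) -> List[EPISpectrum]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SPECTRUM_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spectrum CSV {path!r} lacks columns {missing}")
    spectra = []
    for (precursor, rt), group in df.groupby(["precursor_mz", "rt_min"], sort=True):
        spectra.append(
            EPISpectrum(float(precursor), float(rt), group["mz"].to_numpy(),
                        group["intensity"].to_numpy())
        )
    if not spectra:
        raise ValueError(f"empty spectrum CSV {path!r}")
    return spectra


def write_chromatograms_csv(chroms: Sequence[Chromatogram],
                            path: Union[str, Path]) -> None:
    frames = [
        pd.DataFrame(
            {"q1_mz": c.q1_mz, "q3_mz": c.q3_mz, "rt_min": c.times,
             "intensity": c.intensities}
        )
        for c in chroms
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_spectra_csv(spectra: Sequence[EPISpectrum],
                      path: Union[str, Path]) -> None:
    frames = [
        pd.DataFrame(
            {"precursor_mz": s.precursor_mz, "rt_min": s.retention_time_min,
             "mz": s.mz, "intensity": s.intensities}
        )
        for s in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_mzml(path: Union[str, Path],
               chromatograms: Sequence[Chromatogram] = (),
               spectra: Sequence[EPISpectrum] = ()) -> None:
    _mzml.write_mzml(
        str(path),
        [(c.q1_mz, c.q3_mz, c.times, c.intensities) for c in chromatograms],
        [(s.precursor_mz, s.retention_time_min, s.mz, s.intensities)
         for s in spectra],
    )


def read_spectra(
    path: Union[str, Path], format: Optional[str] = None
) -> Tuple[List[Chromatogram], List[EPISpectrum]]:
    """Load chromatograms and EPI spectra from mzML or the CSV dialects.

    ``format`` may be ``mzml``, ``chromatogram-csv`` or ``spectrum-csv``;
    when omitted it is inferred from the file extension / CSV header.
    Unknown MS levels in mzML are skipped with a logged count.
    """
    path = Path(path)
    if format is None:
        if path.suffix.lower() == ".mzml":
            format = "mzml"
        elif path.suffix.lower() in (".csv", ".tsv", ".txt"):
            header = pd.read_csv(path, nrows=0, comment="#").columns
            format = "chromatogram-csv" if "q1_mz" in header else "spectrum-csv"
        else:
            raise ValueError(f"cannot infer format of {path}")
    if format == "mzml":
        raw_chroms, raw_spectra, n_skipped = _mzml.read_mzml(str(path))
        if n_skipped:
            logger.info("skipped %d entries with unknown MS level in %s",
                        n_skipped, path)
        chroms = [Chromatogram(q1, q3, t, i) for q1, q3, t, i in raw_chroms]
        spectra = [EPISpectrum(p, rt, mz, i) for p, rt, mz, i in raw_spectra]
        return chroms, spectra
    if format == "chromatogram-csv":
        return read_chromatograms_csv(path), []
    if format == "spectrum-csv":
        return [], read_spectra_csv(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Peak integration

def _moving_average(values: np.ndarray, width: int = 5) -> np.ndarray:
    if len(values) < width:
        return values.copy()
    kernel = np.ones(width) / width
    smoothed = np.convolve(values, kernel, mode="same")
    # the convolution underweights the edges; renormalize
    norm = np.convolve(np.ones_like(values), kernel, mode="same")
    return smoothed / norm


def _auto_window(times: np.ndarray, smoothed: np.ndarray) -> Optional[Tuple[int, int]]:
    """Widest contiguous index run above the MAD-based noise threshold."""
    median = np.median(smoothed)
    mad = np.median(np.abs(smoothed - median))
    # MAD-based threshold with a relative floor so that (near-)noise-free
    # traces do not select their entire tail; both terms scale linearly with
    # intensity, preserving integration linearity
    threshold = max(median + 3.0 * 1.4826 * mad, 1e-4 * smoothed.max())
    above = smoothed > threshold
    if not above.any():
        return None
    # widest contiguous run
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    widths = times[np.minimum(stops, len(times) - 1)] - times[starts]
    best = int(np.argmax(widths))
    lo = max(starts[best] - 1, 0)
    hi = min(stops[best] + 1, len(times))
    return lo, hi


def integrate_peak(
    chrom: Chromatogram,
    window: Union[None, str, Tuple[float, float]] = None,
    smooth_points: int = 5,
) -> PeakArea:
    """Detect the apex and integrate the peak above a linear local baseline.

    ``window`` is either an explicit ``(t0, t1)`` retention-time interval or
    ``None``/``"auto"`` for automatic selection (widest contiguous region
    above a 3x median-absolute-deviation noise threshold).  Returns a
    zero-area result flagged ``not_detected`` when no peak rises above noise.
    """
    times, raw = chrom.times, chrom.intensities
    smoothed = _moving_average(raw, smooth_points)

    if window is None or window == "auto":
        indices = _auto_window(times, smoothed) if len(times) >= 5 else None
        if indices is None:
            return PeakArea(chrom.q1_mz, chrom.q3_mz,
                            rt_apex_min=float(times[0]) if len(times) else 0.0,
                            area=0.0, height=0.0, fwhm_min=0.0,
                            not_detected=True, transition=chrom.transition)
        lo, hi = indices
    else:
        t0, t1 = window
        mask = (times >= t0) & (times <= t1)
        if mask.sum() < 5:
            raise ValueError(
                f"integration window [{t0}, {t1}] covers {int(mask.sum())} points; "
                "need >= 5"
            )
        lo = int(np.flatnonzero(mask)[0])
        hi = int(np.flatnonzero(mask)[-1]) + 1

    t = times[lo:hi]
    y = raw[lo:hi]
    y_smooth = smoothed[lo:hi]

    # linear baseline between the window edges (smoothed edge values)
    if t[-1] > t[0]:
        slope = (y_smooth[-1] - y_smooth[0]) / (t[-1] - t[0])
    else:
        slope = 0.0
    baseline = y_smooth[0] + slope * (t - t[0])

    signal = y - baseline
    area = float(np.trapezoid(np.clip(signal, 0.0, None), t))
    apex_idx = int(np.argmax(y_smooth - baseline))
    height = float(y_smooth[apex_idx] - baseline[apex_idx])
    rt_apex = float(t[apex_idx])

    if height <= 0 or area <= 0:
        return PeakArea(chrom.q1_mz, chrom.q3_mz, rt_apex_min=rt_apex,
                        area=0.0, height=max(height, 0.0), fwhm_min=0.0,
                        not_detected=True, transition=chrom.transition)

    fwhm = _fwhm(t, y_smooth - baseline, apex_idx, height)
    return PeakArea(chrom.q1_mz, chrom.q3_mz, rt_apex_min=rt_apex, area=area,
                    height=height, fwhm_min=fwhm, transition=chrom.transition)


def _fwhm(t: np.ndarray, y: np.ndarray, apex_idx: int, height: float) -> float:
    half = height / 2.0
    left = t[0]
    for i in range(apex_idx, 0, -1):
        if y[i - 1] <= half <= y[i]:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1]) if y[i] != y[i - 1] else 0.0
            left = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    right = t[-1]
    for i in range(apex_idx, len(y) - 1):
        if y[i] >= half >= y[i + 1]:
            frac = (y[i] - half) / (y[i] - y[i + 1]) if y[i] != y[i + 1] else 0.0
            right = t[i] + frac * (t[i + 1] - t[i])
            break
    return float(max(right - left, 0.0))


def peak_areas_to_frame(areas: Sequence[PeakArea]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "q1_mz": a.q1_mz,
                "q3_mz": a.q3_mz,
                "rt_apex_min": a.rt_apex_min,
                "area": a.area,
                "height": a.height,
                "fwhm_min": a.fwhm_min,
                "not_detected": a.not_detected,
            }
            for a in areas
        ]
    )
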