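"""Baseline subtraction, noise estimation, normalization and blood QC.

The raw acquisitions carry a slowly decaying chemical baseline; spectra are
baseline-subtracted by morphological opening with a window that scales with
local m/z, per-segment noise is estimated robustly from first differences,
and intensities are normalized to the median total ion current within each
(age, laser-tier) group, since peak composition differs strongly by age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .simulate import GLOBIN_MZ
from .spectrum import Spectrum

__all__ = [
    "subtract_baseline",
    "estimate_noise",
    "normalize_by_group",
    "qc_blood",
    "NormalizationReport",
]

#: m/z below which TIC is never accumulated (matrix/EAM-dominated region).
TIC_MIN_MZ = 1_500.0


def _opening_baseline(y: np.ndarray, mz: np.ndarray, window_frac: float, n_segments: int = 6):
    """Morphological opening (erosion then dilation) with a window of
    ``window_frac * m/z`` Da, approximated piecewise on log-m/z segments and
    blended linearly across segment boundaries."""
    n = y.size
    spacing = (mz[-1] - mz[0]) / max(n - 1, 1)
    edges = np.exp(np.linspace(np.log(mz[0]), np.log(mz[-1]), n_segments + 1))
    centers = np.sqrt(edges[:-1] * edges[1:])
    baselines = np.empty((n_segments, n))
    for k, c in enumerate(centers):
        w = max(int(round(window_frac * c / spacing)), 3)
        w = min(w, n)
        baselines[k] = maximum_filter1d(minimum_filter1d(y, size=w), size=w)
    # interpolate between per-segment baselines by log-m/z position
    logmz = np.log(mz)
    logc = np.log(centers)
    idx = np.clip(np.searchsorted(logc, logmz) - 1, 0, n_segments - 2)
    t = (logmz - logc[idx]) / (logc[idx + 1] - logc[idx])
    t = np.clip(t, 0.0, 1.0)
    cols = np.arange(n)
    return (1.0 - t) * baselines[idx, cols] + t * baselines[idx + 1, cols]


def subtract_baseline(spectrum: Spectrum, window: float = 0.02) -> Spectrum:
    """Remove the slowly varying baseline by morphological opening.

    ``window`` is the opening width as a fraction of local m/z (values > 1
    are interpreted as an absolute width in Da at the spectrum midpoint).
    The window must be much wider than the peak FWHM (m/z / resolution) so
    peaks survive the opening; the result is clipped at zero.
    """
    if window <= 0:
        raise ValueError("baseline window must be > 0")
    span = spectrum.mz[-1] - spectrum.mz[0]
    window_frac = window if window <= 1 else window / float(np.median(spectrum.mz))
    if window_frac * float(np.median(spectrum.mz)) >= span:
        raise ValueError("baseline window is wider than the spectrum span")
    base = _opening_baseline(spectrum.intensity, spectrum.mz, window_frac)
    out = spectrum.copy()
    out.intensity = np.clip(spectrum.intensity - base, 0.0, None)
    out.flags["baseline_done"] = True
    return out


def estimate_noise(spectrum: Spectrum, segment_count: int = 8) -> np.ndarray:
    """Robust per-segment noise SD.

    Uses 1.4826 * MAD of first differences / sqrt(2), which is immune to a
    smooth baseline and to sparse peaks; segments with fewer than 8 points
    are merged with their neighbour.
    """
    if segment_count < 1:
        raise ValueError("segment_count must be >= 1")
    n = spectrum.intensity.size
    bounds = np.linspace(0, n, segment_count + 1).astype(int)
    # merge segments shorter than 8 points into their left neighbour
    keep = [bounds[0]]
    for b in bounds[1:-1]:
        if b - keep[-1] >= 8 and n - b >= 8:
            keep.append(b)
    keep.append(bounds[-1])
    out = np.empty(len(keep) - 1)
    d = np.diff(spectrum.intensity)
    for k in range(len(keep) - 1):
        seg = d[keep[k] : max(keep[k + 1] - 1, keep[k] + 1)]
        mad = np.median(np.abs(seg - np.median(seg)))
        out[k] = 1.4826 * mad / np.sqrt(2.0)
    return out


def noise_at(spectrum: Spectrum, segment_count: int = 8) -> np.ndarray:
    """Per-point noise SD, piecewise constant over the estimation segments."""
    sds = estimate_noise(spectrum, segment_count)
    n = spectrum.intensity.size
    bounds = np.linspace(0, n, sds.size + 1).astype(int)
    out = np.empty(n)
    for k in range(sds.size):
        out[bounds[k] : bounds[k + 1]] = sds[k]
    return out


@dataclass
class NormalizationReport:
    """Per-spectrum TIC scale factors and the per-(age, tier) reference."""

    factors: pd.DataFrame  # sample_id, tier, age, tic, factor
    reference: pd.DataFrame  # age, tier, median_tic

    def factor(self, sample_id: str, tier: str) -> float:
        m = self.factors
        row = m[(m["sample_id"] == sample_id) & (m["tier"] == tier)]
        return float(row["factor"].iloc[0])


def normalize_by_group(
    spectra: list[Spectrum],
    tic_min_mz: float = TIC_MIN_MZ,
) -> tuple[list[Spectrum], NormalizationReport]:
    """Scale each spectrum so its total ion current matches the median TIC of
    its (age, tier) group.  Spectra with zero TIC are dropped with a flag in
    the report (factor NaN)."""
    tics = np.array(
        [float(s.intensity[s.mz >= tic_min_mz].sum()) for s in spectra]
    )
    keys = [(s.age, s.tier) for s in spectra]
    medians: dict[tuple[str, str], float] = {}
    for key in set(keys):
        vals = tics[[i for i, k in enumerate(keys) if k == key]]
        vals = vals[vals > 0]
        medians[key] = float(np.median(vals)) if vals.size else np.nan
    out, rows = [], []
    for s, tic, key in zip(spectra, tics, keys):
        if tic <= 0 or not np.isfinite(medians[key]):
            rows.append((s.sample_id, s.tier, s.age, tic, np.nan))
            continue
        f = medians[key] / tic
        ns = s.copy()
        ns.intensity = ns.intensity * f
        ns.flags["normalized"] = True
        out.append(ns)
        rows.append((s.sample_id, s.tier, s.age, tic, f))
    report = NormalizationReport(
        factors=pd.DataFrame(
            rows, columns=["sample_id", "tier", "age", "tic", "factor"]
        ),
        reference=pd.DataFrame(
            [(a, t, m) for (a, t), m in sorted(medians.items())],
            columns=["age", "tier", "median_tic"],
        ),
    )
    return out, report


def qc_blood(
    spectra: list[Spectrum],
    globin_mz: float = GLOBIN_MZ,
    threshold: float = 3.0,
    window_frac: float = 0.003,
) -> list[str]:
    """Flag samples with blood contamination.

    The apex intensity in a +/-0.3% window around the globin peak is compared
    per sample against the cohort median; samples exceeding ``threshold`` x
    median are flagged (and should be excluded from group testing).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    per_sample: dict[str, float] = {}
    for s in spectra:
        lo, hi = globin_mz * (1 - window_frac), globin_mz * (1 + window_frac)
        sel = (s.mz >= lo) & (s.mz <= hi)
        if not sel.any():
            continue
        v = float(s.intensity[sel].max())
        per_sample[s.sample_id] = max(per_sample.get(s.sample_id, 0.0), v)
    if not per_sample:
        return []
    med = float(np.median(list(per_sample.values())))
    if med <= 0:
        med = np.finfo(float).tiny
    flagged = sorted(sid for sid, v in per_sample.items() if v > threshold * med)
    for s in spectra:
        if s.sample_id in flagged:
            s.flags["blood_flag"] = True
    return flagged
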