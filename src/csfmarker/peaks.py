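"""Peak finding on recombined spectra, per-sample quantification, and
annotation of charge-state/dimer satellites and proteoform adducts.

Peaks are detected per laser tier on the mean of all preprocessed spectra
(all ages recombined), then every sample is quantified at every peak window
so the peaks x samples matrix is complete.  Satellite ("alias") peaks — the
same protein seen at z=2 or z=3, as a non-covalent dimer, or re-acquired in
an overlapping laser tier — are resolved into a parent map; covalent adduct
ladders (cysteinylation, Cys-Gly, glutathionylation, ...) are labelled from
a base peak using the fixed mass-shift table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _find_peaks

from .masscalc import ADDUCT_MASSES
from .preprocess import noise_at
from .spectrum import Spectrum, preferred_tier

__all__ = [
    "PeakDef",
    "AliasGraph",
    "detect_peaks",
    "quantify",
    "find_aliases",
    "annotate_adducts",
]

#: Quantification window half-width as a fraction of the apex m/z.
WINDOW_FRAC = 0.003

#: Cross-tier re-acquisitions of one peak agree to ~0.1% m/z — far tighter
#: than the alias-arithmetic tolerance, which must span charge-conversion
#: calibration error.  Using the alias tolerance for merging would fuse
#: distinct proteoform satellites interleaved across tiers.
MERGE_TOL = 0.0015

#: Alias arithmetic for a singly protonated parent at m.
_EXPECTED = {
    "z2": lambda m: (m + 1.0) / 2.0,
    "z3": lambda m: (m + 2.0) / 3.0,
    "dimer": lambda m: 2.0 * m - 1.0,
}


@dataclass(frozen=True)
class PeakDef:
    peak_id: str
    tier: str
    mz_center: float
    mz_lo: float
    mz_hi: float
    snr_at_detection: float = np.nan

    def __post_init__(self) -> None:
        if not self.mz_lo < self.mz_center < self.mz_hi:
            raise ValueError(f"{self.peak_id}: window must bracket the center")


def detect_peaks(
    spectra: list[Spectrum],
    snr_min: float = 5.0,
    min_fraction_present: float = 0.0,
) -> list[PeakDef]:
    """Find peaks per tier on the mean spectrum of all samples.

    Local maxima whose height exceeds ``snr_min`` times the local noise of
    the mean spectrum become peaks with windows of apex +/- 0.3% m/z;
    overlapping windows are trimmed at their midpoint so windows partition
    disjointly within a tier.  ``min_fraction_present`` optionally requires
    the apex to exceed twice the per-spectrum noise in at least that
    fraction of individual spectra.
    """
    if not spectra:
        raise ValueError("no spectra given")
    if snr_min <= 0:
        raise ValueError("snr_min must be > 0")
    defs: list[PeakDef] = []
    for tier in sorted({s.tier for s in spectra}):
        tier_spectra = [s for s in spectra if s.tier == tier]
        mz = tier_spectra[0].mz
        for s in tier_spectra[1:]:
            if s.mz.shape != mz.shape or not np.allclose(s.mz, mz):
                raise ValueError(f"spectra in tier {tier} are not on a common grid")
        mean = np.mean([s.intensity for s in tier_spectra], axis=0)
        # SNR is referenced to the noise of an individual acquisition (the
        # median per-spectrum noise profile): a peak must be measurable in
        # single spectra, not merely in the n-fold averaged one
        probe = tier_spectra[:: max(len(tier_spectra) // 20, 1)]
        noise = np.median([noise_at(s) for s in probe], axis=0)
        noise = np.maximum(noise, 1e-12 * max(float(np.max(mean)), 1e-12))
        idx, _ = _find_peaks(
            mean,
            height=snr_min * noise,
            prominence=0.5 * snr_min * float(np.median(noise)),
            width=3,
            distance=5,
        )
        if min_fraction_present > 0 and idx.size:
            keep = []
            per_noise = [noise_at(s) for s in tier_spectra]
            for i in idx:
                lo = np.searchsorted(mz, mz[i] * (1 - WINDOW_FRAC))
                hi = np.searchsorted(mz, mz[i] * (1 + WINDOW_FRAC))
                frac = np.mean(
                    [
                        s.intensity[lo:hi].max() > 2.0 * pn[i]
                        for s, pn in zip(tier_spectra, per_noise)
                    ]
                )
                if frac >= min_fraction_present:
                    keep.append(i)
            idx = np.asarray(keep, dtype=int)
        centers = mz[idx]
        los = centers * (1 - WINDOW_FRAC)
        his = centers * (1 + WINDOW_FRAC)
        # trim overlapping windows at the midpoint between apexes
        for k in range(len(centers) - 1):
            if his[k] > los[k + 1]:
                mid = 0.5 * (centers[k] + centers[k + 1])
                his[k] = mid
                los[k + 1] = mid
        for k, i in enumerate(idx):
            defs.append(
                PeakDef(
                    peak_id=f"{tier}:{mz[i]:.0f}",
                    tier=tier,
                    mz_center=float(mz[i]),
                    mz_lo=float(los[k]),
                    mz_hi=float(his[k]),
                    snr_at_detection=float(mean[i] / noise[i]),
                )
            )
    return defs


def quantify(spectra: list[Spectrum], peakdefs: list[PeakDef]) -> pd.DataFrame:
    """Peaks x samples apex-height matrix.

    Intensity is the window maximum minus the smaller window-edge value (a
    local baseline remnant), clipped at zero.  Every sample is quantified at
    every peak; samples missing a tier get zeros there and the affected
    cells are listed in ``matrix.attrs['missing']``.
    """
    sample_ids = sorted({s.sample_id for s in spectra})
    by_key = {(s.sample_id, s.tier): s for s in spectra}
    # window indices depend only on the tier grid; compute them once
    grid_by_tier = {}
    for s in spectra:
        grid_by_tier.setdefault(s.tier, s.mz)
    windows = []
    for pk in peakdefs:
        grid = grid_by_tier.get(pk.tier)
        if grid is None:
            windows.append((0, 0))
        else:
            windows.append(
                (int(np.searchsorted(grid, pk.mz_lo)), int(np.searchsorted(grid, pk.mz_hi)))
            )
    mat = np.zeros((len(peakdefs), len(sample_ids)))
    missing: list[tuple[str, str]] = []
    for j, sid in enumerate(sample_ids):
        for i, pk in enumerate(peakdefs):
            s = by_key.get((sid, pk.tier))
            lo, hi = windows[i]
            if s is None or hi <= lo:
                missing.append((pk.peak_id, sid))
                continue
            window = s.intensity[lo:hi]
            remnant = min(window[0], window[-1])
            mat[i, j] = max(float(window.max() - remnant), 0.0)
    out = pd.DataFrame(mat, index=[p.peak_id for p in peakdefs], columns=sample_ids)
    out.attrs["missing"] = missing
    return out


@dataclass
class AliasGraph:
    """Resolved satellite structure of a peak list.

    edges : alias_peak -> parent_peak with relation in {z2, z3, dimer} and
        the relative deviation from the expected position.
    duplicates : cross-tier re-acquisitions merged into the peak whose
        optimisation range best matches the m/z.
    adducts : covalent proteoform labels from `annotate_adducts`.
    """

    edges: pd.DataFrame
    duplicates: pd.DataFrame
    adducts: pd.DataFrame

    def parent_of(self, peak_id: str) -> str | None:
        hit = self.edges[self.edges["alias"] == peak_id]
        return None if hit.empty else str(hit["parent"].iloc[0])


def _merge_cross_tier(
    peakdefs: list[PeakDef], rel_tol: float
) -> tuple[list[PeakDef], pd.DataFrame]:
    used = [True] * len(peakdefs)
    dup_rows = []
    order = sorted(range(len(peakdefs)), key=lambda i: peakdefs[i].mz_center)
    for a_pos in range(len(order)):
        i = order[a_pos]
        if not used[i]:
            continue
        group = [i]
        for b_pos in range(a_pos + 1, len(order)):
            j = order[b_pos]
            if (peakdefs[j].mz_center - peakdefs[i].mz_center) / peakdefs[i].mz_center > rel_tol:
                break
            if used[j] and peakdefs[j].tier != peakdefs[i].tier:
                group.append(j)
        if len(group) > 1:
            best = min(
                group,
                key=lambda k: 0 if peakdefs[k].tier == preferred_tier(peakdefs[k].mz_center) else 1,
            )
            for k in group:
                if k != best:
                    used[k] = False
                    dup_rows.append((peakdefs[k].peak_id, peakdefs[best].peak_id))
    kept = [p for p, u in zip(peakdefs, used) if u]
    dups = pd.DataFrame(dup_rows, columns=["duplicate", "kept"])
    return kept, dups


def find_aliases(
    peakdefs: list[PeakDef],
    peak_matrix: pd.DataFrame | None = None,
    rel_tol: float = 0.005,
    corr_min: float = 0.5,
    mean_intensity: pd.Series | None = None,
) -> AliasGraph:
    """Resolve charge-state and dimer satellites into a parent map.

    For each ordered pair the observed m/z is tested against (m+1)/2,
    (m+2)/3 and 2m-1 of a putative parent within ``rel_tol``.  Candidates
    are gated on intensity (a satellite cannot be more intense than its
    parent; unknown intensities pass) and, when a matrix is available, on
    across-sample Pearson correlation with the parent (same protein, so the
    intensities must co-vary).  Each alias keeps its minimum-deviation
    parent; symmetric two-cycles (a=z2-of-m is arithmetically m=dimer-of-a)
    are broken in favour of the charge-state reading, then by intensity.
    Cross-tier duplicates are merged beforehand.
    """
    if rel_tol <= 0:
        raise ValueError("rel_tol must be > 0")
    kept, dups = _merge_cross_tier(peakdefs, min(rel_tol, MERGE_TOL))
    mz = {p.peak_id: p.mz_center for p in kept}
    if mean_intensity is None and peak_matrix is not None:
        mean_intensity = peak_matrix.mean(axis=1)

    def _intensity(pid: str) -> float | None:
        if mean_intensity is None or pid not in mean_intensity.index:
            return None
        return float(mean_intensity[pid])

    candidates: dict[str, list[tuple[float, str, str]]] = {p.peak_id: [] for p in kept}
    for a in kept:
        for m in kept:
            if a.peak_id == m.peak_id:
                continue
            for rel, f in _EXPECTED.items():
                exp = f(mz[m.peak_id])
                dev = abs(mz[a.peak_id] - exp) / exp
                if dev > rel_tol:
                    continue
                ia, im = _intensity(a.peak_id), _intensity(m.peak_id)
                if ia is not None and im is not None and ia > im:
                    continue
                if peak_matrix is not None and {a.peak_id, m.peak_id} <= set(peak_matrix.index):
                    va = peak_matrix.loc[a.peak_id].to_numpy(dtype=float)
                    vm = peak_matrix.loc[m.peak_id].to_numpy(dtype=float)
                    if va.std() == 0 or vm.std() == 0:
                        continue
                    if np.corrcoef(va, vm)[0, 1] < corr_min:
                        continue
                candidates[a.peak_id].append((dev, rel, m.peak_id))

    chosen: dict[str, tuple[float, str, str]] = {}
    for pid, cands in candidates.items():
        if cands:
            chosen[pid] = min(cands)
    # break symmetric 2-cycles: prefer the charge-state direction, then the
    # direction whose alias is the less intense member
    for pid in list(chosen):
        if pid not in chosen:
            continue
        dev, rel, parent = chosen[pid]
        back = chosen.get(parent)
        if back is None or back[2] != pid:
            continue
        bdev, brel, _ = back
        a_is_charge = rel in ("z2", "z3")
        b_is_charge = brel in ("z2", "z3")
        if a_is_charge and not b_is_charge:
            del chosen[parent]
        elif b_is_charge and not a_is_charge:
            del chosen[pid]
        else:
            ia, ip = _intensity(pid), _intensity(parent)
            if ia is not None and ip is not None and ia != ip:
                del chosen[pid if ia > ip else parent]
            else:
                del chosen[pid if dev >= bdev else parent]
    # guard against longer residual cycles
    while True:
        cycle_edge = _find_cycle_edge(chosen)
        if cycle_edge is None:
            break
        del chosen[cycle_edge]
    edges = pd.DataFrame(
        [(a, p, rel, dev) for a, (dev, rel, p) in sorted(chosen.items())],
        columns=["alias", "parent", "relation", "deviation"],
    )
    return AliasGraph(edges=edges, duplicates=dups, adducts=pd.DataFrame(
        columns=["peak_id", "base", "adduct", "delta", "deviation", "ambiguous"]
    ))


def _find_cycle_edge(chosen: dict) -> str | None:
    """Return an alias key participating in a cycle (largest deviation), or None."""
    for start in chosen:
        seen = []
        node = start
        while node in chosen:
            if node in seen:
                cycle = seen[seen.index(node):]
                return max(cycle, key=lambda k: chosen[k][0])
            seen.append(node)
            node = chosen[node][2]
    return None


def annotate_adducts(
    peakdefs: list[PeakDef],
    base_peak: str,
    rel_tol: float = 0.001,
    adduct_masses: dict | None = None,
) -> pd.DataFrame:
    """Label peaks sitting at base + adduct mass within tolerance.

    Returns one row per (peak, adduct) match; a peak matching two adducts is
    reported twice with ``ambiguous=True``.
    """
    table = dict(ADDUCT_MASSES if adduct_masses is None else adduct_masses)
    by_id = {p.peak_id: p for p in peakdefs}
    if base_peak not in by_id:
        raise ValueError(f"base peak {base_peak!r} not in peak definitions")
    base_mz = by_id[base_peak].mz_center
    rows = []
    for p in peakdefs:
        if p.peak_id == base_peak:
            continue
        hits = []
        for name, delta in table.items():
            exp = base_mz + delta
            dev = abs(p.mz_center - exp) / exp
            if dev <= rel_tol:
                hits.append((name, delta, dev))
        for name, delta, dev in hits:
            rows.append((p.peak_id, base_peak, name, delta, dev, len(hits) > 1))
    return pd.DataFrame(
        rows, columns=["peak_id", "base", "adduct", "delta", "deviation", "ambiguous"]
    )
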