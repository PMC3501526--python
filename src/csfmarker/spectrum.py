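"""Spectrum container and plain-text / mzML input-output.

A `Spectrum` is one laser-energy acquisition for one sample: an ascending m/z
grid with intensities plus the sample metadata carried through the pipeline
(group, age, laser tier, processing provenance flags).

Cohorts are persisted as a long-form CSV (sample_id, tier, mz, intensity)
next to a metadata CSV (sample_id, group, age); mzML runs can be read via
pyteomics when real acquisitions are available.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Laser-energy tiers and the m/z range each one is optimised for.
TIERS: dict[str, tuple[float, float]] = {
    "low": (2_000.0, 10_000.0),
    "med": (5_000.0, 30_000.0),
    "high": (20_000.0, 200_000.0),
}

GROUPS = ("ENU", "control")


@dataclass
class Spectrum:
    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str
    group: str
    age: str
    tier: str
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz grid must be strictly increasing")
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}; expected one of {sorted(TIERS)}")
        lo, hi = TIERS[self.tier]
        if self.mz.size and (self.mz[0] < lo - 1e-9 or self.mz[-1] > hi + 1e-9):
            raise ValueError(f"mz grid extends outside the {self.tier} tier range {lo}-{hi}")

    def copy(self) -> "Spectrum":
        return replace(
            self, mz=self.mz.copy(), intensity=self.intensity.copy(), flags=dict(self.flags)
        )


def cohort_metadata(spectra: list[Spectrum]) -> pd.DataFrame:
    """One row per sample: sample_id, group, age."""
    rows = {}
    for s in spectra:
        rows[s.sample_id] = (s.sample_id, s.group, s.age)
    return pd.DataFrame(sorted(rows.values()), columns=["sample_id", "group", "age"])


def write_spectra_csv(spectra: list[Spectrum], out_dir: str) -> None:
    """Write a cohort as spectra.csv (long form) + metadata.csv."""
    os.makedirs(out_dir, exist_ok=True)
    frames = [
        pd.DataFrame(
            {
                "sample_id": s.sample_id,
                "tier": s.tier,
                "mz": s.mz,
                "intensity": s.intensity,
            }
        )
        for s in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        os.path.join(out_dir, "spectra.csv"), index=False
    )
    cohort_metadata(spectra).to_csv(os.path.join(out_dir, "metadata.csv"), index=False)


def read_spectra_csv(in_dir: str) -> list[Spectrum]:
    """Read a cohort written by `write_spectra_csv`."""
    long = pd.read_csv(os.path.join(in_dir, "spectra.csv"))
    meta = pd.read_csv(os.path.join(in_dir, "metadata.csv")).set_index("sample_id")
    spectra = []
    for (sid, tier), g in long.groupby(["sample_id", "tier"], sort=True):
        g = g.sort_values("mz")
        spectra.append(
            Spectrum(
                mz=g["mz"].to_numpy(),
                intensity=g["intensity"].to_numpy(),
                sample_id=str(sid),
                group=str(meta.loc[sid, "group"]),
                age=str(meta.loc[sid, "age"]),
                tier=str(tier),
            )
        )
    return spectra


def read_mzml(path: str, sample_id: str, group: str, age: str, tier: str) -> Spectrum:
    """Read one run from an mzML file as a single profile spectrum."""
    from pyteomics import mzml as _mzml

    with _mzml.read(path) as reader:
        scan = next(iter(reader))
    return Spectrum(
        mz=np.asarray(scan["m/z array"], dtype=float),
        intensity=np.asarray(scan["intensity array"], dtype=float),
        sample_id=sample_id,
        group=group,
        age=age,
        tier=tier,
    )


def covering_tiers(mz: float) -> list[str]:
    """Tiers whose acquisition range contains the given m/z."""
    return [t for t, (lo, hi) in TIERS.items() if lo <= mz <= hi]


def preferred_tier(mz: float) -> str | None:
    """The tier best matched to an m/z: the covering tier whose range is
    geometrically centred closest to it (log scale)."""
    cands = covering_tiers(mz)
    if not cands:
        return None
    return min(
        cands,
        key=lambda t: abs(np.log(mz) - 0.5 * (np.log(TIERS[t][0]) + np.log(TIERS[t][1]))),
    )
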