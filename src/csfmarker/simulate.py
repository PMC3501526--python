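"""Synthetic SELDI-like CSF cohorts for an age-structured carcinogen-exposure study.

The generator emulates the statistical structure of cisternal-CSF linear-TOF
spectra from ENU-exposed and control rats sampled at three postnatal ages:

* three laser-energy tiers with overlapping m/z ranges, a decaying-exponential
  chemical baseline and additive grid noise;
* ~250 detectable peaks, most of them anonymous "filler" proteins, plus named
  anchors — an albumin-like high-mass protein with charge-state (z=2, z=3) and
  dimer satellites, a transthyretin-like proteoform family whose total is
  conserved while the adduct fractions shift with exposure, a PGD2S-like
  abundant peak whose apparent intensity is depressed by the albumin-like
  suppressor (ion-suppression artifact), and a low-mass fragment peptide;
* multiplicative lognormal biological variation per protein, group effects
  that grow with age, and charge/dimer alias peaks that co-vary with their
  parent protein;
* an optional blood-contamination globin peak at m/z 15216.

Every latent quantity is recorded in a `GroundTruth` so downstream stages can
be scored against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masscalc import ADDUCT_MASSES
from .spectrum import GROUPS, TIERS, Spectrum, covering_tiers, preferred_tier

__all__ = [
    "AGES",
    "CohortDesign",
    "Proteoform",
    "ProteinSpec",
    "SuppressionSpec",
    "SpectrumModel",
    "GroundTruth",
    "GLOBIN_MZ",
    "default_panel",
    "null_panel",
    "five_marker_panel",
    "build_entity_table",
    "simulate_cohort",
    "simulate_peak_matrix",
    "simulate_pathology",
    "inject_blood_contamination",
]

AGES = ("P30", "P60", "P90")

#: Haemoglobin subunit marker of blood contamination.
GLOBIN_MZ = 15216.0

#: Alias m/z conventions for a singly protonated parent at m (≈ M+H):
#: doubly/triply charged ions and the singly charged non-covalent dimer.
ALIAS_MZ = {
    "z2": lambda m: (m + 1.0) / 2.0,
    "z3": lambda m: (m + 2.0) / 3.0,
    "dimer": lambda m: 2.0 * m - 1.0,
}

#: Default ionization variability of satellite peaks relative to their parent.
DEFAULT_ALIAS_CV = 0.10

#: Expected apex height below which a peak is not rendered: sub-noise
#: satellites are not observable and would never survive detection
#: (6x the default grid noise, 20% above the default detection threshold).
MIN_PEAK_INTENSITY = 0.30


@dataclass(frozen=True)
class CohortDesign:
    """Per-age ENU/control sample counts.

    Defaults are the study's cohorts: P30 13/11, P60 16/16, P90 22/23.
    """

    ages: tuple[str, ...] = AGES
    n_per_group: dict = field(
        default_factory=lambda: {
            ("P30", "ENU"): 13,
            ("P30", "control"): 11,
            ("P60", "ENU"): 16,
            ("P60", "control"): 16,
            ("P90", "ENU"): 22,
            ("P90", "control"): 23,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for age in self.ages:
            for group in GROUPS:
                n = self.n_per_group.get((age, group))
                if n is None or n <= 0:
                    raise ValueError(f"missing or non-positive count for ({age}, {group})")
        groups = {g for (_, g) in self.n_per_group}
        if not groups <= set(GROUPS):
            raise ValueError(f"groups must be exactly {GROUPS}, got {sorted(groups)}")

    def samples(self) -> pd.DataFrame:
        rows = []
        for age in self.ages:
            for group in GROUPS:
                for i in range(self.n_per_group[(age, group)]):
                    rows.append((f"{age}_{group}_{i:02d}", group, age))
        return pd.DataFrame(rows, columns=["sample_id", "group", "age"])


@dataclass(frozen=True)
class Proteoform:
    """One covalent form of a protein: adduct label, mass shift, and the
    fraction of total protein it carries in each group (ENU fraction given at
    the reference age; intermediate ages interpolate)."""

    label: str
    delta: float  # Da
    frac_control: float
    frac_enu: float


@dataclass
class ProteinSpec:
    name: str
    base_mz: float
    tier: str
    base_intensity: float
    effect: dict = field(default_factory=dict)  # age -> ENU/control ratio
    cv: float = 0.25
    aliases: dict = field(default_factory=dict)  # relation -> relative abundance
    proteoforms: list | None = None
    form_cv: float = 0.05
    #: ionization variability of this protein's satellite peaks
    alias_cv: float = DEFAULT_ALIAS_CV
    #: developmental baseline per age (both groups); CSF composition changes
    #: strongly with postnatal age, which is why normalization is age-grouped
    age_scale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_mz <= 0 or self.base_intensity <= 0:
            raise ValueError(f"{self.name}: base_mz and base_intensity must be > 0")
        if not covering_tiers(self.base_mz):
            raise ValueError(
                f"{self.name}: base m/z {self.base_mz} is outside all laser-tier ranges"
            )
        for rel, ab in self.aliases.items():
            if rel not in ALIAS_MZ:
                raise ValueError(f"{self.name}: unknown alias relation {rel!r}")
            if not 0 < ab <= 1:
                raise ValueError(f"{self.name}: alias abundance must be in (0, 1]")
        if self.proteoforms:
            for tot in (
                sum(f.frac_control for f in self.proteoforms),
                sum(f.frac_enu for f in self.proteoforms),
            ):
                if abs(tot - 1.0) > 1e-6:
                    raise ValueError(f"{self.name}: proteoform fractions must sum to 1")

    def effect_at(self, age: str) -> float:
        return float(self.effect.get(age, 1.0))


@dataclass(frozen=True)
class SuppressionSpec:
    """Ion suppression: the target's signal is reduced by a fraction
    ``strength * S`` where S is the suppressor's per-sample intensity scaled
    to its cohort maximum."""

    suppressor: str
    target: str
    strength: float

    def __post_init__(self) -> None:
        if self.suppressor == self.target:
            raise ValueError("suppressor and target must differ")
        if not 0 <= self.strength < 1:
            raise ValueError("suppression strength must be in [0, 1)")


@dataclass(frozen=True)
class SpectrumModel:
    """Peak shape, grid, baseline and noise of the synthetic acquisitions."""

    resolution: float = 400.0  # FWHM = m/z / resolution
    points_per_fwhm: float = 6.0  # grid spacing = FWHM at tier start / this
    baseline_amplitude: float = 2.0
    baseline_tau_frac: float = 1.0 / 3.0  # decay length as fraction of tier span
    baseline_offset: float = 0.1
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.resolution <= 0 or self.points_per_fwhm <= 0:
            raise ValueError("resolution and points_per_fwhm must be > 0")
        if self.baseline_amplitude < 0 or self.baseline_offset < 0 or self.noise_sd < 0:
            raise ValueError("baseline and noise parameters must be >= 0")

    def fwhm(self, mz):
        return np.asarray(mz, dtype=float) / self.resolution

    def grid(self, tier: str) -> np.ndarray:
        lo, hi = TIERS[tier]
        spacing = (lo / self.resolution) / self.points_per_fwhm
        n = int(np.floor((hi - lo) / spacing)) + 1
        return lo + spacing * np.arange(n)

    def baseline(self, tier: str, mz: np.ndarray) -> np.ndarray:
        lo, hi = TIERS[tier]
        tau = (hi - lo) * self.baseline_tau_frac
        return self.baseline_amplitude * np.exp(-(mz - lo) / tau) + self.baseline_offset


@dataclass
class GroundTruth:
    """Everything the generator planted.

    entities : one row per rendered peak — ``peak_key``, protein, form,
        relation (parent/z2/z3/dimer), tier, mz, relative abundance,
        ``parent_key`` (empty for parents) and the expected ENU/control
        intensity ratio per age.
    latent : entity x sample true intensities before suppression and noise.
    expected : entity x sample intensities after suppression, before noise.
    """

    proteins: list
    entities: pd.DataFrame
    latent: pd.DataFrame
    expected: pd.DataFrame
    metadata: pd.DataFrame

    def differential_entities(self, age: str, min_ratio: float = 1.0 + 1e-9) -> pd.Index:
        """Peaks whose planted ENU/control ratio differs from 1 by at least
        ``min_ratio`` (fold change in either direction) at the given age."""
        r = self.entities[f"ratio_{age}"]
        fold = np.maximum(r, 1.0 / r)
        return self.entities.index[fold >= min_ratio]

    def alias_parent_map(self) -> dict:
        sub = self.entities[self.entities["relation"] != "parent"]
        return dict(zip(sub.index, sub["parent_key"]))


# ---------------------------------------------------------------------------
# entity table


def build_entity_table(proteins: list, min_intensity: float = MIN_PEAK_INTENSITY) -> pd.DataFrame:
    """Expand protein specs into one row per rendered peak.

    A protein contributes its (proteoform) parent peaks in every tier that
    covers them — overlapping laser ranges record the same molecule twice,
    as in real acquisitions — plus alias satellites at the z2/z3/dimer
    positions in every tier covering those.  ``parent_key`` points an alias
    or a cross-tier duplicate at the parent entity in the parent's preferred
    tier, so the planted alias map has exactly one parent per satellite.
    """
    names = [p.name for p in proteins]
    if len(set(names)) != len(names):
        raise ValueError("duplicate protein names in panel")
    rows = []
    for p in proteins:
        forms = p.proteoforms or [Proteoform("", 0.0, 1.0, 1.0)]
        for f in forms:
            mz0 = p.base_mz + f.delta
            home = preferred_tier(mz0)
            if home is None:
                raise ValueError(f"{p.name}/{f.label}: m/z {mz0} outside all tiers")
            parent_key = f"{p.name}|{f.label}|parent|{home}"
            positions = [("parent", mz0)] + [
                (rel, ALIAS_MZ[rel](mz0)) for rel in sorted(p.aliases)
            ]
            for rel, mz in positions:
                ab = 1.0 if rel == "parent" else p.aliases[rel]
                if p.base_intensity * f.frac_control * ab < min_intensity:
                    continue
                for tier in covering_tiers(mz):
                    key = f"{p.name}|{f.label}|{rel}|{tier}"
                    is_parent = key == parent_key
                    rows.append(
                        {
                            "peak_key": key,
                            "protein": p.name,
                            "form": f.label,
                            "relation": rel,
                            "tier": tier,
                            "mz": mz,
                            "abundance": 1.0 if rel == "parent" else p.aliases[rel],
                            "parent_key": "" if is_parent else parent_key,
                        }
                    )
    ent = pd.DataFrame(rows).set_index("peak_key")
    for age in AGES:
        ratios = {}
        for p in proteins:
            eff = p.effect_at(age)
            forms = p.proteoforms or [Proteoform("", 0.0, 1.0, 1.0)]
            g = _form_shift_progress(age)
            for f in forms:
                fr_enu = f.frac_control + g * (f.frac_enu - f.frac_control)
                ratios[(p.name, f.label)] = eff * (
                    fr_enu / f.frac_control if f.frac_control > 0 else 1.0
                )
        ent[f"ratio_{age}"] = [
            ratios[(r.protein, r.form)] for r in ent.itertuples()
        ]
    return ent


def _form_shift_progress(age: str) -> float:
    """Fraction of the full proteoform-fraction shift realised at each age;
    the redistribution grows with lesion progression."""
    return {"P30": 0.10, "P60": 0.45, "P90": 1.0}.get(age, 1.0)


# ---------------------------------------------------------------------------
# latent intensities


def _latent_intensities(
    design: CohortDesign,
    proteins: list,
    suppression: list,
    entities: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-sample entity intensities before (latent) and after (expected)
    suppression; noise-free apex heights in arbitrary µA-like units."""
    meta = design.samples()
    sample_ids = meta["sample_id"].tolist()

    # per-(protein, form) totals per sample
    form_level = {}
    protein_total = {}
    for p in proteins:
        forms = p.proteoforms or [Proteoform("", 0.0, 1.0, 1.0)]
        ln_sd = np.sqrt(np.log1p(p.cv**2))
        tot = (
            p.base_intensity
            * np.exp(rng.normal(0.0, ln_sd, len(sample_ids)) - 0.5 * ln_sd**2)
            if p.cv > 0
            else np.full(len(sample_ids), p.base_intensity)
        )
        eff = np.array(
            [
                (p.effect_at(a) if g == "ENU" else 1.0) * p.age_scale.get(a, 1.0)
                for g, a in zip(meta["group"], meta["age"])
            ]
        )
        tot = tot * eff
        protein_total[p.name] = tot
        fsd = np.sqrt(np.log1p(p.form_cv**2))
        for f in forms:
            g_age = np.array([_form_shift_progress(a) for a in meta["age"]])
            fr = np.where(
                meta["group"] == "ENU",
                f.frac_control + g_age * (f.frac_enu - f.frac_control),
                f.frac_control,
            )
            jitter = (
                np.exp(rng.normal(0.0, fsd, len(sample_ids)) - 0.5 * fsd**2)
                if p.form_cv > 0 and len(forms) > 1
                else 1.0
            )
            form_level[(p.name, f.label)] = tot * fr * jitter

    # entity level: alias satellites get their abundance and ionization jitter
    alias_sd = {
        p.name: np.sqrt(np.log1p(p.alias_cv**2)) for p in proteins
    }
    lat = np.empty((len(entities), len(sample_ids)))
    for i, e in enumerate(entities.itertuples()):
        base = form_level[(e.protein, e.form)]
        if e.relation == "parent":
            lat[i] = base
        else:
            asd = alias_sd[e.protein]
            jit = (
                np.exp(rng.normal(0.0, asd, len(sample_ids)) - 0.5 * asd**2)
                if asd > 0
                else 1.0
            )
            lat[i] = base * e.abundance * jit
    latent = pd.DataFrame(lat, index=entities.index, columns=sample_ids)

    # ion suppression, applied to every entity of the target protein
    expected = latent.copy()
    for sup in suppression:
        if sup.suppressor not in protein_total or sup.target not in protein_total:
            raise ValueError(
                f"suppression references unknown protein(s): {sup.suppressor}, {sup.target}"
            )
        s = protein_total[sup.suppressor]
        scale = 1.0 - sup.strength * (s / s.max())
        mask = entities["protein"] == sup.target
        expected.loc[mask] = expected.loc[mask] * scale
    return latent, expected, meta


# ---------------------------------------------------------------------------
# public simulation entry points


def simulate_cohort(
    design: CohortDesign,
    proteins: list,
    model: SpectrumModel | None = None,
    suppression: list | None = None,
) -> tuple[list[Spectrum], GroundTruth]:
    """Render one spectrum per sample per laser tier plus the ground truth."""
    model = model or SpectrumModel()
    suppression = suppression or []
    rng = np.random.default_rng(design.seed)
    entities = build_entity_table(proteins)
    latent, expected, meta = _latent_intensities(design, proteins, suppression, entities, rng)

    grids = {t: model.grid(t) for t in TIERS}
    baselines = {t: model.baseline(t, grids[t]) for t in TIERS}
    by_tier = {t: entities.index[entities["tier"] == t] for t in TIERS}

    spectra = []
    for _, (sid, group, age) in meta.iterrows():
        for tier in TIERS:
            mz = grids[tier]
            y = baselines[tier].copy()
            for key in by_tier[tier]:
                center = entities.at[key, "mz"]
                h = expected.at[key, sid]
                sigma = model.fwhm(center) / 2.354820045
                lo = np.searchsorted(mz, center - 4 * sigma)
                hi = np.searchsorted(mz, center + 4 * sigma)
                if hi > lo:
                    y[lo:hi] += h * np.exp(-0.5 * ((mz[lo:hi] - center) / sigma) ** 2)
            if model.noise_sd > 0:
                y = y + rng.normal(0.0, model.noise_sd, y.size)
            spectra.append(
                Spectrum(mz=mz, intensity=y, sample_id=sid, group=group, age=age, tier=tier)
            )
    truth = GroundTruth(
        proteins=proteins, entities=entities, latent=latent, expected=expected, metadata=meta
    )
    return spectra, truth


def simulate_peak_matrix(
    design: CohortDesign,
    proteins: list,
    suppression: list | None = None,
    measurement_cv: float = 0.05,
    noise_floor: float = 0.05,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Quantified peaks x samples matrix without rendering spectra.

    Matrix values are the post-suppression entity intensities with a small
    multiplicative read-out error and a half-normal noise floor emulating
    apex picking on a noisy grid.  This is the input contract of the stats
    and classification stages and keeps large permutation and subsampling
    studies cheap.
    """
    rng = np.random.default_rng(design.seed)
    entities = build_entity_table(proteins)
    latent, expected, meta = _latent_intensities(
        design, proteins, suppression or [], entities, rng
    )
    vals = expected.to_numpy()
    if measurement_cv > 0:
        sd = np.sqrt(np.log1p(measurement_cv**2))
        vals = vals * np.exp(rng.normal(0.0, sd, vals.shape) - 0.5 * sd**2)
    if noise_floor > 0:
        vals = vals + np.abs(rng.normal(0.0, noise_floor, vals.shape))
    matrix = pd.DataFrame(vals, index=expected.index, columns=expected.columns)
    truth = GroundTruth(
        proteins=proteins, entities=entities, latent=latent, expected=expected, metadata=meta
    )
    return matrix, truth


def simulate_pathology(
    design: CohortDesign,
    p_microtumor: dict,
    seed: int,
    n_per_age: dict | None = None,
) -> pd.DataFrame:
    """Per-rat pathology incidence for the exposed animals.

    Nestin+ precursor nests are present in every exposed rat at every age;
    hyperplastic microtumors appear with an age-dependent probability.
    """
    for age, p in p_microtumor.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {age} must be in [0, 1]")
    if n_per_age is None:
        n_per_age = {age: design.n_per_group[(age, "ENU")] for age in design.ages}
    rng = np.random.default_rng(seed)
    rows = []
    for age in design.ages:
        n = n_per_age[age]
        flags = rng.random(n) < p_microtumor.get(age, 0.0)
        for i in range(n):
            rows.append((f"{age}_rat_{i:02d}", age, True, bool(flags[i])))
    return pd.DataFrame(rows, columns=["rat_id", "age", "nests", "microtumor"])


def inject_blood_contamination(
    spectrum: Spectrum,
    fraction: float,
    model: SpectrumModel | None = None,
    globin_intensity_per_unit: float = 400.0,
    blood_proteins: list | None = None,
) -> Spectrum:
    """Dope a spectrum with blood at the given blood:CSF volume ratio.

    Adds a globin peak at m/z 15216 with intensity proportional to the
    fraction and boosts any designated blood-borne peaks (``blood_proteins``
    as (m/z, intensity-per-unit-fraction) pairs, e.g. the albumin-like peak).
    """
    if fraction < 0:
        raise ValueError("blood fraction must be >= 0")
    model = model or SpectrumModel()
    out = spectrum.copy()
    if fraction == 0:
        return out
    additions = [(GLOBIN_MZ, globin_intensity_per_unit)] + list(blood_proteins or [])
    for center, per_unit in additions:
        lo_t, hi_t = TIERS[spectrum.tier]
        if not lo_t <= center <= hi_t:
            continue
        sigma = model.fwhm(center) / 2.354820045
        lo = np.searchsorted(out.mz, center - 4 * sigma)
        hi = np.searchsorted(out.mz, center + 4 * sigma)
        out.intensity[lo:hi] += (
            per_unit * fraction * np.exp(-0.5 * ((out.mz[lo:hi] - center) / sigma) ** 2)
        )
    out.flags["blood_fraction"] = out.flags.get("blood_fraction", 0.0) + fraction
    return out


# ---------------------------------------------------------------------------
# panels


def _ttr_proteoforms() -> list:
    # Fractions follow the measured proportions of the transthyretin forms in
    # control vs exposed CSF (both sum to 1: the total is conserved, exposure
    # redistributes mass away from the glutathionylated form).
    ctl = {"unmodified": 70.86, "sulfonation": 38.96, "cysteinyl": 58.45,
           "cys-gly": 44.48, "glutathionyl": 143.62, "glu-cys": 8.0}
    enu = {"unmodified": 80.66, "sulfonation": 49.70, "cysteinyl": 74.09,
           "cys-gly": 51.29, "glutathionyl": 122.75, "glu-cys": 12.0}
    tc, te = sum(ctl.values()), sum(enu.values())
    deltas = {"unmodified": 0.0, **{k: ADDUCT_MASSES[k] for k in
                                    ("sulfonation", "cysteinyl", "cys-gly",
                                     "glutathionyl", "glu-cys")}}
    return [
        Proteoform(label, deltas[label], ctl[label] / tc, enu[label] / te)
        for label in ctl
    ]


def _named_anchors() -> tuple[list, list]:
    albumin = ProteinSpec(
        name="albumin",
        base_mz=66110.0,
        tier="high",
        base_intensity=13.1,
        effect={"P30": 1.02, "P60": 1.15, "P90": 1.30},
        cv=0.20,
        aliases={"z2": 0.32, "z3": 0.042, "dimer": 0.034},
        age_scale={"P30": 0.40, "P60": 0.70, "P90": 1.0},
    )
    ttr = ProteinSpec(
        name="transthyretin",
        base_mz=13601.0,
        tier="med",
        base_intensity=364.0,
        effect={},  # total conserved; group difference enters via fractions
        cv=0.15,
        aliases={"z2": 0.20, "dimer": 0.010},
        proteoforms=_ttr_proteoforms(),
    )
    pgd2s = ProteinSpec(
        name="pgd2s",
        base_mz=22893.0,
        tier="high",
        base_intensity=23.0,
        effect={},
        cv=0.06,
    )
    a1m_frag = ProteinSpec(
        name="a1m_fragment",
        base_mz=3493.0,
        tier="low",
        base_intensity=6.5,
        effect={"P30": 1.05, "P60": 1.30, "P90": 1.87},
        cv=0.50,
    )
    suppression = [SuppressionSpec(suppressor="albumin", target="pgd2s", strength=0.6)]
    return [albumin, ttr, pgd2s, a1m_frag], suppression


def default_panel(
    seed: int = 0,
    n_peaks_target: int = 247,
    n_differential: int = 28,
) -> tuple[list, list]:
    """The default study panel: named anchor proteins plus anonymous fillers
    drawn until the rendered peak count (across tiers) reaches the target.

    Differential fillers get a P90 ENU/control fold change drawn uniformly
    from 1.4-1.9 (40% of them decreased), realised progressively with age
    (~5% of the log effect at P30, ~40% at P60).
    """
    rng = np.random.default_rng(seed)
    proteins, suppression = _named_anchors()
    positions = [
        (e.mz, e.tier) for e in build_entity_table(proteins).itertuples()
    ]
    lo_all, hi_all = 2000.0, 180000.0
    n_filler = 0
    while len(positions) < n_peaks_target:
        mz = float(np.exp(rng.uniform(np.log(lo_all), np.log(hi_all))))
        intensity = float(np.exp(rng.uniform(np.log(0.4), np.log(30.0))))
        aliases = {}
        if rng.random() < 0.45 and covering_tiers(ALIAS_MZ["z2"](mz)):
            aliases["z2"] = float(rng.uniform(0.10, 0.50))
        if rng.random() < 0.15 and covering_tiers(ALIAS_MZ["z3"](mz)):
            aliases["z3"] = float(rng.uniform(0.05, 0.20))
        if rng.random() < 0.12 and covering_tiers(ALIAS_MZ["dimer"](mz)):
            aliases["dimer"] = float(rng.uniform(0.02, 0.15))
        # drop satellites that would fall below the observable floor
        aliases = {r: a for r, a in aliases.items() if intensity * a >= MIN_PEAK_INTENSITY}
        cand = [(mz, t) for t in covering_tiers(mz)]
        for rel in aliases:
            amz = ALIAS_MZ[rel](mz)
            cand += [(amz, t) for t in covering_tiers(amz)]
        # reject panels whose peaks would sit inside another peak's window
        clash = any(
            abs(cmz - pmz) / pmz < 0.012 and ct == pt
            for cmz, ct in cand
            for pmz, pt in positions
        ) or any(
            abs(a[0] - b[0]) / b[0] < 0.012 and a[1] == b[1]
            for i, a in enumerate(cand)
            for b in cand[i + 1 :]
        )
        if clash:
            continue
        effect = {}
        if n_filler < n_differential:
            r90 = float(rng.uniform(1.4, 1.9))
            if rng.random() < 0.4:
                r90 = 1.0 / r90
            g60 = float(rng.uniform(0.25, 0.60))
            g30 = float(rng.uniform(0.0, 0.12))
            effect = {
                "P30": float(np.exp(g30 * np.log(r90))),
                "P60": float(np.exp(g60 * np.log(r90))),
                "P90": r90,
            }
        proteins.append(
            ProteinSpec(
                name=f"filler_{n_filler:03d}",
                base_mz=mz,
                tier=preferred_tier(mz),
                base_intensity=intensity,
                effect=effect,
                cv=float(rng.uniform(0.15, 0.30)),
                aliases=aliases,
            )
        )
        positions.extend(cand)
        n_filler += 1
    return proteins, suppression


def null_panel(seed: int = 0, n_peaks_target: int = 247) -> tuple[list, list]:
    """The default panel with every group effect removed (global null):
    same peaks, variances, alias correlations — no ENU/control difference."""
    proteins, suppression = default_panel(seed=seed, n_peaks_target=n_peaks_target)
    out = []
    for p in proteins:
        forms = None
        if p.proteoforms:
            forms = [
                Proteoform(f.label, f.delta, f.frac_control, f.frac_control)
                for f in p.proteoforms
            ]
        out.append(
            ProteinSpec(
                name=p.name, base_mz=p.base_mz, tier=p.tier,
                base_intensity=p.base_intensity, effect={}, cv=p.cv,
                aliases=dict(p.aliases), proteoforms=forms, form_cv=p.form_cv,
                alias_cv=p.alias_cv, age_scale=dict(p.age_scale),
            )
        )
    return out, []


def five_marker_panel(
    seed: int = 0,
    n_peaks: int = 247,
    n_informative: int = 5,
    ratio: float = 1.7,
    cv: float = 0.20,
) -> list:
    """A flat panel for classifier benchmarking: ``n_informative`` peaks with
    a P90 group ratio, the rest pure null; no aliases, no suppression."""
    rng = np.random.default_rng(seed)
    mzs = []
    while len(mzs) < n_peaks:
        mz = float(np.exp(rng.uniform(np.log(2000.0), np.log(180000.0))))
        # keep each peak in a single laser tier so matrix rows are 1:1 with peaks
        if len(covering_tiers(mz)) == 1 and all(abs(mz - m) / m > 0.004 for m in mzs):
            mzs.append(mz)
    informative = rng.choice(n_peaks, size=n_informative, replace=False)
    proteins = []
    for i, mz in enumerate(mzs):
        effect = {"P90": ratio} if i in informative else {}
        proteins.append(
            ProteinSpec(
                name=f"peak_{i:03d}",
                base_mz=mz,
                tier=preferred_tier(mz),
                base_intensity=float(np.exp(rng.uniform(np.log(0.5), np.log(30.0)))),
                effect=effect,
                cv=cv,
            )
        )
    return proteins
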