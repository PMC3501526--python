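"""Generator invariants: planted structure, suppression, proteoform
conservation, pathology incidence and blood doping."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

import csfmarker.simulate as sim
from csfmarker.simulate import (
    CohortDesign,
    ProteinSpec,
    Proteoform,
    SpectrumModel,
    SuppressionSpec,
    inject_blood_contamination,
    simulate_pathology,
)
from csfmarker.stats import mann_whitney


def tiny_design(seed=0):
    return CohortDesign(
        ages=("P90",),
        n_per_group={("P90", "ENU"): 6, ("P90", "control"): 6},
        seed=seed,
    )


class TestValidation:
    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            CohortDesign(ages=("P30",), n_per_group={("P30", "ENU"): 0, ("P30", "control"): 5})

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(ages=("P30",), n_per_group={("P30", "ENU"): 3, ("P30", "sham"): 3})

    def test_protein_outside_all_tiers_rejected(self):
        with pytest.raises(ValueError, match="outside all laser-tier ranges"):
            ProteinSpec("x", base_mz=500.0, tier="low", base_intensity=1.0)

    def test_duplicate_protein_names_rejected(self):
        p = ProteinSpec("x", 5000.0, "low", 1.0)
        with pytest.raises(ValueError, match="duplicate"):
            sim.build_entity_table([p, p])

    def test_proteoform_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ProteinSpec(
                "x", 13601.0, "med", 10.0,
                proteoforms=[Proteoform("a", 0.0, 0.6, 0.6), Proteoform("b", 119.0, 0.3, 0.4)],
            )

    def test_suppression_strength_bounds(self):
        with pytest.raises(ValueError):
            SuppressionSpec("a", "b", 1.0)
        with pytest.raises(ValueError):
            SuppressionSpec("a", "a", 0.5)


class TestNoNoiseDegeneracy:
    def test_groups_identical_without_noise_or_effects(self):
        proteins = [
            ProteinSpec("p1", 8000.0, "low", 5.0, cv=0.0),
            ProteinSpec("p2", 40000.0, "high", 2.0, cv=0.0, aliases={"z2": 0.5}, alias_cv=0.0),
        ]
        mat, truth = sim.simulate_peak_matrix(
            tiny_design(), proteins, None, measurement_cv=0.0, noise_floor=0.0
        )
        enu = truth.metadata.query("group=='ENU'")["sample_id"]
        ctl = truth.metadata.query("group=='control'")["sample_id"]
        assert np.array_equal(mat[list(enu)].to_numpy(), mat[list(ctl)].to_numpy())

    def test_spectra_identical_within_tier(self):
        proteins = [ProteinSpec("p1", 8000.0, "low", 5.0, cv=0.0)]
        model = SpectrumModel(noise_sd=0.0)
        spectra, _ = sim.simulate_cohort(tiny_design(), proteins, model)
        low = [s for s in spectra if s.tier == "low"]
        for s in low[1:]:
            assert np.array_equal(s.intensity, low[0].intensity)


class TestGroundTruth:
    def test_alias_map_single_parent_acyclic(self, default_cohort):
        _, truth = default_cohort
        parents = truth.alias_parent_map()
        for alias, parent in parents.items():
            assert parent != alias
            # parents are never themselves aliases: one-level tree
            assert parent not in parents
            assert truth.entities.loc[parent, "relation"] == "parent"

    def test_entity_count_near_target(self, default_cohort):
        matrix, truth = default_cohort
        assert 240 <= len(truth.entities) <= 255
        assert matrix.shape == (len(truth.entities), 101)

    def test_differential_flags_track_effects(self, default_cohort):
        _, truth = default_cohort
        flagged = truth.differential_entities("P90")
        ratios = truth.entities["ratio_P90"]
        assert set(flagged) == set(ratios.index[np.abs(np.log(ratios)) > 1e-9])

    def test_determinism(self):
        proteins, supp = sim.default_panel(seed=5)
        m1, _ = sim.simulate_peak_matrix(CohortDesign(seed=5), proteins, supp)
        m2, _ = sim.simulate_peak_matrix(CohortDesign(seed=5), proteins, supp)
        pd.testing.assert_frame_equal(m1, m2)


class TestSuppression:
    def test_albumin_like_suppressor_inverts_target(self):
        """An abundant age-increasing suppressor at strength 0.6 produces a
        strong inverse correlation with the co-detected target peak."""
        rs = []
        for seed in range(3):
            proteins, supp = sim._named_anchors()
            mat, _ = sim.simulate_peak_matrix(CohortDesign(seed=seed), proteins, supp)
            rs.append(
                pearsonr(
                    mat.loc["albumin||parent|high"], mat.loc["pgd2s||parent|high"]
                ).statistic
            )
        assert max(rs) <= -0.8

    def test_suppression_reduces_expected_not_latent(self, default_cohort):
        _, truth = default_cohort
        target_rows = truth.entities.index[truth.entities["protein"] == "pgd2s"]
        assert (
            truth.expected.loc[target_rows].to_numpy()
            < truth.latent.loc[target_rows].to_numpy()
        ).all()
        others = truth.entities.index[truth.entities["protein"] == "albumin"]
        assert np.array_equal(
            truth.expected.loc[others].to_numpy(), truth.latent.loc[others].to_numpy()
        )


class TestProteoformConservation:
    def test_family_total_not_significant_when_shifts_cancel(self):
        """Exposure redistributes the transthyretin-like adduct fractions but
        conserves the per-sample total, so the summed intensity shows no
        group difference at the study's sample sizes."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            proteins, _ = sim._named_anchors()
            mat, truth = sim.simulate_peak_matrix(CohortDesign(seed=seed), proteins, None)
            fam = truth.entities.index[
                (truth.entities["protein"] == "transthyretin")
                & (truth.entities["relation"] == "parent")
                & (truth.entities["tier"] == "med")
            ]
            meta = truth.metadata.query("age=='P90'")
            total = mat.loc[fam, meta["sample_id"]].sum(axis=0)
            grp = meta.set_index("sample_id")["group"]
            _, p = mann_whitney(total[grp == "ENU"], total[grp == "control"])
            hits += p > 0.05
        assert hits >= 17  # ~90% of seeds

    def test_individual_forms_do_differ(self, default_cohort):
        _, truth = default_cohort
        ratios = truth.entities.loc[
            truth.entities["protein"] == "transthyretin", "ratio_P90"
        ]
        assert (np.abs(np.log(ratios)) > 0.01).all()
        # redistribution: some forms up, the glutathionylated form down
        assert (ratios > 1).any() and (ratios < 1).any()


class TestPathology:
    def test_expected_counts_match_incidence(self):
        """With the study's exposed-cohort sizes (20, 22, 21) and the printed
        incidence (0%, 18%, 67%), expected microtumor counts are 0/3.96/14.07."""
        design = CohortDesign()
        p = {"P30": 0.0, "P60": 4 / 22, "P90": 0.67}
        n = {"P30": 20, "P60": 22, "P90": 21}
        expected = {a: n[a] * p[a] for a in p}
        assert expected["P30"] == 0
        assert expected["P60"] == pytest.approx(3.96, abs=0.05)
        assert expected["P90"] == pytest.approx(14.07, abs=0.01)
        tabs = [
            simulate_pathology(design, p, seed=s, n_per_age=n) for s in range(40)
        ]
        mean_counts = {
            a: np.mean([t.loc[t["age"] == a, "microtumor"].sum() for t in tabs])
            for a in p
        }
        assert mean_counts["P30"] == 0.0
        assert mean_counts["P60"] == pytest.approx(3.96, abs=1.0)
        assert mean_counts["P90"] == pytest.approx(14.07, abs=1.5)
        for t in tabs:
            assert t["nests"].all()

    def test_zero_probability_and_determinism(self):
        design = CohortDesign()
        p0 = {a: 0.0 for a in design.ages}
        t = simulate_pathology(design, p0, seed=1)
        assert not t["microtumor"].any()
        p = {"P30": 0.2, "P60": 0.5, "P90": 0.8}
        pd.testing.assert_frame_equal(
            simulate_pathology(design, p, seed=7), simulate_pathology(design, p, seed=7)
        )

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            simulate_pathology(CohortDesign(), {"P30": 1.5}, seed=0)


class TestBloodContamination:
    def _spectrum(self):
        proteins = [ProteinSpec("p1", 14000.0, "med", 5.0, cv=0.0)]
        spectra, _ = sim.simulate_cohort(
            tiny_design(), proteins, SpectrumModel(noise_sd=0.0)
        )
        return next(s for s in spectra if s.tier == "med")

    def _globin_height(self, s):
        selector = np.abs(s.mz - sim.GLOBIN_MZ) / sim.GLOBIN_MZ < 0.003
        return s.intensity[selector].max()

    def test_zero_fraction_is_identity(self):
        s = self._spectrum()
        out = inject_blood_contamination(s, 0.0)
        assert np.array_equal(out.intensity, s.intensity)

    def test_globin_monotone_in_fraction(self):
        s = self._spectrum()
        heights = [
            self._globin_height(inject_blood_contamination(s, f))
            for f in (0.001, 0.01, 0.05, 0.2)
        ]
        assert all(a < b for a, b in zip(heights, heights[1:]))

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            inject_blood_contamination(self._spectrum(), -0.1)
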