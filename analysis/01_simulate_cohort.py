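"""Simulate the study cohorts: pathology incidence and a SELDI-like peak set.

Generates the exposed-cohort pathology table (nests in every animal,
microtumors rising 0% -> 18% -> 67% across the three ages) and a default
~247-peak quantified cohort with planted age-growing group effects, and
writes both under results/cohort/ together with the ground truth.
"""

import os

import csfmarker.simulate as sim
from csfmarker.stats import chi_square_homogeneity

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "cohort")
SEED = 1


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    design = sim.CohortDesign(seed=SEED)

    pathology = sim.simulate_pathology(
        design, {"P30": 0.0, "P60": 4 / 22, "P90": 0.67}, seed=SEED,
        n_per_age={"P30": 20, "P60": 22, "P90": 21},
    )
    pathology.to_csv(os.path.join(OUT, "pathology.csv"), index=False)
    counts = pathology.groupby("age")["microtumor"].agg(["sum", "count"])
    table = [[int(s), int(c - s)] for s, c in counts.to_numpy()]
    stat, dof, p = chi_square_homogeneity(table)
    print("microtumor incidence per age:")
    print(counts)
    print(f"chi-square homogeneity: chi2={stat:.2f}, df={dof}, p={p:.2g}")

    proteins, suppression = sim.default_panel(seed=SEED)
    matrix, truth = sim.simulate_peak_matrix(design, proteins, suppression)
    matrix.to_csv(os.path.join(OUT, "peak_matrix.csv"))
    truth.metadata.to_csv(os.path.join(OUT, "metadata.csv"), index=False)
    truth.entities.to_csv(os.path.join(OUT, "ground_truth_entities.csv"))
    n_diff = len(truth.differential_entities("P90", min_ratio=1.3))
    print(
        f"\nsimulated {matrix.shape[0]} peaks x {matrix.shape[1]} samples; "
        f"{n_diff} peaks carry a strong (>=1.3-fold) planted P90 effect"
    )


if __name__ == "__main__":
    main()
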