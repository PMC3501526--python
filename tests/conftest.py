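import numpy as np
import pandas as pd
import pytest

import csfmarker.simulate as sim
from csfmarker.peaks import PeakDef, detect_peaks, quantify
from csfmarker.preprocess import normalize_by_group, subtract_baseline

#: Published peak list of the top differential P90 peaks: (m/z, laser tier,
#: mean intensity in the exposed group; the 13840 glutamyl-cysteinyl parent
#: is referenced by annotation only, without a printed intensity).
TABLE2_ROWS = [
    (6909, "med", 9.97), (6859, "med", 14.07), (22054, "med", 1.00),
    (66110, "high", 17.04), (46643, "high", 0.24), (13725, "med", 74.09),
    (3493, "low", 12.17), (27410, "med", 0.59), (22893, "high", 17.94),
    (21365, "high", 3.39), (6823, "med", 9.85), (33109, "high", 5.24),
    (36781, "high", 0.74), (14120, "med", 24.90), (110080, "high", 0.03),
    (13670, "med", 49.70), (131938, "high", 0.76), (3504, "low", 2.75),
    (38453, "high", 0.65), (21593, "high", 3.30), (6795, "med", 16.26),
    (13913, "med", 122.75), (27538, "med", 0.81), (2887, "low", 2.38),
    (6865, "low", 11.02), (13788, "med", 51.29), (13601, "med", 80.66),
    (13840, "med", None),
]

#: The charge-state/dimer annotations printed alongside those peaks:
#: alias m/z -> (parent m/z, relation).
TABLE2_ALIASES = {
    6909: (13840, "z2"),
    6859: (13725, "z2"),
    22054: (66110, "z3"),
    27410: (13725, "dimer"),
    6823: (13670, "z2"),
    33109: (66110, "z2"),
    131938: (66110, "dimer"),
    6795: (13601, "z2"),
    6865: (13725, "z2"),
}

#: The proteoform ladder on the 13601 base peak: peak m/z -> adduct label.
TABLE2_ADDUCTS = {
    13725: "cysteinyl",
    13788: "cys-gly",
    13913: "glutathionyl",
    13670: "sulfonation",
    13840: "glu-cys",
}


@pytest.fixture(scope="session")
def table2_peakdefs():
    return [
        PeakDef(f"{t}:{m}", t, float(m), m * 0.997, m * 1.003)
        for m, t, _ in TABLE2_ROWS
    ]


@pytest.fixture(scope="session")
def table2_intensities():
    return pd.Series(
        {f"{t}:{m}": v for m, t, v in TABLE2_ROWS if v is not None}
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One matrix-mode cohort with the default panel, shared across tests."""
    proteins, suppression = sim.default_panel(seed=3)
    matrix, truth = sim.simulate_peak_matrix(
        sim.CohortDesign(seed=3), proteins, suppression
    )
    return matrix, truth


@pytest.fixture(scope="session")
def processed_cohort():
    """One fully rendered cohort taken through preprocessing, detection and
    quantification (the expensive spectra-mode path), shared across tests."""
    proteins, suppression = sim.default_panel(seed=3)
    spectra, truth = sim.simulate_cohort(
        sim.CohortDesign(seed=3), proteins, suppression=suppression
    )
    proc = [subtract_baseline(s) for s in spectra]
    proc, report = normalize_by_group(proc)
    defs = detect_peaks(proc, snr_min=5)
    matrix = quantify(proc, defs)
    return {
        "raw": spectra,
        "processed": proc,
        "report": report,
        "defs": defs,
        "matrix": matrix,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
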