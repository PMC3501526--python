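"""Per-peak nonparametric testing and permutation false-discovery analysis.

Group differences in peak intensity are ranked with two-sided Mann-Whitney U
tests (exact enumeration for small tie-free samples, tie-corrected normal
approximation with continuity correction otherwise).  Because hundreds of
peaks are tested at once, discoveries are calibrated by permuting the animal
identities within an age stratum: the global FDR curve compares the number of
observed discoveries at each p-value threshold with the average permuted
count, and the local FDR of each peak is the permutation-null density around
its observed p divided by the observed density there (pooled across peaks),
clipped to [0, 1] and monotonized in p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "mann_whitney",
    "test_all_peaks",
    "FDRCurve",
    "global_fdr_curve",
    "local_fdr",
    "chi_square_homogeneity",
    "suppression_diagnostic",
    "proteoform_sum_test",
]

#: Sample-size bound below which the exact MWU null distribution is used.
EXACT_MAX_N = 12


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two intensity samples.

    Returns (U of the first sample, two-sided p).  The exact null
    distribution is enumerated when n1+n2 <= 12 and the pooled data are
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction is used.  Identical pooled values give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return x.size * y.size / 2.0, 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = _sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _mwu_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise asymptotic MWU for a (peaks x n1) vs (peaks x n2) pair."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _sps.mannwhitneyu(
            a, b, axis=-1, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
    u = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    flat = np.ptp(np.concatenate([a, b], axis=-1), axis=-1) == 0
    u[flat] = a.shape[-1] * b.shape[-1] / 2.0
    p[flat] = 1.0
    return u, np.minimum(np.nan_to_num(p, nan=1.0), 1.0)


def _split_by_group(matrix: pd.DataFrame, metadata: pd.DataFrame, age: str):
    meta = metadata[metadata["age"] == age]
    enu = meta.loc[meta["group"] == "ENU", "sample_id"]
    ctl = meta.loc[meta["group"] == "control", "sample_id"]
    enu = [s for s in enu if s in matrix.columns]
    ctl = [s for s in ctl if s in matrix.columns]
    if len(enu) < 2 or len(ctl) < 2:
        raise ValueError(f"both groups need >= 2 samples at {age}")
    return matrix[enu].to_numpy(dtype=float), matrix[ctl].to_numpy(dtype=float)


def test_all_peaks(matrix: pd.DataFrame, metadata: pd.DataFrame, age: str) -> pd.DataFrame:
    """One Mann-Whitney test per peak at one age, sorted by ascending p.

    Returns a frame with group means and SEMs, the U statistic and two-sided
    p per peak; ``local_fdr`` is NaN until `local_fdr` fills it in.
    """
    a, b = _split_by_group(matrix, metadata, age)
    u, p = _mwu_rows(a, b)
    out = pd.DataFrame(
        {
            "peak_id": matrix.index,
            "age": age,
            "n_enu": a.shape[1],
            "n_ctl": b.shape[1],
            "mean_enu": a.mean(axis=1),
            "sem_enu": a.std(axis=1, ddof=1) / np.sqrt(a.shape[1]),
            "mean_ctl": b.mean(axis=1),
            "sem_ctl": b.std(axis=1, ddof=1) / np.sqrt(b.shape[1]),
            "u_stat": u,
            "p_value": p,
            "local_fdr": np.nan,
        }
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def _null_pvalues(
    matrix: pd.DataFrame, metadata: pd.DataFrame, age: str, n_perm: int, seed
) -> np.ndarray:
    """(n_perm x n_peaks) p-values under within-age label permutation."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a, b = _split_by_group(matrix, metadata, age)
    pooled = np.concatenate([a, b], axis=1)
    n1 = a.shape[1]
    rng = np.random.default_rng(seed)
    out = np.empty((n_perm, pooled.shape[0]))
    for k in range(n_perm):
        order = rng.permutation(pooled.shape[1])
        _, out[k] = _mwu_rows(pooled[:, order[:n1]], pooled[:, order[n1:]])
    return out


@dataclass
class FDRCurve:
    """Observed vs permutation-null discovery counts on a p-threshold grid."""

    thresholds: np.ndarray
    observed: np.ndarray
    null_mean: np.ndarray
    n_permutations: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "observed": self.observed,
                "null_mean": self.null_mean,
            }
        )


def global_fdr_curve(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    age: str,
    n_perm: int = 100,
    seed: int = 0,
    thresholds: np.ndarray | None = None,
) -> FDRCurve:
    """Discoveries vs average permuted discoveries at each p-value up to 0.05.

    Labels are permuted within the age stratum (group sizes preserved by
    construction); the null curve is the mean count over ``n_perm`` shuffles.
    """
    if thresholds is None:
        thresholds = np.linspace(0.001, 0.05, 50)
    thresholds = np.asarray(thresholds, dtype=float)
    obs_p = test_all_peaks(matrix, metadata, age)["p_value"].to_numpy()
    null_p = _null_pvalues(matrix, metadata, age, n_perm, seed)
    observed = (obs_p[None, :] < thresholds[:, None]).sum(axis=1)
    null_mean = (null_p[None, :, :] < thresholds[:, None, None]).sum(axis=2).mean(axis=1)
    return FDRCurve(
        thresholds=thresholds,
        observed=observed.astype(float),
        null_mean=null_mean,
        n_permutations=n_perm,
    )


def local_fdr(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    age: str,
    n_perm: int = 100,
    bandwidth: float = 2.0,
    seed: int = 0,
) -> pd.Series:
    """Permutation local false discovery rate per peak.

    For peak i with observed p_i, a window W_i = [p_i/c, p_i*c] (c =
    ``bandwidth``) on the log-p scale is widened until it holds at least 5
    observed p-values; the local FDR is the mean permuted count of null
    p-values in W_i (pooled across peaks) divided by the observed count,
    clipped to [0, 1] and made non-decreasing in p.
    """
    if bandwidth <= 1.0:
        raise ValueError("bandwidth must be > 1 on the p-ratio scale")
    tests = test_all_peaks(matrix, metadata, age)
    obs = tests["p_value"].to_numpy()
    null = np.sort(_null_pvalues(matrix, metadata, age, n_perm, seed).ravel())
    obs_sorted = np.sort(obs)
    raw = np.empty_like(obs)
    for i, p in enumerate(obs):
        c = bandwidth
        while True:
            lo, hi = p / c, min(p * c, 1.0)
            n_obs = np.searchsorted(obs_sorted, hi, side="right") - np.searchsorted(
                obs_sorted, lo, side="left"
            )
            if n_obs >= 5 or c > 1e6:
                break
            c = c * bandwidth
        n_null = np.searchsorted(null, hi, side="right") - np.searchsorted(
            null, lo, side="left"
        )
        raw[i] = min((n_null / n_perm) / max(n_obs, 1), 1.0)
    # monotonize: local FDR cannot decrease as p grows
    order = np.argsort(obs, kind="stable")
    raw[order] = np.maximum.accumulate(raw[order])
    return pd.Series(raw, index=tests["peak_id"].to_numpy(), name="local_fdr")


def chi_square_homogeneity(table) -> tuple[float, int, float]:
    """Pearson chi-square test of homogeneity on an ages x outcome count table."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need a 2-D contingency table with >= 2 rows and columns")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("cell counts must be non-negative integers")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total; expected counts would be 0")
    res = _sps.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def suppression_diagnostic(
    matrix: pd.DataFrame, peak_a: str, peak_b: str
) -> tuple[float, float, float]:
    """Least-squares fit of peak_b on peak_a across all samples (all ages
    pooled): returns (Pearson r, slope, intercept).  Diagnoses ion
    suppression as a strong inverse linear relation between an abundant
    suppressor and a co-detected peak."""
    a = matrix.loc[peak_a].to_numpy(dtype=float)
    b = matrix.loc[peak_b].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in one of the peaks")
    fit = _sps.linregress(a, b)
    return float(fit.rvalue), float(fit.slope), float(fit.intercept)


def proteoform_sum_test(
    matrix: pd.DataFrame, metadata: pd.DataFrame, family: list[str], age: str
) -> dict:
    """Mann-Whitney test of the per-sample summed intensity of a proteoform
    family.  A conserved total (fractions shifting, sum unchanged) shows no
    group difference even when every member peak does."""
    if not family:
        raise ValueError("family must be non-empty")
    missing = [p for p in family if p not in matrix.index]
    if missing:
        raise ValueError(f"peaks not in matrix: {missing}")
    summed = matrix.loc[family].sum(axis=0).to_frame().T
    summed.index = ["family_sum"]
    a, b = _split_by_group(summed, metadata, age)
    u, p = mann_whitney(a.ravel(), b.ravel())
    return {
        "peak_id": "+".join(family),
        "age": age,
        "n_enu": a.size,
        "n_ctl": b.size,
        "mean_enu": float(a.mean()),
        "sem_enu": float(a.std(ddof=1) / np.sqrt(a.size)),
        "mean_ctl": float(b.mean()),
        "sem_ctl": float(b.std(ddof=1) / np.sqrt(b.size)),
        "u_stat": u,
        "p_value": p,
    }
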