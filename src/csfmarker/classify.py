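"""Sparse marker selection by the homotopy (LARS-LASSO) path with
repeated-subsample cross-validation and selection-frequency analysis.

The classifier is the classical least-squares LASSO on +/-1 labels,

    min_b  1/2 ||y - X b||^2 + lam ||b||_1 ,

whose solution path is piecewise linear in the penalty ``lam``: starting from
the all-zero solution at lam = max|X^T y|, features enter (or drop) one at a
time at computable breakpoints.  Tracing the path and stopping once a desired
number of markers is active yields classifiers of every size in one fit;
prediction is the sign of the linear score.  Marker stability is assessed by
refitting on many random subsamples and recording, for the size-k classifier,
how often each peak is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LassoPath",
    "CVCurve",
    "lasso_path",
    "coefficients_at",
    "classifier_at_k",
    "cross_validate",
    "selection_frequency",
    "standardize",
]

_EPS = 1e-12


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize; zero-variance columns get unit scale (and are
    effectively inert: their correlation with any residual is zero)."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < _EPS, 1.0, sd)
    return (X - mean) / sd, mean, sd


@dataclass
class LassoPath:
    """Breakpoints of the homotopy path.

    ``penalties[j]`` is the penalty at breakpoint j (strictly decreasing),
    ``coefs[j]`` the coefficient vector there, ``active_sets[j]`` the sorted
    active feature indices, and ``entry_order`` the features in the order
    they first entered.  Between breakpoints coefficients are linear in the
    penalty.
    """

    penalties: np.ndarray
    coefs: np.ndarray
    active_sets: list[tuple[int, ...]]
    entry_order: list[int]
    n_features: int


def lasso_path(X: np.ndarray, y: np.ndarray, k_max: int) -> LassoPath:
    """Trace the LASSO homotopy path until ``k_max`` features are active.

    ``X`` must be column-standardized and ``y`` in {-1, +1} (centred
    internally).  Exact duplicate columns are resolved deterministically:
    the lower-index (lower m/z, given m/z-sorted columns) member enters.
    Features may drop and re-enter per the homotopy rules; the path stops at
    the first breakpoint with ``k_max`` active features (or at penalty 0).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if k_max < 1 or k_max > min(n - 1, p):
        raise ValueError(f"k_max must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    yc = y - y.mean()

    c = X.T @ yc  # current correlations X^T r
    lam = float(np.max(np.abs(c)))
    active: list[int] = [int(np.argmax(np.abs(c)))]
    signs: dict[int, float] = {active[0]: float(np.sign(c[active[0]]))}
    b = np.zeros(p)
    penalties = [lam]
    coefs = [b.copy()]
    active_sets = [tuple(sorted(active))]
    entry_order = [active[0]]

    while lam > _EPS:
        A = np.array(active, dtype=int)
        s = np.array([signs[j] for j in A])
        G = X[:, A].T @ X[:, A]
        try:
            d = np.linalg.solve(G, s)
        except np.linalg.LinAlgError:
            d = np.linalg.lstsq(G, s, rcond=None)[0]
        # b_A(lam - t) = b_A + t * d ; correlations of inactive features move
        # as c_j(lam - t) = c_j - t * v_j
        v = X.T @ (X[:, A] @ d)

        inactive = np.ones(p, dtype=bool)
        inactive[A] = False
        with np.errstate(divide="ignore", invalid="ignore"):
            t_plus = (lam - c) / (1.0 - v)
            t_minus = (lam + c) / (1.0 + v)
        for arr in (t_plus, t_minus):
            arr[~inactive] = np.inf
            arr[~np.isfinite(arr)] = np.inf
            arr[arr <= _EPS] = np.inf
        t_cand = np.minimum(t_plus, t_minus)
        join_j = int(np.argmin(t_cand)) if inactive.any() else -1
        t_join = float(t_cand[join_j]) if join_j >= 0 else np.inf

        with np.errstate(divide="ignore", invalid="ignore"):
            t_dropv = -b[A] / d
        t_dropv[~np.isfinite(t_dropv)] = np.inf
        t_dropv[t_dropv <= _EPS] = np.inf
        drop_idx = int(np.argmin(t_dropv))
        t_drop = float(t_dropv[drop_idx])
        drop_j = int(A[drop_idx]) if np.isfinite(t_drop) else -1
        t = min(t_join, t_drop, lam)

        b[A] = b[A] + t * d
        c = c - t * v
        lam = lam - t
        if t == t_drop and t_drop <= t_join:
            b[drop_j] = 0.0
            active.remove(drop_j)
            del signs[drop_j]
        elif t == t_join and join_j >= 0:
            active.append(join_j)
            signs[join_j] = float(np.sign(c[join_j]))
            if join_j not in entry_order:
                entry_order.append(join_j)
        penalties.append(lam)
        coefs.append(b.copy())
        active_sets.append(tuple(sorted(active)))
        # trace one segment beyond the k_max-th entry so the size-k_max
        # classifier (the end of its segment) has realised coefficients
        if len(active) > k_max:
            break
        if not active:  # fully relaxed before k_max reached (degenerate)
            break
    return LassoPath(
        penalties=np.asarray(penalties),
        coefs=np.asarray(coefs),
        active_sets=active_sets,
        entry_order=entry_order,
        n_features=p,
    )


def coefficients_at(path: LassoPath, penalty: float) -> np.ndarray:
    """Coefficients at an arbitrary penalty by linear interpolation between
    the flanking breakpoints (exact: the path is piecewise linear)."""
    lams = path.penalties
    if penalty >= lams[0]:
        return np.zeros(path.n_features)
    if penalty < lams[-1] - _EPS:
        raise ValueError(
            f"penalty {penalty} below the end of the traced path ({lams[-1]})"
        )
    k = int(np.searchsorted(-lams, -penalty, side="right")) - 1
    k = min(k, len(lams) - 2)
    lo, hi = lams[k + 1], lams[k]
    w = 0.0 if hi - lo < _EPS else (hi - penalty) / (hi - lo)
    return (1 - w) * path.coefs[k] + w * path.coefs[k + 1]


def classifier_at_k(path: LassoPath, k: int) -> tuple[tuple[int, ...], np.ndarray, float]:
    """Marker set and coefficients of the size-k classifier.

    The classifier with k markers is the solution at the end of the first
    path segment whose active set has size k — i.e. just before the (k+1)-th
    feature would enter (or a feature drop), when all k coefficients are
    realised.  k = 0 gives the majority-label classifier.
    """
    if k == 0:
        return (), np.zeros(path.n_features), 0.0
    for j, aset in enumerate(path.active_sets):
        if len(aset) == k and j + 1 < len(path.coefs):
            return aset, path.coefs[j + 1].copy(), 0.0
    raise ValueError(f"path never completes a segment with {k} active features")


@dataclass
class CVCurve:
    """Mean held-out misclassification per classifier size."""

    k: np.ndarray
    error: np.ndarray
    n_repeats: int

    def best_k(self) -> int:
        return int(self.k[int(np.argmin(self.error))])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "mean_error": self.error})


def _proportional_train_counts(labels: np.ndarray, train_n: int) -> dict:
    classes, counts = np.unique(labels, return_counts=True)
    raw = counts * train_n / counts.sum()
    take = np.floor(raw).astype(int)
    # distribute the remainder by largest fractional part
    rem = train_n - take.sum()
    order = np.argsort(-(raw - take), kind="stable")
    for i in order[:rem]:
        take[i] += 1
    return dict(zip(classes.tolist(), take.tolist()))


def _subsample_runs(
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int,
    train_n: int,
    k_max: int,
    seed,
    proportional: bool = True,
    refit: bool = True,
):
    """Yield (active_sets_by_k, per-k held-out error) for each subsample."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not 0 < train_n < n:
        raise ValueError("train_n must be in (0, n_samples)")
    rng = np.random.default_rng(seed)
    counts = _proportional_train_counts(y, train_n) if proportional else None
    for _ in range(n_repeats):
        while True:
            if proportional:
                idx = np.concatenate(
                    [
                        rng.choice(np.flatnonzero(y == cls), size=cnt, replace=False)
                        for cls, cnt in counts.items()
                    ]
                )
            else:
                idx = rng.choice(n, size=train_n, replace=False)
            train = np.zeros(n, dtype=bool)
            train[idx] = True
            if len(np.unique(y[train])) == 2:
                break
        Xt, mean, sd = standardize(X[train])
        yt = y[train]
        Xh = (X[~train] - mean) / sd  # held-out scaled by training parameters
        yh = y[~train]
        path = lasso_path(Xt, yt, k_max=k_max)
        intercept = yt.mean()
        sets_by_k: dict[int, tuple[int, ...]] = {}
        errors = np.full(k_max, np.nan)
        for k in range(1, k_max + 1):
            try:
                aset, beta, _ = classifier_at_k(path, k)
            except ValueError:
                break
            sets_by_k[k] = aset
            if refit:
                # LARS-OLS hybrid: the path chooses the markers, an
                # unpenalized fit on them scores held-out samples, so the
                # cost of a superfluous marker is not masked by shrinkage
                A = list(aset)
                coef = np.linalg.lstsq(
                    np.column_stack([Xt[:, A], np.ones(len(yt))]), yt, rcond=None
                )[0]
                score = Xh[:, A] @ coef[:-1] + coef[-1]
            else:
                score = Xh @ beta + intercept
            pred = np.where(score >= 0, 1.0, -1.0)
            errors[k - 1] = float(np.mean(pred != yh))
        yield sets_by_k, errors


def cross_validate(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_repeats: int = 1000,
    train_n: int = 36,
    k_max: int = 10,
    seed: int = 0,
    proportional: bool = True,
    refit: bool = True,
) -> CVCurve:
    """Repeated-subsample cross-validation of classifier size.

    Each repeat draws ``train_n`` samples (group-proportional by default),
    fits the homotopy path on the training draw and scores the size-k
    classifier on the held-out samples for every k; errors are averaged
    over repeats.  With ``refit`` (default) the size-k marker set is scored
    by its unpenalized least-squares fit, so the error curve turns upward
    once superfluous markers enter.
    """
    X = matrix.to_numpy(dtype=float).T
    y = _encode_labels(labels, matrix.columns)
    errs = []
    for _, e in _subsample_runs(X, y, n_repeats, train_n, k_max, seed, proportional, refit):
        errs.append(e)
    mean_err = np.nanmean(np.asarray(errs), axis=0)
    return CVCurve(k=np.arange(1, k_max + 1), error=mean_err, n_repeats=n_repeats)


def selection_frequency(
    matrix: pd.DataFrame,
    labels: pd.Series,
    k: int = 5,
    n_repeats: int = 1000,
    train_n: int = 36,
    seed: int = 0,
    proportional: bool = True,
) -> pd.Series:
    """Fraction of subsample repeats in which each peak is in the size-k
    active set, sorted descending (the marker stability table)."""
    X = matrix.to_numpy(dtype=float).T
    y = _encode_labels(labels, matrix.columns)
    counts = np.zeros(matrix.shape[0])
    n_ok = 0
    for sets_by_k, _ in _subsample_runs(X, y, n_repeats, train_n, k, seed, proportional):
        aset = sets_by_k.get(k)
        if aset is None:
            continue
        counts[list(aset)] += 1
        n_ok += 1
    freq = counts / max(n_ok, 1)
    return pd.Series(freq, index=matrix.index, name="selection_frequency").sort_values(
        ascending=False, kind="stable"
    )


def _encode_labels(labels: pd.Series, columns) -> np.ndarray:
    lab = pd.Series(labels)
    lab = lab.reindex(columns) if set(columns) <= set(lab.index) else lab
    vals = lab.to_numpy()
    uniq = sorted(set(vals))
    if set(vals) == {-1, 1} or set(vals) == {-1.0, 1.0}:
        return vals.astype(float)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 label values, got {uniq}")
    # ENU (exposed) coded +1, control -1; otherwise sorted order
    if set(vals) == {"ENU", "control"}:
        return np.where(vals == "ENU", 1.0, -1.0)
    return np.where(vals == uniq[1], 1.0, -1.0)
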