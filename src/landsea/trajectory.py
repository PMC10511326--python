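"""Pre-disturbance reef trajectory analysis.

Reefs are classified as positive / negative / no-change from the change in
coral cover over the monitoring period (default cutoff ±3 percentage
points), then the local land–sea conditions of positive versus negative
reefs are contrasted three ways:

* per-factor drop-one jackknife differences (mean with min/max bars),
* a one-factor PERMANOVA on the Euclidean distance matrix of the
  normalized factors (permutation pseudo-F test),
* a canonical analysis of principal coordinates (CAP) with leave-one-out
  allocation success as the measure of group distinctness.

`TrajectoryContrast` is the model object; `fit()` returns a
`TrajectoryResults` carrying all three.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ._util import informative_columns, zscore

__all__ = [
    "classify_trajectory",
    "median_sd_outlier_filter",
    "jackknife_group_difference",
    "permanova",
    "cap",
    "PermanovaResult",
    "CapResult",
    "TrajectoryContrast",
    "TrajectoryResults",
]


def classify_trajectory(cover_start: float, cover_end: float, cutoff: float = 3.0) -> str:
    """Classify a reef's cover trajectory by the change in percent cover.

    Positive if the change exceeds ``cutoff`` percentage points, negative if
    below ``-cutoff``, otherwise "no-change".
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    for v in (cover_start, cover_end):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"cover {v} outside [0, 100]")
    delta = cover_end - cover_start
    if delta > cutoff:
        return "positive"
    if delta < -cutoff:
        return "negative"
    return "no-change"


def median_sd_outlier_filter(values, k: float = 2.0):
    """Drop values outside median ± k × sample SD.

    Returns ``(retained_values, removed_indices)``.  The SD is the ordinary
    sample SD (ddof=1) of the full vector; the centre is the median, which
    keeps the rule robust to the very outliers being screened.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 values to screen outliers")
    med = np.median(x)
    sd = x.std(ddof=1)
    keep = np.abs(x - med) <= k * sd
    if not keep.any():
        raise ValueError("outlier filter removed every value (degenerate input)")
    return x[keep], np.flatnonzero(~keep)


def _drop_one_means(x: np.ndarray) -> np.ndarray:
    return (x.sum() - x) / (x.size - 1)


def jackknife_group_difference(group_a, group_b) -> dict:
    """Drop-one jackknife contrast of one factor between two groups.

    All drop-one means are computed per group; the statistic is the mean,
    minimum and maximum of the pairwise differences (A minus B) between the
    two sets of drop-one means.  The mean of drop-one means equals the full
    sample mean, so the central dot equals the plain group-mean difference.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values for drop-one jackknife")
    da = _drop_one_means(a)
    db = _drop_one_means(b)
    diffs = da[:, None] - db[None, :]
    return {
        "mean_difference": float(diffs.mean()),
        "min_difference": float(diffs.min()),
        "max_difference": float(diffs.max()),
    }


@dataclass
class PermanovaResult:
    pseudo_f: float
    df_between: int
    df_residual: int
    p_value: float
    n_permutations: int
    exact: bool = False
    degenerate: bool = False

    def __str__(self):  # pragma: no cover - cosmetic
        return (
            f"PERMANOVA pseudo-F({self.df_between},{self.df_residual}) = "
            f"{self.pseudo_f:.3f}, P = {self.p_value:.4g} "
            f"({'exact, ' if self.exact else ''}{self.n_permutations} permutations)"
        )


def _pseudo_f(sq_dist: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """One-factor PERMANOVA pseudo-F from a squared Euclidean distance matrix."""
    n = labels.size
    ss_total = sq_dist[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = sq_dist[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    a = groups.size
    ss_between = ss_total - ss_within
    if ss_within <= 1e-12 * max(ss_total, 1.0):
        return math.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    data,
    labels,
    n_perm: int = 9999,
    seed: int | None = None,
    exact_limit: int = 20000,
) -> PermanovaResult:
    """One-factor PERMANOVA on Euclidean distances of (already normalized) data.

    ``p`` uses unrestricted permutations of the rows with the +1 tie
    convention; when the number of distinct orderings (n!) is within
    ``exact_limit`` the full permutation distribution is enumerated instead
    of sampled.
    """
    X = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need >= 2 groups")
    counts = {g: int((labels == g).sum()) for g in groups}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"groups with < 2 members: {small}")
    sq = np.square(X[:, None, :] - X[None, :, :]).sum(axis=2)
    f_obs = _pseudo_f(sq, labels, groups)
    n = labels.size
    degenerate = not np.isfinite(f_obs)

    if math.factorial(n) <= exact_limit:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            f = _pseudo_f(sq, labels[list(perm)], groups)
            count += f >= f_obs
            total += 1
        p = count / total
        return PermanovaResult(
            f_obs, groups.size - 1, n - groups.size, p, total, exact=True, degenerate=degenerate
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f = _pseudo_f(sq, rng.permutation(labels), groups)
        count += f >= f_obs
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(
        f_obs, groups.size - 1, n - groups.size, p, n_perm, degenerate=degenerate
    )


@dataclass
class CapResult:
    m: int
    scores: np.ndarray  # canonical axis-1 score per observation
    allocation_success: dict  # group -> % correctly allocated (leave-one-out)
    overall_success: float
    m_scan: pd.DataFrame = field(repr=False, default=None)


def _pco(X: np.ndarray):
    """Classical principal coordinates of the Euclidean distance matrix."""
    sq = np.square(X[:, None, :] - X[None, :, :]).sum(axis=2)
    n = sq.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ sq @ J
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = w > 1e-9 * max(w.max(), 1.0)
    return v[:, keep] * np.sqrt(w[keep])


def cap(data, labels, m: int | None = None, max_m: int | None = None) -> CapResult:
    """Canonical analysis of principal coordinates with LOO validation.

    PCO axes of the Euclidean distance matrix feed a linear discriminant on
    the first ``m`` axes; ``m`` (when not given) is chosen to maximize the
    leave-one-out allocation success, preferring the smallest ``m`` on ties.
    """
    X = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need >= 2 groups")
    axes = _pco(X)
    n, n_axes = axes.shape
    cap_m = min(n_axes, n - 2)
    if max_m is not None:
        cap_m = min(cap_m, max_m)
    if m is not None and m > n_axes:
        raise ValueError(f"m = {m} exceeds the {n_axes} available PCO axes")
    candidates = [m] if m is not None else list(range(1, cap_m + 1))

    def loo_success(mm: int) -> np.ndarray:
        correct = np.zeros(n, dtype=bool)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            lda = LinearDiscriminantAnalysis()
            lda.fit(axes[mask, :mm], labels[mask])
            correct[i] = lda.predict(axes[[i], :mm])[0] == labels[i]
        return correct

    scan = []
    best = None
    for mm in candidates:
        correct = loo_success(mm)
        overall = correct.mean() * 100.0
        scan.append((mm, overall))
        if best is None or overall > best[1]:
            best = (mm, overall, correct)
    m_best, overall, correct = best
    per_group = {
        str(g): float(correct[labels == g].mean() * 100.0) for g in groups
    }
    lda = LinearDiscriminantAnalysis()
    lda.fit(axes[:, :m_best], labels)
    scores = lda.transform(axes[:, :m_best])[:, 0]
    return CapResult(
        m=m_best,
        scores=scores,
        allocation_success=per_group,
        overall_success=float(overall),
        m_scan=pd.DataFrame(scan, columns=["m", "overall_success"]),
    )


class TrajectoryContrast:
    """Contrast local conditions between positive- and negative-trajectory reefs.

    Parameters
    ----------
    factors : DataFrame
        Reefs × factors table of pre-disturbance driver summaries (raw
        scale; normalization happens inside).
    labels : Series or array
        Trajectory class per reef; only "positive" and "negative" rows
        enter the contrast.
    outlier_k : float
        Median ± k·SD screen applied per factor before the jackknife.
    """

    def __init__(self, factors: pd.DataFrame, labels, outlier_k: float = 2.0):
        self.factors = pd.DataFrame(factors).astype(float)
        self.labels = np.asarray(labels)
        if len(self.labels) != len(self.factors):
            raise ValueError("labels and factors disagree in length")
        self.outlier_k = outlier_k

    def fit(self, n_perm: int = 9999, seed: int | None = None) -> "TrajectoryResults":
        use = np.isin(self.labels, ["positive", "negative"])
        fac = self.factors.loc[use]
        lab = self.labels[use]
        fac = informative_columns(fac)
        keep_cols = fac.columns
        Z = pd.DataFrame(
            zscore(fac.to_numpy()), index=fac.index, columns=keep_cols
        )
        perm = permanova(Z.to_numpy(), lab, n_perm=n_perm, seed=seed)
        cap_res = cap(Z.to_numpy(), lab)
        rows = []
        for col in keep_cols:
            a = fac.loc[lab == "positive", col].to_numpy()
            b = fac.loc[lab == "negative", col].to_numpy()
            try:
                a_f, _ = median_sd_outlier_filter(a, self.outlier_k)
            except ValueError:
                a_f = a
            try:
                b_f, _ = median_sd_outlier_filter(b, self.outlier_k)
            except ValueError:
                b_f = b
            if a_f.size < 2 or b_f.size < 2:
                continue
            d = jackknife_group_difference(a_f, b_f)
            rows.append({"factor": col, **d})
        table = pd.DataFrame(rows).set_index("factor") if rows else pd.DataFrame()
        return TrajectoryResults(self, perm, cap_res, table)


@dataclass
class TrajectoryResults:
    model: TrajectoryContrast
    permanova: PermanovaResult
    cap: CapResult
    jackknife_table: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "Pre-disturbance trajectory contrast (positive vs negative reefs)",
            "-" * 64,
            str(self.permanova),
            (
                f"CAP: m = {self.cap.m} PCO axes, leave-one-out allocation success "
                + ", ".join(f"{g}: {s:.1f}%" for g, s in self.cap.allocation_success.items())
            ),
            "",
            "Drop-one jackknife differences (positive - negative):",
            self.jackknife_table.to_string(float_format=lambda v: f"{v: .3f}"),
        ]
        return "\n".join(lines)
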