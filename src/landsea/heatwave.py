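"""Heatwave-response stage: what modified coral loss during the event.

The response is the percentage difference in coral cover across the
heatwave, Δ = (A_a − A_b)/A_b × 100, where A_b is the pre-event mean cover
and A_a the cover one year after.  Predictors pass through an outlier
screen with a retention rule, named root transforms, z-standardization and
a correlation prune (|r| > 0.7 drops one of each pair, honouring
hypothesis-driven keep preferences).  Reefs are grouped into ~10-km coast
sections by hierarchical clustering (random intercept in the model), and
all predictor subsets up to five terms are fitted as penalized-spline
additive mixed models, ranked by AICc, and summarised by Akaike weights,
relative importance, and weighted model-averaged prediction curves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from ._util import informative_columns, zscore
from .modelselect import ModelSet, dredge
from .smooth import AdditiveModelFit, fit_additive_model

__all__ = [
    "percentage_difference",
    "outlier_filter_with_retention",
    "transform_predictors",
    "prune_correlated",
    "coast_sections",
    "HeatwaveAdditiveModel",
]


def percentage_difference(cover_before: float, cover_after: float) -> float:
    """Percent change in cover relative to the pre-event baseline."""
    if cover_before <= 0:
        raise ValueError("pre-event cover must be positive (reef excluded)")
    return (cover_after - cover_before) / cover_before * 100.0


def outlier_filter_with_retention(values, k: float = 2.0, retention: float = 0.25):
    """Median ± k·SD outlier screen with a near-threshold retention rule.

    A value flagged above the high threshold is kept if it is within
    ``retention`` (fractional) of the maximum unflagged value; symmetric on
    the low side.  Returns ``(keep_mask, removed_indices)`` so callers can
    drop whole rows when any predictor flags a reef.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 values to screen outliers")
    med = np.median(x)
    sd = x.std(ddof=1)
    lo, hi = med - k * sd, med + k * sd
    flagged = (x < lo) | (x > hi)
    keep = ~flagged
    if keep.any():
        max_in = x[keep].max()
        min_in = x[keep].min()
        for i in np.flatnonzero(flagged):
            if x[i] > hi and x[i] <= max_in * (1.0 + retention) and max_in > 0:
                keep[i] = True
            elif x[i] < lo:
                bound = min_in * (1.0 - retention) if min_in > 0 else min_in * (1.0 + retention)
                if x[i] >= bound:
                    keep[i] = True
    if not keep.any():
        raise ValueError("outlier screen removed every value")
    return keep, np.flatnonzero(~keep)


def transform_predictors(
    table: pd.DataFrame,
    sqrt: list[str] | None = None,
    fourth_root: list[str] | None = None,
    standardize: bool = True,
):
    """Apply named root transforms then z-standardization.

    Root transforms down-weight the right tail of skewed load distributions.
    Returns ``(transformed table, log)`` where the log records each applied
    transform and the standardization statistics needed to map raw scenario
    lever values later.
    """
    out = table.copy().astype(float)
    log = []
    for name, power, cols in (("sqrt", 0.5, sqrt or []), ("fourth_root", 0.25, fourth_root or [])):
        for col in cols:
            if col not in out.columns:
                raise ValueError(f"unknown predictor for {name} transform: {col}")
            if (out[col] < 0).any():
                bad = out.index[out[col] < 0][0]
                raise ValueError(f"negative value under {name} transform: {col} at {bad}")
            out[col] = out[col] ** power
            log.append({"predictor": col, "action": name})
    if standardize:
        for col in out.columns:
            mu, sd = out[col].mean(), out[col].std(ddof=1)
            if sd == 0:
                raise ValueError(f"zero-variance predictor cannot be standardized: {col}")
            out[col] = (out[col] - mu) / sd
            log.append({"predictor": col, "action": "zscore", "mean": mu, "sd": sd})
    return out, log


def prune_correlated(
    table: pd.DataFrame, threshold: float = 0.7, keep: list[str] | None = None
):
    """Drop one of each pair of predictors with |Pearson r| > threshold.

    ``keep`` lists hypothesis-preferred predictors that must survive; for a
    correlated pair the non-preferred member is dropped, otherwise the one
    with the larger mean absolute correlation to everything else goes.
    Returns ``(pruned table, removal log)``.
    """
    keep = list(keep or [])
    cols = list(table.columns)
    corr = table.corr().abs()
    removed = []
    while True:
        sub = corr.loc[cols, cols].copy()
        np.fill_diagonal(sub.values, 0.0)
        if sub.values.max() <= threshold:
            break
        i, j = np.unravel_index(np.argmax(sub.values), sub.shape)
        a, b = cols[i], cols[j]
        if a in keep and b in keep:
            raise ValueError(f"keep preferences conflict: {a} and {b} correlate at r > {threshold}")
        if a in keep:
            drop = b
        elif b in keep:
            drop = a
        else:
            drop = a if sub.loc[a].mean() >= sub.loc[b].mean() else b
        other = b if drop == a else a
        removed.append({"predictor": drop, "reason": f"|r|>{threshold} with {other}"})
        cols.remove(drop)
    return table[cols], removed


def coast_sections(positions_m, target_km: float = 10.0) -> np.ndarray:
    """Group reefs into contiguous alongshore sections of ~``target_km``.

    Average-linkage hierarchical clustering on pairwise alongshore
    distances; the number of groups is the inflection (maximum curvature)
    of intragroup variance versus group count, constrained so the mean
    section span stays near the target, with the earliest inflection on
    ties.  A single reef forms a single section.
    """
    x = np.asarray(positions_m, dtype=float)
    if x.size == 0:
        raise ValueError("no reef positions")
    if x.size == 1:
        return np.zeros(1, dtype=int)
    lk = linkage(x.reshape(-1, 1), method="average")
    span = x.max() - x.min()
    g_max = min(x.size, max(2, int(np.ceil(span / (target_km * 1000.0))) + 2))
    gs = np.arange(1, g_max + 1)
    wvar = []
    assignments = {}
    for g in gs:
        lab = fcluster(lk, t=g, criterion="maxclust")
        assignments[g] = lab
        w = 0.0
        for lev in np.unique(lab):
            xs = x[lab == lev]
            if xs.size > 1:
                w += np.sum((xs - xs.mean()) ** 2)
        wvar.append(w)
    wvar = np.asarray(wvar)
    if gs.size <= 2:
        g_best = gs[-1]
    else:
        curv = wvar[:-2] - 2 * wvar[1:-1] + wvar[2:]  # curvature at gs[1:-1]
        order = np.argsort(-curv, kind="stable")
        g_best = None
        for idx in order:
            g = gs[idx + 1]
            lab = assignments[g]
            spans = [np.ptp(x[lab == lev]) for lev in np.unique(lab)]
            if np.mean(spans) <= 1.5 * target_km * 1000.0:
                g_best = g
                break
        if g_best is None:
            g_best = gs[-1]
    lab = assignments[g_best]
    # relabel contiguously north to south
    order = {lev: rank for rank, lev in enumerate(pd.unique(lab[np.argsort(x)]))}
    return np.array([order[v] for v in lab], dtype=int)


class HeatwaveAdditiveModel:
    """Additive mixed model of heatwave coral response vs local drivers.

    Parameters
    ----------
    response : Series
        Percentage-difference Δ per reef.
    predictors : DataFrame
        Analysis-ready standardized predictor table (reefs × predictors).
    sections : array, optional
        Coast-section id per reef (random intercept); omit for none.
    n_knots : int
        Knots per penalized cubic regression spline (max 4).
    """

    def __init__(self, response, predictors, sections=None, n_knots: int = 4, smooth: bool = True):
        self.response = np.asarray(response, dtype=float)
        self.predictors = pd.DataFrame(predictors).astype(float)
        if len(self.response) != len(self.predictors):
            raise ValueError("response and predictor table disagree in length")
        self.sections = None if sections is None else np.asarray(sections)
        self.n_knots = min(int(n_knots), 4)
        self.smooth = smooth

    @classmethod
    def from_raw(
        cls,
        response,
        raw_predictors: pd.DataFrame,
        positions_m=None,
        sqrt=None,
        fourth_root=None,
        prune_threshold: float = 0.7,
        keep=None,
        exclude=("population", "browser_biomass"),
        outlier_k: float = 2.0,
        retention: float = 0.25,
        **kwargs,
    ):
        """Full predictor-preparation pipeline from raw driver summaries.

        Applies the a-priori exclusions, the outlier screen with retention
        (dropping flagged reefs), the named root transforms with
        standardization, the correlation prune, and coast sectioning.
        The preparation log is stored as ``prep_log``.
        """
        raw = raw_predictors.drop(columns=[c for c in exclude if c in raw_predictors], errors="ignore")
        raw = informative_columns(raw)
        log = [{"predictor": c, "action": "a-priori exclusion"} for c in exclude if c in raw_predictors]
        keep_rows = np.ones(len(raw), dtype=bool)
        for col in raw.columns:
            mask, removed = outlier_filter_with_retention(raw[col].to_numpy(), outlier_k, retention)
            for i in removed:
                log.append({"predictor": col, "action": "outlier removed", "reef": raw.index[i]})
            keep_rows &= mask
        raw = raw.loc[keep_rows]
        response = np.asarray(response, dtype=float)[keep_rows]
        table, tlog = transform_predictors(
            raw,
            sqrt=[c for c in (sqrt or []) if c in raw],
            fourth_root=[c for c in (fourth_root or []) if c in raw],
        )
        log += tlog
        table, plog = prune_correlated(table, prune_threshold, keep=keep)
        log += plog
        sections = None
        if positions_m is not None:
            sections = coast_sections(np.asarray(positions_m, dtype=float)[keep_rows])
        model = cls(response, table, sections=sections, **kwargs)
        model.prep_log = log
        return model

    def fit(self, subset=None) -> AdditiveModelFit:
        """Fit one candidate (default: all predictors, capped at 5)."""
        subset = tuple(subset) if subset is not None else tuple(self.predictors.columns[:5])
        if len(subset) > 5:
            raise ValueError("candidate models are limited to five predictors")
        cov = {name: self.predictors[name].to_numpy() for name in subset}
        return fit_additive_model(
            self.response, cov, sections=self.sections, n_knots=self.n_knots, smooth=self.smooth
        )

    def dredge(self, max_predictors: int = 5) -> ModelSet:
        """Fit all predictor subsets of size 0..max and rank by AICc."""
        return dredge(tuple(self.predictors.columns), self.fit, max_predictors)

    def average_prediction(
        self,
        model_set: ModelSet,
        focal: str,
        grid=None,
        level: float = 0.80,
        weighted: bool = True,
    ) -> pd.DataFrame:
        """Akaike-weighted model-averaged curve for one focal predictor.

        Each ΔAICc <= 2 model containing the focal term predicts over the
        grid with other predictors at their medians; predictions combine by
        Akaike weights (or unweighted mean), and the pointwise interval uses
        the combined (within + between model) variance.
        """
        from scipy.stats import norm

        top = model_set.top_table
        members = [s for s in top.index if focal in s]
        if not members:
            raise ValueError(f"focal predictor {focal} is in no top model")
        if grid is None:
            x = self.predictors[focal].to_numpy()
            grid = np.linspace(x.min(), x.max(), 50)
        grid = np.asarray(grid, dtype=float)
        w = top.loc[members, "weight"].to_numpy()
        w = w / w.sum() if weighted else np.full(len(members), 1.0 / len(members))
        means = np.zeros((len(members), grid.size))
        ses = np.zeros_like(means)
        for i, s in enumerate(members):
            means[i], ses[i] = model_set.fits[s].predict(focal, grid)
        avg = w @ means
        # model-averaged variance: weighted within-model + between-model spread
        var = w @ (ses**2 + (means - avg) ** 2)
        zcrit = norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {
                "grid": grid,
                "prediction": avg,
                "se": np.sqrt(var),
                "lower": avg - zcrit * np.sqrt(var),
                "upper": avg + zcrit * np.sqrt(var),
            }
        )
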