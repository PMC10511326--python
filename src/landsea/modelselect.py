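"""All-subsets candidate enumeration with AICc multimodel inference.

Given a fitting backend (additive model or ordinal regression), `dredge`
fits every predictor subset up to a size cap, ranks candidates by AICc,
computes ΔAICc and Akaike weights, extracts the ΔAICc <= 2 top set, and
sums weights per predictor to give relative importance.  Unfittable
candidates are skipped and logged rather than aborting the enumeration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["n_candidates", "dredge", "ModelSet"]


def n_candidates(p: int, max_k: int) -> int:
    """Number of predictor subsets of size 0..max_k out of p."""
    return sum(math.comb(p, k) for k in range(min(p, max_k) + 1))


@dataclass
class ModelSet:
    """Ranked candidate models with AICc weights and relative importance."""

    table: pd.DataFrame  # one row per fitted candidate, AICc-sorted
    fits: dict = field(repr=False)  # subset tuple -> backend fit object
    predictors: tuple
    max_predictors: int
    skipped: list = field(default_factory=list)

    @property
    def best(self):
        return self.fits[self.table.index[0]]

    @property
    def top_table(self) -> pd.DataFrame:
        return self.table[self.table["delta_aicc"] <= 2.0]

    @property
    def top_fits(self) -> list:
        return [self.fits[s] for s in self.top_table.index]

    def relative_importance(self) -> pd.Series:
        """Sum of Akaike weights over all models containing each predictor."""
        imp = {}
        for name in self.predictors:
            mask = [name in subset for subset in self.table.index]
            imp[name] = float(self.table.loc[mask, "weight"].sum())
        return pd.Series(imp, name="relative_importance").sort_values(ascending=False)

    def summary(self, top_only: bool = True) -> str:
        tab = self.top_table if top_only else self.table
        show = tab.copy()
        show.index = [" + ".join(s) if s else "(null)" for s in show.index]
        lines = [
            f"Candidate set: {len(self.table)} models "
            f"({len(self.predictors)} predictors, max {self.max_predictors} per model, "
            f"{len(self.skipped)} skipped)",
            show.to_string(float_format=lambda v: f"{v:.3f}"),
            "",
            "Relative importance (sum of Akaike weights):",
            self.relative_importance().to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


def dredge(
    predictors: Sequence[str],
    fit_fn: Callable[[tuple], object],
    max_predictors: int,
    extra_columns: Callable[[object], dict] | None = None,
) -> ModelSet:
    """Fit all predictor subsets of size 0..max_predictors and rank by AICc.

    ``fit_fn(subset)`` must return an object with ``aicc``, ``loglik`` and
    ``edf`` (or ``k``) attributes; candidates raising ``ValueError`` or
    failing to converge are recorded in ``skipped``.
    """
    predictors = tuple(predictors)
    rows = []
    fits = {}
    skipped = []
    for k in range(min(len(predictors), max_predictors) + 1):
        for subset in itertools.combinations(predictors, k):
            try:
                fit = fit_fn(subset)
            except ValueError as err:
                skipped.append((subset, str(err)))
                continue
            kval = float(fit.edf) + 1.0 if hasattr(fit, "edf") else float(fit.k)
            row = {
                "n_predictors": k,
                "loglik": float(fit.loglik),
                "k": kval,
                "aicc": float(fit.aicc),
            }
            if extra_columns is not None:
                row.update(extra_columns(fit))
            rows.append((subset, row))
            fits[subset] = fit
    if not rows:
        raise ValueError("no candidate model could be fitted")
    idx = np.empty(len(rows), dtype=object)
    idx[:] = [s for s, _ in rows]  # keep subsets as tuple-valued scalars
    table = pd.DataFrame([r for _, r in rows], index=pd.Index(idx))
    table = table.sort_values("aicc")
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    rel = np.exp(-0.5 * table["delta_aicc"])
    table["weight"] = rel / rel.sum()
    return ModelSet(
        table=table,
        fits=fits,
        predictors=predictors,
        max_predictors=max_predictors,
        skipped=skipped,
    )
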