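"""Post-disturbance persistence stage: proportional-odds ordinal regression.

Reef-builder cover (hard coral + crustose coralline algae) is parsed into
low / moderate / high categories at the 25th and 75th percentiles and
modelled with a cumulative-logit proportional-odds regression fitted by
maximum likelihood:

    logit P(y_i <= j) = C_j - (B_1 z_i1 + ... + B_k z_ik)

with categories ordered low < moderate < high internally, so a positive
B_k means the predictor favours *better* reef-builder outcomes.  (The
equivalent high-first indexing, where the same coefficients appear with
logit P(y <= j) = C_j + B z for j = 1 meaning high, is available through
``category_probabilities(..., high_first=True)`` and verified equivalent.)

The stage includes Brant's Wald test and a likelihood-ratio test of the
parallel-regression assumption, McFadden's pseudo-R², an AICc dredge
capped at four predictors per candidate, and the management scenario
engine that converts raw lever settings (scraper biomass, wastewater) into
category probabilities and fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from ._util import percentile_of, quantile
from .modelselect import ModelSet, dredge

__all__ = [
    "categorize_cover",
    "ProportionalOdds",
    "ProportionalOddsResults",
    "brant_test",
    "lr_test",
    "mcfadden_r2",
    "dredge_ordinal",
    "ScenarioSpec",
    "ScenarioResult",
    "scenario_probabilities",
    "percentile_of",
    "CATEGORIES",
]

CATEGORIES = ("low", "moderate", "high")


def categorize_cover(cover, thresholds: tuple[float, float] | None = None) -> pd.DataFrame:
    """Assign low / moderate / high categories at the 25th/75th percentiles.

    low: value <= q25; high: value >= q75; moderate otherwise.  Explicit
    ``thresholds`` override the percentile rule (required when the spread
    is degenerate).
    """
    x = np.asarray(cover, dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 cover values to set percentile thresholds")
    if thresholds is None:
        q25, q75 = quantile(x, 0.25), quantile(x, 0.75)
        if q25 == q75:
            raise ValueError(
                "25th and 75th percentiles coincide; supply explicit thresholds"
            )
    else:
        q25, q75 = thresholds
    cat = np.where(x <= q25, "low", np.where(x >= q75, "high", "moderate"))
    return pd.DataFrame({"cover": x, "category": cat}), (float(q25), float(q75))


def _encode(categories) -> np.ndarray:
    cats = np.asarray(categories)
    lut = {c: i for i, c in enumerate(CATEGORIES)}
    try:
        return np.array([lut[c] for c in cats], dtype=int)
    except KeyError as err:
        raise ValueError(f"unknown category {err}") from err


class ProportionalOdds:
    """Cumulative-logit proportional-odds model (statsmodels-style).

    Parameters
    ----------
    endog : sequence of {"low","moderate","high"} or integer codes 0..J-1
    exog : DataFrame or array of standardized predictors (no intercept)
    """

    def __init__(self, endog, exog=None):
        if exog is None:
            exog = np.empty((len(endog), 0))
        self.exog = pd.DataFrame(exog).astype(float)
        y = np.asarray(endog)
        if y.dtype.kind in "iu":
            self.y = y.astype(int)
            self.n_cat = int(self.y.max()) + 1
            self.category_labels = tuple(range(self.n_cat))
        else:
            self.y = _encode(y)
            self.n_cat = 3
            self.category_labels = CATEGORIES
        if self.y.min() < 0:
            raise ValueError("category codes must be non-negative")
        counts = np.bincount(self.y, minlength=self.n_cat)
        if (counts == 0).any():
            empty = [self.category_labels[i] for i in np.flatnonzero(counts == 0)]
            raise ValueError(f"empty outcome categories: {empty}")
        if self.n_cat < 2:
            raise ValueError("need >= 2 outcome categories")
        self.n = self.y.size
        self.k = self.exog.shape[1]

    # --- parameterization: theta = (c1, g2.., B) with C_j = c1 + sum exp(g) ---
    def _cuts(self, theta):
        c = np.empty(self.n_cat - 1)
        c[0] = theta[0]
        for j in range(1, self.n_cat - 1):
            c[j] = c[j - 1] + np.exp(theta[j])
        return c

    def _unpack(self, theta):
        return self._cuts(theta), theta[self.n_cat - 1 :]

    def loglike(self, cuts, beta) -> float:
        eta = self.exog.to_numpy() @ beta if self.k else np.zeros(self.n)
        padded = np.concatenate([[-np.inf], cuts, [np.inf]])
        hi = padded[self.y + 1] - eta
        lo = padded[self.y] - eta
        # log(F(hi) - F(lo)) computed stably
        p = expit(hi) - expit(lo)
        p = np.clip(p, 1e-300, None)
        return float(np.log(p).sum())

    def _nll_grad(self, theta):
        cuts, beta = self._unpack(theta)
        eta = self.exog.to_numpy() @ beta if self.k else np.zeros(self.n)
        padded = np.concatenate([[-np.inf], cuts, [np.inf]])
        hi = padded[self.y + 1] - eta
        lo = padded[self.y] - eta
        Fhi, Flo = expit(hi), expit(lo)
        p = np.clip(Fhi - Flo, 1e-12, None)
        fhi = Fhi * (1 - Fhi)
        flo = Flo * (1 - Flo)
        nll = -float(np.log(p).sum())
        # d nll / d C_j: obs with upper cut j get -fhi/p, lower cut j get +flo/p
        dC = np.zeros(self.n_cat - 1)
        whi = -fhi / p
        wlo = flo / p
        for j in range(self.n_cat - 1):
            dC[j] = whi[self.y == j].sum() + wlo[self.y == j + 1].sum()
        # chain rule to (c1, g2..): C_j depends on c1 and g_2..g_j
        dtheta = np.zeros_like(theta)
        dtheta[0] = dC.sum()
        for j in range(1, self.n_cat - 1):
            dtheta[j] = dC[j:].sum() * np.exp(theta[j])
        if self.k:
            deta = (fhi - flo) / p  # d nll / d eta (eta enters the cuts as C - eta)
            dtheta[self.n_cat - 1 :] = self.exog.to_numpy().T @ deta
        return nll, dtheta

    def fit(self, tol: float = 1e-10, maxiter: int = 500) -> "ProportionalOddsResults":
        """Maximize the likelihood; quasi-Newton with ordered-cut reparam."""
        counts = np.bincount(self.y, minlength=self.n_cat)
        cum = np.cumsum(counts)[:-1] / self.n
        cuts0 = np.log(cum / (1 - cum))
        theta0 = np.concatenate(
            [[cuts0[0]], np.log(np.clip(np.diff(cuts0), 1e-3, None)), np.zeros(self.k)]
        )
        res = optimize.minimize(
            self._nll_grad,
            theta0,
            jac=True,
            method="BFGS",
            options={"gtol": tol ** 0.5, "maxiter": maxiter},
        )
        grad_norm = float(np.max(np.abs(res.jac)))
        if not res.success and grad_norm > 1e-3:
            raise ValueError(
                f"ordinal MLE did not converge (|grad|={grad_norm:.2g}); "
                "possible complete separation"
            )
        cuts, beta = self._unpack(res.x)
        # observed information on the natural (C, B) scale via numeric Hessian
        params = np.concatenate([cuts, beta])

        def nll_natural(q):
            c = q[: self.n_cat - 1]
            if np.any(np.diff(c) <= 0):
                return np.inf
            return -self.loglike(c, q[self.n_cat - 1 :])

        H = _numeric_hessian(nll_natural, params)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.full((params.size, params.size), np.nan)
        return ProportionalOddsResults(
            model=self,
            cuts=cuts,
            params=pd.Series(beta, index=self.exog.columns, name="coef"),
            cov=cov,
            loglik=-float(res.fun),
            converged=bool(res.success or grad_norm <= 1e-3),
            n_iter=int(res.nit),
        )


def _numeric_hessian(f, x, eps: float = 1e-5):
    n = x.size
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei) - f(x + ej) + f0
            ) / eps**2
    return H


@dataclass
class ProportionalOddsResults:
    model: ProportionalOdds
    cuts: np.ndarray  # C_j, strictly increasing
    params: pd.Series  # B_k
    cov: np.ndarray = field(repr=False)
    loglik: float = np.nan
    converged: bool = True
    n_iter: int = 0

    @property
    def k(self) -> int:
        """Parameter count (cut points + coefficients) for AICc."""
        return self.cuts.size + self.params.size

    @property
    def aicc(self) -> float:
        n, k = self.model.n, self.k
        return -2 * self.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    @property
    def bse(self) -> pd.Series:
        se = np.sqrt(np.diag(self.cov))[self.cuts.size :]
        return pd.Series(se, index=self.params.index, name="se")

    def wald(self) -> pd.DataFrame:
        z = self.params / self.bse
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({"coef": self.params, "se": self.bse, "z": z, "p": p})

    def predict_proba(self, exog=None) -> np.ndarray:
        """Category probabilities per observation (columns low..high)."""
        if exog is None:
            exog = self.model.exog
        Z = np.asarray(pd.DataFrame(exog), dtype=float)
        eta = Z @ self.params.to_numpy() if self.params.size else np.zeros(len(Z))
        return category_probabilities(self.cuts, eta)

    def summary(self) -> str:
        lines = [
            "Proportional-odds (cumulative logit) regression",
            "-" * 56,
            f"n = {self.model.n}, categories = {self.model.category_labels}",
            f"log-likelihood = {self.loglik:.4f}, AICc = {self.aicc:.3f}",
            "cut points: " + ", ".join(f"C{j+1} = {c:.4f}" for j, c in enumerate(self.cuts)),
        ]
        if self.params.size:
            lines += ["", self.wald().to_string(float_format=lambda v: f"{v: .4f}")]
        return "\n".join(lines)


def category_probabilities(cuts, eta, high_first: bool = False) -> np.ndarray:
    """Map linear predictor values to category probabilities.

    Internal convention: logit P(y <= j) = C_j - eta with categories ordered
    low < moderate < high.  ``high_first=True`` instead evaluates the
    equivalent published indexing logit P(y* <= j) = C*_j + eta where j = 1
    is "high" (C*_j = -C_{J-1-j} reversed); both give identical
    probabilities, which the test-suite verifies.
    """
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    cuts = np.asarray(cuts, dtype=float)
    if high_first:
        star = -cuts[::-1]
        cum = expit(star[None, :] + eta[:, None])  # P(y* <= j), high first
        full = np.hstack([cum, np.ones((eta.size, 1))])
        probs_star = np.diff(np.hstack([np.zeros((eta.size, 1)), full]), axis=1)
        return probs_star[:, ::-1]  # reorder to low..high
    cum = expit(cuts[None, :] - eta[:, None])  # P(y <= j), low first
    full = np.hstack([cum, np.ones((eta.size, 1))])
    return np.diff(np.hstack([np.zeros((eta.size, 1)), full]), axis=1)


def brant_test(results: ProportionalOddsResults) -> pd.DataFrame:
    """Brant's Wald test of the parallel-regression assumption.

    Fits the J-1 cumulative binary logits separately, assembles the
    between-model covariance of the slope estimates (Brant 1990), and tests
    equality of each predictor's coefficients across cut points plus the
    omnibus hypothesis; chi-squared reference.
    """
    import statsmodels.api as sm

    model = results.model
    if model.n_cat < 3:
        raise ValueError("Brant test needs >= 3 outcome categories")
    if model.k == 0:
        return pd.DataFrame(
            [{"term": "omnibus", "statistic": np.nan, "df": 0, "p": np.nan,
              "note": "not applicable for an intercept-only model"}]
        ).set_index("term")
    X = np.column_stack([np.ones(model.n), model.exog.to_numpy()])
    J1 = model.n_cat - 1
    p = model.k
    betas = []
    pis = []
    for j in range(J1):
        z = (model.y > j).astype(float)
        try:
            with np.errstate(over="ignore", divide="ignore"):
                fit = sm.Logit(z, X).fit(disp=0, maxiter=200)
        except Exception as err:
            raise ValueError(f"separation in binary sub-model for cut {j + 1}") from err
        if not fit.mle_retvals.get("converged", True):
            raise ValueError(f"separation in binary sub-model for cut {j + 1}")
        betas.append(fit.params)
        pis.append(fit.predict(X))
    # Brant's global covariance of the stacked slope estimates
    V = np.zeros((J1 * p, J1 * p))
    XtWX_inv = []
    for j in range(J1):
        w = pis[j] * (1 - pis[j])
        XtWX_inv.append(np.linalg.inv(X.T @ (X * w[:, None])))
    for j in range(J1):
        for l in range(j, J1):
            wjl = pis[l] - pis[j] * pis[l]
            M = XtWX_inv[j] @ (X.T @ (X * wjl[:, None])) @ XtWX_inv[l]
            block = M[1:, 1:]
            V[j * p : (j + 1) * p, l * p : (l + 1) * p] = block
            V[l * p : (l + 1) * p, j * p : (j + 1) * p] = block.T
    beta_stack = np.concatenate([b[1:] for b in betas])
    # contrast: differences between consecutive cut-point coefficient vectors
    D = np.zeros(((J1 - 1) * p, J1 * p))
    for j in range(J1 - 1):
        D[j * p : (j + 1) * p, j * p : (j + 1) * p] = np.eye(p)
        D[j * p : (j + 1) * p, (j + 1) * p : (j + 2) * p] = -np.eye(p)
    rows = []
    d = D @ beta_stack
    Vd = D @ V @ D.T
    stat = float(d @ np.linalg.solve(Vd, d))
    df = (J1 - 1) * p
    rows.append({"term": "omnibus", "statistic": stat, "df": df,
                 "p": float(stats.chi2.sf(stat, df)), "note": ""})
    for v_idx, name in enumerate(model.exog.columns):
        sel = [j * p + v_idx for j in range(J1)]
        Dv = np.zeros((J1 - 1, J1 * p))
        for j in range(J1 - 1):
            Dv[j, sel[j]] = 1.0
            Dv[j, sel[j + 1]] = -1.0
        dv = Dv @ beta_stack
        Vv = Dv @ V @ Dv.T
        sv = float(dv @ np.linalg.solve(Vv, dv))
        rows.append({"term": str(name), "statistic": sv, "df": J1 - 1,
                     "p": float(stats.chi2.sf(sv, J1 - 1)), "note": ""})
    return pd.DataFrame(rows).set_index("term")


def lr_test(nested: ProportionalOddsResults, full: ProportionalOddsResults, alpha: float = 0.05):
    """Likelihood-ratio test of nested proportional-odds models."""
    if nested.model.n != full.model.n:
        raise ValueError("models were fitted to different data")
    nested_terms = set(nested.params.index)
    full_terms = set(full.params.index)
    if not nested_terms <= full_terms:
        raise ValueError("models are not nested")
    df = full.k - nested.k
    stat = max(2.0 * (full.loglik - nested.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return {"statistic": stat, "df": df, "p": p, "reject": p < alpha}


def mcfadden_r2(full: ProportionalOddsResults, null: ProportionalOddsResults) -> float:
    """McFadden's pseudo-R² = 1 - l_full / l_null."""
    if full.model.n != null.model.n:
        raise ValueError("fits use different data")
    if null.loglik == 0:
        raise ValueError("null log-likelihood is zero")
    return 1.0 - full.loglik / null.loglik


def dredge_ordinal(endog, predictor_table: pd.DataFrame, max_predictors: int = 4) -> ModelSet:
    """All-subsets proportional-odds dredge (<= 4 predictors per candidate)."""
    table = pd.DataFrame(predictor_table).astype(float)
    null_ll = ProportionalOdds(endog).fit().loglik

    def fit_fn(subset):
        return ProportionalOdds(endog, table[list(subset)]).fit()

    def extras(fit):
        r2 = 1.0 - fit.loglik / null_ll if null_ll != 0 else np.nan
        return {"mcfadden_r2": r2}

    return dredge(tuple(table.columns), fit_fn, max_predictors, extra_columns=extras)


@dataclass
class ScenarioSpec:
    """Raw-scale management lever settings; non-levers sit at their mean."""

    levers: dict  # predictor name -> raw value (e.g. kg ha^-1, l ha^-1)
    name: str = ""


@dataclass
class ScenarioResult:
    name: str
    probabilities: dict  # category -> probability

    def fold_change(self, other: "ScenarioResult", category: str = "high") -> float:
        """P(category) under this scenario relative to ``other``."""
        return self.probabilities[category] / other.probabilities[category]


def scenario_probabilities(
    results: ProportionalOddsResults,
    spec: ScenarioSpec,
    standardization: dict | None = None,
) -> ScenarioResult:
    """Category probabilities under a management-lever scenario.

    ``standardization`` maps predictor name -> dict with the recorded
    transform chain (``transform`` in {None, "sqrt", "fourth_root"},
    ``mean``, ``sd`` on the transformed scale).  Lever raw values pass
    through that chain; predictors without a lever sit at their sample mean
    (standardized 0).
    """
    standardization = standardization or {}
    z = pd.Series(0.0, index=results.params.index)
    for name, raw in spec.levers.items():
        if name not in z.index:
            raise ValueError(f"lever {name} is not a predictor of the fitted model")
        rec = standardization.get(name, {})
        v = float(raw)
        tf = rec.get("transform")
        if tf in ("sqrt", "fourth_root"):
            if v < 0:
                raise ValueError(f"lever {name} outside the {tf} transform domain: {v}")
            v = v**0.5 if tf == "sqrt" else v**0.25
        elif tf not in (None, "identity"):
            raise ValueError(f"unknown transform {tf!r} recorded for {name}")
        mu, sd = rec.get("mean", 0.0), rec.get("sd", 1.0)
        if sd <= 0:
            raise ValueError(f"non-positive standardization SD for {name}")
        z[name] = (v - mu) / sd
    probs = results.predict_proba(z.to_frame().T)[0]
    labels = results.model.category_labels
    return ScenarioResult(spec.name, {str(c): float(p) for c, p in zip(labels, probs)})
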