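"""Penalized cubic regression splines and a Gaussian additive mixed fitter.

The smooth basis is the cubic regression spline of Wood (2006, §4.1.2):
the spline is parameterized by its values at a small set of knots (here
<= 4, spread evenly over the covariate's observed range) and the wiggliness
penalty is the integrated squared second derivative, which has the closed
form S = D' B^-1 D in the knot values.  Each smooth carries a sum-to-zero
constraint (absorbed by reparameterization) so it is identifiable next to
the global intercept; its penalty null space is then the linear trend, so
an infinitely penalized smooth collapses to a straight line.

The model is

    y_i = alpha + sum_j f_j(x_ij) + b_{section(i)} + e_i,

with the section random intercept represented as a ridge-penalized dummy
block (the standard mixed-model identity) and all smoothing/variance
parameters chosen by maximizing the exact Gaussian restricted likelihood
(REML).  Effective degrees of freedom are tr{(X'X + S)^-1 X'X}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = ["cr_spline", "AdditiveModelFit", "fit_additive_model", "aicc"]


def cr_spline(knots: np.ndarray):
    """Return the evaluation closure and penalty of a cubic regression spline.

    ``knots`` must be strictly increasing.  The returned ``evaluate(x)``
    maps covariate values to the basis whose coefficients are the spline's
    values at the knots (linear extrapolation outside the knot range);
    ``penalty`` is the integrated squared second-derivative matrix.
    """
    xk = np.asarray(knots, dtype=float)
    K = xk.size
    if K < 3:
        raise ValueError("need >= 3 knots for a cubic regression spline")
    if np.any(np.diff(xk) <= 0):
        raise ValueError("knots must be strictly increasing")
    h = np.diff(xk)
    D = np.zeros((K - 2, K))
    B = np.zeros((K - 2, K - 2))
    for i in range(K - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < K - 3:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    F = linalg.solve(B, D, assume_a="pos")  # second derivatives at interior knots
    S = D.T @ F  # integrated squared second derivative

    def evaluate(x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros((x.size, K))
        # second-derivative map padded with natural boundary conditions
        Ffull = np.vstack([np.zeros(K), F, np.zeros(K)])
        j = np.clip(np.searchsorted(xk, x, side="right") - 1, 0, K - 2)
        inside = (x >= xk[0]) & (x <= xk[-1])
        for idx in range(x.size):
            if inside[idx]:
                jj = j[idx]
                hj = h[jj]
                xl, xr = xk[jj], xk[jj + 1]
                am, ap = (xr - x[idx]) / hj, (x[idx] - xl) / hj
                cm = ((xr - x[idx]) ** 3 / hj - hj * (xr - x[idx])) / 6.0
                cp = ((x[idx] - xl) ** 3 / hj - hj * (x[idx] - xl)) / 6.0
                row = np.zeros(K)
                row[jj] += am
                row[jj + 1] += ap
                row += cm * Ffull[jj] + cp * Ffull[jj + 1]
                out[idx] = row
            else:  # linear extrapolation from the boundary value and slope
                if x[idx] < xk[0]:
                    x0, jj, hj = xk[0], 0, h[0]
                    val = np.zeros(K)
                    val[0] = 1.0
                    slope = np.zeros(K)
                    slope[0] -= 1.0 / hj
                    slope[1] += 1.0 / hj
                    slope += -hj / 3.0 * Ffull[0] - hj / 6.0 * Ffull[1]
                else:
                    x0, jj, hj = xk[-1], K - 2, h[-1]
                    val = np.zeros(K)
                    val[-1] = 1.0
                    slope = np.zeros(K)
                    slope[-2] -= 1.0 / hj
                    slope[-1] += 1.0 / hj
                    slope += hj / 6.0 * Ffull[K - 2] + hj / 3.0 * Ffull[K - 1]
                out[idx] = val + (x[idx] - x0) * slope
        return out

    return evaluate, S


def _constrained_smooth(x: np.ndarray, n_knots: int):
    """Sum-to-zero constrained smooth block for one covariate.

    Returns (design block, penalty block, evaluate_new(x) -> block rows,
    penalty rank).  The constraint sum_i f(x_i) = 0 is absorbed with a QR
    reparameterization so the block is identifiable next to an intercept.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("zero-variance covariate cannot carry a smooth")
    knots = np.linspace(lo, hi, n_knots)
    evaluate, S = cr_spline(knots)
    Xb = evaluate(x)
    c = Xb.sum(axis=0)  # constraint vector: c' beta = 0
    q, _ = np.linalg.qr(np.column_stack([c / np.linalg.norm(c)]), mode="complete")
    Z = q[:, 1:]  # basis of the constraint null space
    Sz = Z.T @ S @ Z

    def evaluate_new(xnew):
        return evaluate(xnew) @ Z

    return Xb @ Z, Sz, evaluate_new, n_knots - 2


@dataclass
class AdditiveModelFit:
    """Fitted Gaussian additive mixed model (one candidate)."""

    terms: tuple
    coef: np.ndarray
    cov: np.ndarray = field(repr=False)
    lambdas: dict
    edf: float
    edf_by_term: dict
    loglik: float
    sigma2: float
    reml: float
    n: int
    aicc: float
    _predict_info: dict = field(repr=False, default_factory=dict)

    def predict(self, focal: str, grid, others_at: dict | None = None):
        """Population-level prediction over a focal-covariate grid.

        Non-focal smooth terms are evaluated at the values in ``others_at``
        (defaults to their training medians); the section random intercept
        is set to zero.  Returns ``(mean, se)`` arrays.
        """
        info = self._predict_info
        if focal not in info["smooths"]:
            raise ValueError(f"{focal} is not a term of this model")
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        others_at = others_at or {}
        X = np.zeros((grid.size, self.coef.size))
        X[:, 0] = 1.0
        for name, (sl, ev, med) in info["smooths"].items():
            if name == focal:
                X[:, sl] = ev(grid)
            else:
                X[:, sl] = ev(np.full(grid.size, others_at.get(name, med)))
        mean = X @ self.coef
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov, X), 0.0))
        return mean, se


def aicc(loglik: float, k: float, n: int) -> float:
    """AIC with the small-sample bias correction."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n - k - 1 <= 0")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def fit_additive_model(
    y,
    covariates: dict,
    sections=None,
    n_knots: int = 4,
    smooth: bool = True,
    reml_tol: float = 1e-4,
) -> AdditiveModelFit:
    """Fit the Gaussian additive mixed model for one candidate subset.

    Parameters
    ----------
    y : array
        Response (heatwave percentage-difference values).
    covariates : dict of name -> array
        Standardized predictors entering as penalized smooths (or plain
        linear terms when ``smooth=False``).
    sections : array or None
        Coast-section id per observation; fitted as a ridge-penalized dummy
        block (random intercept).
    n_knots : int
        Knots per smooth; capped at 4 to limit flexibility.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    blocks = [np.ones((n, 1))]
    penalties = []  # (slice, Sz, rank, logdet_plus) for each penalized block
    smooth_info = {}
    col = 1
    for name, x in covariates.items():
        x = np.asarray(x, dtype=float)
        if x.std() == 0:
            raise ValueError(f"zero-variance predictor in subset: {name}")
        if smooth:
            Xb, Sz, ev, rank = _constrained_smooth(x, n_knots)
        else:
            Xb = (x - x.mean()).reshape(-1, 1)
            Sz, rank = np.zeros((1, 1)), 0
            mu, = [x.mean()]
            ev = (lambda mu_: lambda xn: (np.asarray(xn, float) - mu_).reshape(-1, 1))(mu)
        sl = slice(col, col + Xb.shape[1])
        blocks.append(Xb)
        if rank > 0:
            w = np.linalg.eigvalsh(Sz)
            logdet_plus = float(np.sum(np.log(w[w > 1e-10 * w.max()])))
            penalties.append((name, sl, Sz, rank, logdet_plus))
        smooth_info[name] = (sl, ev, float(np.median(x)))
        col += Xb.shape[1]

    section_slice = None
    if sections is not None:
        sections = np.asarray(sections)
        levels = np.unique(sections)
        if levels.size > 1:
            Zs = (sections[:, None] == levels[None, :]).astype(float)
            section_slice = slice(col, col + levels.size)
            blocks.append(Zs)
            penalties.append(("__section__", section_slice, np.eye(levels.size), levels.size, 0.0))
            col += levels.size

    X = np.hstack(blocks)
    p = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    n_pen = len(penalties)
    # unpenalized dimensions: intercept + penalty null spaces inside blocks
    m_p = p - sum(rank for _, _, _, rank, _ in penalties)

    def assemble(rho):
        S = np.zeros((p, p))
        logdet_s = 0.0
        for (name, sl, Sz, rank, ldp), r in zip(penalties, rho):
            lam = np.exp(r)
            S[sl, sl] += lam * Sz
            logdet_s += rank * r + ldp
        return S, logdet_s

    def solve(rho):
        S, logdet_s = assemble(rho)
        A = XtX + S
        try:
            c, low = linalg.cho_factor(A + 1e-10 * np.eye(p))
        except linalg.LinAlgError as err:
            raise ValueError(f"singular fit (candidate {list(covariates)})") from err
        beta = linalg.cho_solve((c, low), Xty)
        rss = float(np.sum((y - X @ beta) ** 2))
        bsb = float(beta @ S @ beta)
        logdet_a = 2.0 * float(np.sum(np.log(np.diag(c))))
        return beta, rss, bsb, logdet_a, logdet_s, (c, low), S

    def neg_reml(rho):
        _, rss, bsb, logdet_a, logdet_s, _, _ = solve(rho)
        sig2 = (rss + bsb) / max(n - m_p, 1)
        if sig2 <= 0:
            sig2 = 1e-12
        return 0.5 * ((n - m_p) * (np.log(2 * np.pi * sig2) + 1.0) + logdet_a - logdet_s)

    if n_pen:
        res = optimize.minimize(
            neg_reml,
            x0=np.zeros(n_pen),
            method="L-BFGS-B",
            bounds=[(-12.0, 18.0)] * n_pen,
            options={"ftol": reml_tol, "gtol": 1e-4, "maxiter": 200},
        )
        rho = res.x
        reml_val = -float(res.fun)
    else:
        rho = np.zeros(0)
        reml_val = -neg_reml(rho)

    beta, rss, bsb, logdet_a, logdet_s, chol, S = solve(rho)
    Ainv = linalg.cho_solve(chol, np.eye(p))
    hat = Ainv @ XtX
    edf = float(np.trace(hat))
    edf_by_term = {}
    for name, (sl, _, _) in smooth_info.items():
        edf_by_term[name] = float(np.trace(hat[sl, sl]))
    if section_slice is not None:
        edf_by_term["section"] = float(np.trace(hat[section_slice, section_slice]))
    sigma2_ml = rss / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
    sigma2 = (rss + bsb) / max(n - m_p, 1)
    k = edf + 1.0  # + residual variance
    fit = AdditiveModelFit(
        terms=tuple(covariates),
        coef=beta,
        cov=sigma2 * Ainv,
        lambdas={name: float(np.exp(r)) for (name, *_), r in zip(penalties, rho)},
        edf=edf,
        edf_by_term=edf_by_term,
        loglik=float(loglik),
        sigma2=float(sigma2),
        reml=reml_val,
        n=n,
        aicc=aicc(loglik, k, n),
        _predict_info={"smooths": smooth_info, "section_slice": section_slice},
    )
    return fit
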