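"""End-to-end validation experiments with known ground truth.

Each function runs one of the package's verifiable properties from scratch
— closed forms, brute-force oracles, or Monte-Carlo parameter-recovery
experiments at the study's scale — and returns plain numbers.  They back
both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import drivers as drv
from . import synth
from .heatwave import HeatwaveAdditiveModel
from .modelselect import n_candidates
from .ordinal import (
    ProportionalOdds,
    ScenarioSpec,
    category_probabilities,
    dredge_ordinal,
    scenario_probabilities,
)
from .smooth import fit_additive_model
from .trajectory import jackknife_group_difference, permanova

__all__ = [
    "ordinal_grid_oracle",
    "ordinal_intercept_closed_form",
    "ordinal_recovery",
    "scenario_fold_consistency",
    "permanova_null_calibration",
    "permanova_exact_agreement",
    "jackknife_identity_error",
    "dhw_closed_forms",
    "kernel_checks",
    "dredge_counts",
    "gamm_slope_recovery",
    "gamm_importance_recovery",
]


def _simulate_ordinal(n, betas, cuts, rng):
    Z = pd.DataFrame(
        rng.normal(size=(n, len(betas))), columns=[f"z{i}" for i in range(len(betas))]
    )
    eta = Z.to_numpy() @ np.asarray(betas)
    latent = eta + rng.logistic(size=n)
    y = np.where(latent <= cuts[0], "low", np.where(latent <= cuts[1], "moderate", "high"))
    return y, Z


def ordinal_grid_oracle(seed: int = 0, n: int = 12) -> dict:
    """Fitted log-likelihood vs a dense brute-force grid on (C1, C2, B)."""
    rng = np.random.default_rng(seed)
    while True:  # n = 12 draws occasionally miss a category; redraw
        y, Z = _simulate_ordinal(n, [1.0], (-1.0986, 1.0986), rng)
        if len(set(y)) == 3:
            break
    model = ProportionalOdds(y, Z)
    fit = model.fit()
    best = -np.inf
    for c1 in np.linspace(-4, 2, 61):
        for dc in np.linspace(0.05, 5, 50):
            for b in np.linspace(-4, 4, 81):
                ll = model.loglike(np.array([c1, c1 + dc]), np.array([b]))
                best = max(best, ll)
    return {"loglik_fit": fit.loglik, "loglik_grid": best, "gap": fit.loglik - best, "n": n}


def ordinal_intercept_closed_form() -> dict:
    """Intercept-only fit on balanced (10,10,10) counts vs the logit closed form."""
    y = np.repeat(["low", "moderate", "high"], 10)
    fit = ProportionalOdds(y).fit()
    return {
        "c1": float(fit.cuts[0]),
        "c2": float(fit.cuts[1]),
        "c1_error": abs(fit.cuts[0] + np.log(2.0)),
        "c2_error": abs(fit.cuts[1] - np.log(2.0)),
        "n": 30,
    }


def ordinal_recovery(seed: int = 0, reps: int = 100, n: int = 55) -> dict:
    """Parameter recovery at the study's scale.

    Truth B = (+1.2, -1.0) plus four pure-noise predictors; per replicate
    the full model estimates B and an AICc dredge (max four predictors)
    checks whether the top model contains both true predictors.
    """
    truth = np.array([1.2, -1.0, 0.0, 0.0, 0.0, 0.0])
    cuts = (-1.0986, 1.0986)
    rng = np.random.default_rng(seed)
    estimates = []
    errs = []
    hits = 0
    done = 0
    while done < reps:
        y, Z = _simulate_ordinal(n, truth, cuts, rng)
        if min((y == c).sum() for c in ("low", "moderate", "high")) < 2:
            continue
        try:
            full = ProportionalOdds(y, Z).fit()
        except ValueError:
            continue
        estimates.append(full.params.to_numpy()[:2])
        errs.append(np.abs(full.params.to_numpy()[:2] - truth[:2]).mean())
        ms = dredge_ordinal(y, Z, max_predictors=4)
        best = ms.table.index[0]
        hits += ("z0" in best) and ("z1" in best)
        done += 1
    estimates = np.asarray(estimates)
    return {
        # recovery bias: how far the average estimate sits from the truth
        "mean_abs_coef_bias": float(np.abs(estimates.mean(axis=0) - truth[:2]).mean()),
        # per-replicate mean absolute error (at the MLE information limit)
        "mean_abs_coef_error": float(np.mean(errs)),
        "top_model_recovery_rate": hits / reps,
        "reps": reps,
        "n": n,
    }


def scenario_fold_consistency(seed: int = 0, n: int = 500, reps: int = 10) -> dict:
    """Scenario engine vs the generating ordinal model.

    The synthetic-coast generator injects B = (+1.5 scraper, -1.5
    wastewater); levers sit at the 92nd/36th (scraper) and 95th/36th
    (wastewater) percentiles of the generated standardized driver
    distributions.  Per replicate coastline (n reefs each) the combined-
    lever fold change in P(high) implied by the truth is compared with the
    fold the fitted engine reproduces; folds are averaged over replicates
    to separate engine error from single-dataset Monte-Carlo noise.
    """
    B_true = np.array([1.5, -1.5])
    folds_truth = []
    folds_fit = []
    seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**31)
    for rep_seed in seeds:
        cfg = synth.SynthConfig(
            n_cells=2 * n,
            n_reefs=n,
            years=(2014, 2016),
            heatwave_year=2015,
            rng_seed=int(rep_seed),
        )
        bundle = synth.generate(cfg)
        z = bundle.standardized_drivers()[["scraper_biomass", "wastewater"]]
        y = bundle.truth["category"].to_numpy()
        cuts_true = np.array(bundle.config.truth_ordinal["C"])

        lever_z = {
            "scraper_biomass": {
                "low": float(np.quantile(z["scraper_biomass"], 0.36)),
                "high": float(np.quantile(z["scraper_biomass"], 0.92)),
            },
            "wastewater": {
                "low": float(np.quantile(z["wastewater"], 0.36)),
                "high": float(np.quantile(z["wastewater"], 0.95)),
            },
        }

        def scen(which_s, which_w):
            return lever_z["scraper_biomass"][which_s], lever_z["wastewater"][which_w]

        def truth_p_high(zs, zw):
            eta = B_true @ np.array([zs, zw])
            return float(category_probabilities(cuts_true, eta)[0, 2])

        p_truth = {
            "A": truth_p_high(*scen("high", "high")),
            "B": truth_p_high(*scen("low", "low")),
            "C": truth_p_high(*scen("high", "low")),
        }
        folds_truth.append(p_truth["C"] / max(p_truth["A"], p_truth["B"]))

        fit = ProportionalOdds(y, z).fit()
        p_fit = {}
        for name, (zs, zw) in {
            "A": scen("high", "high"),
            "B": scen("low", "low"),
            "C": scen("high", "low"),
        }.items():
            res = scenario_probabilities(
                fit, ScenarioSpec({"scraper_biomass": zs, "wastewater": zw}, name)
            )
            p_fit[name] = res.probabilities["high"]
        folds_fit.append(p_fit["C"] / max(p_fit["A"], p_fit["B"]))
    fold_truth = float(np.mean(folds_truth))
    fold_fit = float(np.mean(folds_fit))
    return {
        "fold_truth": fold_truth,
        "fold_fitted": fold_fit,
        "relative_error": float(abs(fold_fit - fold_truth) / fold_truth),
        "n": n,
    }


def permanova_null_calibration(
    seed: int = 0, reps: int = 1000, n: int = 12, n_perm: int = 199
) -> dict:
    """Type-I error of the permutation test on exchangeable data."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        X = rng.normal(size=(n, 3))
        lab = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
        res = permanova(
            X, lab, n_perm=n_perm, seed=int(rng.integers(2**31)), exact_limit=1
        )
        rejections += res.p_value <= 0.05
    return {"rejection_rate": rejections / reps, "reps": reps, "n": n}


def permanova_exact_agreement(seed: int = 0) -> dict:
    """Exact enumeration p on n = 6 vs an independent direct enumeration."""
    import itertools
    import math

    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(2.5, 1, (3, 2))])
    lab = np.array(["a"] * 3 + ["b"] * 3)
    res = permanova(X, lab)
    count = 0
    for perm in itertools.permutations(range(6)):
        lp = lab[list(perm)]
        f = _anova_f_multivariate(X, lp)
        count += f >= res.pseudo_f - 1e-12
    p_oracle = count / math.factorial(6)
    return {
        "p_exact": res.p_value,
        "p_oracle": p_oracle,
        "difference": abs(res.p_value - p_oracle),
        "n": 6,
    }


def _anova_f_multivariate(X, labels):
    """Direct pseudo-F via group centroids (Euclidean identity)."""
    sst = np.sum((X - X.mean(axis=0)) ** 2)
    ssw = 0.0
    for g in np.unique(labels):
        sub = X[labels == g]
        ssw += np.sum((sub - sub.mean(axis=0)) ** 2)
    a = len(np.unique(labels))
    if ssw == 0:
        return np.inf
    return ((sst - ssw) / (a - 1)) / (ssw / (X.shape[0] - a))


def jackknife_identity_error(seed: int = 0, reps: int = 50) -> dict:
    """Max |mean of drop-one means - sample mean| over random fixtures."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(reps):
        x = rng.lognormal(1, 1, size=int(rng.integers(3, 40)))
        drop_one = (x.sum() - x) / (x.size - 1)
        worst = max(worst, abs(drop_one.mean() - x.mean()) / max(1.0, abs(x.mean())))
    d = jackknife_group_difference([2.0, 4.0, 6.0], [2.0, 4.0, 6.0])
    return {"max_identity_error": worst, "self_difference": d["mean_difference"], "n": reps}


def dhw_closed_forms() -> dict:
    s = drv.ThermalStressSeries(np.full(84, 29.0), mmm=27.0)
    dhw_2deg = drv.dhw(s)
    s2 = drv.ThermalStressSeries(np.full(120, 27.5), mmm=27.0)
    dhw_half = drv.dhw(s2)
    return {"dhw_2deg_84days": dhw_2deg, "dhw_half_degree": dhw_half, "n": 84}


def kernel_checks() -> dict:
    d = np.linspace(0, 5000, 501)
    w = drv.dispersal_weight(d)
    return {
        "weight_at_zero": float(drv.dispersal_weight(0.0)),
        "weight_2km_error": float(abs(drv.dispersal_weight(2000.0) - np.exp(-4.5))),
        "strictly_decreasing": bool(np.all(np.diff(w) < 0)),
        "n": d.size,
    }


def dredge_counts(seed: int = 0) -> dict:
    """Real dredges must enumerate the binomial-sum candidate counts."""
    rng = np.random.default_rng(seed)
    n = 45
    Z13 = pd.DataFrame(rng.normal(size=(n, 13)), columns=[f"p{i}" for i in range(13)])
    y = rng.normal(size=n)
    ms13 = HeatwaveAdditiveModel(y, Z13, smooth=False).dredge(5)
    count13 = len(ms13.table) + len(ms13.skipped)

    n2 = 70
    Z10 = pd.DataFrame(rng.normal(size=(n2, 10)), columns=[f"q{i}" for i in range(10)])
    y2, _ = _simulate_ordinal(n2, [1.0] + [0.0] * 9, (-1.0, 1.0), rng)
    ms10 = dredge_ordinal(y2, Z10, max_predictors=4)
    count10 = len(ms10.table) + len(ms10.skipped)
    return {
        "candidates_p13_max5": count13,
        "expected_p13_max5": n_candidates(13, 5),
        "candidates_p10_max4": count10,
        "expected_p10_max4": n_candidates(10, 4),
        "weight_sum_error": float(
            max(abs(ms13.table.weight.sum() - 1), abs(ms10.table.weight.sum() - 1))
        ),
        "n": n,
    }


def gamm_slope_recovery(seed: int = 0, n: int = 200) -> dict:
    """Linear truth slope recovered by the penalized smooth (finite difference)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = 2.0 * x + rng.normal(0, 1, n)
    fit = fit_additive_model(y, {"x": x})
    mean, _ = fit.predict("x", np.array([-0.5, 0.5]))
    slope = float(mean[1] - mean[0])
    return {"slope": slope, "truth": 2.0, "relative_error": abs(slope - 2.0) / 2.0, "n": n}


def gamm_importance_recovery(seed: int = 0, reps: int = 100, n: int = 80) -> dict:
    """True predictors should top the relative-importance ranking.

    Truth: response = 8·scraper - 10·urban-runoff + section effects + noise
    among four extra pure-noise predictors; 100 replicates at the study's
    scale (n = 80 reefs).
    """
    rng = np.random.default_rng(seed)
    names = ["scraper", "urban", "n1", "n2", "n3", "n4"]
    hits = 0
    for _ in range(reps):
        Z = pd.DataFrame(rng.normal(size=(n, 6)), columns=names)
        sec = rng.integers(0, 5, n)
        sec_eff = rng.normal(0, 3, 5)
        y = (
            8.0 * Z["scraper"].to_numpy()
            - 10.0 * Z["urban"].to_numpy()
            + sec_eff[sec]
            + rng.normal(0, 8, n)
        )
        ms = HeatwaveAdditiveModel(y, Z, sections=sec).dredge(5)
        top2 = set(ms.relative_importance().index[:2])
        hits += top2 == {"scraper", "urban"}
    return {"top2_importance_rate": hits / reps, "reps": reps, "n": n}
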