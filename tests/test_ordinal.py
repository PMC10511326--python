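"""Proportional-odds regression: MLE, assumption tests, dredge, scenarios."""

import numpy as np
import pandas as pd
import pytest

from landsea._util import percentile_of
from landsea.ordinal import (
    ProportionalOdds,
    ScenarioSpec,
    brant_test,
    categorize_cover,
    category_probabilities,
    dredge_ordinal,
    lr_test,
    mcfadden_r2,
    scenario_probabilities,
)


def simulate_po(n, betas, cuts=(-1.0986, 1.0986), seed=0):
    """Draw (y, Z) from a proportional-odds truth with standardized predictors."""
    rng = np.random.default_rng(seed)
    Z = pd.DataFrame(
        rng.normal(size=(n, len(betas))), columns=[f"z{i}" for i in range(len(betas))]
    )
    eta = Z.to_numpy() @ np.asarray(betas)
    latent = eta + rng.logistic(size=n)
    y = np.where(latent <= cuts[0], "low", np.where(latent <= cuts[1], "moderate", "high"))
    return y, Z


class TestCategorize:
    def test_one_to_eight_percentile_convention(self):
        out, (q25, q75) = categorize_cover(np.arange(1.0, 9.0))
        assert (q25, q75) == (2.75, 6.25)
        cats = out.set_index("cover").category
        assert all(cats[v] == "low" for v in (1, 2))
        assert all(cats[v] == "high" for v in (7, 8))
        assert all(cats[v] == "moderate" for v in (3, 4, 5, 6))

    def test_quarter_tails_split(self):
        vals = np.r_[np.arange(5), 10 + np.arange(10), 30 + np.arange(5)].astype(float)
        out, _ = categorize_cover(vals)
        freq = out.category.value_counts()
        assert freq["low"] == 5 and freq["high"] == 5 and freq["moderate"] == 10

    def test_constant_vector_needs_explicit_thresholds(self):
        with pytest.raises(ValueError, match="thresholds"):
            categorize_cover(np.full(10, 20.0))
        out, _ = categorize_cover(np.full(10, 20.0), thresholds=(10.0, 30.0))
        assert (out.category == "moderate").all()


class TestMLE:
    def test_intercept_only_closed_form(self):
        y = np.repeat(["low", "moderate", "high"], 10)
        fit = ProportionalOdds(y).fit()
        assert fit.cuts[0] == pytest.approx(-np.log(2), abs=1e-4)
        assert fit.cuts[1] == pytest.approx(np.log(2), abs=1e-4)

    def test_beats_dense_grid_oracle(self):
        y, Z = simulate_po(12, [1.0], seed=3)
        model = ProportionalOdds(y, Z)
        fit = model.fit()
        best = -np.inf
        for c1 in np.linspace(-3, 1, 41):
            for c2 in np.linspace(c1 + 0.05, c1 + 4, 40):
                for b in np.linspace(-3, 3, 61):
                    best = max(best, model.loglike(np.array([c1, c2]), np.array([b])))
        assert fit.loglik >= best - 1e-6

    def test_matches_statsmodels(self):
        sm_ord = pytest.importorskip("statsmodels.miscmodels.ordinal_model")
        y, Z = simulate_po(150, [1.2, -0.8], seed=1)
        fit = ProportionalOdds(y, Z).fit()
        codes = pd.Series(
            pd.Categorical(y, categories=["low", "moderate", "high"], ordered=True)
        )
        om = sm_ord.OrderedModel(codes, Z, distr="logit").fit(method="bfgs", disp=0)
        assert fit.loglik == pytest.approx(om.llf, abs=1e-5)
        assert np.allclose(fit.params.to_numpy(), om.params.to_numpy()[:2], atol=1e-4)
        assert np.allclose(fit.bse.to_numpy(), om.bse.to_numpy()[:2], atol=1e-3)

    def test_fixing_beta_zero_reduces_to_intercept_only(self):
        y, Z = simulate_po(60, [0.8], seed=5)
        null = ProportionalOdds(y).fit()
        model = ProportionalOdds(y, Z)
        assert model.loglike(null.cuts, np.zeros(1)) == pytest.approx(null.loglik)

    def test_probabilities_sum_to_one_and_cuts_ordered(self):
        y, Z = simulate_po(80, [1.5, -1.0, 0.3], seed=7)
        fit = ProportionalOdds(y, Z).fit()
        probs = fit.predict_proba()
        assert np.abs(probs.sum(axis=1) - 1).max() < 1e-12
        assert fit.cuts[0] < fit.cuts[1]

    def test_empty_category_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ProportionalOdds(np.repeat(["low", "high"], 10))

    def test_dual_indexing_equivalence(self):
        # the published high-first indexing and the internal low-first
        # ordering must give identical category probabilities
        cuts = np.array([-0.9, 1.3])
        eta = np.linspace(-3, 3, 11)
        p_internal = category_probabilities(cuts, eta)
        p_published = category_probabilities(cuts, eta, high_first=True)
        assert np.abs(p_internal - p_published).max() < 1e-12

    def test_wald_and_summary(self):
        y, Z = simulate_po(200, [1.5], seed=9)
        fit = ProportionalOdds(y, Z).fit()
        w = fit.wald()
        assert w.loc["z0", "p"] < 0.05 and w.loc["z0", "coef"] > 0
        assert "cut points" in fit.summary()


class TestBrant:
    def test_null_rejection_near_alpha(self):
        rej = 0
        reps = 120
        for rep in range(reps):
            y, Z = simulate_po(250, [1.0], seed=2000 + rep)
            try:
                fit = ProportionalOdds(y, Z).fit()
                tab = brant_test(fit)
            except ValueError:
                continue
            rej += tab.loc["omnibus", "p"] < 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.05)

    def test_violation_detected(self):
        # cut-point-specific slopes: generate from two different binary logits
        rng = np.random.default_rng(4)
        hits = 0
        reps = 30
        for rep in range(reps):
            r = np.random.default_rng(500 + rep)
            n = 500
            z = r.normal(size=n)
            p_gt_low = 1 / (1 + np.exp(-(0.5 + 1.8 * z)))  # strong slope at cut 1
            p_high = 1 / (1 + np.exp(-(-1.0 + 0.2 * z)))  # weak slope at cut 2
            u = r.random(n)
            y = np.where(u > p_gt_low, "low", np.where(r.random(n) < p_high / np.clip(p_gt_low, 1e-9, None), "high", "moderate"))
            if min((y == c).sum() for c in ("low", "moderate", "high")) < 5:
                continue
            try:
                fit = ProportionalOdds(pd.Series(y), pd.DataFrame({"z": z})).fit()
                tab = brant_test(fit)
            except ValueError:
                continue
            hits += tab.loc["omnibus", "p"] < 0.05
        assert hits / reps > 0.5

    def test_intercept_only_not_applicable(self):
        fit = ProportionalOdds(np.repeat(["low", "moderate", "high"], 5)).fit()
        tab = brant_test(fit)
        assert "not applicable" in tab.loc["omnibus", "note"]


class TestLrAndR2:
    def test_identical_models(self):
        y, Z = simulate_po(60, [1.0], seed=11)
        fit = ProportionalOdds(y, Z).fit()
        out = lr_test(fit, fit)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-8) and out["p"] == 1.0

    def test_pure_noise_extra_parameter_null_uniform(self):
        ps = []
        for rep in range(60):
            y, Z = simulate_po(150, [1.0, 0.0], seed=3000 + rep)
            full = ProportionalOdds(y, Z).fit()
            nested = ProportionalOdds(y, Z[["z0"]]).fit()
            ps.append(lr_test(nested, full)["p"])
        ps = np.asarray(ps)
        # uniform p: roughly correct mean and no pile-up at 0
        assert 0.35 < ps.mean() < 0.65
        assert (ps < 0.05).mean() < 0.15

    def test_strong_effect_detected(self):
        hits = 0
        for rep in range(30):
            y, Z = simulate_po(500, [1.5], seed=4000 + rep)
            full = ProportionalOdds(y, Z).fit()
            nested = ProportionalOdds(y).fit()
            hits += lr_test(nested, full)["p"] < 0.05
        assert hits >= 29

    def test_non_nested_rejected(self):
        y, Z = simulate_po(60, [1.0, 0.5], seed=13)
        f1 = ProportionalOdds(y, Z[["z0"]]).fit()
        f2 = ProportionalOdds(y, Z[["z1"]]).fit()
        with pytest.raises(ValueError, match="nested"):
            lr_test(f1, f2)

    def test_mcfadden_fixture(self):
        y, Z = simulate_po(40, [2.0], seed=15)
        full = ProportionalOdds(y, Z).fit()
        null = ProportionalOdds(y).fit()
        r2 = mcfadden_r2(full, null)
        assert r2 == pytest.approx(1 - full.loglik / null.loglik, abs=1e-12)
        assert 0 <= r2 < 1
        assert mcfadden_r2(null, null) == 0.0


class TestDredgeOrdinal:
    def test_candidate_count_and_weights(self):
        y, Z = simulate_po(60, [1.2, -1.0, 0, 0, 0], seed=17)
        ms = dredge_ordinal(y, Z, max_predictors=4)
        # sum_{k=0..4} C(5,k) = 1+5+10+10+5
        assert len(ms.table) + len(ms.skipped) == 31
        assert ms.table.weight.sum() == pytest.approx(1.0, abs=1e-10)
        assert ms.table.delta_aicc.iloc[0] == 0.0
        assert "mcfadden_r2" in ms.table.columns

    def test_true_predictors_recovered(self):
        y, Z = simulate_po(300, [1.5, -1.2, 0, 0], seed=19)
        ms = dredge_ordinal(y, Z, max_predictors=3)
        best = ms.table.index[0]
        assert "z0" in best and "z1" in best


class TestScenarios:
    def test_zero_effect_closed_form(self):
        c = np.log(0.25 / 0.75)
        y, Z = simulate_po(200, [0.0], cuts=(c, -c), seed=21)
        fit = ProportionalOdds(y, Z).fit()
        fit = fit.__class__(  # force exact truth coefficients for the closed form
            model=fit.model, cuts=np.array([c, -c]),
            params=pd.Series([0.0], index=["z0"]), cov=fit.cov, loglik=fit.loglik,
        )
        res = scenario_probabilities(fit, ScenarioSpec({"z0": 5.0}, "any"))
        assert res.probabilities["low"] == pytest.approx(0.25, abs=1e-9)
        assert res.probabilities["moderate"] == pytest.approx(0.50, abs=1e-9)
        assert res.probabilities["high"] == pytest.approx(0.25, abs=1e-9)

    def test_monotone_in_positive_lever(self):
        y, Z = simulate_po(400, [1.5], seed=23)
        fit = ProportionalOdds(y, Z).fit()
        assert fit.params["z0"] > 0
        probs = [
            scenario_probabilities(fit, ScenarioSpec({"z0": v}, "s")).probabilities
            for v in (-2.0, 0.0, 2.0)
        ]
        highs = [p["high"] for p in probs]
        lows = [p["low"] for p in probs]
        assert highs[0] < highs[1] < highs[2]
        assert lows[0] > lows[1] > lows[2]

    def test_transform_chain_applied(self):
        y, Z = simulate_po(200, [1.0], seed=25)
        fit = ProportionalOdds(y, Z).fit()
        std = {"z0": {"transform": "sqrt", "mean": 3.0, "sd": 2.0}}
        res = scenario_probabilities(fit, ScenarioSpec({"z0": 25.0}, "s"), std)
        # sqrt(25)=5 -> z=(5-3)/2 = 1
        direct = fit.predict_proba(pd.DataFrame({"z0": [1.0]}))[0]
        assert res.probabilities["high"] == pytest.approx(direct[2])
        with pytest.raises(ValueError, match="domain"):
            scenario_probabilities(fit, ScenarioSpec({"z0": -1.0}, "s"), std)

    def test_unknown_lever_rejected(self):
        y, Z = simulate_po(60, [1.0], seed=27)
        fit = ProportionalOdds(y, Z).fit()
        with pytest.raises(ValueError, match="lever"):
            scenario_probabilities(fit, ScenarioSpec({"nope": 1.0}, "s"))


class TestPercentileOf:
    def test_extremes_and_median(self):
        x = np.arange(1.0, 12.0)  # odd length
        assert percentile_of(x.min(), x) == 0.0
        assert percentile_of(x.max(), x) == 100.0
        assert percentile_of(np.median(x), x) == 50.0

    def test_counting_oracle_on_1_to_100(self):
        x = np.arange(1.0, 101.0)
        v = 37.0
        # linear-interpolation convention: rank/(n-1)
        expect = (37 - 1) / 99 * 100
        assert percentile_of(v, x) == pytest.approx(expect)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            percentile_of(1.0, [])
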