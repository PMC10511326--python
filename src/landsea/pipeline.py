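"""Staged end-to-end pipeline: simulate → drivers → three analysis stages.

`run_pipeline` executes the requested stages in dependency order on a
synthetic coastline, writing every stage's tables under the configured
output directory together with a config snapshot and a structured log of
every exclusion/transform decision, so a run replays bit-identically from
its snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import heatwave as hw
from . import ordinal as po
from . import synth
from ._util import informative_columns
from .io import RunConfig, write_config, write_json, write_long_table
from .trajectory import TrajectoryContrast, classify_trajectory

__all__ = ["ResultBundle", "run_pipeline"]

_ORDER = ["simulate", "drivers", "trajectory", "heatwave", "persistence", "scenarios"]


@dataclass
class ResultBundle:
    config: RunConfig
    tables: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    log: list = field(default_factory=list)


def _predictor_prep(bundle, cfg, years):
    """Driver summaries -> analysis-ready standardized predictor table."""
    sub = bundle.driver_table[bundle.driver_table.year.isin(years)]
    wide = sub.pivot_table(index="reef_id", columns="variable", values="value", aggfunc="mean")
    wide = wide.drop(columns=[c for c in ("population", "browser_biomass") if c in wide])
    wide = informative_columns(wide)
    table, tlog = hw.transform_predictors(
        wide,
        sqrt=[c for c in cfg.sqrt_transforms if c in wide],
        fourth_root=[c for c in cfg.fourth_root_transforms if c in wide],
    )
    keep = [c for c in cfg.keep_preferences if c in table]
    while True:
        try:
            table, plog = hw.prune_correlated(table, cfg.prune_threshold, keep=keep)
            break
        except ValueError as err:
            # two keep-preferred predictors collide in this sample: release
            # the lower-priority one (later in the list) and retry
            involved = [c for c in keep if c in str(err)]
            if not involved:
                raise
            released = involved[-1]
            keep.remove(released)
            tlog.append(
                {"predictor": released, "action": "keep preference released", "reason": str(err)}
            )
    return wide, table, tlog + plog


def run_pipeline(cfg: RunConfig) -> ResultBundle:
    stages = sorted(set(cfg.stages), key=_ORDER.index)
    analysis = {"trajectory", "heatwave", "persistence", "scenarios"} & set(stages)
    if analysis and "simulate" not in stages:
        raise ValueError(
            f"stage(s) {sorted(analysis)} need 'simulate' to provide inputs"
        )
    out = Path(cfg.out_dir)
    result = ResultBundle(config=cfg)
    write_config(cfg, out / "config.yaml")

    scfg = synth.SynthConfig(
        n_cells=cfg.n_cells,
        n_reefs=cfg.n_reefs,
        years=tuple(cfg.years),
        heatwave_year=cfg.heatwave_year,
        heatwave_anomaly_C=cfg.heatwave_anomaly_C,
        rng_seed=cfg.seed,
    )
    bundle = None
    if "simulate" in stages or "drivers" in stages:
        bundle = synth.generate(scfg)
        write_long_table(bundle.driver_table, out / "driver_table.csv")
        write_long_table(bundle.survey_table, out / "survey_table.csv")
        result.tables["driver_table"] = bundle.driver_table
        result.tables["survey_table"] = bundle.survey_table
        result.log += [
            {"stage": "simulate", "event": "cover clipped", "detail": str(c)}
            for c in bundle.clip_log
        ]

    survey = bundle.survey_table if bundle is not None else None
    cover = None
    if survey is not None:
        cover = survey[survey.variable == "coral_cover"].pivot(
            index="reef_id", columns="year", values="value"
        ).astype(float)

    if "trajectory" in stages:
        y0, y1 = cfg.years[0], cfg.heatwave_year - 1
        labels = pd.Series(
            [
                classify_trajectory(cover.loc[r, y0], cover.loc[r, y1], cfg.trajectory_cutoff)
                for r in cover.index
            ],
            index=cover.index,
            name="trajectory",
        )
        factors = bundle.driver_matrix()
        tc = TrajectoryContrast(factors, labels.to_numpy())
        tr = tc.fit(n_perm=cfg.n_perm, seed=cfg.seed)
        labels.to_frame().assign(
            delta_cover=cover[y1] - cover[y0]
        ).to_csv(out / "trajectory_labels.csv")
        tr.jackknife_table.to_csv(out / "trajectory_jackknife.csv")
        write_json(
            {
                "permanova": {
                    "pseudo_f": tr.permanova.pseudo_f,
                    "df": [tr.permanova.df_between, tr.permanova.df_residual],
                    "p": tr.permanova.p_value,
                    "n_permutations": tr.permanova.n_permutations,
                },
                "cap": {
                    "m": tr.cap.m,
                    "allocation_success": tr.cap.allocation_success,
                },
            },
            out / "trajectory_summary.json",
        )
        result.tables["trajectory_labels"] = labels
        result.diagnostics["trajectory"] = tr

    heatwave_set = None
    if "heatwave" in stages:
        hw_year = cfg.heatwave_year
        a_b = cover[hw_year]
        a_a = cover[hw_year + 1]
        delta = pd.Series(
            [hw.percentage_difference(b, a) for b, a in zip(a_b, a_a)], index=cover.index
        )
        _, table, log = _predictor_prep(bundle, cfg, range(hw_year - 3, hw_year + 2))
        sections = hw.coast_sections(bundle.reef_cells * 100.0)
        model = hw.HeatwaveAdditiveModel(delta.loc[table.index], table, sections=sections)
        heatwave_set = model.dredge(cfg.max_predictors_heatwave)
        tab = heatwave_set.table.copy()
        tab.index = [" + ".join(s) if s else "(null)" for s in tab.index]
        tab.to_csv(out / "heatwave_models.csv")
        heatwave_set.relative_importance().to_csv(out / "heatwave_importance.csv")
        result.tables["heatwave_models"] = heatwave_set.table
        result.diagnostics["heatwave"] = heatwave_set
        result.log += [{"stage": "heatwave", **e} for e in log]

    ord_fit = None
    std_stats = {}
    if "persistence" in stages or "scenarios" in stages:
        rb = survey[survey.variable == "reef_builder_cover"].set_index("reef_id")["value"].astype(float)
        cats, thresholds = po.categorize_cover(rb.to_numpy())
        raw, table, log = _predictor_prep(bundle, cfg, range(cfg.heatwave_year + 1, cfg.years[1] + 1))
        # SST mean/variability excluded: negligible between-reef range
        table = table.drop(columns=[c for c in ("sst_mean", "sst_sd") if c in table])
        mset = po.dredge_ordinal(cats["category"].to_numpy(), table, cfg.max_predictors_ordinal)
        best_terms = list(mset.table.index[0])
        ord_fit = mset.fits[mset.table.index[0]]
        null_fit = po.ProportionalOdds(cats["category"].to_numpy()).fit()
        diag = {
            "thresholds": thresholds,
            "best_model": best_terms,
            "mcfadden_r2": po.mcfadden_r2(ord_fit, null_fit),
            "lr_vs_null": po.lr_test(null_fit, ord_fit),
        }
        if best_terms:
            try:
                diag["brant"] = po.brant_test(ord_fit).to_dict()
            except ValueError as err:
                diag["brant"] = f"not available: {err}"
                result.log.append({"stage": "persistence", "event": "brant skipped", "detail": str(err)})
        tab = mset.table.copy()
        tab.index = [" + ".join(s) if s else "(null)" for s in tab.index]
        tab.to_csv(out / "persistence_models.csv")
        write_json(diag, out / "persistence_diagnostics.json")
        result.tables["persistence_models"] = mset.table
        result.diagnostics["persistence"] = mset
        result.log += [{"stage": "persistence", **e} for e in log]
        for e in log:
            if e.get("action") in ("sqrt", "fourth_root"):
                std_stats.setdefault(e["predictor"], {})["transform"] = e["action"]
            if e.get("action") == "zscore":
                std_stats.setdefault(e["predictor"], {}).update(
                    {"mean": e["mean"], "sd": e["sd"]}
                )

    if "scenarios" in stages and ord_fit is not None and ord_fit.params.size:
        lever_names = [n for n in ("scraper_biomass", "wastewater") if n in ord_fit.params.index]
        raw_prep = raw  # raw-scale predictor summaries from the persistence prep
        rows = []
        specs = {}
        for name in lever_names:
            vals = raw_prep[name]
            specs[name] = {
                "low": float(np.quantile(vals, 0.36)),
                "high": float(np.quantile(vals, 0.95 if name == "wastewater" else 0.92)),
            }
        if len(lever_names) == 2:
            s, w = lever_names if lever_names[0] == "scraper_biomass" else lever_names[::-1]
            scenario_defs = {
                "initial": {s: specs[s]["low"], w: specs[w]["high"]},
                "A": {s: specs[s]["high"], w: specs[w]["high"]},
                "B": {s: specs[s]["low"], w: specs[w]["low"]},
                "C": {s: specs[s]["high"], w: specs[w]["low"]},
            }
        else:
            scenario_defs = {
                "initial": {n: specs[n]["low"] for n in lever_names},
                "managed": {n: specs[n]["high"] for n in lever_names},
            }
        for name, levers in scenario_defs.items():
            res = po.scenario_probabilities(
                ord_fit, po.ScenarioSpec(levers, name=name), std_stats
            )
            rows.append({"scenario": name, **levers, **res.probabilities})
        scen = pd.DataFrame(rows).set_index("scenario")
        scen.to_csv(out / "scenario_probabilities.csv")
        result.tables["scenarios"] = scen

    write_json(result.log, out / "run_log.json")
    return result
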