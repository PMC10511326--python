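"""Seeded synthetic coastline, driver inputs, and reef outcomes.

The generator emulates the structure of a west-facing island coastline
monitored before, during, and after a marine heatwave: a 100-m alongshore
cell lattice, right-skewed land-based loads (wastewater, golf-course
nitrogen, impervious surface), seasonal gamma rainfall, a sinusoidal SST
climatology with AR(1) noise and a boxcar heatwave anomaly, and reef
outcomes (pre-disturbance cover slopes, heatwave percentage-difference
response, post-disturbance reef-builder category) generated from *known*
injected effect coefficients so that every downstream inference stage can
be checked against ground truth.

It makes no claim about the real Hawai'i distributions; distributional
forms are stand-ins chosen for realism of shape (skew, seasonality,
episodicity), not parameter fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import drivers as drv
from ._util import zscore

__all__ = ["SynthConfig", "SyntheticBundle", "generate_coast", "generate_outcomes", "generate"]

#: canonical driver-variable names produced by the generator
DRIVER_NAMES = [
    "total_fish_biomass",
    "herbivore_biomass",
    "scraper_biomass",
    "grazer_biomass",
    "browser_biomass",
    "population",
    "wastewater",
    "nutrients",
    "urban_runoff",
    "annual_rainfall",
    "peak_rainfall",
    "sediment",
    "gear_rank",
    "sst_mean",
    "sst_sd",
    "dhw",
    "phytoplankton",
    "irradiance",
    "wave_power",
    "depth",
]


def _logit(p):
    return float(np.log(p / (1.0 - p)))


@dataclass
class SynthConfig:
    """Study conditions for one synthetic coastline.

    Defaults emulate the observed setting: ~200 km of coast (2,000 cells),
    80 reefs, a 2003–2019 record with a heatwave in 2015 whose regional
    anomaly is 2.2 °C, and ordinal truth coefficients giving a strong
    positive scraper and strong negative wastewater effect on post-
    disturbance reef-builder cover.
    """

    n_cells: int = 2000
    n_reefs: int = 80
    years: tuple[int, int] = (2003, 2019)
    heatwave_year: int = 2015
    heatwave_anomaly_C: float = 2.2
    truth_trajectory_effects: dict[str, float] = field(
        default_factory=lambda: {"scraper_biomass": 0.6, "urban_runoff": -0.5}
    )
    truth_heatwave_effects: dict[str, float] = field(
        default_factory=lambda: {
            "phytoplankton": 8.0,
            "urban_runoff": -10.0,
            "sediment": -8.0,
            "scraper_biomass": 5.0,
        }
    )
    truth_ordinal: dict = field(
        default_factory=lambda: {
            "C": (_logit(0.25), _logit(0.75)),
            "B": {"scraper_biomass": 1.5, "wastewater": -1.5},
        }
    )
    trajectory_noise_sd: float = 0.15  # percentage points of cover per year
    heatwave_noise_sd: float = 8.0  # percent-difference units
    sst_noise_sd: float = 0.15  # °C, AR(1) innovations
    cover_noise_sd: float = 1.0  # percentage points around the trend
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_reefs > self.n_cells:
            raise ValueError("n_reefs exceeds n_cells: reefs must occupy distinct cells")
        if self.years[1] - self.years[0] < 1:
            raise ValueError("years must span at least 2 calendar years")
        if not (self.years[0] <= self.heatwave_year <= self.years[1]):
            raise ValueError("heatwave_year outside the simulated year range")
        for name in ("trajectory_noise_sd", "heatwave_noise_sd", "sst_noise_sd", "cover_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        C = self.truth_ordinal["C"]
        if not C[0] < C[1]:
            raise ValueError("truth_ordinal intercepts C must be strictly increasing")
        for eff in (self.truth_trajectory_effects, self.truth_heatwave_effects, self.truth_ordinal["B"]):
            unknown = set(eff) - set(DRIVER_NAMES)
            if unknown:
                raise ValueError(f"unknown driver names in truth effects: {sorted(unknown)}")


@dataclass
class SyntheticBundle:
    """Everything one synthetic study produces, plus its ground truth."""

    config: SynthConfig
    reef_cells: np.ndarray
    driver_inputs: dict
    driver_table: pd.DataFrame  # long: reef_id, year, variable, value
    survey_table: pd.DataFrame | None = None  # long: reef_id, year, variable, value
    truth: dict = field(default_factory=dict)
    clip_log: list = field(default_factory=list)

    def driver_matrix(self) -> pd.DataFrame:
        """Per-reef across-year mean of every driver (wide, reefs × drivers)."""
        wide = self.driver_table.pivot_table(
            index="reef_id", columns="variable", values="value", aggfunc="mean"
        )
        return wide[DRIVER_NAMES]

    def standardized_drivers(self) -> pd.DataFrame:
        """Z-scored driver matrix (columns with zero variance are dropped)."""
        wide = self.driver_matrix()
        keep = wide.columns[wide.std(ddof=1) > 0]
        dropped = wide.columns.difference(keep)
        z = pd.DataFrame(zscore(wide[keep].to_numpy()), index=wide.index, columns=keep)
        for c in dropped:
            z[c] = 0.0
        return z[[c for c in DRIVER_NAMES if c in z.columns]]


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _sst_year(rng, anomaly: float, noise_sd: float, n_days: int = 365) -> np.ndarray:
    """One year of daily SST: sinusoid + AR(1) noise + boxcar anomaly.

    The seasonal cycle peaks near day 240 (late summer); the heatwave
    anomaly is a boxcar over days 185–300, covering the seasonal peak.
    """
    t = np.arange(n_days)
    base = 25.1 + 2.1 * np.cos(2 * np.pi * (t - 240) / 365.25)
    eps = np.zeros(n_days)
    innov = rng.normal(0.0, noise_sd, n_days)
    for i in range(1, n_days):
        eps[i] = 0.8 * eps[i - 1] + innov[i]
    hw = np.zeros(n_days)
    hw[185:300] = anomaly
    return base + eps + hw


def _mmm() -> float:
    """Maximum monthly mean of the noise-free baseline climatology."""
    t = np.arange(365)
    base = 25.1 + 2.1 * np.cos(2 * np.pi * (t - 240) / 365.25)
    months = np.minimum(t // 30, 11)
    return float(max(base[months == m].mean() for m in range(12)))


def generate_coast(config: SynthConfig) -> SyntheticBundle:
    """Generate the coastline, raw driver inputs, and the driver table."""
    config.validate()
    rngs = _streams(
        config.rng_seed,
        ["layout", "fish", "sources", "rain", "sst", "wave", "pop", "reg", "phyto"],
    )
    years = list(range(config.years[0], config.years[1] + 1))
    n_cells = config.n_cells

    reef_cells = np.sort(
        rngs["layout"].choice(n_cells, size=config.n_reefs, replace=False)
    )
    depth = rngs["layout"].uniform(3.0, 18.0, config.n_reefs)
    # per-reef wave exposure multiplier (aspect/fetch differences); heat
    # stress stays regional — all reefs see the same heatwave
    wave_exposure = rngs["layout"].lognormal(0.0, 0.3, config.n_reefs)

    # --- land-based point sources (right-skewed loads) -----------------------
    n_osds = max(5, n_cells // 20)
    osds = [
        drv.PointSource(
            kind="OSDS",
            entry_cell=int(c),
            effluent_l_yr=float(e),
            nitrogen_kg_yr=float(n),
            within_one_year_travel=bool(w),
        )
        for c, e, n, w in zip(
            rngs["sources"].integers(0, n_cells, n_osds),
            rngs["sources"].lognormal(10.0, 1.2, n_osds),
            rngs["sources"].lognormal(3.0, 1.0, n_osds),
            rngs["sources"].random(n_osds) < 0.8,
        )
    ]
    n_golf = max(1, n_cells // 400)
    golf = [
        drv.PointSource(
            kind="golf",
            entry_cell=int(c),
            area_ha=float(a),
            inland_distance_m=float(d),
        )
        for c, a, d in zip(
            rngs["sources"].integers(0, n_cells, n_golf),
            rngs["sources"].lognormal(3.5, 0.5, n_golf),
            rngs["sources"].uniform(0, 3000, n_golf),
        )
    ]

    # impervious surface: two snapshots with growth, per-cell lognormal
    base_imperv = rngs["sources"].lognormal(1.0, 1.0, n_cells)
    snapshots = {
        years[0]: base_imperv,
        years[-1]: base_imperv * rngs["sources"].uniform(1.1, 1.8, n_cells),
    }

    # rainfall: one watershed per 10 cells, daily gamma with a winter-wet cycle
    n_sheds = max(1, n_cells // 10)
    shed_of_cell = np.minimum(np.arange(n_cells) // 10, n_sheds - 1)
    shed_scale = rngs["rain"].lognormal(0.0, 0.4, n_sheds)
    t = np.arange(365)
    season = 1.0 + 0.6 * np.cos(2 * np.pi * (t - 15) / 365.25)
    rain = {
        y: rngs["rain"].gamma(0.6, 1.0, (n_sheds, 365)) * season * shed_scale[:, None]
        for y in years
    }

    # SST: one regional daily series per year (coast shares the climate)
    sst = {
        y: _sst_year(
            rngs["sst"],
            config.heatwave_anomaly_C if y == config.heatwave_year else 0.0,
            config.sst_noise_sd,
        )
        for y in years
    }
    mmm = _mmm()

    # waves: daily maximum wave power, lognormal with episodic winter swell
    wave = {y: rngs["wave"].lognormal(1.5, 0.8, 365) * season for y in years}

    # population: point grid along the coast, 1-km spacing, lognormal counts
    grid_x = np.arange(0, n_cells * 100.0, 1000.0)
    grid_xy = np.column_stack([grid_x, rngs["pop"].uniform(0, 10000.0, grid_x.size)])
    pop_by_year = {
        y: rngs["pop"].lognormal(4.0, 1.0, grid_x.size) for y in (years[0], years[-1])
    }

    # gear regulations: per-reef static rank flags
    reg_flags = []
    for _ in range(config.n_reefs):
        u = rngs["reg"].random()
        reg_flags.append(
            dict(
                no_take=u < 0.1,
                lay_net=u < 0.4,
                spear=(0.1 <= u < 0.25),
                aquarium=u < 0.55,
            )
        )

    # phytoplankton / irradiance: spatially smooth alongshore gradients
    grad = np.sin(2 * np.pi * np.arange(n_cells) / n_cells)
    phyto_cell = 0.15 + 0.08 * grad + rngs["phyto"].lognormal(-3.0, 0.5, n_cells)
    irrad_cell = 45.0 - 8.0 * grad + rngs["phyto"].normal(0, 1.5, n_cells)

    driver_inputs = dict(
        osds=osds,
        golf=golf,
        impervious_snapshots=snapshots,
        rain=rain,
        shed_of_cell=shed_of_cell,
        sst=sst,
        mmm=mmm,
        wave=wave,
        grid_xy=grid_xy,
        population_by_year=pop_by_year,
        regulations=reg_flags,
        phyto_cell=phyto_cell,
        irrad_cell=irrad_cell,
        depth=depth,
        wave_exposure=wave_exposure,
    )

    driver_table = _build_driver_table(config, reef_cells, driver_inputs, rngs["fish"], years)
    return SyntheticBundle(
        config=config,
        reef_cells=reef_cells,
        driver_inputs=driver_inputs,
        driver_table=driver_table,
    )


def _build_driver_table(config, reef_cells, inputs, fish_rng, years) -> pd.DataFrame:
    """Run the driver-layer computations for every reef × year."""
    n_cells = config.n_cells
    ww = drv.wastewater_load(inputs["osds"], n_cells)
    nut = drv.nutrient_input(ww["nitrogen_kg_ha_yr"].to_numpy(), inputs["golf"])
    imperv = drv.urban_runoff(inputs["impervious_snapshots"], years).set_index("cell")
    # long-term mean sediment delivery differs by watershed (right-skewed)
    n_sheds = int(inputs["shed_of_cell"].max()) + 1
    sed_rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 77]))
    longterm_sed_by_shed = sed_rng.lognormal(3.5, 0.8, n_sheds)

    # reef-level fish "capacity" gradients: fishing pressure rises with
    # population and falls with gear protection; these feed observation counts
    gear = np.array([drv.gear_rank(**flags) for flags in inputs["regulations"]])
    # regional series are shared along the coast: compute their annual
    # summaries once, not per reef
    sst_stats = {}
    wave_stat = {}
    for y in years:
        s = drv.ThermalStressSeries(inputs["sst"][y], mmm=inputs["mmm"])
        smean, ssd = drv.sst_summary(s)
        sst_stats[y] = (smean, ssd, drv.dhw(s))
        wave_stat[y] = drv.wave_power_metric(inputs["wave"][y])
    records = []
    for i, cell in enumerate(reef_cells):
        cell_x = cell * 100.0
        pop15 = {
            y: drv.population_within(inputs["grid_xy"], p, (cell_x, 0.0))
            for y, p in inputs["population_by_year"].items()
        }
        pop_series = drv.interpolate_years(pop15, years)
        shed = inputs["shed_of_cell"][cell]
        # discharge proxy per year: peak 3-day rainfall of the reef's watershed
        discharge = {}
        rain_metrics = {}
        for y in years:
            annual, peak = drv.rainfall_metrics(inputs["rain"][y][shed])
            rain_metrics[y] = (annual, peak)
            discharge[y] = peak
        sed_series = drv.sediment_input(float(longterm_sed_by_shed[shed]), discharge, beta=1.5)

        # fish: mean TL and abundance scale with protection (lower rank =
        # more protected = more and larger fish); guild composition varies
        # independently between reefs so guild biomasses are not collinear
        protect = (7 - gear[i]) / 6.0
        base_abund = 20 + 40 * protect
        gw = np.array([0.2, 0.2, 0.05, 0.1, 0.45]) * fish_rng.lognormal(0.0, 0.6, 5)
        gw = gw / gw.sum()
        for y in years:
            obs = []
            n_fish = int(fish_rng.poisson(base_abund))
            guilds = fish_rng.choice(
                ["scraper", "grazer", "browser", "other-herbivore", "other"],
                size=max(n_fish, 1),
                p=gw,
            )
            tl = fish_rng.lognormal(2.6 + 0.3 * protect, 0.4, max(n_fish, 1))
            for g, L in zip(guilds, tl):
                obs.append(
                    drv.FishObservation(
                        species=f"sp_{g}",
                        count=1,
                        tl_cm=float(L),
                        a=0.02,
                        b=3.0,
                        area_m2=125.0,
                        guild=str(g),
                    )
                )
            smean, ssd, maxdhw = sst_stats[y]
            annual, peak = rain_metrics[y]
            vals = {
                "total_fish_biomass": drv.fish_biomass(obs),
                "herbivore_biomass": drv.fish_biomass(obs, "herbivore"),
                "scraper_biomass": drv.fish_biomass(obs, "scraper"),
                "grazer_biomass": drv.fish_biomass(obs, "grazer"),
                "browser_biomass": drv.fish_biomass(obs, "browser"),
                "population": float(pop_series[y]),
                "wastewater": float(ww["effluent_l_ha_yr"].iloc[cell]),
                "nutrients": float(nut[cell]),
                "urban_runoff": float(imperv.loc[cell, y]),
                "annual_rainfall": annual,
                "peak_rainfall": peak,
                "sediment": float(sed_series[y]),
                "gear_rank": float(gear[i]),
                "sst_mean": smean,
                "sst_sd": ssd,
                "dhw": maxdhw,
                "phytoplankton": float(inputs["phyto_cell"][cell]),
                "irradiance": float(inputs["irrad_cell"][cell]),
                "wave_power": wave_stat[y] * float(inputs["wave_exposure"][i]),
                "depth": float(inputs["depth"][i]),
            }
            for k, v in vals.items():
                records.append((f"reef_{i:03d}", y, k, v))
    return pd.DataFrame(records, columns=["reef_id", "year", "variable", "value"])


def generate_outcomes(bundle: SyntheticBundle, config: SynthConfig | None = None) -> SyntheticBundle:
    """Realize reef outcomes from the injected truth coefficients.

    Three response structures are generated on top of the driver table:

    * a pre-disturbance linear coral-cover trajectory per reef whose slope is
      ``truth_trajectory_effects`` applied to the standardized drivers plus
      Gaussian noise;
    * a heatwave percentage-difference response from
      ``truth_heatwave_effects``;
    * a post-disturbance reef-builder category drawn from the proportional-
      odds model in ``truth_ordinal`` (latent-logistic draw), with a
      reef-builder cover value consistent with the category.
    """
    config = config or bundle.config
    if bundle.driver_table is None or bundle.driver_table.empty:
        raise ValueError("missing driver inputs: generate_coast must run first")
    z = bundle.standardized_drivers()
    missing = [
        k
        for eff in (
            config.truth_trajectory_effects,
            config.truth_heatwave_effects,
            config.truth_ordinal["B"],
        )
        for k in eff
        if k not in z.columns
    ]
    if missing:
        raise ValueError(f"missing driver inputs for truth effects: {sorted(set(missing))}")

    rngs = _streams(config.rng_seed + 1, ["trajectory", "heatwave", "ordinal", "cover"])
    reefs = z.index.to_numpy()
    n = len(reefs)
    years = list(range(config.years[0], config.years[1] + 1))
    hw_year = config.heatwave_year

    def lincomb(effects: Mapping[str, float]) -> np.ndarray:
        out = np.zeros(n)
        for k, b in effects.items():
            out += b * z[k].to_numpy()
        return out

    slope = lincomb(config.truth_trajectory_effects)
    if config.trajectory_noise_sd > 0:
        slope = slope + rngs["trajectory"].normal(0, config.trajectory_noise_sd, n)
    start_cover = 20.0 + 30.0 * rngs["cover"].random(n)

    delta_pct = lincomb(config.truth_heatwave_effects) - 15.0
    if config.heatwave_noise_sd > 0:
        delta_pct = delta_pct + rngs["heatwave"].normal(0, config.heatwave_noise_sd, n)

    eta = lincomb(config.truth_ordinal["B"])
    c1, c2 = config.truth_ordinal["C"]
    # latent-logistic draw: category j when C_{j-1} < eta + e <= C_j
    latent = eta + rngs["ordinal"].logistic(0.0, 1.0, n)
    category = np.where(latent <= c1, "low", np.where(latent <= c2, "moderate", "high"))

    clip_log = []
    records = []
    for j, reef in enumerate(reefs):
        pre_years = [y for y in years if y < hw_year]
        for y in pre_years:
            c = start_cover[j] + slope[j] * (y - pre_years[0])
            if config.cover_noise_sd > 0:
                c += rngs["cover"].normal(0, config.cover_noise_sd)
            if not 0.0 <= c <= 100.0:
                clip_log.append((reef, y, float(c)))
                c = float(np.clip(c, 0.0, 100.0))
            records.append((reef, y, "coral_cover", float(c)))
        a_b = max(start_cover[j] + slope[j] * (hw_year - 1 - pre_years[0]), 1.0)
        a_a = a_b * (1.0 + delta_pct[j] / 100.0)
        if not 0.0 <= a_a <= 100.0:
            clip_log.append((reef, hw_year + 1, float(a_a)))
            a_a = float(np.clip(a_a, 0.0, 100.0))
        records.append((reef, hw_year, "coral_cover", float(a_b)))
        records.append((reef, hw_year + 1, "coral_cover", float(a_a)))
        # post-disturbance reef-builder cover consistent with the category
        u = rngs["cover"].random()
        lo, hi = {"low": (3.0, 15.0), "moderate": (15.0, 35.0), "high": (35.0, 55.0)}[category[j]]
        records.append((reef, years[-1], "reef_builder_cover", float(lo + u * (hi - lo))))
        records.append((reef, years[-1], "reef_builder_category", category[j]))

    bundle.survey_table = pd.DataFrame(records, columns=["reef_id", "year", "variable", "value"])
    bundle.clip_log = clip_log
    bundle.truth = {
        "trajectory_effects": dict(config.truth_trajectory_effects),
        "heatwave_effects": dict(config.truth_heatwave_effects),
        "ordinal": {"C": tuple(config.truth_ordinal["C"]), "B": dict(config.truth_ordinal["B"])},
        "slope": pd.Series(slope, index=reefs),
        "delta_pct": pd.Series(delta_pct, index=reefs),
        "category": pd.Series(category, index=reefs),
        "eta": pd.Series(eta, index=reefs),
    }
    return bundle


def generate(config: SynthConfig | None = None) -> SyntheticBundle:
    """Convenience: generate_coast followed by generate_outcomes."""
    config = config or SynthConfig()
    return generate_outcomes(generate_coast(config), config)
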