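"""Synthetic split-plot field studies for exercising the full pipeline.

Generates a two-level split-plot design (snowmelt manipulation on whole
plots, precipitation manipulation on subplots, repeated over years),
correlated lognormal volatile emissions with configurable plasticity,
soil-moisture structure, and fitness components produced from known true
selection gradients plus seed predation.  Every downstream stage can be
validated against the stored truth without any external data.

All randomness flows through :class:`numpy.random.Generator` objects
derived from a single named seed via ``SeedSequence`` spawning, so studies
are byte-identical under the same seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .volatiles import COMPOUND_CLASSES, DEFAULT_CLASS_STANDARDS

__all__ = [
    "DesignConfig",
    "TrueParams",
    "PlasticityEffect",
    "SimulatedStudy",
    "build_design",
    "simulate_soil_moisture",
    "simulate_plants",
    "simulate_ambient",
    "simulate_dilution_series",
    "simulate_study",
    "write_study",
    "sampling_dates",
    "default_compound_catalog",
    "MORPH_TRAITS",
]

#: (compound, class) catalog: 29 volatiles in four classes.
_CATALOG: tuple[tuple[str, str], ...] = (
    ("alpha-pinene", "monoterpene"),
    ("beta-pinene", "monoterpene"),
    ("limonene", "monoterpene"),
    ("3-carene", "monoterpene"),
    ("sabinene", "monoterpene"),
    ("beta-myrcene", "monoterpene"),
    ("(Z)-beta-ocimene", "monoterpene"),
    ("(E)-beta-ocimene", "monoterpene"),
    ("verbenone", "monoterpene"),
    ("camphene", "monoterpene"),
    ("beta-caryophyllene", "sesquiterpene"),
    ("(Z)-alpha-bergamotene", "sesquiterpene"),
    ("alpha-humulene", "sesquiterpene"),
    ("germacrene D", "sesquiterpene"),
    ("(E,E)-alpha-farnesene", "sesquiterpene"),
    ("delta-cadinene", "sesquiterpene"),
    ("methyl salicylate", "benzenoid"),
    ("methyl benzoate", "benzenoid"),
    ("indole", "benzenoid"),
    ("benzaldehyde", "benzenoid"),
    ("benzyl alcohol", "benzenoid"),
    ("phenylacetaldehyde", "benzenoid"),
    ("hexan-1-ol", "aliphatic"),
    ("(Z)-3-hexen-1-ol", "aliphatic"),
    ("(E)-4-oxohex-2-enal", "aliphatic"),
    ("hexanal", "aliphatic"),
    ("(Z)-3-hexenyl acetate", "aliphatic"),
    ("nonanal", "aliphatic"),
    ("decanal", "aliphatic"),
)

MORPH_TRAITS = (
    "corolla_length",
    "corolla_width",
    "style_length",
    "sepal_width",
    "nectar_production",
    "nectar_concentration",
    "inflorescence_height",
)

_MORPH_MEANS = {
    "corolla_length": 28.0,
    "corolla_width": 3.5,
    "style_length": 30.0,
    "sepal_width": 2.2,
    "nectar_production": 2.5,
    "nectar_concentration": 25.0,
    "inflorescence_height": 40.0,
}
_MORPH_SDS = {
    "corolla_length": 2.5,
    "corolla_width": 0.5,
    "style_length": 2.5,
    "sepal_width": 0.4,
    "nectar_production": 1.2,
    "nectar_concentration": 5.0,
    "inflorescence_height": 12.0,
}

#: detector response (area per ng) of each class's calibration standard
DEFAULT_CLASS_SLOPES = {
    "monoterpene": 1200.0,
    "sesquiterpene": 900.0,
    "benzenoid": 1500.0,
    "aliphatic": 800.0,
}

#: the seven dilution-series standards and their compound classes
STANDARD_CLASSES = {
    "alpha-pinene": "monoterpene",
    "linalool": "monoterpene",
    "beta-caryophyllene": "sesquiterpene",
    "(E,E)-farnesol": "sesquiterpene",
    "methyl salicylate": "benzenoid",
    "indole": "benzenoid",
    "(Z)-3-hexen-1-ol": "aliphatic",
}


def default_compound_catalog() -> dict[str, str]:
    return dict(_CATALOG)


@dataclass
class DesignConfig:
    n_years: int = 3
    plots_per_level: int = 3
    precip_levels: tuple[str, ...] = ("control", "mock", "reduced", "addition")
    control_melt_doy: tuple[int, ...] = (119, 158, 126)
    # advancement of snowmelt in early plots: support [3, 11] d, mean 6 d.
    # "mean6_beta" draws 3 + 8*Beta(3, 5) (mean exactly 6); "uniform" is a
    # flat alternative (mean 7) kept for sensitivity checks.
    advancement_range: tuple[float, float] = (3.0, 11.0)
    advancement_dist: str = "mean6_beta"
    precip_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"reduced": 0.5, "addition": 2.0, "mock": 1.0, "control": 1.0}
    )
    base_precip_mm: float = 120.0
    first_year: int = 2018
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1 or self.plots_per_level < 1:
            raise ValueError("n_years and plots_per_level must be >= 1")
        if len(self.control_melt_doy) < self.n_years:
            raise ValueError("need a control snowmelt day-of-year for every year")
        lo, hi = self.advancement_range
        if not (3.0 <= lo < hi <= 11.0):
            raise ValueError("advancement range must lie within [3, 11] days")
        if self.advancement_dist not in ("mean6_beta", "uniform"):
            raise ValueError("advancement_dist must be 'mean6_beta' or 'uniform'")
        for level, mult in self.precip_multipliers.items():
            if mult < 0:
                raise ValueError(f"negative precipitation multiplier for {level!r}")
        missing = set(self.precip_levels) - set(self.precip_multipliers)
        if missing:
            raise ValueError(f"precip levels without multipliers: {sorted(missing)}")

    @property
    def years(self) -> list[int]:
        return [self.first_year + i for i in range(self.n_years)]


@dataclass
class PlasticityEffect:
    """One plasticity rule applied during simulation.

    ``target`` names a compound, a compound class, a morphological trait,
    or "*" for all volatiles.  ``factor`` selects what drives the effect:
    "snow" (applies under early snowmelt), "precip" (requires ``level``),
    or "moisture" (scaled by VWC deviation from its design mean).  For
    volatiles the effect is a log-scale multiplier; for morphological
    traits it is an additive shift in trait SD units.
    """

    target: str
    factor: str  # "snow" | "precip" | "moisture"
    amount: float
    level: str | None = None


@dataclass
class TrueParams:
    compound_catalog: Mapping[str, str] = field(default_factory=default_compound_catalog)
    baseline_log_means: Mapping[str, float] | None = None
    log_sds: Mapping[str, float] | None = None
    within_class_corr: float = 0.5
    detection_p: float = 0.85
    plasticity_effects: tuple[PlasticityEffect, ...] = ()
    trait_means: Mapping[str, float] = field(default_factory=lambda: dict(_MORPH_MEANS))
    trait_sds: Mapping[str, float] = field(default_factory=lambda: dict(_MORPH_SDS))
    beta_poll: Mapping[str, float] = field(default_factory=dict)
    beta_pred: Mapping[str, float] = field(default_factory=dict)
    # environment-dependent selection: added to beta_poll under early
    # snowmelt, or per day of snowmelt date (centered within the study)
    beta_poll_snow_delta: Mapping[str, float] = field(default_factory=dict)
    beta_poll_melt_slope: Mapping[str, float] = field(default_factory=dict)
    flowers_mean: float = 40.0
    flowers_k: float = 4.0  # negative-binomial dispersion
    attack_baseline: float = 0.15
    fly_fraction: float = 0.875
    abort_p: float = 0.35
    dehisce_p: float = 0.12
    early_collect_p: float = 0.02
    seeds_per_fruit_mean: float = 8.0
    plant_fitness_sd: float = 0.3  # lognormal plant effect on seeds per fruit
    egg_rate: float = 0.25
    multi_sample_p: float = 0.16
    plant_var_share: float = 0.7  # share of log-emission variance between plants
    class_slopes: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_SLOPES))
    contaminants: tuple[tuple[str, float, float], ...] = (
        ("siloxane-D5", 12.4, 5000.0),  # (name, retention time, mean area)
        ("benzophenone", 14.9, 2500.0),
    )
    duration_h: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.within_class_corr < 1:
            raise ValueError("within_class_corr must be in [0, 1)")
        if not 0 < self.attack_baseline < 1:
            raise ValueError("attack_baseline must be in (0, 1)")
        if self.baseline_log_means is None:
            # alpha-pinene dominant, long tail for the rest
            names = list(self.compound_catalog)
            self.baseline_log_means = {
                name: (3.3 if name == "alpha-pinene" else 2.0 - 0.08 * i)
                for i, name in enumerate(names)
            }
        if self.log_sds is None:
            self.log_sds = {name: 1.0 for name in self.compound_catalog}

    @property
    def compounds(self) -> list[str]:
        return list(self.compound_catalog)

    def correlation_matrix(self) -> np.ndarray:
        """Block-diagonal correlation: ``within_class_corr`` inside a class."""
        names = self.compounds
        classes = [self.compound_catalog[c] for c in names]
        R = np.eye(len(names))
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if classes[i] == classes[j]:
                    R[i, j] = R[j, i] = self.within_class_corr
        # positive definite for corr in [0,1); assert to catch bad input
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("within-class correlation matrix is not positive definite")
        return R


@dataclass
class SimulatedStudy:
    design: pd.DataFrame
    peak_table: pd.DataFrame
    trait_table: pd.DataFrame
    fitness_components: pd.DataFrame
    ambient_samples: pd.DataFrame
    dilution_series: pd.DataFrame
    truth: TrueParams
    dilution_slopes: Mapping[str, float] = field(default_factory=dict)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def build_design(config: DesignConfig) -> pd.DataFrame:
    """One row per (year, plot, subplot) with treatments and environment.

    Early plots melt earlier than the year's control date by a uniform
    draw on the advancement range; every whole plot holds all
    precipitation levels exactly once.
    """
    rng = _rng(config.rng_seed)
    lo, hi = config.advancement_range

    def draw_advance() -> float:
        if config.advancement_dist == "uniform":
            return float(rng.uniform(lo, hi))
        return float(lo + (hi - lo) * rng.beta(3.0, 5.0))

    rows = []
    plot_ids = [f"E{i + 1}" for i in range(config.plots_per_level)] + [
        f"C{i + 1}" for i in range(config.plots_per_level)
    ]
    for yi, year in enumerate(config.years):
        control_doy = float(config.control_melt_doy[yi])
        for plot_id in plot_ids:
            early = plot_id.startswith("E")
            melt = control_doy - draw_advance() if early else control_doy
            for si, level in enumerate(config.precip_levels):
                rows.append(
                    {
                        "year": year,
                        "plot_id": plot_id,
                        "snow_treatment": "early" if early else "control",
                        "subplot_id": f"s{si + 1}",
                        "precip_treatment": level,
                        "snowmelt_date": melt,
                        "summer_precip": config.base_precip_mm
                        * config.precip_multipliers[level],
                    }
                )
    return pd.DataFrame(rows)


def simulate_soil_moisture(
    design: pd.DataFrame,
    config: DesignConfig,
    seed: int | np.random.Generator = 0,
    n_plants_per_subplot: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Season subplot VWC (2-8%) and plant-level daily VWC (0-15%).

    Moisture increases stochastically with summer precipitation and with
    later snowmelt.  Returns the design with a ``season_vwc`` column and a
    plant-level table of VWC draws.
    """
    rng = _rng(seed)
    out = design.copy()
    out["season_vwc"] = _season_vwc(out, rng)

    plant_rows = []
    for idx, row in out.iterrows():
        vwc = rng.gamma(3.0, row["season_vwc"] / 3.0, size=n_plants_per_subplot)
        for v in np.clip(vwc, 0.0, 15.0):
            plant_rows.append(
                {
                    "year": row["year"],
                    "plot_id": row["plot_id"],
                    "subplot_id": row["subplot_id"],
                    "plant_vwc": float(v),
                }
            )
    return out, pd.DataFrame(plant_rows)


def _season_vwc(design: pd.DataFrame, rng: np.random.Generator | None) -> np.ndarray:
    """Season-mean subplot VWC: saturating in precipitation, rising with
    later snowmelt, clipped to the observed 2-8% range."""
    precip = design["summer_precip"].to_numpy(float)
    melt = design["snowmelt_date"].to_numpy(float)
    season = (
        2.0
        + 4.0 * precip / (precip + 150.0)  # saturating absolute response
        + 1.5 * np.clip((melt - 100.0) / 60.0, 0.0, 1.0)
    )
    if rng is not None:
        season = season + rng.normal(0, 0.4, len(design))
    return np.clip(season, 2.0, 8.0)


def sampling_dates(year: int, melt_doy: float, n_dates: int = 8) -> list[str]:
    """Deterministic ISO sampling dates for a year, spread after snowmelt."""
    start = int(melt_doy) + 45
    return [
        (pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=start + 4 * k)).date().isoformat()
        for k in range(n_dates)
    ]


def _effect_sum(
    truth: TrueParams,
    target_name: str,
    target_class: str | None,
    snow_early: np.ndarray,
    precip_level: pd.Series,
    vwc_dev: np.ndarray,
) -> np.ndarray:
    """Total plasticity effect for one compound/trait across plants."""
    total = np.zeros(len(snow_early))
    for eff in truth.plasticity_effects:
        if eff.target not in ("*", target_name, target_class):
            continue
        if eff.factor == "snow":
            total = total + eff.amount * snow_early
        elif eff.factor == "precip":
            if eff.level is None:
                raise ValueError("precip plasticity effect needs a level")
            total = total + eff.amount * (precip_level == eff.level).to_numpy(float)
        elif eff.factor == "moisture":
            total = total + eff.amount * vwc_dev
        else:
            raise ValueError(f"unknown plasticity factor {eff.factor!r}")
    return total


def simulate_plants(
    design: pd.DataFrame,
    truth: TrueParams,
    n_plants_per_subplot: int = 5,
    seed: int | np.random.Generator = 0,
    n_plants_total: int | None = None,
    include_peaks: bool = True,
    include_fitness: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate plants: traits, floral peak table, and fitness components.

    Emissions are multivariate lognormal with within-class correlation and
    a per-compound Bernoulli detection gate; expected seeds per flower
    follow a log-linear link in the standardized traits (``beta_poll``) and
    fruit attack follows a logit link (``beta_pred``), with fly eggs
    Poisson-linked to the same preference score.
    """
    if n_plants_per_subplot <= 0 and not n_plants_total:
        raise ValueError("n_plants_per_subplot must be positive")
    rng = _rng(seed)
    n_sub = len(design)
    if n_plants_total is not None:
        if n_plants_total <= 0:
            raise ValueError("n_plants_total must be positive")
        per = np.full(n_sub, n_plants_total // n_sub, int)
        per[: n_plants_total - per.sum()] += 1
    else:
        per = np.full(n_sub, int(n_plants_per_subplot), int)

    if "season_vwc" not in design.columns:
        design = design.copy()
        design["season_vwc"] = _season_vwc(design, None)

    # one row per plant
    plant_design = design.loc[design.index.repeat(per)].reset_index(drop=True)
    n = len(plant_design)
    plant_design["plant_id"] = [
        f"{row.year}-{row.plot_id}-{row.subplot_id}-p{i}"
        for i, row in enumerate(plant_design.itertuples())
    ]
    plant_vwc = np.clip(
        rng.gamma(3.0, plant_design["season_vwc"].to_numpy() / 3.0), 0.0, 15.0
    )
    plant_design["plant_vwc"] = plant_vwc
    vwc_dev = plant_vwc - plant_vwc.mean()
    snow_early = (plant_design["snow_treatment"] == "early").to_numpy(float)
    precip_level = plant_design["precip_treatment"]

    compounds = truth.compounds
    classes = truth.compound_catalog
    R = truth.correlation_matrix()
    chol = np.linalg.cholesky(R)
    sds = np.array([truth.log_sds[c] for c in compounds])
    base = np.array([truth.baseline_log_means[c] for c in compounds])

    # per-plant log-mean including plasticity
    logmu = np.tile(base, (n, 1))
    for j, c in enumerate(compounds):
        logmu[:, j] = logmu[:, j] + _effect_sum(
            truth, c, classes[c], snow_early, precip_level, vwc_dev
        )

    share = truth.plant_var_share
    z_plant = rng.standard_normal((n, len(compounds))) @ chol.T
    plant_log = logmu + np.sqrt(share) * sds * z_plant

    # sample-level draws: every plant has 1 sample, a fraction get a second
    second = rng.random(n) < truth.multi_sample_p
    rt_lookup = {c: 2.5 + 14.0 * i / max(len(compounds) - 1, 1) for i, c in enumerate(compounds)}

    date_lookup: dict[int, list[str]] = {}
    for year, grp in plant_design.groupby("year"):
        date_lookup[year] = sampling_dates(int(year), float(grp["snowmelt_date"].mean()))

    peak_rows = []
    emission_plant_mean = np.zeros((n, len(compounds)))
    sample_noise_sd = np.sqrt(1 - share) * sds
    for i in range(n):
        n_samples = 2 if second[i] else 1
        year = int(plant_design.at[i, "year"])
        per_sample = []
        for s in range(n_samples):
            eps = (rng.standard_normal(len(compounds)) @ chol.T) * sample_noise_sd
            log_e = plant_log[i] + eps
            gate = rng.random(len(compounds)) < truth.detection_p
            emission = np.exp(log_e) * gate
            per_sample.append(emission)
            if not include_peaks:
                continue
            sample_id = f"{plant_design.at[i, 'plant_id']}-smp{s}"
            date = date_lookup[year][int(rng.integers(len(date_lookup[year])))]
            for j, c in enumerate(compounds):
                if emission[j] > 0:
                    peak_rows.append(
                        {
                            "sample_id": sample_id,
                            "plant_id": plant_design.at[i, "plant_id"],
                            "date": date,
                            "sample_type": "floral",
                            "compound": c,
                            "retention_time": rt_lookup[c] + rng.normal(0, 0.02),
                            "peak_area": emission[j]
                            * truth.duration_h
                            * truth.class_slopes[classes[c]],
                        }
                    )
            # contaminant compounds appear in floral samples at ambient-like level
            for name, rt, level in truth.contaminants:
                peak_rows.append(
                    {
                        "sample_id": sample_id,
                        "plant_id": plant_design.at[i, "plant_id"],
                        "date": date,
                        "sample_type": "floral",
                        "compound": name,
                        "retention_time": rt + rng.normal(0, 0.02),
                        "peak_area": max(rng.normal(level * 2.0, level * 0.3), 0.0),
                    }
                )
        emission_plant_mean[i] = np.mean(per_sample, axis=0)

    peak_table = pd.DataFrame(peak_rows)

    # morphological traits with additive plasticity in SD units
    trait_table = plant_design[
        ["plant_id", "year", "plot_id", "subplot_id", "snow_treatment",
         "precip_treatment", "snowmelt_date", "summer_precip", "season_vwc", "plant_vwc"]
    ].copy()
    for t in MORPH_TRAITS:
        shift = _effect_sum(truth, t, None, snow_early, precip_level, vwc_dev)
        trait_table[t] = (
            truth.trait_means[t]
            + truth.trait_sds[t] * (shift + rng.standard_normal(n))
        )
    for j, c in enumerate(compounds):
        trait_table[c] = emission_plant_mean[:, j]
    for cls in COMPOUND_CLASSES:
        cols = [c for c in compounds if classes[c] == cls]
        trait_table[cls + "_total"] = emission_plant_mean[
            :, [compounds.index(c) for c in cols]
        ].sum(axis=1)

    # standardized traits for the fitness links (sample standardization,
    # matching what downstream estimators do)
    def z_of(name: str) -> np.ndarray:
        x = trait_table[name].to_numpy(float)
        sd = x.std(ddof=1)
        if sd == 0:
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    flowers = rng.negative_binomial(
        truth.flowers_k, truth.flowers_k / (truth.flowers_k + truth.flowers_mean), n
    )
    flowers = np.maximum(flowers, 1)
    trait_table["flower_number"] = flowers

    melt_c = (
        plant_design["snowmelt_date"].to_numpy(float)
        - plant_design["snowmelt_date"].mean()
    )
    poll_score = np.zeros(n)
    all_poll = set(truth.beta_poll) | set(truth.beta_poll_snow_delta) | set(
        truth.beta_poll_melt_slope
    )
    for name in all_poll:
        b = (
            truth.beta_poll.get(name, 0.0)
            + truth.beta_poll_snow_delta.get(name, 0.0) * snow_early
            + truth.beta_poll_melt_slope.get(name, 0.0) * melt_c
        )
        poll_score = poll_score + b * z_of(name)
    pred_score = np.zeros(n)
    for name, b in truth.beta_pred.items():
        pred_score += b * z_of(name)

    early_cnt = rng.binomial(flowers, truth.early_collect_p)
    at_risk = flowers - early_cnt
    aborted = rng.binomial(at_risk, truth.abort_p)
    nonaborted = at_risk - aborted
    logit0 = np.log(truth.attack_baseline / (1 - truth.attack_baseline))
    p_attack = 1.0 / (1.0 + np.exp(-(logit0 + pred_score)))
    attacked = rng.binomial(nonaborted, p_attack)
    fly = rng.binomial(attacked, truth.fly_fraction)
    caterpillar = attacked - fly
    noneaten = nonaborted - attacked
    plant_eps = rng.normal(0, truth.plant_fitness_sd, n)
    seed_mu = truth.seeds_per_fruit_mean * np.exp(poll_score + plant_eps)
    dehisced = rng.binomial(noneaten, truth.dehisce_p)
    intact = noneaten - dehisced
    eggs = rng.poisson(flowers * truth.egg_rate * np.exp(pred_score))

    if not include_fitness:
        return trait_table, peak_table, pd.DataFrame()

    fit_rows = []
    for i in range(n):
        counts = rng.poisson(seed_mu[i], size=int(intact[i]))
        fit_rows.append(
            {
                "plant_id": plant_design.at[i, "plant_id"],
                "year": int(plant_design.at[i, "year"]),
                "plot_id": plant_design.at[i, "plot_id"],
                "subplot_id": plant_design.at[i, "subplot_id"],
                "flowers_total": int(flowers[i]),
                "aborted": int(aborted[i]),
                "intact_seed_counts": ";".join(str(int(x)) for x in counts),
                "fruits_dehisced": int(dehisced[i]),
                "fruits_fly": int(fly[i]),
                "fruits_caterpillar": int(caterpillar[i]),
                "flowers_collected_early": int(early_cnt[i]),
                "eggs_total": int(eggs[i]),
                "flowers_surveyed": int(flowers[i]),
            }
        )
    fitness_components = pd.DataFrame(fit_rows)
    return trait_table, peak_table, fitness_components


def simulate_ambient(
    design: pd.DataFrame,
    truth: TrueParams,
    contamination_level: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """At least one ambient air control per sampling date.

    Real floral compounds appear in ambient air at a small fraction of
    floral levels scaled by ``contamination_level`` (0 means clean air);
    listed contaminant compounds appear at levels comparable to floral
    samples so the four-fold ambient-ratio filter has something to catch.
    """
    if contamination_level < 0:
        raise ValueError("contamination_level must be nonnegative")
    rng = _rng(seed)
    compounds = truth.compounds
    classes = truth.compound_catalog
    rt_lookup = {c: 2.5 + 14.0 * i / max(len(compounds) - 1, 1) for i, c in enumerate(compounds)}
    rows = []
    k = 0
    for year, grp in design.groupby("year"):
        dates = sampling_dates(int(year), float(grp["snowmelt_date"].mean()))
        for date in dates:
            sample_id = f"ambient-{year}-{k}"
            k += 1
            for c in compounds:
                typical_area = (
                    np.exp(truth.baseline_log_means[c])
                    * truth.duration_h
                    * truth.class_slopes[classes[c]]
                )
                area = contamination_level * 0.02 * typical_area * rng.random()
                rows.append(
                    {
                        "sample_id": sample_id,
                        "plant_id": "",
                        "date": date,
                        "sample_type": "ambient",
                        "compound": c,
                        "retention_time": rt_lookup[c] + rng.normal(0, 0.02),
                        "peak_area": float(area),
                    }
                )
            for name, rt, level in truth.contaminants:
                area = (
                    max(rng.normal(level, level * 0.3), 0.0)
                    if contamination_level > 0
                    else 0.0
                )
                rows.append(
                    {
                        "sample_id": sample_id,
                        "plant_id": "",
                        "date": date,
                        "sample_type": "ambient",
                        "compound": name,
                        "retention_time": rt + rng.normal(0, 0.02),
                        "peak_area": float(area),
                    }
                )
    return pd.DataFrame(rows)


def simulate_dilution_series(
    standards: Sequence[str] | None = None,
    dosages: Sequence[float] | None = None,
    replicates: int = 10,
    noise_cv: float = 0.05,
    seed: int | np.random.Generator = 0,
    true_slopes: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Dilution series: area = slope * dosage * (1 + noise); slope stored as truth."""
    if replicates < 2:
        raise ValueError("need at least 2 replicates per dosage for a variance estimate")
    rng = _rng(seed)
    standards = list(standards) if standards is not None else list(STANDARD_CLASSES)
    dosages = list(dosages) if dosages is not None else [1.0, 2.0, 5.0, 10.0, 20.0, 50.0]
    arr = np.asarray(dosages, float)
    if (arr <= 0).any() or (np.diff(arr) <= 0).any():
        raise ValueError("dosages must be strictly positive and increasing")
    if true_slopes is None:
        true_slopes = {
            s: DEFAULT_CLASS_SLOPES[STANDARD_CLASSES.get(s, "monoterpene")]
            for s in standards
        }
    rows = []
    for s in standards:
        slope = true_slopes[s]
        for d in dosages:
            noise = noise_cv * rng.standard_normal(replicates)
            for a in slope * d * (1.0 + noise):
                rows.append({"standard": s, "dosage_ng": d, "peak_area": max(float(a), 0.0)})
    return pd.DataFrame(rows), dict(true_slopes)


def simulate_study(
    config: DesignConfig | None = None,
    truth: TrueParams | None = None,
    n_plants_per_subplot: int = 5,
    seed: int = 0,
    contamination_level: float = 1.0,
    n_plants_total: int | None = None,
    dilution_noise_cv: float = 0.05,
) -> SimulatedStudy:
    """Assemble a full synthetic study from one seed."""
    config = config or DesignConfig(rng_seed=seed)
    truth = truth or TrueParams()
    children = np.random.SeedSequence(seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in children]

    design = build_design(dataclasses.replace(config, rng_seed=int(children[0].generate_state(1)[0])))
    design, _ = simulate_soil_moisture(design, config, rngs[1])
    trait_table, peak_table, fitness_components = simulate_plants(
        design, truth, n_plants_per_subplot, rngs[2], n_plants_total=n_plants_total
    )
    ambient = simulate_ambient(design, truth, contamination_level, rngs[3])
    dilution, slopes = simulate_dilution_series(
        noise_cv=dilution_noise_cv, seed=rngs[4]
    )
    return SimulatedStudy(
        design=design,
        peak_table=peak_table,
        trait_table=trait_table,
        fitness_components=fitness_components,
        ambient_samples=ambient,
        dilution_series=dilution,
        truth=truth,
        dilution_slopes=slopes,
    )


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the five CSV inputs plus a truth.json of generator parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "design": study.design,
        "peak_table": pd.concat([study.peak_table, study.ambient_samples], ignore_index=True),
        "trait_table": study.trait_table,
        "fitness_components": study.fitness_components,
        "dilution_series": study.dilution_series,
    }
    for name, frame in tables.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    truth_path = outdir / "truth.json"
    payload = _jsonable(study.truth)
    payload["dilution_slopes"] = _jsonable(dict(study.dilution_slopes))
    truth_path.write_text(json.dumps(payload, indent=2))
    paths["truth"] = truth_path
    return paths
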