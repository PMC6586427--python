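"""Synthetic mesocosm-experiment generator.

Emulates a 30-tank outdoor warming experiment: 10 heater power levels
(0-450 W in 50 W steps) crossed with three trophic treatments — algae only
(A), algae + grazers (AG), algae + grazers + predators (AGP) — observed
weekly in weeks 2-9 (240 ecosystem-weeks).  Generated features:

* a declining seasonal temperature baseline with heater offsets; tanks at
  the same power level share a thermal environment (pairwise-comparable
  temperatures, as in the experiment);
* ln-linear Boltzmann-Arrhenius structure in chlorophyll-a and in the latent
  NEP/ER fluxes, with treatment-specific between-ecosystem slopes,
  tank-level random intercepts and lognormal residual noise;
* dawn/dusk/dawn dissolved-oxygen profiles constructed by inverting the
  flux estimators, so the estimators recover the latent fluxes exactly;
* Poisson zooplankton counts per 10 L (Daphnia with a predator effect on
  ln density, copepods declining with temperature), sampled weeks 4-9 in
  the 20 grazer tanks;
* a configurable fraction of missing diel-oxygen records (default 21/240).

A single root seed feeds named substreams per component, so changing e.g.
zooplankton settings does not perturb the temperature draws.  The
generating parameters and realized random intercepts are returned as a
:class:`SyntheticTruth` sidecar so recovery errors are exactly computable.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .oxygen import equilibrium_oxygen
from .units import PhysicalConstants, celsius_to_kelvin, inv_kT

__all__ = [
    "TemperatureModel",
    "ResponseModel",
    "ZooplanktonModel",
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_temperatures",
    "simulate_chla",
    "simulate_diel_oxygen",
    "simulate_zooplankton",
    "generate_experiment",
]


@dataclass(frozen=True)
class TemperatureModel:
    """Weekly mean water temperature: declining seasonal baseline plus a
    heater offset proportional to power, plus shared weekly weather noise.

    Defaults put tank means on a 19.7-26.1 C gradient with within-tank SD
    near 3.1 C (trend + weather)."""

    baseline_start: float = 23.9   # C in week 2, unheated
    weekly_decline: float = 1.2    # C per week
    heater_gain: float = 6.4 / 4.5  # C per 100 W
    weekly_noise_sd: float = 1.5   # C, shared within a power level


@dataclass(frozen=True)
class ResponseModel:
    """Generating coefficients of one ln response on the centered
    inverse-temperature covariates (within/between decomposition).

    ``b_z`` / ``b_z_between`` / ``b_z_within`` map treatment code to the
    treatment offset and its temperature interactions (A is reference).
    """

    beta0: float
    b_within: float
    b_between: float
    b_within_between: float = 0.0
    b_z: dict[str, float] = field(default_factory=dict)
    b_z_between: dict[str, float] = field(default_factory=dict)
    b_z_within: dict[str, float] = field(default_factory=dict)
    var_group: float = 0.01
    var_resid: float = 0.12


def _default_chla() -> ResponseModel:
    # AG between-slope 1.30 + 4.0 = 5.3 eV: chlorophyll spans ~3 orders of
    # magnitude per 10 C of between-ecosystem warming.
    return ResponseModel(beta0=2.05, b_within=-0.52, b_between=1.30,
                         b_z={"AG": -0.8, "AGP": -0.3},
                         b_z_between={"AG": 4.0, "AGP": 0.0})


def _default_nep() -> ResponseModel:
    return ResponseModel(beta0=-6.15, b_within=0.29, b_between=-1.40,
                         b_z={"AG": 0.2, "AGP": 0.3},
                         b_z_between={"AG": 0.4, "AGP": 0.8})


def _default_er() -> ResponseModel:
    return ResponseModel(beta0=-5.79, b_within=0.11, b_between=-1.32,
                         b_z={"AG": 0.1, "AGP": 0.2},
                         b_z_between={"AG": 0.4, "AGP": 0.9})


@dataclass(frozen=True)
class ZooplanktonModel:
    """Poisson counts per 10 L with log-mean linear in centered 1/kT.

    Daphnia: no temperature trend, predators lower ln density by 0.23.
    Copepods: density declines with warming (positive slope on 1/kT).
    Counts are emitted for weeks >= ``first_week`` in AG/AGP tanks only.
    """

    daphnia_log_mean: float = 1.0
    daphnia_slope: float = 0.0
    daphnia_predator_effect: float = -0.23
    copepod_log_mean: float = 1.5
    copepod_slope: float = 1.21
    first_week: int = 4


@dataclass(frozen=True)
class SyntheticConfig:
    """Full study design plus generating parameters."""

    n_power_levels: int = 10
    watts_step: float = 50.0
    treatments: tuple[str, ...] = ("A", "AG", "AGP")
    weeks: tuple[int, ...] = tuple(range(2, 10))
    seed: int = 0
    temp_model: TemperatureModel = TemperatureModel()
    chla_model: ResponseModel = field(default_factory=_default_chla)
    nep_model: ResponseModel = field(default_factory=_default_nep)
    er_model: ResponseModel = field(default_factory=_default_er)
    zoop_model: ZooplanktonModel = ZooplanktonModel()
    missing_flux_fraction: float = 21.0 / 240.0
    diel_amplitude_C: float = 2.0   # dusk minus weekly mean
    overnight_drop_C: float = 0.5   # second dawn below first dawn

    @property
    def watts(self) -> np.ndarray:
        return np.arange(self.n_power_levels) * self.watts_step

    def tank_ids(self) -> list[tuple[str, float, str]]:
        """(tank_id, watts, treatment) for the full crossed design."""
        return [(f"{trt}-{int(w):03d}", float(w), trt)
                for w in self.watts for trt in self.treatments]


@dataclass
class SyntheticTruth:
    """Generating parameters and realized latent quantities."""

    config: SyntheticConfig
    tank_intercepts: dict[str, dict[str, float]]
    latent: pd.DataFrame  # per row: true ln chla, true NEP/ER fluxes

    def to_json(self, path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "tank_intercepts": self.tank_intercepts,
            "latent": self.latent.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ("temperature", "chla", "flux", "zooplankton", "missing")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_temperatures(config: SyntheticConfig,
                          rng: np.random.Generator | None = None
                          ) -> pd.DataFrame:
    """Weekly mean temperature per tank: one row per (tank, week).

    T(tank, week) = baseline_start - weekly_decline*(week - first_week)
    + heater_gain * watts/100 + weather noise shared across the treatments
    at the same power level.
    """
    rng = rng or _substreams(config.seed)["temperature"]
    tm = config.temp_model
    weeks = np.asarray(config.weeks)
    noise = rng.normal(0.0, tm.weekly_noise_sd,
                       size=(config.n_power_levels, len(weeks)))
    rows = []
    for ip, w in enumerate(config.watts):
        base = (tm.baseline_start - tm.weekly_decline * (weeks - weeks[0])
                + tm.heater_gain * w / 100.0 + noise[ip])
        for trt in config.treatments:
            for iw, wk in enumerate(weeks):
                rows.append((f"{trt}-{int(w):03d}", float(w), trt, int(wk),
                             float(base[iw])))
    return pd.DataFrame(rows, columns=["tank_id", "watts", "treatment",
                                       "week", "temp_week_C"])


def _centered_covariates(temps: pd.DataFrame,
                         constants: PhysicalConstants
                         ) -> tuple[np.ndarray, np.ndarray]:
    x = inv_kT(celsius_to_kelvin(temps["temp_week_C"].to_numpy()), constants)
    s = pd.Series(x, index=temps.index)
    tank_mean = s.groupby(temps["tank_id"]).transform("mean")
    grand = float(s.groupby(temps["tank_id"]).mean().mean())
    return (s - tank_mean).to_numpy(), (tank_mean - grand).to_numpy()


def _ln_response(temps: pd.DataFrame, model: ResponseModel,
                 rng: np.random.Generator, constants: PhysicalConstants
                 ) -> tuple[np.ndarray, dict[str, float]]:
    x_w, x_b = _centered_covariates(temps, constants)
    trt = temps["treatment"].to_numpy()
    tanks = pd.unique(temps["tank_id"])
    u = dict(zip(tanks, rng.normal(0.0, np.sqrt(model.var_group),
                                   size=len(tanks))))
    eta = (model.beta0 + model.b_within * x_w + model.b_between * x_b
           + model.b_within_between * x_w * x_b)
    eta = eta + np.array([model.b_z.get(t, 0.0) for t in trt])
    eta = eta + np.array([model.b_z_between.get(t, 0.0) for t in trt]) * x_b
    eta = eta + np.array([model.b_z_within.get(t, 0.0) for t in trt]) * x_w
    eta = eta + temps["tank_id"].map(u).to_numpy()
    eta = eta + rng.normal(0.0, np.sqrt(model.var_resid), size=len(temps))
    return eta, u


def simulate_chla(config: SyntheticConfig, temps: pd.DataFrame,
                  rng: np.random.Generator | None = None,
                  constants: PhysicalConstants = PhysicalConstants()
                  ) -> tuple[np.ndarray, dict[str, float]]:
    """Chlorophyll-a (ug/L) per tank-week; returns values and the realized
    tank random intercepts."""
    rng = rng or _substreams(config.seed)["chla"]
    ln_chla, u = _ln_response(temps, config.chla_model, rng, constants)
    return np.exp(ln_chla), u


def simulate_diel_oxygen(config: SyntheticConfig, temps: pd.DataFrame,
                         rng: np.random.Generator | None = None,
                         constants: PhysicalConstants = PhysicalConstants()
                         ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Diel DO profiles whose estimator output equals the latent fluxes.

    Latent NEP and ER (umol O2/L/h) follow the ln-linear generating models;
    dawn DO is anchored at the saturation value for the dawn temperature and
    dusk / second-dawn readings are constructed by inverting the corrected
    flux estimators.  Returns (diel columns, latent fluxes, intercepts).
    """
    rng = rng or _substreams(config.seed)["flux"]
    ln_nep, u_nep = _ln_response(temps, config.nep_model, rng, constants)
    ln_er, u_er = _ln_response(temps, config.er_model, rng, constants)
    nep, er = np.exp(ln_nep), np.exp(ln_er)

    t_mean = temps["temp_week_C"].to_numpy()
    temp_dawn = t_mean - config.diel_amplitude_C
    temp_dusk = t_mean + config.diel_amplitude_C
    temp_dawn2 = temp_dawn - config.overnight_drop_C
    t_dawn, t_dusk, t_dawn2 = 6.0, 18.0, 30.0

    sat_dawn = equilibrium_oxygen(temp_dawn)
    sat_dusk = equilibrium_oxygen(temp_dusk)
    sat_dawn2 = equilibrium_oxygen(temp_dawn2)
    o2_dawn = sat_dawn
    o2_dusk = (o2_dawn + nep * (t_dusk - t_dawn) / constants.z
               + (sat_dusk - sat_dawn))
    o2_dawn2 = (o2_dusk - er * (t_dawn2 - t_dusk) / constants.z
                + (sat_dawn2 - sat_dusk))
    for arr in (o2_dusk, o2_dawn2):
        neg = arr < 0
        if neg.any():
            warnings.warn(f"{int(neg.sum())} constructed DO readings were "
                          "negative; clipped to 0", stacklevel=2)
            arr[neg] = 0.0

    diel = pd.DataFrame({
        "o2_dawn": o2_dawn, "o2_dusk": o2_dusk, "o2_dawn2": o2_dawn2,
        "temp_dawn_C": temp_dawn, "temp_dusk_C": temp_dusk,
        "temp_dawn2_C": temp_dawn2,
        "t_dawn": t_dawn, "t_dusk": t_dusk, "t_dawn2": t_dawn2,
    }, index=temps.index)
    latent = pd.DataFrame({"true_nep": nep, "true_er": er},
                          index=temps.index)
    return diel, latent, {"nep": u_nep, "er": u_er}


def simulate_zooplankton(config: SyntheticConfig, temps: pd.DataFrame,
                         rng: np.random.Generator | None = None,
                         constants: PhysicalConstants = PhysicalConstants()
                         ) -> pd.DataFrame:
    """Poisson Daphnia and copepod counts per 10 L.

    Emitted only for AG/AGP tanks in weeks >= ``first_week``; all other
    rows carry missing counts (algae-only tanks hold no zooplankton and
    early weeks were not sampled)."""
    rng = rng or _substreams(config.seed)["zooplankton"]
    zm = config.zoop_model
    x = inv_kT(celsius_to_kelvin(temps["temp_week_C"].to_numpy()), constants)
    x = x - x.mean()
    sampled = (temps["treatment"].isin(["AG", "AGP"]).to_numpy()
               & (temps["week"].to_numpy() >= zm.first_week))
    pred = (temps["treatment"] == "AGP").to_numpy().astype(float)

    lam_d = np.exp(zm.daphnia_log_mean + zm.daphnia_slope * x
                   + zm.daphnia_predator_effect * pred)
    lam_c = np.exp(zm.copepod_log_mean + zm.copepod_slope * x)
    daphnia = np.where(sampled, rng.poisson(lam_d), np.nan)
    copepod = np.where(sampled, rng.poisson(lam_c), np.nan)
    return pd.DataFrame({"daphnia_per10L": daphnia,
                         "copepod_per10L": copepod}, index=temps.index)


def generate_experiment(config: SyntheticConfig = SyntheticConfig(),
                        constants: PhysicalConstants = PhysicalConstants()
                        ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate one complete synthetic experiment.

    Returns the canonical-schema observation table (240 rows for the default
    design) and the :class:`SyntheticTruth` sidecar.  Fully deterministic
    under a fixed config (byte-identical CSV output).
    """
    rngs = _substreams(config.seed)
    temps = simulate_temperatures(config, rngs["temperature"])
    chla, u_chla = simulate_chla(config, temps, rngs["chla"])
    diel, latent, u_flux = simulate_diel_oxygen(config, temps, rngs["flux"])
    zoop = simulate_zooplankton(config, temps, rngs["zooplankton"])

    n_missing = int(round(config.missing_flux_fraction * len(temps)))
    if n_missing:
        drop = rngs["missing"].choice(len(temps), size=n_missing,
                                      replace=False)
        diel.iloc[drop] = np.nan

    df = pd.concat([temps, pd.Series(chla, index=temps.index,
                                     name="chla_ug_L"), diel, zoop], axis=1)
    df = df[["tank_id", "treatment", "watts", "week", "temp_week_C",
             "chla_ug_L", "o2_dawn", "o2_dusk", "o2_dawn2",
             "t_dawn", "t_dusk", "t_dawn2",
             "temp_dawn_C", "temp_dusk_C", "temp_dawn2_C",
             "daphnia_per10L", "copepod_per10L"]]

    latent = latent.copy()
    latent["flux_missing"] = diel["o2_dawn"].isna().to_numpy()
    truth = SyntheticTruth(
        config=config,
        tank_intercepts={"chla": {k: float(v) for k, v in u_chla.items()},
                         "nep": {k: float(v) for k, v in u_flux["nep"].items()},
                         "er": {k: float(v) for k, v in u_flux["er"].items()}},
        latent=latent)
    return df, truth
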