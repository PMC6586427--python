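"""Mixed-model inference: nested model sets, AICc ranking, coefficient
pooling into composite activation energies.

The core statistical model is a Gaussian random-intercept LMM fit by maximum
likelihood (ML, not REML, because the model sets compared differ in their
fixed effects).  For a ln response y of ecosystem j in week w:

    y_wj = b0 + b1*x_within + b2*x_between + b3*x_within*x_between
           + b4*Z_j + b5*Z_j*x_between + b6*Z_j*x_within + u_j + e_wj

with x_within / x_between the centered inverse-temperature covariates
(eV^-1), Z_j treatment indicators (A reference), u_j ~ N(0, var_group), and
e_wj ~ N(0, var_resid).  Parameter count for AICc is the number of fixed
effects plus the two variance components.

Candidate models form a nested ladder (term subsets respect marginality);
they are ranked by the small-sample Akaike criterion

    AICc = -2 logL + 2p + 2p(p+1)/(n - p - 1)

with Akaike weights w_i = exp(-delta_i/2) / sum exp(-delta/2).  Models
within delta AICc < 2 are treated as equivalent; coefficients may then be
conditionally model-averaged (renormalized weights over the models that
contain the term).

Composite quantities pool coefficients: the between-ecosystem slope for
treatment t is b2 + b5[t], its intercept b0 + b4[t], and the reported
temperature dependence is E = -slope with a normal-approximation CI from
the fixed-effect covariance (half-width 1.96 * sqrt(c' V c)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as scipy_stats

from .units import activation_energy_from_slope

__all__ = [
    "LmmSpec",
    "LmmFit",
    "ModelComparison",
    "PooledEffect",
    "MODEL_SETS",
    "fit_lmm",
    "aicc",
    "akaike_weights",
    "rank_models",
    "model_average_conditional",
    "pool_effects",
    "pool_within_effects",
    "composite_ci",
    "cascade_temperature_dependence",
    "run_model_set",
]

# Term -> design columns.  Multi-column entries are treatment dummies.
_TERM_COLUMNS = {
    # within/between family (phytoplankton biomass, NEP, ER)
    "x_within": ["x_within"],
    "x_between": ["x_between"],
    "x_within:x_between": ["x_within:x_between"],
    "Z": ["z_ag", "z_agp"],
    "Z:x_between": ["z_ag:x_between", "z_agp:x_between"],
    "Z:x_within": ["z_ag:x_within", "z_agp:x_within"],
    # trophic-cascade family
    "week": ["week_c"],
    "x_within:week": ["x_within:week_c"],
    # zooplankton family
    "x_temp": ["x_temp"],
    "z_pred": ["z_pred"],
    "x_temp:z_pred": ["x_temp:z_pred"],
}

_MARGINALITY = {
    "x_within:x_between": {"x_within", "x_between"},
    "Z:x_between": {"Z", "x_between"},
    "Z:x_within": {"Z", "x_within"},
    "x_within:week": {"x_within", "week"},
    "x_temp:z_pred": {"x_temp", "z_pred"},
}


@dataclass(frozen=True)
class LmmSpec:
    """One candidate model: a named subset of fixed-effect terms plus the
    random-intercept grouping key.  The intercept is always present."""

    name: str
    terms: tuple[str, ...]
    grouping: str = "tank_id"

    def __post_init__(self) -> None:
        for t in self.terms:
            need = _MARGINALITY.get(t, set())
            if not need <= set(self.terms):
                raise ValueError(
                    f"{self.name}: interaction {t} requires main effects {need}")


def _nested_ladder(prefix: str, full_name: str) -> list[LmmSpec]:
    """The ten-model within/between ladder used for each ln response."""
    w, b, z = "x_within", "x_between", "Z"
    return [
        LmmSpec(f"{prefix}0", ()),
        LmmSpec(f"{prefix}1", (z,)),
        LmmSpec(f"{prefix}2", (w,)),
        LmmSpec(f"{prefix}3", (w, b)),
        LmmSpec(f"{prefix}4", (w, b, "x_within:x_between")),
        LmmSpec(f"{prefix}5", (w, z)),
        LmmSpec(f"{prefix}6", (w, z, "Z:x_within")),
        LmmSpec(f"{prefix}7", (w, b, z, "Z:x_between")),
        LmmSpec(f"{prefix}8", (w, b, z, "Z:x_between", "Z:x_within")),
        LmmSpec(full_name, (w, b, z, "Z:x_between", "Z:x_within",
                            "x_within:x_between")),
    ]


def _cascade_set() -> list[LmmSpec]:
    g = "watts"
    return [
        LmmSpec("TCFull", ("x_within", "week", "x_within:week"), g),
        LmmSpec("TCmC", ("x_within", "week"), g),
        LmmSpec("TCmE", ("week",), g),
        LmmSpec("TCmD", ("x_within",), g),
        LmmSpec("TCmF", (), g),
    ]


def _zoop_set(prefix: str) -> list[LmmSpec]:
    return [
        LmmSpec(f"{prefix}c", ()),
        LmmSpec(f"{prefix}b", ("x_temp",)),
        LmmSpec(f"{prefix}a", ("z_pred",)),
        LmmSpec(f"{prefix}d", ("x_temp", "z_pred")),
        LmmSpec(prefix, ("x_temp", "z_pred", "x_temp:z_pred")),
    ]


MODEL_SETS: dict[str, list[LmmSpec]] = {
    "phyto_biomass": _nested_ladder("PB", "PBF"),
    "nep": _nested_ladder("NEP", "NEPF"),
    "er": _nested_ladder("ER", "ERF"),
    "cascade": _cascade_set(),
    "zoop_total": _zoop_set("Z1"),
    "daphnia": _zoop_set("D1"),
    "copepod": _zoop_set("C1"),
}


@dataclass
class LmmFit:
    """A fitted random-intercept model."""

    spec: LmmSpec
    beta: pd.Series
    vcov: pd.DataFrame
    var_group: float
    var_resid: float
    loglik: float
    n_params: int
    n_obs: int
    n_groups: int
    random_effects: dict = field(default_factory=dict, repr=False)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.n_params, self.n_obs)


@dataclass
class ModelComparison:
    """A ranked model set (ascending AICc)."""

    fits: list[LmmFit]
    aicc_values: np.ndarray
    delta_aicc: np.ndarray
    weights: np.ndarray

    @property
    def best(self) -> LmmFit:
        return self.fits[0]

    def equivalence_set(self, threshold: float = 2.0) -> list[LmmFit]:
        """Models within ``threshold`` delta AICc of the best."""
        return [f for f, d in zip(self.fits, self.delta_aicc) if d < threshold]

    def to_table(self) -> pd.DataFrame:
        """Selection table: Mod, Int, term columns, df, logLik, AICc,
        dAICc, w.  Single-column terms print their coefficient, treatment
        terms print '+', absent terms 'NA'."""
        all_terms: list[str] = []
        for f in self.fits:
            for t in f.spec.terms:
                if t not in all_terms:
                    all_terms.append(t)
        rows = []
        for f, a, d, w in zip(self.fits, self.aicc_values, self.delta_aicc,
                              self.weights):
            row = {"Mod": f.spec.name,
                   "Int": round(float(f.beta["Intercept"]), 2)}
            for t in all_terms:
                if t not in f.spec.terms:
                    row[t] = "NA"
                else:
                    cols = _TERM_COLUMNS[t]
                    row[t] = (round(float(f.beta[cols[0]]), 2)
                              if len(cols) == 1 else "+")
            row.update({"df": f.n_params,
                        "logLik": round(f.loglik, 2),
                        "AICc": round(float(a), 2),
                        "dAICc": round(float(d), 2),
                        "w": round(float(w), 2)})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PooledEffect:
    """A composite slope on 1/kT and the activation energy it implies.

    ``slope`` is the pooled coefficient (eV); ``E = -slope`` is the reported
    temperature dependence with 95% normal CI [ci_low, ci_high] on the E
    scale; ``intercept`` the pooled intercept.
    """

    treatment: str
    scope: str
    slope: float
    E: float
    ci_low: float
    ci_high: float
    intercept: float


def _design_matrix(design: pd.DataFrame, spec: LmmSpec) -> pd.DataFrame:
    cols = {"Intercept": np.ones(len(design))}
    for term in spec.terms:
        for c in _TERM_COLUMNS[term]:
            if c in design.columns:
                cols[c] = design[c].to_numpy(dtype=float)
            elif ":" in c:
                a, b = c.split(":")
                cols[c] = (design[a].to_numpy(dtype=float)
                           * design[b].to_numpy(dtype=float))
            else:
                raise ValueError(f"design lacks column {c!r} for term {term!r}")
    return pd.DataFrame(cols, index=design.index)


def _ml_ols(y: np.ndarray, X: pd.DataFrame, spec: LmmSpec,
            n_groups: int, n_params: int | None = None) -> LmmFit:
    # Closed-form ML fit with the group variance fixed at zero.  Also serves
    # as the boundary solution when the LMM group variance converges to 0
    # (then n_params still counts the boundary variance component).
    beta, _, rank, _ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(f"{spec.name}: singular design matrix "
                         f"(columns {list(X.columns)})")
    resid = y - X.to_numpy() @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n
    llf = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    vcov = sigma2 * np.linalg.inv(X.to_numpy().T @ X.to_numpy())
    return LmmFit(spec=spec, beta=pd.Series(beta, index=X.columns),
                  vcov=pd.DataFrame(vcov, index=X.columns, columns=X.columns),
                  var_group=0.0, var_resid=sigma2, loglik=llf,
                  n_params=n_params or X.shape[1] + 1, n_obs=n,
                  n_groups=n_groups)


def fit_lmm(design: pd.DataFrame, spec: LmmSpec,
            zero_group_variance: bool = False) -> LmmFit:
    """Fit one random-intercept LMM by maximum likelihood.

    ``design`` must carry a ``y`` column, the covariate columns the spec's
    terms need, and the grouping column.  With ``zero_group_variance`` the
    group variance is fixed at 0 and the fit reduces to closed-form OLS with
    the ML residual variance (used when only a single group is available).

    Raises on a rank-deficient design (naming the columns) and on
    non-convergence.
    """
    y = design["y"].to_numpy(dtype=float)
    X = _design_matrix(design, spec)
    groups = design[spec.grouping].to_numpy()
    n_groups = len(pd.unique(groups))
    if zero_group_variance or n_groups == 1:
        return _ml_ols(y, X, spec, n_groups)
    if n_groups < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"{spec.name}: singular design matrix "
                         f"(columns {list(X.columns)})")

    k = X.shape[1]
    # The var_group = 0 boundary solution is available in closed form; keep
    # it as a candidate so optimizer failures near the boundary are handled
    # by likelihood comparison rather than trust in convergence flags.
    boundary_fit = _ml_ols(y, X, spec, n_groups, n_params=k + 2)
    model = sm.MixedLM(y, X, groups=groups)
    res = None
    for method in ("powell", "cg", "bfgs"):
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand = model.fit(reml=False, method=[method])
        except (np.linalg.LinAlgError, ValueError):
            continue
        if not np.isfinite(cand.llf):
            continue
        if res is None or cand.llf > res.llf:
            res = cand
        if cand.converged and cand.llf >= boundary_fit.loglik - 1e-6:
            break
    if res is None or res.llf <= boundary_fit.loglik + 1e-8:
        return boundary_fit
    if not res.converged:
        raise RuntimeError(
            f"{spec.name}: LMM did not converge "
            f"(n={len(y)}, groups={n_groups}, params={res.params})")
    vcov = pd.DataFrame(np.asarray(res.cov_params())[:k, :k],
                        index=X.columns, columns=X.columns)
    var_group = float(res.cov_re.iloc[0, 0])
    re = {g: float(v.iloc[0]) for g, v in res.random_effects.items()}
    return LmmFit(spec=spec, beta=pd.Series(res.fe_params, index=X.columns),
                  vcov=vcov, var_group=var_group,
                  var_resid=float(res.scale), loglik=float(res.llf),
                  n_params=k + 2, n_obs=len(y), n_groups=n_groups,
                  random_effects=re)


def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Small-sample Akaike criterion
    -2 logL + 2p + 2p(p+1)/(n - p - 1)."""
    denom = n_obs - n_params - 1
    if denom <= 0:
        raise ValueError(f"AICc undefined: n_obs={n_obs} <= n_params+1="
                         f"{n_params + 1}")
    return -2.0 * loglik + 2.0 * n_params + 2.0 * n_params * (n_params + 1) / denom


def akaike_weights(delta_aicc) -> np.ndarray:
    """Akaike weights exp(-delta/2), normalized over the model set."""
    rel = np.exp(-np.asarray(delta_aicc, dtype=float) / 2.0)
    return rel / rel.sum()


def rank_models(fits: list[LmmFit]) -> ModelComparison:
    """Rank fitted models by AICc; delta AICc and Akaike weights.

    All fits must share the same observation set (checked via n_obs);
    otherwise likelihoods are not comparable.
    """
    if not fits:
        raise ValueError("rank_models requires at least one fit")
    n_set = {f.n_obs for f in fits}
    if len(n_set) > 1:
        raise ValueError(f"fits on differing observation counts: {n_set}")
    a = np.array([f.aicc for f in fits])
    order = np.argsort(a, kind="stable")
    fits = [fits[i] for i in order]
    a = a[order]
    delta = a - a[0]
    return ModelComparison(fits=fits, aicc_values=a, delta_aicc=delta,
                           weights=akaike_weights(delta))


def model_average_conditional(comparison: ModelComparison,
                              coef: str) -> float:
    """Conditional (natural) model-averaged coefficient.

    Weighted mean of ``coef`` over only the models containing it, with the
    Akaike weights renormalized over that subset.
    """
    vals, ws = [], []
    for f, w in zip(comparison.fits, comparison.weights):
        if coef in f.beta.index:
            vals.append(float(f.beta[coef]))
            ws.append(float(w))
    if not vals:
        raise ValueError(f"coefficient {coef!r} appears in no model")
    ws = np.array(ws)
    return float(np.average(vals, weights=ws / ws.sum()))


def composite_ci(vcov: pd.DataFrame | np.ndarray, contrast: np.ndarray,
                 estimate: float, crit: float = 1.96) -> tuple[float, float]:
    """Normal-approximation CI for a linear combination of coefficients.

    Half-width = crit * sqrt(c' V c).
    """
    V = np.asarray(vcov, dtype=float)
    c = np.asarray(contrast, dtype=float)
    if c.shape[0] != V.shape[0]:
        raise ValueError(f"contrast length {c.shape[0]} != "
                         f"coefficient count {V.shape[0]}")
    half = crit * math.sqrt(float(c @ V @ c))
    return estimate - half, estimate + half


def _contrast(fit: LmmFit, weights: dict[str, float]) -> np.ndarray:
    c = np.zeros(len(fit.beta))
    for name, w in weights.items():
        c[fit.beta.index.get_loc(name)] = w
    return c


def _crit(crit: float, df: int | None) -> float:
    """95% multiplier: normal by default, t(df) when a small-sample df is
    given (e.g. tanks per treatment minus the two between-level params)."""
    if df is None:
        return crit
    return float(scipy_stats.t.ppf(0.975, df))


def pool_effects(fit: LmmFit, treatment: str,
                 crit: float = 1.96, df: int | None = None) -> PooledEffect:
    """Between-ecosystem composite slope and activation energy.

    slope = b2 + b5[treatment]; intercept = b0 + b4[treatment]; E = -slope
    with CI from the composite contrast over the fixed-effect covariance.
    Treatment "A" is the reference level.  ``df`` switches the multiplier to
    a t quantile for the handful of ecosystem means that carry the
    between-ecosystem information.
    """
    if "x_between" not in fit.beta.index:
        raise ValueError(f"{fit.spec.name} has no between-temperature term")
    weights = {"x_between": 1.0}
    int_weights = {"Intercept": 1.0}
    if treatment != "A":
        zcol = f"z_{treatment.lower()}"
        icol = f"{zcol}:x_between"
        if icol not in fit.beta.index or zcol not in fit.beta.index:
            raise ValueError(
                f"{fit.spec.name} lacks treatment terms for {treatment!r}")
        weights[icol] = 1.0
        int_weights[zcol] = 1.0
    c = _contrast(fit, weights)
    slope = float(c @ fit.beta.to_numpy())
    lo_s, hi_s = composite_ci(fit.vcov, c, slope, _crit(crit, df))
    ci = _contrast(fit, int_weights)
    intercept = float(ci @ fit.beta.to_numpy())
    E = activation_energy_from_slope(slope)
    return PooledEffect(treatment=treatment, scope="between", slope=slope,
                        E=E, ci_low=activation_energy_from_slope(hi_s),
                        ci_high=activation_energy_from_slope(lo_s),
                        intercept=intercept)


def pool_within_effects(fit: LmmFit, treatment: str,
                        eval_point: float = 0.0,
                        crit: float = 1.96,
                        df: int | None = None) -> PooledEffect:
    """Within-ecosystem composite slope at a given between-covariate value.

    slope = b1 + b3 * eval_point + b6[treatment], where ``eval_point`` is the
    grand-mean-centered between covariate (default 0: evaluated at the grand
    mean temperature).
    """
    if "x_within" not in fit.beta.index:
        raise ValueError(f"{fit.spec.name} has no within-temperature term")
    weights = {"x_within": 1.0}
    if "x_within:x_between" in fit.beta.index:
        weights["x_within:x_between"] = eval_point
    if treatment != "A":
        icol = f"z_{treatment.lower()}:x_within"
        if icol in fit.beta.index:
            weights[icol] = 1.0
        elif any(k.endswith(":x_within") for k in fit.beta.index
                 if k.startswith("z_")):
            raise ValueError(
                f"{fit.spec.name} lacks within-treatment term for {treatment!r}")
    c = _contrast(fit, weights)
    slope = float(c @ fit.beta.to_numpy())
    lo_s, hi_s = composite_ci(fit.vcov, c, slope, _crit(crit, df))
    E = activation_energy_from_slope(slope)
    return PooledEffect(treatment=treatment, scope="within", slope=slope,
                        E=E, ci_low=activation_energy_from_slope(hi_s),
                        ci_high=activation_energy_from_slope(lo_s),
                        intercept=float(fit.beta["Intercept"]))


def cascade_temperature_dependence(fit: LmmFit, week_c: float,
                                   group=None) -> float:
    """Trophic-cascade temperature dependence at a given (centered) week.

    The cascade model regresses the log biomass ratio on within-power-level
    centered 1/kT, week, and their interaction; the temperature slope at
    week ``week_c`` is b[x_within] + b[x_within:week] * week_c, and the
    reported E is minus that slope.  When ``group`` names a power level, its
    random-intercept BLUP is added to the pooled slope — one interpretation
    of combining the fixed-effect estimate with the realized group effect;
    the construction is underdetermined and this choice is deliberate and
    documented rather than canonical.
    """
    slope = float(fit.beta.get("x_within", 0.0))
    if "x_within:week_c" in fit.beta.index:
        slope += float(fit.beta["x_within:week_c"]) * week_c
    if group is not None:
        slope += fit.random_effects[group]
    return activation_energy_from_slope(slope)


def run_model_set(design: pd.DataFrame, set_name: str) -> ModelComparison:
    """Fit and rank the full nested model set for one response family.

    ``set_name`` is one of phyto_biomass / nep / er / cascade / zoop_total /
    daphnia / copepod.  All models are fit on the identical row set (the
    design is already listwise-complete across the union of terms).
    """
    if set_name not in MODEL_SETS:
        raise ValueError(f"unknown model set {set_name!r}; expected one of "
                         f"{sorted(MODEL_SETS)}")
    fits = [fit_lmm(design, spec) for spec in MODEL_SETS[set_name]]
    return rank_models(fits)
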