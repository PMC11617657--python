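"""Selection-gradient estimation on standardized traits.

Three complementary approaches, each run against relative fitness:

* ``class_selection_model`` — relative fitness on the four compound-class
  totals, the design factors (year, snowmelt, precipitation treatments),
  and all class-by-factor interactions.
* ``univariate_env_selection`` — one trait at a time against the two
  continuous environmental variables (snowmelt date, summer
  precipitation) with trait-by-environment interactions; both
  interactions are dropped when nonsignificant (P > 0.05).
* ``elastic_net_gradients`` — direct (multivariate) gradients by
  elastic-net regression (mixing 0.5, lambda by cross-validation), with
  the environmental covariates left unpenalized so shrinkage targets the
  traits.

Environmental covariates are centered before interactions are formed, so
main-effect gradients are evaluated at the average environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

__all__ = [
    "ENConfig",
    "standardize_traits",
    "eligible_volatiles",
    "class_selection_model",
    "univariate_env_selection",
    "elastic_net_gradients",
    "per_treatment_gradients",
    "env_fitness_effects",
    "univariate_gradient",
]


@dataclass
class ENConfig:
    alpha: float = 0.5  # L1/L2 mixing (glmnet's alpha)
    lambda_rule: str = "min_cv"  # or "one_se"
    n_folds: int = 10
    n_lambdas: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_folds < 3:
            raise ValueError("need at least 3 cross-validation folds")
        if self.lambda_rule not in ("min_cv", "one_se"):
            raise ValueError("lambda_rule must be 'min_cv' or 'one_se'")


def standardize_traits(
    traits: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-center and scale each trait by its sample SD (ddof=1).

    Returns the standardized matrix and a (mean, sd) table.
    """
    stats = pd.DataFrame({"mean": traits.mean(), "sd": traits.std(ddof=1)})
    zero = stats.index[stats["sd"] == 0].tolist()
    if zero:
        raise ValueError(f"trait(s) with zero SD cannot be standardized: {zero}")
    z = (traits - stats["mean"]) / stats["sd"]
    return z, stats


def eligible_volatiles(
    sample_matrix: pd.DataFrame, threshold: float = 0.75
) -> list[str]:
    """Volatiles with nonzero emission in at least ``threshold`` of samples."""
    occurrence = (sample_matrix > 0).mean(axis=0)
    return [str(c) for c in sample_matrix.columns if occurrence[c] >= threshold]


def univariate_gradient(z: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """OLS slope of relative fitness on one standardized trait: (beta, se, p)."""
    X = sm.add_constant(np.asarray(z, float))
    fit = sm.OLS(np.asarray(w, float), X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def class_selection_model(
    data: pd.DataFrame,
    fitness_col: str,
    class_cols: tuple[str, ...] = ("monoterpene", "sesquiterpene", "benzenoid", "aliphatic"),
    year_col: str = "year",
    snow_col: str = "snow_treatment",
    precip_col: str = "precip_treatment",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative fitness on standardized class totals, design factors, and
    all class-by-factor interactions.

    Returns (gradients, interaction_tests): per-context standardized
    gradients for every class (derived from main + interaction
    coefficients) and Wald tests of each interaction term.
    """
    df = data.dropna(subset=[fitness_col, *class_cols]).copy()
    if df.empty:
        raise ValueError("no complete rows for the class selection model")
    z, _ = standardize_traits(df[list(class_cols)])
    for c in class_cols:
        df["z_" + c] = z[c]
    zterms = " + ".join("z_" + c for c in class_cols)
    factors = f"C({year_col}) + C({snow_col}) + C({precip_col})"
    inter = " + ".join(
        f"z_{c}:C({f})" for c in class_cols for f in (year_col, snow_col, precip_col)
    )
    formula = f"{fitness_col} ~ {zterms} + {factors} + {inter}"
    fit = smf.ols(formula, df).fit()

    inter_rows = []
    wald = fit.wald_test_terms(scalar=True)
    for term, row in wald.table.iterrows():
        if ":" in term:
            inter_rows.append(
                {"term": term, "F": float(row["statistic"]), "p": float(row["pvalue"]),
                 "df": int(row["df_constraint"])}
            )
    interaction_tests = pd.DataFrame(inter_rows)

    # per-context gradients: d(fitness)/d(z_class) at each factor combination
    params = fit.params
    cov = fit.cov_params()
    contexts = (
        df[[year_col, snow_col, precip_col]].drop_duplicates().sort_values(
            [year_col, snow_col, precip_col]
        )
    )
    grad_rows = []
    for _, ctx in contexts.iterrows():
        for c in class_cols:
            L = pd.Series(0.0, index=params.index)
            L["z_" + c] = 1.0
            for f, val in (
                (year_col, ctx[year_col]),
                (snow_col, ctx[snow_col]),
                (precip_col, ctx[precip_col]),
            ):
                key = f"z_{c}:C({f})[T.{val}]"
                if key in L.index:
                    L[key] = 1.0
            beta = float(L @ params)
            se = float(np.sqrt(L @ cov @ L))
            n_cell = int(
                (
                    (df[year_col] == ctx[year_col])
                    & (df[snow_col] == ctx[snow_col])
                    & (df[precip_col] == ctx[precip_col])
                ).sum()
            )
            grad_rows.append(
                {
                    "fitness": fitness_col,
                    "trait": c,
                    year_col: ctx[year_col],
                    snow_col: ctx[snow_col],
                    precip_col: ctx[precip_col],
                    "beta": beta if n_cell > 0 else np.nan,
                    "se": se if n_cell > 0 else np.nan,
                    "n": n_cell,
                    "method": "class_model",
                }
            )
    return pd.DataFrame(grad_rows), interaction_tests


def univariate_env_selection(
    z: pd.Series | np.ndarray,
    w: pd.Series | np.ndarray,
    snowmelt_date: pd.Series | np.ndarray,
    summer_precip: pd.Series | np.ndarray,
    drop_threshold: float = 0.05,
) -> dict[str, float | bool]:
    """Univariate selection with environment interactions and the drop rule.

    Fits w ~ z + S + P + z:S + z:P with S, P centered.  If both
    interaction p-values exceed ``drop_threshold`` the interactions are
    dropped and the refit main-effect beta is reported; otherwise beta is
    the gradient at the average environment and both interaction slopes
    are reported (per day of snowmelt, per mm of precipitation).
    """
    frame = pd.DataFrame(
        {
            "z": np.asarray(z, float),
            "w": np.asarray(w, float),
            "S": np.asarray(snowmelt_date, float),
            "P": np.asarray(summer_precip, float),
        }
    ).dropna()
    n = len(frame)
    if n < 10:
        raise ValueError(f"need at least 10 complete observations, got {n}")
    if frame["S"].nunique() < 2 or frame["P"].nunique() < 2:
        raise ValueError("snowmelt date and precipitation must both vary")
    frame["Sc"] = frame["S"] - frame["S"].mean()
    frame["Pc"] = frame["P"] - frame["P"].mean()
    full = smf.ols("w ~ z + Sc + Pc + z:Sc + z:Pc", frame).fit()
    p_zs = float(full.pvalues["z:Sc"])
    p_zp = float(full.pvalues["z:Pc"])
    cond = np.linalg.cond(
        np.column_stack([frame["Sc"], frame["Pc"]])
    )
    out: dict[str, float | bool] = {"n": n, "env_condition_number": float(cond)}
    if p_zs > drop_threshold and p_zp > drop_threshold:
        reduced = smf.ols("w ~ z + Sc + Pc", frame).fit()
        out.update(
            beta=float(reduced.params["z"]),
            se=float(reduced.bse["z"]),
            p=float(reduced.pvalues["z"]),
            interactions_dropped=True,
            dbeta_dmelt=np.nan,
            dbeta_dmelt_se=np.nan,
            dbeta_dmelt_p=p_zs,
            dbeta_dprecip=np.nan,
            dbeta_dprecip_se=np.nan,
            dbeta_dprecip_p=p_zp,
        )
    else:
        out.update(
            beta=float(full.params["z"]),
            se=float(full.bse["z"]),
            p=float(full.pvalues["z"]),
            interactions_dropped=False,
            dbeta_dmelt=float(full.params["z:Sc"]),
            dbeta_dmelt_se=float(full.bse["z:Sc"]),
            dbeta_dmelt_p=p_zs,
            dbeta_dprecip=float(full.params["z:Pc"]),
            dbeta_dprecip_se=float(full.bse["z:Pc"]),
            dbeta_dprecip_p=p_zp,
        )
    return out


def _enet_coefs(
    X: np.ndarray, y: np.ndarray, lam: float, l1_ratio: float
) -> np.ndarray:
    """Elastic-net coefficients (no intercept) at one penalty value."""
    model = ElasticNet(
        alpha=lam, l1_ratio=l1_ratio, fit_intercept=False, max_iter=50_000, tol=1e-8
    )
    model.fit(X, y)
    return model.coef_


def _lambda_path(X: np.ndarray, y: np.ndarray, l1_ratio: float, n_lambdas: int) -> np.ndarray:
    n = X.shape[0]
    lam_max = np.abs(X.T @ y).max() / (n * max(l1_ratio, 1e-3))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * 1e-4, n_lambdas)


def elastic_net_gradients(
    Z: pd.DataFrame,
    w: pd.Series | np.ndarray,
    env: pd.DataFrame | None = None,
    config: ENConfig | None = None,
) -> pd.DataFrame:
    """Sparse direct selection gradients by elastic-net regression.

    Environmental covariates (if given) are unpenalized: by the
    partialling-out identity for an unpenalized block, the penalized trait
    coefficients equal the elastic-net fit of the env-residualized fitness
    on the env-residualized traits.  Lambda is chosen by K-fold
    cross-validation with a fixed seed.  Zero coefficients mean "not
    selected"; no SEs or p-values are reported for this method.
    """
    config = config or ENConfig()
    Zm = Z.to_numpy(float)
    y = np.asarray(w, float)
    n = len(y)
    if np.isnan(Zm).any() or np.isnan(y).any():
        raise ValueError("elastic net requires complete trait and fitness data")
    if n < config.n_folds:
        raise ValueError(f"n = {n} is smaller than the number of CV folds")

    if env is not None and env.shape[1] > 0:
        E = np.column_stack([np.ones(n), env.to_numpy(float)])
    else:
        E = np.ones((n, 1))
    # residualize out the unpenalized block (Frisch-Waugh)
    Q, _ = np.linalg.qr(E)
    My = y - Q @ (Q.T @ y)
    MZ = Zm - Q @ (Q.T @ Zm)

    lambdas = _lambda_path(MZ, My, config.alpha, config.n_lambdas)
    kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    cv_mse = np.zeros((config.n_folds, len(lambdas)))
    for fi, (tr, te) in enumerate(kf.split(MZ)):
        Xtr, ytr = MZ[tr], My[tr]
        Xte, yte = MZ[te], My[te]
        model = ElasticNet(
            alpha=1.0, l1_ratio=config.alpha, fit_intercept=False,
            max_iter=50_000, tol=1e-8, warm_start=True,
        )
        for li, lam in enumerate(lambdas):
            model.set_params(alpha=lam)
            model.fit(Xtr, ytr)
            resid = yte - Xte @ model.coef_
            cv_mse[fi, li] = float(resid @ resid) / len(te)
    mean_mse = cv_mse.mean(axis=0)
    se_mse = cv_mse.std(axis=0, ddof=1) / np.sqrt(config.n_folds)
    i_min = int(np.argmin(mean_mse))
    if config.lambda_rule == "one_se":
        limit = mean_mse[i_min] + se_mse[i_min]
        candidates = np.flatnonzero(mean_mse <= limit)
        i_pick = int(candidates[0])  # largest lambda within one SE (path is descending)
    else:
        i_pick = i_min
    lam = float(lambdas[i_pick])

    coefs = _enet_coefs(MZ, My, lam, config.alpha)
    env_beta = np.linalg.lstsq(E, y - Zm @ coefs, rcond=None)[0]

    out = pd.DataFrame(
        {
            "trait": list(Z.columns),
            "beta": coefs,
            "selected": coefs != 0,
            "method": "elastic_net",
        }
    )
    out.attrs["lambda"] = lam
    out.attrs["env_coefficients"] = env_beta
    out.attrs["n"] = n
    return out


def per_treatment_gradients(
    traits: pd.DataFrame,
    w: pd.Series,
    subsets: pd.Series,
    config: ENConfig | None = None,
    min_n: int = 10,
) -> pd.DataFrame:
    """Univariate and elastic-net gradients within each subset label.

    ``subsets`` assigns each plant a context label (e.g. "2019/early").
    Traits are restandardized within each subset.  Subsets smaller than
    ``min_n`` are flagged missing, never zero.
    """
    config = config or ENConfig()
    rows = []
    for label in pd.unique(subsets.dropna()):
        mask = (subsets == label).to_numpy()
        sub_t = traits.loc[mask]
        sub_w = w.loc[mask]
        complete = sub_t.notna().all(axis=1) & sub_w.notna()
        sub_t, sub_w = sub_t.loc[complete], sub_w.loc[complete]
        n = len(sub_w)
        if n < min_n:
            for trait in traits.columns:
                rows.append(
                    {"context": label, "trait": trait, "method": "univariate",
                     "beta": np.nan, "se": np.nan, "p": np.nan, "n": n,
                     "note": "subset too small"}
                )
            continue
        z, _ = standardize_traits(sub_t)
        for trait in traits.columns:
            beta, se, p = univariate_gradient(z[trait], sub_w)
            rows.append(
                {"context": label, "trait": trait, "method": "univariate",
                 "beta": beta, "se": se, "p": p, "n": n, "note": ""}
            )
        if n >= config.n_folds:
            en = elastic_net_gradients(z, sub_w, env=None, config=config)
            for _, r in en.iterrows():
                rows.append(
                    {"context": label, "trait": r["trait"], "method": "elastic_net",
                     "beta": r["beta"], "se": np.nan, "p": np.nan, "n": n, "note": ""}
                )
    return pd.DataFrame(rows)


def env_fitness_effects(
    w: pd.Series | np.ndarray,
    snowmelt_date: pd.Series | np.ndarray,
    summer_precip: pd.Series | np.ndarray,
) -> dict[str, float]:
    """Direct environmental effects on relative fitness, traits excluded.

    Fits w ~ S + P and expresses the snowmelt-date coefficient as percent
    change of mean fitness per day of *earlier* melt (positive = fitness
    rises as the snow melts earlier) and the precipitation coefficient as
    percent change per mm.
    """
    frame = pd.DataFrame(
        {
            "w": np.asarray(w, float),
            "S": np.asarray(snowmelt_date, float),
            "P": np.asarray(summer_precip, float),
        }
    ).dropna()
    frame["Sc"] = frame["S"] - frame["S"].mean()
    frame["Pc"] = frame["P"] - frame["P"].mean()
    fit = smf.ols("w ~ Sc + Pc", frame).fit()
    mean_w = float(frame["w"].mean())
    return {
        "pct_per_day_earlier": -float(fit.params["Sc"]) / mean_w * 100.0,
        "pct_per_day_earlier_se": float(fit.bse["Sc"]) / mean_w * 100.0,
        "pct_per_day_earlier_p": float(fit.pvalues["Sc"]),
        "pct_per_mm_precip": float(fit.params["Pc"]) / mean_w * 100.0,
        "pct_per_mm_precip_se": float(fit.bse["Pc"]) / mean_w * 100.0,
        "pct_per_mm_precip_p": float(fit.pvalues["Pc"]),
        "n": len(frame),
    }
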