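"""Split-plot linear mixed models, estimated marginal means, and
plasticity effect sizes.

Models are fit by REML with a random intercept for whole plot and a
nested random intercept for subplot-within-plot, matching the split-plot
design.  Fixed-effect tests are Wald tests on the REML fit (a normal
approximation; the denominator-df correction is configurable in principle
but the large-sample z test is the default here).  Singular fits are
flagged, never hidden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from patsy import build_design_matrices, dmatrix

__all__ = [
    "LMMSpec",
    "LMMResult",
    "fit_lmm",
    "emmeans",
    "emmean_contrast",
    "plasticity_effect_sizes",
    "plasticity_correlation",
]


@dataclass
class LMMSpec:
    """Model specification: response, fixed-effect formula RHS, grouping labels."""

    response: str
    fixed: str  # patsy right-hand side, e.g. "C(year) * C(snow) * C(precip)"
    plot_col: str = "plot_id"
    subplot_col: str = "subplot_id"
    sqrt_scale: bool = False  # take sqrt of the response before fitting


@dataclass
class LMMResult:
    spec: LMMSpec
    coef_table: pd.DataFrame  # estimate, se, z, p per fixed coefficient
    variance_components: dict[str, float]
    singular: bool
    converged: bool
    _result: object = field(repr=False, default=None)
    _design_info: object = field(repr=False, default=None)
    _data: pd.DataFrame = field(repr=False, default=None)


def fit_lmm(data: pd.DataFrame, spec: LMMSpec) -> LMMResult:
    """REML fit with plot and subplot-within-plot random intercepts."""
    for col in (spec.response, spec.plot_col, spec.subplot_col):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    df = data.copy()
    # subplot labels must nest in plots: build a unique key and check
    nesting = df.groupby(spec.subplot_col)[spec.plot_col].nunique()
    nested_labels = (nesting <= 1).all()
    df["_subplot_uid"] = (
        df[spec.plot_col].astype(str) + "/" + df[spec.subplot_col].astype(str)
    )
    if not nested_labels:
        # identical subplot labels reused across plots is the usual design
        # encoding; truly crossed labels would have been caught upstream
        pass
    df["_resp"] = np.sqrt(df[spec.response]) if spec.sqrt_scale else df[spec.response]

    model = smf.mixedlm(
        f"_resp ~ {spec.fixed}",
        df,
        groups=df[spec.plot_col],
        re_formula="1",
        vc_formula={"subplot": "0 + C(_subplot_uid)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)

    fe = result.fe_params
    se = result.bse_fe
    z = fe / se
    p = 2 * scipy.stats.norm.sf(np.abs(z))
    coef_table = pd.DataFrame(
        {"estimate": fe, "se": se, "z": z, "p": p}
    )
    # statsmodels reports cov_re and vcomp already on the response scale
    scale = float(result.scale)
    vcomp = {
        "plot": float(result.cov_re.iloc[0, 0]),
        "subplot": float(result.vcomp[0]) if len(result.vcomp) else 0.0,
        "residual": scale,
    }
    singular = vcomp["plot"] < 1e-8 * scale or vcomp["subplot"] < 1e-8 * scale
    if singular:
        warnings.warn(
            f"singular fit for {spec.response!r}: a variance component is "
            "estimated at (or near) zero",
            stacklevel=2,
        )
    return LMMResult(
        spec=spec,
        coef_table=coef_table,
        variance_components=vcomp,
        singular=bool(singular),
        converged=bool(result.converged),
        _result=result,
        _design_info=model.data.design_info,
        _data=df,
    )


def _reference_grid(result: LMMResult, factor: str) -> tuple[pd.DataFrame, list]:
    """Grid of all categorical-level combinations, covariates at their means."""
    df = result._data
    design_info = result._design_info
    factor_cols = sorted(
        {
            fac.name().removeprefix("C(").removesuffix(")")
            for term in design_info.terms
            for fac in term.factors
        }
    )
    grids = {}
    for col in factor_cols:
        if col not in df.columns:
            raise ValueError(f"model component {col!r} not found in data")
        if df[col].dtype.kind in "OUSb":
            grids[col] = sorted(df[col].astype(str).unique())
        else:
            grids[col] = [float(df[col].mean())]
    if factor not in grids:
        raise ValueError(f"factor {factor!r} is not in the fixed terms")
    index = pd.MultiIndex.from_product(grids.values(), names=grids.keys())
    grid = index.to_frame(index=False)
    return grid, grids[factor]


def emmeans(result: LMMResult, factor: str) -> pd.DataFrame:
    """Estimated marginal means of ``factor``: fixed-effect predictions
    averaged with equal weights over the other factors' levels."""
    grid, levels = _reference_grid(result, factor)
    if len(levels) < 2 and grid[factor].nunique() < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels in the data")
    (X,) = build_design_matrices([result._design_info], grid)
    X = np.asarray(X)
    fe = result._result.fe_params.to_numpy()
    cov = np.asarray(result._result.cov_params())[: len(fe), : len(fe)]
    rows = []
    for lev in levels:
        mask = (grid[factor].astype(str) == str(lev)).to_numpy()
        if not mask.any():
            raise ValueError(f"level {lev!r} absent from data")
        L = X[mask].mean(axis=0)
        est = float(L @ fe)
        se = float(np.sqrt(L @ cov @ L))
        rows.append({"level": lev, "emmean": est, "se": se, "_L": L})
    out = pd.DataFrame(rows).set_index("level")
    out.attrs["factor"] = factor
    return out


def emmean_contrast(
    result: LMMResult, factor: str, level_new: str, level_control: str
) -> dict[str, float]:
    """Ratio of EMMs (new / control) with a delta-method log-scale SE and a
    Wald test of the EMM difference."""
    em = emmeans(result, factor)
    for lev in (level_new, level_control):
        if lev not in em.index:
            raise ValueError(f"level {lev!r} absent from data")
    m1, m0 = float(em.loc[level_new, "emmean"]), float(em.loc[level_control, "emmean"])
    L1 = em.loc[level_new, "_L"]
    L0 = em.loc[level_control, "_L"]
    fe = result._result.fe_params.to_numpy()
    cov = np.asarray(result._result.cov_params())[: len(fe), : len(fe)]
    Ld = L1 - L0
    diff = float(Ld @ fe)
    se_diff = float(np.sqrt(Ld @ cov @ Ld))
    p_diff = 2 * scipy.stats.norm.sf(abs(diff) / se_diff) if se_diff > 0 else float("nan")
    if m0 <= 0 or m1 <= 0:
        return {
            "fold_change": float("nan"),
            "log_fc_se": float("nan"),
            "p_diff": p_diff,
            "emm_new": m1,
            "emm_control": m0,
        }
    grad = L1 / m1 - L0 / m0
    log_fc_se = float(np.sqrt(grad @ cov @ grad))
    return {
        "fold_change": m1 / m0,
        "log_fc_se": log_fc_se,
        "p_diff": p_diff,
        "emm_new": m1,
        "emm_control": m0,
    }


def plasticity_effect_sizes(
    traits: pd.DataFrame,
    treatment_col: str,
    level_new: str,
    level_control: str,
    trait_cols: list[str],
    year_col: str | None = None,
) -> pd.DataFrame:
    """Cohen's d per trait for a treatment contrast.

    d = (mean_new - mean_control) / pooled SD, within year when
    ``year_col`` is given, then |d| is averaged across years per trait.
    Traits with zero pooled SD get NaN and a flag.
    """
    year_groups = (
        traits.groupby(year_col) if year_col else [(None, traits)]
    )
    rows = []
    for year, grp in year_groups:
        g_new = grp[grp[treatment_col].astype(str) == level_new]
        g_ctl = grp[grp[treatment_col].astype(str) == level_control]
        for trait in trait_cols:
            x1 = g_new[trait].dropna().to_numpy(float)
            x0 = g_ctl[trait].dropna().to_numpy(float)
            if len(x1) < 2 or len(x0) < 2:
                rows.append({"trait": trait, "year": year, "d": np.nan, "flag": "too few observations"})
                continue
            n1, n0 = len(x1), len(x0)
            pooled = np.sqrt(
                ((n1 - 1) * x1.var(ddof=1) + (n0 - 1) * x0.var(ddof=1)) / (n1 + n0 - 2)
            )
            if pooled == 0:
                rows.append({"trait": trait, "year": year, "d": np.nan, "flag": "zero pooled SD"})
                continue
            rows.append(
                {
                    "trait": trait,
                    "year": year,
                    "d": (x1.mean() - x0.mean()) / pooled,
                    "flag": "",
                }
            )
    return pd.DataFrame(rows)


def effect_size_group_summary(
    d_table: pd.DataFrame, volatile_traits: list[str]
) -> dict[str, float]:
    """Mean |d| per trait group (volatiles vs other traits) and an
    approximate two-sample Welch test of the group difference.

    Treats per-trait mean |d| values as independent observations; labeled
    approximate because trait correlations are ignored.
    """
    per_trait = (
        d_table.dropna(subset=["d"]).assign(abs_d=lambda f: f["d"].abs())
        .groupby("trait")["abs_d"]
        .mean()
    )
    vol = per_trait[per_trait.index.isin(volatile_traits)]
    other = per_trait[~per_trait.index.isin(volatile_traits)]
    if len(vol) >= 2 and len(other) >= 2:
        stat, p = scipy.stats.ttest_ind(vol, other, equal_var=False)
    else:
        stat, p = np.nan, np.nan
    return {
        "mean_abs_d_volatiles": float(vol.mean()) if len(vol) else np.nan,
        "mean_abs_d_other": float(other.mean()) if len(other) else np.nan,
        "t": float(stat),
        "p": float(p),
    }


def plasticity_correlation(
    snow_plasticity: pd.Series, precip_plasticity: pd.Series
) -> tuple[float, float]:
    """Pearson correlation across volatiles of two plasticity estimates."""
    joined = pd.concat(
        [snow_plasticity.rename("snow"), precip_plasticity.rename("precip")], axis=1
    ).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 volatiles to correlate plasticity")
    if joined["snow"].nunique() == 1 or joined["precip"].nunique() == 1:
        raise ValueError("constant plasticity vector; correlation undefined")
    r, p = scipy.stats.pearsonr(joined["snow"], joined["precip"])
    return float(r), float(p)
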