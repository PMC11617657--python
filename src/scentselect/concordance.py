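"""Plasticity x selection concordance: is plasticity adaptive?

Each trait's plastic response to a treatment contrast (fold change of
estimated marginal means, new vs control environment) is paired with the
univariate selection gradient estimated in the new environment.  The
quadrant rule classifies the pair: adaptive when log fold change and beta
share a sign, maladaptive when they oppose, neutral when either is zero.
A stringent flag additionally requires significant plasticity,
significant univariate selection (P < 0.05), and a nonzero elastic-net
direct gradient.

Fly oviposition is excluded from concordance by default, being a less
direct fitness measure.  Fold changes are computed on the measurement
scale, and the quadrant x-axis is the log fold change (symmetric about 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .selection import standardize_traits, univariate_gradient

__all__ = [
    "PlasticityEstimate",
    "ConcordanceRecord",
    "plasticity_fold_change",
    "selection_in_new_env",
    "classify",
    "proportion_test",
    "stringent_summary",
    "CONCORDANCE_MEASURES",
]

#: fitness measures used for concordance (fly eggs per flower excluded)
CONCORDANCE_MEASURES = ("total_seeds", "seeds_per_flower", "escape_predation")


@dataclass
class PlasticityEstimate:
    trait: str
    contrast: str  # e.g. "early_vs_control_snow"
    year: int | None
    fold_change: float
    log_fc_se: float
    significant: bool
    missing_reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.missing_reason is not None


@dataclass
class ConcordanceRecord:
    trait: str
    contrast: str
    year: int | None
    fitness: str
    beta_new_env: float
    beta_se: float
    beta_p: float
    fold_change: float
    classification: str  # adaptive | maladaptive | neutral
    stringent: bool
    plasticity_significant: bool
    selection_significant: bool
    en_selected: bool | None = None


def plasticity_fold_change(
    data: pd.DataFrame,
    trait: str,
    contrast_col: str,
    level_new: str,
    level_control: str,
    other_factor: str,
    year: int | None = None,
    year_col: str = "year",
    alpha: float = 0.05,
) -> PlasticityEstimate:
    """Fold change of estimated marginal means (new / control environment).

    EMMs come from a linear model of the trait on both treatment factors
    (within year when given); the log-scale SE is by the delta method and
    significance is a Wald test of the EMM difference.
    """
    df = data if year is None else data[data[year_col] == year]
    df = df.dropna(subset=[trait, contrast_col, other_factor])
    contrast_name = f"{level_new}_vs_{level_control}"
    levels = set(df[contrast_col].astype(str))
    if not {level_new, level_control} <= levels:
        return PlasticityEstimate(
            trait, contrast_name, year, np.nan, np.nan, False,
            missing_reason="contrast level absent",
        )
    fit = smf.ols(f"Q('{trait}') ~ C({contrast_col}) + C({other_factor})", df).fit()
    params = fit.params
    cov = fit.cov_params()

    def emm_vector(level: str) -> pd.Series:
        L = pd.Series(0.0, index=params.index)
        L["Intercept"] = 1.0
        key = f"C({contrast_col})[T.{level}]"
        if key in L.index:
            L[key] = 1.0
        other_levels = sorted(df[other_factor].astype(str).unique())
        for lev in other_levels[1:]:
            L[f"C({other_factor})[T.{lev}]"] = 1.0 / len(other_levels)
        return L

    L1, L0 = emm_vector(level_new), emm_vector(level_control)
    m1, m0 = float(L1 @ params), float(L0 @ params)
    Ld = L1 - L0
    se_diff = float(np.sqrt(Ld @ cov @ Ld))
    p_diff = (
        2 * scipy.stats.norm.sf(abs(float(Ld @ params)) / se_diff)
        if se_diff > 0
        else np.nan
    )
    if m0 <= 0 or m1 <= 0:
        return PlasticityEstimate(
            trait, contrast_name, year, np.nan, np.nan, False,
            missing_reason="nonpositive estimated marginal mean; fold change undefined",
        )
    grad = L1 / m1 - L0 / m0
    log_se = float(np.sqrt(grad @ cov @ grad))
    return PlasticityEstimate(
        trait=trait,
        contrast=contrast_name,
        year=year,
        fold_change=m1 / m0,
        log_fc_se=log_se,
        significant=bool(p_diff < alpha),
    )


def selection_in_new_env(
    trait_values: pd.Series,
    w: pd.Series,
    subset_mask: pd.Series | np.ndarray,
    min_n: int = 10,
) -> dict[str, float]:
    """Univariate standardized gradient within a treatment-by-year subset."""
    mask = np.asarray(subset_mask, bool)
    t = trait_values[mask]
    fw = w[mask]
    complete = t.notna() & fw.notna()
    t, fw = t[complete], fw[complete]
    if len(t) < min_n:
        return {"beta": np.nan, "se": np.nan, "p": np.nan, "n": len(t),
                "note": "subset too small"}
    if t.std(ddof=1) == 0:
        return {"beta": np.nan, "se": np.nan, "p": np.nan, "n": len(t),
                "note": "constant trait in subset"}
    z, _ = standardize_traits(t.to_frame("t"))
    beta, se, p = univariate_gradient(z["t"], fw)
    return {"beta": beta, "se": se, "p": p, "n": len(t), "note": ""}


def classify(
    plasticity: PlasticityEstimate,
    selection: dict[str, float],
    fitness: str,
    en_selected: bool | None = None,
    alpha: float = 0.05,
) -> ConcordanceRecord:
    """Quadrant rule on (log fold change, beta), with the stringent flag."""
    if plasticity.is_missing or not np.isfinite(selection.get("beta", np.nan)):
        raise ValueError("classify requires non-missing plasticity and selection")
    log_fc = np.log(plasticity.fold_change)
    beta = float(selection["beta"])
    s = np.sign(log_fc) * np.sign(beta)
    if s > 0:
        label = "adaptive"
    elif s < 0:
        label = "maladaptive"
    else:
        label = "neutral"
    sel_sig = bool(selection.get("p", np.nan) < alpha)
    stringent = bool(
        plasticity.significant and sel_sig and (en_selected if en_selected is not None else False)
    )
    return ConcordanceRecord(
        trait=plasticity.trait,
        contrast=plasticity.contrast,
        year=plasticity.year,
        fitness=fitness,
        beta_new_env=beta,
        beta_se=float(selection.get("se", np.nan)),
        beta_p=float(selection.get("p", np.nan)),
        fold_change=plasticity.fold_change,
        classification=label,
        stringent=stringent,
        plasticity_significant=plasticity.significant,
        selection_significant=sel_sig,
        en_selected=en_selected,
    )


def records_frame(records: list[ConcordanceRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def proportion_test(records: pd.DataFrame) -> pd.DataFrame:
    """Exact binomial test of adaptive fraction = 0.5 among non-neutral
    records, per fitness measure."""
    rows = []
    for fitness, grp in records.groupby("fitness"):
        non_neutral = grp[grp["classification"] != "neutral"]
        k = int((non_neutral["classification"] == "adaptive").sum())
        n = len(non_neutral)
        if n == 0:
            rows.append({"fitness": fitness, "n_non_neutral": 0, "adaptive_fraction": np.nan,
                         "p": np.nan, "note": "all records neutral; test undefined"})
            continue
        test = scipy.stats.binomtest(k, n, 0.5, alternative="two-sided")
        rows.append(
            {"fitness": fitness, "n_non_neutral": n, "adaptive_fraction": k / n,
             "p": float(test.pvalue), "note": ""}
        )
    return pd.DataFrame(rows)


def stringent_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Cross-tab of plasticity x selection significance with trait lists."""
    rows = []
    for psig in (False, True):
        for ssig in (False, True):
            cell = records[
                (records["plasticity_significant"] == psig)
                & (records["selection_significant"] == ssig)
            ]
            rows.append(
                {
                    "plasticity_significant": psig,
                    "selection_significant": ssig,
                    "count": len(cell),
                    "traits": ";".join(sorted(cell["trait"].unique())),
                }
            )
    return pd.DataFrame(rows)
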