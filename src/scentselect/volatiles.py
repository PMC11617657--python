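"""Peak-table filtering, calibration, quantitation, and plant averaging.

The pipeline starts from a long-format per-sample peak-area table (floral
samples plus ambient air controls) and produces a plant x compound matrix
of emission rates in ng flower^-1 h^-1:

1. :func:`filter_compounds` applies four inclusion rules (retention-time
   window, occurrence frequency, floral/ambient ratio, contaminant list)
   and emits a per-compound audit record.
2. :func:`fit_calibration` fits a through-origin line to each standard's
   dilution series.
3. :func:`quantify_samples` converts areas to rates via the class
   standard's slope and the sampling duration.
4. :func:`plant_means` averages repeated samples of a plant.
5. :func:`transform_sqrt` square-root transforms for plasticity analyses;
   :func:`class_totals` sums untransformed rates by compound class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "CalibrationCurve",
    "FilterAudit",
    "filter_compounds",
    "fit_calibration",
    "quantify_samples",
    "plant_means",
    "transform_sqrt",
    "class_totals",
    "COMPOUND_CLASSES",
    "DEFAULT_CLASS_STANDARDS",
]

COMPOUND_CLASSES = ("monoterpene", "sesquiterpene", "benzenoid", "aliphatic")

#: Default class -> calibration standard assignment.  The study ran seven
#: standards for four classes, so this mapping is fully overridable.
DEFAULT_CLASS_STANDARDS = {
    "monoterpene": "alpha-pinene",
    "sesquiterpene": "beta-caryophyllene",
    "benzenoid": "methyl salicylate",
    "aliphatic": "(Z)-3-hexen-1-ol",
}


@dataclass
class FilterConfig:
    """Inclusion rules for compounds in the peak table."""

    rt_min: float = 2.0
    rt_max: float = 17.0
    min_freq: float = 0.10
    ambient_ratio: float = 4.0
    contaminants: tuple[str, ...] = ()
    detection_threshold: float = 0.0  # peak_area must exceed this to count as detected

    def __post_init__(self) -> None:
        if not 0 < self.min_freq < 1:
            raise ValueError("min_freq must be in (0, 1)")
        if self.ambient_ratio <= 0:
            raise ValueError("ambient_ratio must be positive")
        if self.rt_min >= self.rt_max:
            raise ValueError("rt_min must be below rt_max")
        self.contaminants = tuple(self.contaminants)


@dataclass
class CalibrationCurve:
    standard_name: str
    slope: float  # detector area per ng
    n_points: int
    r_squared: float
    slope_se: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(
                f"calibration slope for {self.standard_name!r} must be positive, "
                f"got {self.slope}"
            )


@dataclass
class FilterAudit:
    compound: str
    median_rt: float
    detect_freq: float
    floral_mean: float
    ambient_mean: float
    failed_rules: tuple[str, ...] = field(default_factory=tuple)

    @property
    def retained(self) -> bool:
        return not self.failed_rules


def _require_columns(frame: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def filter_compounds(
    peaks: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Apply the four inclusion rules; return retained compounds and an audit.

    A compound is retained iff its median retention time lies in
    ``[rt_min, rt_max]``, it is detected in at least ``min_freq`` of floral
    samples, its floral mean strictly exceeds ``ambient_ratio`` times the
    ambient mean, and it is not a listed contaminant.  Means treat samples
    with no peak for the compound as zero.
    """
    config = config or FilterConfig()
    _require_columns(
        peaks, ["sample_id", "sample_type", "compound", "retention_time", "peak_area"], "peak table"
    )
    if (peaks["peak_area"] < 0).any():
        raise ValueError("peak areas must be nonnegative")
    floral = peaks[peaks["sample_type"] == "floral"]
    ambient = peaks[peaks["sample_type"] == "ambient"]
    if ambient["sample_id"].nunique() == 0:
        raise ValueError(
            "no ambient control samples present: the ambient-ratio rule cannot "
            "be applied; refusing to filter without controls"
        )
    n_floral = floral["sample_id"].nunique()
    n_ambient = ambient["sample_id"].nunique()
    if n_floral == 0:
        raise ValueError("no floral samples present")

    retained: list[str] = []
    audits: list[FilterAudit] = []
    for compound, grp in peaks.groupby("compound", sort=True):
        fl = grp[grp["sample_type"] == "floral"]
        am = grp[grp["sample_type"] == "ambient"]
        median_rt = float(grp["retention_time"].median())
        detected = fl.loc[fl["peak_area"] > config.detection_threshold, "sample_id"].nunique()
        freq = detected / n_floral
        # missing (sample, compound) rows are implicit zeros
        floral_mean = float(fl["peak_area"].sum()) / n_floral
        ambient_mean = float(am["peak_area"].sum()) / n_ambient
        failed = []
        if not (config.rt_min <= median_rt <= config.rt_max):
            failed.append("retention_time")
        if freq < config.min_freq:
            failed.append("occurrence")
        if not floral_mean > config.ambient_ratio * ambient_mean:
            failed.append("ambient_ratio")
        if compound in config.contaminants:
            failed.append("contaminant")
        audit = FilterAudit(
            compound=str(compound),
            median_rt=median_rt,
            detect_freq=freq,
            floral_mean=floral_mean,
            ambient_mean=ambient_mean,
            failed_rules=tuple(failed),
        )
        audits.append(audit)
        if audit.retained:
            retained.append(str(compound))

    audit_frame = pd.DataFrame(
        {
            "compound": [a.compound for a in audits],
            "median_rt": [a.median_rt for a in audits],
            "detect_freq": [a.detect_freq for a in audits],
            "floral_mean": [a.floral_mean for a in audits],
            "ambient_mean": [a.ambient_mean for a in audits],
            "failed_rules": [";".join(a.failed_rules) for a in audits],
            "retained": [a.retained for a in audits],
        }
    )
    return retained, audit_frame


def apply_filter(peaks: pd.DataFrame, retained: Iterable[str]) -> pd.DataFrame:
    """Subset the peak table to retained compounds, preserving the sample universe.

    Samples whose every compound was removed keep one zero-area placeholder
    row so occurrence denominators and ambient means are unchanged on
    re-filtering (filtering is idempotent).
    """
    retained = set(retained)
    kept = peaks[peaks["compound"].isin(retained)]
    lost = peaks[~peaks["sample_id"].isin(kept["sample_id"])]
    if not lost.empty:
        placeholders = lost.drop_duplicates("sample_id").copy()
        placeholders["peak_area"] = 0.0
        kept = pd.concat([kept, placeholders], ignore_index=True)
    return kept.reset_index(drop=True)


def fit_calibration(series: pd.DataFrame) -> dict[str, CalibrationCurve]:
    """Least-squares line through the origin of area on dosage, per standard.

    ``series`` needs columns ``standard``, ``dosage_ng``, ``peak_area``.
    R-squared is the uncentered through-origin version.
    """
    _require_columns(series, ["standard", "dosage_ng", "peak_area"], "dilution series")
    curves: dict[str, CalibrationCurve] = {}
    for standard, grp in series.groupby("standard", sort=True):
        x = grp["dosage_ng"].to_numpy(float)
        y = grp["peak_area"].to_numpy(float)
        if np.unique(x).size < 2:
            raise ValueError(
                f"standard {standard!r} has fewer than 2 distinct dosages; "
                "cannot fit a calibration line"
            )
        sxx = float(x @ x)
        slope = float(x @ y) / sxx
        resid = y - slope * x
        ss_res = float(resid @ resid)
        ss_tot = float(y @ y)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        # sandwich (HC0) slope variance: dilution noise is multiplicative,
        # so the homoskedastic formula would understate the uncertainty
        slope_se = float(np.sqrt((x**2 * resid**2).sum()) / sxx)
        curves[str(standard)] = CalibrationCurve(
            standard_name=str(standard),
            slope=slope,
            n_points=int(x.size),
            r_squared=r2,
            slope_se=slope_se,
        )
    return curves


def quantify_samples(
    peaks: pd.DataFrame,
    curves: Mapping[str, CalibrationCurve],
    standard_map: Mapping[str, str],
    duration_h: float = 0.25,
) -> pd.DataFrame:
    """Convert floral peak areas to emission rates (ng flower^-1 h^-1).

    rate = (area / slope) / duration_h.  Every compound present must map to
    a standard with a fitted curve; orphans raise with their names listed.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    _require_columns(peaks, ["sample_id", "compound", "peak_area"], "peak table")
    floral = peaks[peaks.get("sample_type", "floral") == "floral"].copy()
    compounds = floral["compound"].unique()
    orphans = sorted(
        c for c in compounds if c not in standard_map or standard_map[c] not in curves
    )
    if orphans:
        raise KeyError(
            f"compounds without a mapped calibration curve: {orphans}"
        )
    slopes = floral["compound"].map(lambda c: curves[standard_map[c]].slope)
    floral["emission_rate"] = floral["peak_area"] / slopes / duration_h
    cols = [c for c in ("sample_id", "plant_id", "date", "compound", "emission_rate") if c in floral.columns]
    return floral[cols].reset_index(drop=True)


def plant_means(samples: pd.DataFrame) -> pd.DataFrame:
    """Average repeated samples of each plant; one row per plant.

    Input is a long table with ``plant_id``, ``sample_id``, ``compound``,
    ``emission_rate``.  A compound absent from a sample counts as zero for
    that sample.  Returns a wide plant x compound matrix.
    """
    _require_columns(samples, ["plant_id", "sample_id", "compound", "emission_rate"], "sample table")
    if samples["plant_id"].isna().any():
        raise ValueError("sample table contains rows without a plant_id")
    per_sample = samples.pivot_table(
        index=["plant_id", "sample_id"],
        columns="compound",
        values="emission_rate",
        aggfunc="sum",
        fill_value=0.0,
    )
    matrix = per_sample.groupby(level="plant_id").mean()
    matrix.columns.name = "compound"
    matrix.attrs["scale"] = "raw"
    return matrix


def transform_sqrt(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise square root, flagged in ``attrs['scale']``."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("emission matrix has negative entries; cannot sqrt-transform")
    if matrix.attrs.get("scale") == "sqrt":
        raise ValueError("matrix is already on the sqrt scale")
    out = np.sqrt(matrix)
    out.attrs["scale"] = "sqrt"
    return out


def class_totals(
    matrix: pd.DataFrame, catalog: Mapping[str, str]
) -> pd.DataFrame:
    """Sum untransformed rates into the four compound classes plus a grand total.

    Compounds missing from ``catalog`` are summed into an ``unclassed``
    column (reported separately, included in the total).  A catalog value
    outside the four known classes raises.
    """
    if matrix.attrs.get("scale") == "sqrt":
        raise ValueError("class totals must be computed on untransformed rates")
    bad = sorted({v for v in catalog.values()} - set(COMPOUND_CLASSES))
    if bad:
        raise ValueError(f"unknown compound class label(s): {bad}")
    totals = pd.DataFrame(index=matrix.index)
    for cls in COMPOUND_CLASSES:
        cols = [c for c in matrix.columns if catalog.get(c) == cls]
        totals[cls] = matrix[cols].sum(axis=1) if cols else 0.0
    unclassed_cols = [c for c in matrix.columns if c not in catalog]
    totals["unclassed"] = matrix[unclassed_cols].sum(axis=1) if unclassed_cols else 0.0
    totals["total"] = totals[list(COMPOUND_CLASSES)].sum(axis=1) + totals["unclassed"]
    return totals
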