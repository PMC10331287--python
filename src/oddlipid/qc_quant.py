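"""Peak-table ingestion, internal-standard normalization, QC filtering and robustness.

Quantification software exports one integrated peak per sample x transition
(area, RT, peak width at half height, S/N).  This module reads those tables,
divides each species' area by its matched deuterated internal standard (so
per-sample instrument drift cancels), and applies the method's data-quality
rules:

* CV filter — a species is kept only if its coefficient of variation across
  the pooled-QC injections is below 20 %;
* blank filter — the mean study signal must exceed 5x the mean blank signal
  to count as true signal;
* S/N filter — median signal-to-noise of at least 10.

Robustness summaries report the empirical distributions of RT deviation from
prediction, FWHM, per-subclass CV, and the IS peak-area series across
consecutive injections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "PeakTable",
    "FilterVerdicts",
    "QCReport",
    "read_peak_table",
    "normalize_to_is",
    "impute_missing",
    "qc_cv_filter",
    "blank_sn_filter",
    "combine_filters",
    "robustness_summary",
]

REQUIRED_COLUMNS = ("sample", "role", "component", "area", "rt", "fwhm", "sn")
_NUMERIC = ("area", "rt", "fwhm", "sn")
ROLES = ("study", "QC", "blank")


@dataclass
class PeakTable:
    """Typed peak measurements plus row-level parse errors."""

    data: pd.DataFrame
    errors: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def by_role(self, role: str) -> pd.DataFrame:
        return self.data[self.data["role"] == role]


def read_peak_table(path_or_df: str | Path | pd.DataFrame) -> PeakTable:
    """Read a delimited peak table (sample, role, component, area, rt, fwhm, sn).

    Unknown columns are preserved; rows with non-numeric mandatory values are
    kept with NaN and reported in ``errors``; the row count is conserved.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column: {', '.join(missing)}")
    errors: list[str] = []
    for col in _NUMERIC:
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        for idx in df.index[bad]:
            errors.append(f"row {idx}: non-numeric {col} {raw[idx]!r}")
        df[col] = parsed
    unknown_roles = set(df["role"].unique()) - set(ROLES)
    for role in sorted(unknown_roles):
        errors.append(f"unknown sample role {role!r}")
    return PeakTable(data=df, errors=errors)


def normalize_to_is(
    peaks: PeakTable | pd.DataFrame,
    is_assignments: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species x samples matrix of area ratios to the matched internal standard.

    ``is_assignments`` maps each species component to its IS component (from
    the nearest-IS parameter matching).  IS components themselves are
    excluded from the output matrix.  Cells where the IS area is zero or
    missing are NaN, with the reason recorded in the returned issues table.
    """
    df = peaks.data if isinstance(peaks, PeakTable) else peaks
    area = df.pivot_table(index="component", columns="sample", values="area",
                          aggfunc="first")
    is_components = set(is_assignments.values())
    species = [c for c in area.index if c not in is_components]
    issues: list[dict] = []
    rows = {}
    for sp in species:
        is_comp = is_assignments.get(sp)
        if is_comp is None or is_comp not in area.index:
            issues.append({"component": sp, "sample": "*",
                           "reason": "no IS assignment"})
            continue
        ratio = area.loc[sp] / area.loc[is_comp]
        bad = area.loc[is_comp].isna() | (area.loc[is_comp] == 0)
        ratio[bad] = np.nan
        for sample in area.columns[bad]:
            issues.append({"component": sp, "sample": sample, "reason": "zero IS"})
        missing = area.loc[sp].isna() & ~bad
        for sample in area.columns[missing]:
            issues.append({"component": sp, "sample": sample,
                           "reason": "missing species area"})
        rows[sp] = ratio
    matrix = pd.DataFrame(rows).T
    matrix.index.name = "component"
    issues_df = pd.DataFrame(issues, columns=["component", "sample", "reason"])
    return matrix, issues_df


def impute_missing(
    matrix: pd.DataFrame, max_missing_frac: float = 0.3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop species with too many missing cells; floor-impute the rest.

    Species with more than ``max_missing_frac`` missing cells are removed;
    remaining gaps are filled with half the species minimum (the standard
    metabolomics detection-floor imputation).
    """
    frac = matrix.isna().mean(axis=1)
    dropped = pd.DataFrame(
        {"component": matrix.index[frac > max_missing_frac],
         "reason": f">{max_missing_frac:.0%} missing"}
    )
    kept = matrix.loc[frac <= max_missing_frac].copy()
    fill = kept.min(axis=1) / 2.0
    kept = kept.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    return kept, dropped


def qc_cv_filter(
    qc_matrix: pd.DataFrame, threshold_pct: float = 20.0
) -> pd.DataFrame:
    """Per-species CV% across QC injections; KEPT iff CV% < threshold.

    CV% = 100 * sample (n-1) standard deviation / mean.  Requires at least
    three QC injections.  Species with zero mean are dropped with reason
    "no signal".
    """
    if qc_matrix.shape[1] < 3:
        raise ValueError(
            f"need >= 3 QC injections, got {qc_matrix.shape[1]}"
        )
    mean = qc_matrix.mean(axis=1)
    sd = qc_matrix.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    out = pd.DataFrame({"cv_pct": cv})
    out["kept"] = (cv < threshold_pct) & (mean > 0)
    out["reason"] = ""
    out.loc[mean <= 0, ["kept", "reason"]] = [False, "no signal"]
    out.loc[(mean > 0) & (cv >= threshold_pct), "reason"] = (
        f"CV >= {threshold_pct:g}%"
    )
    return out


def blank_sn_filter(
    study_matrix: pd.DataFrame,
    blank_matrix: pd.DataFrame | None,
    sn_by_species: pd.Series | None = None,
    blank_fold: float = 5.0,
    sn_min: float = 10.0,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Blank-ratio and signal-to-noise filter.

    KEPT iff mean study signal exceeds ``blank_fold`` times the mean blank
    signal (median aggregation available as an option) and the species'
    median S/N is at least ``sn_min``.  Without blanks the blank rule is
    skipped with a warning flag in the output.
    """
    agg: Callable = pd.DataFrame.mean if aggregate == "mean" else pd.DataFrame.median
    study = agg(study_matrix, axis=1)
    out = pd.DataFrame(index=study_matrix.index)
    out["study_signal"] = study
    if blank_matrix is None or blank_matrix.empty:
        out["blank_ratio"] = np.inf
        out["blank_pass"] = True
        out["blank_skipped"] = True
    else:
        blank = agg(blank_matrix.reindex(study_matrix.index), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = study / blank
        ratio[blank == 0] = np.inf
        out["blank_ratio"] = ratio
        out["blank_pass"] = ratio > blank_fold
        out["blank_skipped"] = False
    if sn_by_species is None:
        out["sn_pass"] = True
    else:
        out["sn_pass"] = sn_by_species.reindex(study_matrix.index) >= sn_min
    out["kept"] = out["blank_pass"] & out["sn_pass"]
    out["reason"] = ""
    out.loc[~out["sn_pass"], "reason"] = "S/N"
    out.loc[~out["blank_pass"], "reason"] = f"blank ratio <= {blank_fold:g}x"
    out.loc[~out["blank_pass"] & ~out["sn_pass"], "reason"] = "blank ratio; S/N"
    return out


@dataclass
class FilterVerdicts:
    """Combined per-species verdicts; KEPT iff all enabled filters pass."""

    table: pd.DataFrame

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def combine_filters(*verdict_tables: pd.DataFrame) -> FilterVerdicts:
    """Intersect filter verdicts; order of application never matters."""
    if not verdict_tables:
        raise ValueError("no verdict tables")
    index = verdict_tables[0].index
    combined = pd.DataFrame(index=index)
    combined["kept"] = True
    reasons = pd.Series("", index=index)
    for tbl in verdict_tables:
        aligned = tbl.reindex(index)
        kept = aligned["kept"].fillna(False).astype(bool)
        combined["kept"] &= kept
        has_reason = aligned["reason"].fillna("") != ""
        reasons[has_reason] = (
            reasons[has_reason].where(reasons[has_reason] == "", reasons[has_reason] + "; ")
            + aligned["reason"][has_reason]
        )
    combined["reason"] = reasons
    return FilterVerdicts(combined)


@dataclass
class QCReport:
    """Robustness distributions of the acquisition."""

    rt_abs_dev_ecdf: tuple[np.ndarray, np.ndarray]
    fwhm_ecdf: tuple[np.ndarray, np.ndarray]
    cv_by_subclass: pd.DataFrame          # columns: subclass, component, cv_pct
    is_drift: pd.DataFrame                # IS area per injection order
    fraction_fwhm_within: float           # FWHM <= 0.7 min
    fraction_rtdev_within: float          # |dRT| <= 0.5 min


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = np.sort(values[~np.isnan(values)])
    return v, (np.arange(1, len(v) + 1) / len(v) if len(v) else np.array([]))


def robustness_summary(
    peaks: PeakTable | pd.DataFrame,
    predicted_rt: Mapping[str, float] | None = None,
    is_components: Sequence[str] = (),
    subclass_of: Callable[[str], str] | None = None,
    fwhm_limit_min: float = 0.7,
    rtdev_limit_min: float = 0.5,
) -> QCReport:
    """Distributional robustness summary over QC injections.

    Computes ECDFs of |predicted - observed| RT and FWHM, per-subclass CV%
    of QC areas, the IS peak-area series in injection order, and the
    fractions of species within the FWHM and RT-deviation limits.
    """
    df = peaks.data if isinstance(peaks, PeakTable) else peaks
    qc = df[df["role"] == "QC"]
    if qc["sample"].nunique() < 2:
        raise ValueError("need >= 2 QC injections for a robustness summary")
    subclass_of = subclass_of or (lambda name: str(name).split(" ")[0])

    obs_rt = qc.groupby("component")["rt"].median()
    if predicted_rt:
        common = [c for c in obs_rt.index if c in predicted_rt]
        devs = np.array([abs(predicted_rt[c] - obs_rt[c]) for c in common])
    else:
        devs = np.array([])
    fwhm = qc["fwhm"].to_numpy(dtype=float)

    area = qc.pivot_table(index="component", columns="sample", values="area",
                          aggfunc="first")
    analyte = area.drop(index=[c for c in is_components if c in area.index])
    mean = analyte.mean(axis=1)
    cv = 100.0 * analyte.std(axis=1, ddof=1) / mean
    cv_tbl = pd.DataFrame(
        {
            "component": analyte.index,
            "subclass": [subclass_of(c) for c in analyte.index],
            "cv_pct": cv.to_numpy(),
        }
    )

    is_rows = area.reindex([c for c in is_components if c in area.index])
    is_drift = is_rows.T.reset_index().rename(columns={"sample": "injection"})

    frac_fwhm = float(np.mean(fwhm[~np.isnan(fwhm)] <= fwhm_limit_min)) if len(fwhm) else 1.0
    frac_rt = float(np.mean(devs <= rtdev_limit_min)) if len(devs) else 1.0
    return QCReport(
        rt_abs_dev_ecdf=_ecdf(devs),
        fwhm_ecdf=_ecdf(fwhm),
        cv_by_subclass=cv_tbl,
        is_drift=is_drift,
        fraction_fwhm_within=frac_fwhm,
        fraction_rtdev_within=frac_rt,
    )
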