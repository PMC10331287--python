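"""End-to-end orchestration: peak table -> QC -> quantification -> statistics.

Ties the modules together the way an analyst would run them: normalize the
peak table to internal standards, apply the QC / blank / S-N filters,
impute and preprocess, then run the univariate and PLS-DA statistics for
each group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import diff_stats, qc_quant

__all__ = ["ComparisonResult", "differential_analysis"]


@dataclass
class ComparisonResult:
    """Per-comparison statistics table and fitted PLS-DA model."""

    group1: str
    group2: str
    results: pd.DataFrame          # p, p_adj, fc, vip, differential, volcano
    model: diff_stats.PLSModel
    s_plot: pd.DataFrame


def differential_analysis(
    peaks: pd.DataFrame,
    design: pd.DataFrame,
    is_assignments: Mapping[str, str],
    comparisons: Sequence[tuple[str, str]],
    cv_threshold_pct: float = 20.0,
    blank_fold: float = 5.0,
    sn_min: float = 10.0,
    iqr_drop_fraction: float = 0.10,
) -> dict[str, ComparisonResult]:
    """Run the full quantification + statistics pipeline on a peak table.

    Returns one ComparisonResult per (group1, group2) pair, keyed
    "group1 vs group2".  Filtering: QC CV < threshold, study signal above
    ``blank_fold`` times blank, median S/N >= ``sn_min``; surviving species
    are floor-imputed, IQR-filtered, logged and Pareto-scaled before
    testing.
    """
    table = qc_quant.read_peak_table(peaks)
    matrix, _ = qc_quant.normalize_to_is(table, dict(is_assignments))

    role = design.set_index("sample")["role"]
    group = design.set_index("sample")["group"]
    qc_samples = [s for s in matrix.columns if role.get(s) == "QC"]
    blank_samples = [s for s in matrix.columns if role.get(s) == "blank"]
    study_samples = [s for s in matrix.columns if role.get(s) == "study"]

    cv_verdicts = qc_quant.qc_cv_filter(matrix[qc_samples], cv_threshold_pct)
    sn_med = (
        table.data[table.data["role"] == "study"]
        .groupby("component")["sn"].median()
    )
    blank_verdicts = qc_quant.blank_sn_filter(
        matrix[study_samples],
        matrix[blank_samples] if blank_samples else None,
        sn_by_species=sn_med,
        blank_fold=blank_fold,
        sn_min=sn_min,
    )
    verdicts = qc_quant.combine_filters(cv_verdicts, blank_verdicts)
    kept = matrix.loc[verdicts.kept, study_samples]
    kept, _ = qc_quant.impute_missing(kept)

    prep = diff_stats.preprocess(kept, iqr_drop_fraction=iqr_drop_fraction)
    processed = prep.matrix
    raw = kept.loc[processed.index]
    study_design = group[study_samples]

    out: dict[str, ComparisonResult] = {}
    for g1, g2 in comparisons:
        stats_tbl = diff_stats.welch_fc(raw, processed, study_design, g1, g2)
        model, vip = diff_stats.plsda_vip(processed, study_design, g1, g2)
        stats_tbl["vip"] = vip
        stats_tbl["differential"] = diff_stats.select_differential(stats_tbl)
        stats_tbl["volcano"] = diff_stats.volcano(stats_tbl)
        out[f"{g1} vs {g2}"] = ComparisonResult(
            group1=g1,
            group2=g2,
            results=stats_tbl,
            model=model,
            s_plot=diff_stats.splot(model, processed),
        )
    return out
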