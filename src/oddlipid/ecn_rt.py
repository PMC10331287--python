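"""Equivalent-carbon-number (ECN) retention-time model.

Within a lipid subclass on reverse-phase LC, retention time is a smooth
function of acyl carbon number, shifted down by unsaturation.  The model
fitted here is a quadratic in relative coordinates,

    y = a + b*x + c*x**2,   x = CN / CN_max,   y = RT / gradient_minutes,

fitted by ordinary least squares per (subclass, double-bond stratum) to the
retention times of internal standards (or, for subclasses lacking standards,
of high-S/N peaks).  Predicted RTs anchor the scheduled-MRM windows; the
deviation between predicted and observed RT is the method's robustness
metric (worst case in practice well under 0.5 min).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem_core import LipidSpecies

__all__ = [
    "CalibrationPoint",
    "RTModel",
    "RTPrediction",
    "RTDeviationReport",
    "fit_ecn",
    "predict_rt",
    "fit_subclass_models",
    "rt_deviation_report",
]

DEFAULT_GRADIENT_MINUTES = 17.0  # total LC runtime
CN_EXTRAPOLATION_MARGIN = 4      # carbons beyond the calibrated range


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibrant: a species' carbon number, unsaturation and observed RT."""

    species: str
    subclass: str
    carbons: int
    double_bonds: int
    rt_min: float
    source: str = "IS"  # "IS" | "high-S/N peak"

    def __post_init__(self) -> None:
        if self.carbons <= 0:
            raise ValueError("carbon number must be positive")
        if self.rt_min <= 0:
            raise ValueError("retention time must be positive")


@dataclass(frozen=True)
class RTModel:
    """Fitted quadratic y = a + b x + c x^2 in relative coordinates."""

    subclass: str
    stratum: int            # double-bond count of the stratum
    a: float
    b: float
    c: float
    cn_max: float           # normalization constant for x = CN/cn_max
    gradient_minutes: float
    r2: float
    n: int
    cn_lo: int              # calibrated CN range
    cn_hi: int

    def in_range(self, cn: float) -> bool:
        return (
            self.cn_lo - CN_EXTRAPOLATION_MARGIN
            <= cn
            <= self.cn_hi + CN_EXTRAPOLATION_MARGIN
        )

    def evaluate(self, cn: float) -> float:
        x = cn / self.cn_max
        return self.gradient_minutes * (self.a + self.b * x + self.c * x * x)


@dataclass(frozen=True)
class RTPrediction:
    rt_min: float
    extrapolated: bool


def fit_ecn(
    points: Sequence[CalibrationPoint],
    subclass: str,
    stratum: int,
    cn_max: float | None = None,
    gradient_minutes: float = DEFAULT_GRADIENT_MINUTES,
) -> RTModel:
    """Fit the quadratic ECN model to calibration points of one stratum by OLS.

    ``cn_max`` defaults to the largest calibrated CN of the subclass so that
    x stays in (0, 1].  Requires >= 3 points at >= 3 distinct carbon numbers
    (the design is rank-deficient otherwise).
    """
    pts = [p for p in points if p.subclass == subclass and p.double_bonds == stratum]
    if len(pts) < 3:
        raise ValueError(
            f"need >= 3 calibration points for {subclass} stratum {stratum}, "
            f"got {len(pts)}"
        )
    cns = np.array([p.carbons for p in pts], dtype=float)
    if len(np.unique(cns)) < 3:
        raise ValueError("rank-deficient design: fewer than 3 distinct carbon numbers")
    if cn_max is None:
        cn_max = float(cns.max())
    if cn_max <= 0:
        raise ValueError("cn_max must be positive")
    x = cns / cn_max
    y = np.array([p.rt_min for p in pts], dtype=float) / gradient_minutes
    design = np.column_stack([np.ones_like(x), x, x * x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return RTModel(
        subclass=subclass,
        stratum=stratum,
        a=float(coef[0]),
        b=float(coef[1]),
        c=float(coef[2]),
        cn_max=float(cn_max),
        gradient_minutes=gradient_minutes,
        r2=float(np.clip(r2, 0.0, 1.0)),
        n=len(pts),
        cn_lo=int(cns.min()),
        cn_hi=int(cns.max()),
    )


def predict_rt(model: RTModel, species: LipidSpecies | int) -> RTPrediction:
    """Predict the RT of a species (or raw carbon number) from a fitted model.

    Predictions outside the calibrated CN range (plus a 4-carbon margin) are
    returned with the EXTRAPOLATED flag rather than refused.
    """
    if isinstance(species, LipidSpecies):
        if species.subclass != model.subclass:
            raise ValueError(
                f"model is for {model.subclass}, species is {species.subclass}"
            )
        cn = species.total_carbons
    else:
        cn = int(species)
    return RTPrediction(rt_min=model.evaluate(cn), extrapolated=not model.in_range(cn))


def fit_subclass_models(
    points: Sequence[CalibrationPoint],
    gradient_minutes: float = DEFAULT_GRADIENT_MINUTES,
) -> dict[tuple[str, int], RTModel]:
    """Fit one model per (subclass, double-bond stratum) with sparse-stratum fallback.

    Strata with fewer than 3 usable points inherit the subclass's saturated
    fit shifted by a constant per-stratum RT offset estimated from whatever
    points the stratum does have (or by a per-double-bond offset pooled
    across strata when it has none).
    """
    by_sub: dict[str, list[CalibrationPoint]] = {}
    for p in points:
        by_sub.setdefault(p.subclass, []).append(p)

    models: dict[tuple[str, int], RTModel] = {}
    for sub, pts in by_sub.items():
        cn_max = float(max(p.carbons for p in pts))
        strata = sorted({p.double_bonds for p in pts})
        fitted: dict[int, RTModel] = {}
        for stratum in strata:
            sp = [p for p in pts if p.double_bonds == stratum]
            if len(sp) >= 3 and len({p.carbons for p in sp}) >= 3:
                fitted[stratum] = fit_ecn(
                    sp, sub, stratum, cn_max=cn_max, gradient_minutes=gradient_minutes
                )
        if not fitted:
            continue
        reference = fitted.get(0) or fitted[min(fitted)]
        # per-double-bond offset pooled over sparse strata with data
        offsets: list[float] = []
        for stratum in strata:
            if stratum in fitted or stratum == reference.stratum:
                continue
            sp = [p for p in pts if p.double_bonds == stratum]
            per_db = [
                (p.rt_min - reference.evaluate(p.carbons)) / (stratum - reference.stratum)
                for p in sp
                if stratum != reference.stratum
            ]
            offsets.extend(per_db)
        pooled_per_db = float(np.mean(offsets)) if offsets else 0.0
        for stratum in strata:
            if stratum in fitted:
                models[(sub, stratum)] = fitted[stratum]
                continue
            sp = [p for p in pts if p.double_bonds == stratum]
            if sp:
                offset = float(
                    np.mean([p.rt_min - reference.evaluate(p.carbons) for p in sp])
                )
            else:
                offset = pooled_per_db * (stratum - reference.stratum)
            models[(sub, stratum)] = RTModel(
                subclass=sub,
                stratum=stratum,
                a=reference.a + offset / (gradient_minutes),
                b=reference.b,
                c=reference.c,
                cn_max=reference.cn_max,
                gradient_minutes=gradient_minutes,
                r2=reference.r2,
                n=len(sp),
                cn_lo=reference.cn_lo,
                cn_hi=reference.cn_hi,
            )
    return models


@dataclass(frozen=True)
class RTDeviationReport:
    """|predicted - observed| RT deviations and their empirical distribution."""

    deviations: Mapping[str, float]          # species -> |delta RT| (min)
    ecdf_x: np.ndarray                        # sorted |delta RT|
    ecdf_y: np.ndarray                        # cumulative fractions
    fraction_exceeding: float                 # fraction with |delta| > threshold
    flagged: tuple[str, ...]                  # species needing wider windows
    threshold_min: float
    unmatched: int                            # species present on one side only

    @property
    def max_deviation(self) -> float:
        return max(self.deviations.values()) if self.deviations else 0.0


def rt_deviation_report(
    predicted: Mapping[str, float],
    observed: Mapping[str, float],
    threshold_min: float = 0.5,
) -> RTDeviationReport:
    """Compare predicted with observed RTs and flag species beyond the threshold.

    Species present on only one side are skipped and counted in a warning.
    """
    common = sorted(set(predicted) & set(observed))
    unmatched = len(set(predicted) ^ set(observed))
    if unmatched:
        warnings.warn(f"{unmatched} species unmatched between predicted and observed")
    deviations = {s: abs(predicted[s] - observed[s]) for s in common}
    values = np.sort(np.array(list(deviations.values()), dtype=float))
    ecdf_y = (
        np.arange(1, len(values) + 1) / len(values) if len(values) else np.array([])
    )
    flagged = tuple(s for s in common if deviations[s] > threshold_min)
    frac = float(np.mean(values > threshold_min)) if len(values) else 0.0
    return RTDeviationReport(
        deviations=deviations,
        ecdf_x=values,
        ecdf_y=ecdf_y,
        fraction_exceeding=frac,
        flagged=flagged,
        threshold_min=threshold_min,
        unmatched=unmatched,
    )
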