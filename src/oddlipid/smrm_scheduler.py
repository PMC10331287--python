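"""Scheduled-MRM acquisition design: RT windows and dwell-time allocation.

Scheduled MRM monitors each transition only inside a retention-time window
around its (predicted or measured) RT, so hundreds of transitions fit in one
run.  The scheduler assigns each transition a window (default half-width
0.5 min — the worst prediction error of the ECN model — widened per species
when the deviation report flags it) and a dwell time by abundance tier:
abundant lipids need little dwell, low-abundance lipids get up to 3x the
base dwell, and all dwells are rescaled wherever co-eluting transitions
would push the cycle time (sum of dwells plus inter-transition pauses) over
the budget.  The budget default (0.75 s) keeps at least 8 points per peak at
the narrowest observed peak width (0.1 min FWHM).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mrm_builder import MRMTransition

__all__ = [
    "ScheduleConfig",
    "ScheduledTransition",
    "ConcurrencyProfile",
    "merge_shared_channels",
    "build_schedule",
    "concurrency_check",
    "export_schedule",
    "read_schedule",
]

TIER_MULTIPLIER = {"high": 1.0, "medium": 2.0, "low": 3.0}
_GRID_STEP_MIN = 0.01


@dataclass(frozen=True)
class ScheduleConfig:
    cycle_budget_s: float = 0.75
    min_points_per_peak: int = 8
    min_fwhm_min: float = 0.1
    pause_ms: float = 2.0
    default_half_width_min: float = 0.5
    min_dwell_ms: float = 3.0
    gradient_minutes: float = 17.0

    def __post_init__(self) -> None:
        for name in (
            "cycle_budget_s",
            "min_points_per_peak",
            "min_fwhm_min",
            "pause_ms",
            "default_half_width_min",
            "min_dwell_ms",
            "gradient_minutes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ScheduledTransition:
    transition: MRMTransition
    rt_center_min: float
    half_width_min: float
    dwell_ms: float
    tier: str = "medium"

    def __post_init__(self) -> None:
        if self.half_width_min <= 0:
            raise ValueError("window half-width must be positive")
        if self.tier not in TIER_MULTIPLIER:
            raise ValueError(f"unknown abundance tier {self.tier!r}")

    @property
    def window(self) -> tuple[float, float]:
        return (self.rt_center_min - self.half_width_min,
                self.rt_center_min + self.half_width_min)


class InfeasibleScheduleError(ValueError):
    """Even minimum dwell times exceed the cycle budget somewhere."""

    def __init__(self, rt_lo: float, rt_hi: float, n_active: int):
        super().__init__(
            f"cycle budget infeasible between {rt_lo:.2f} and {rt_hi:.2f} min "
            f"({n_active} concurrent transitions at minimum dwell)"
        )
        self.congested_interval = (rt_lo, rt_hi)


def _active_matrix(
    entries: Sequence[ScheduledTransition], grid: np.ndarray
) -> np.ndarray:
    """Boolean (n_entries, n_grid) activity matrix on the time grid."""
    lo = np.array([e.window[0] for e in entries])[:, None]
    hi = np.array([e.window[1] for e in entries])[:, None]
    return (grid[None, :] >= lo) & (grid[None, :] <= hi)


def _clusters(entries: Sequence[ScheduledTransition]) -> list[list[int]]:
    """Indices grouped into connected components of overlapping windows."""
    order = sorted(range(len(entries)), key=lambda i: entries[i].window[0])
    clusters: list[list[int]] = []
    current: list[int] = []
    reach = -np.inf
    for i in order:
        lo, hi = entries[i].window
        if current and lo > reach:
            clusters.append(current)
            current = []
            reach = -np.inf
        current.append(i)
        reach = max(reach, hi)
    if current:
        clusters.append(current)
    return clusters


def merge_shared_channels(
    transitions: Sequence[MRMTransition],
    rt_centers: Sequence[float],
    rt_round_min: float = 0.1,
) -> tuple[list[MRMTransition], list[float]]:
    """Merge transitions sharing (Q1, Q3, polarity) within one RT bin.

    Acyl-combination isomers of a sum composition share precursor and
    product channels and elute together; monitoring them twice wastes cycle
    time, so shared channels are collapsed into one entry whose id joins the
    member species.
    """
    merged: dict[tuple, list[int]] = {}
    for i, (t, rt) in enumerate(zip(transitions, rt_centers)):
        key = (t.q1, t.q3, t.polarity, round(rt / rt_round_min))
        merged.setdefault(key, []).append(i)
    out_t: list[MRMTransition] = []
    out_rt: list[float] = []
    for idx in merged.values():
        first = transitions[idx[0]]
        species = sorted({transitions[i].species_name for i in idx})
        rts = [rt_centers[i] for i in idx]
        out_t.append(
            MRMTransition(
                species_name="; ".join(species),
                q1=first.q1, q3=first.q3, polarity=first.polarity,
                annotation=first.annotation, ce=first.ce, dp=first.dp,
                cxp=first.cxp, dwell_ms=first.dwell_ms,
            )
        )
        out_rt.append(float(np.mean(rts)))
    return out_t, out_rt


def build_schedule(
    transitions: Sequence[MRMTransition],
    rt_centers: Mapping[str, float] | Sequence[float],
    config: ScheduleConfig = ScheduleConfig(),
    tiers: Mapping[str, str] | None = None,
    extra_half_width: Mapping[str, float] | None = None,
) -> list[ScheduledTransition]:
    """Assign RT windows and dwell times under the cycle-time budget.

    ``rt_centers`` gives each transition's RT center, keyed by species name
    (or positionally).  ``tiers`` maps species to abundance tiers
    (high/medium/low, default medium); ``extra_half_width`` carries
    per-species RT-deviation magnitudes from the deviation report — the
    window half-width is max(default, flagged deviation).  Dwells start at
    tier multiples of the minimum dwell and are rescaled per overlap cluster
    so the concurrent cycle time never exceeds the budget.  Deterministic.
    """
    if isinstance(rt_centers, Mapping):
        centers = [rt_centers[t.species_name] for t in transitions]
    else:
        centers = list(rt_centers)
    if len(centers) != len(transitions):
        raise ValueError("one RT center per transition required")

    entries: list[ScheduledTransition] = []
    for t, rt in zip(transitions, centers):
        tier = (tiers or {}).get(t.species_name, "medium")
        hw = config.default_half_width_min
        if extra_half_width and t.species_name in extra_half_width:
            hw = max(hw, extra_half_width[t.species_name])
        dwell = config.min_dwell_ms * TIER_MULTIPLIER[tier]
        entries.append(
            ScheduledTransition(
                transition=t, rt_center_min=rt, half_width_min=hw,
                dwell_ms=dwell, tier=tier,
            )
        )
    if not entries:
        return []

    budget_ms = config.cycle_budget_s * 1000.0
    for cluster in _clusters(entries):
        members = [entries[i] for i in cluster]
        lo = min(e.window[0] for e in members)
        hi = max(e.window[1] for e in members)
        grid = np.arange(lo, hi + _GRID_STEP_MIN, _GRID_STEP_MIN)
        active = _active_matrix(members, grid)
        dwells = np.array([e.dwell_ms for e in members])
        pause_load = active.sum(axis=0) * config.pause_ms
        dwell_load = dwells @ active
        # feasibility at minimum dwell
        min_load = config.min_dwell_ms * active.sum(axis=0) + pause_load
        if (min_load > budget_ms).any():
            j = int(np.argmax(min_load))
            bad = min_load > budget_ms
            raise InfeasibleScheduleError(
                float(grid[bad].min()), float(grid[bad].max()),
                int(active[:, j].sum()),
            )
        over = dwell_load + pause_load > budget_ms
        if over.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(
                    dwell_load > 0, (budget_ms - pause_load) / dwell_load, np.inf
                )
            factor = float(min(1.0, scale[over].min()))
            new_dwells = np.maximum(dwells * factor, config.min_dwell_ms)
            # clipping at the floor may re-violate; trim tiers above the floor
            dwell_load = new_dwells @ active
            over2 = dwell_load + pause_load > budget_ms
            if over2.any():
                # all-minimum fallback is feasible (checked above)
                headroom = budget_ms - pause_load - config.min_dwell_ms * active.sum(axis=0)
                excess = new_dwells - config.min_dwell_ms
                with np.errstate(divide="ignore", invalid="ignore"):
                    scale2 = np.where(
                        excess @ active > 0, headroom / (excess @ active), np.inf
                    )
                factor2 = float(min(1.0, max(0.0, scale2[over2].min())))
                new_dwells = config.min_dwell_ms + excess * factor2
            for idx, e, dw in zip(cluster, members, new_dwells):
                entries[idx] = replace(e, dwell_ms=float(dw))

    entries.sort(key=lambda e: (e.rt_center_min, e.transition.q1, e.transition.q3))
    return entries


@dataclass(frozen=True)
class ConcurrencyProfile:
    """Points-per-peak per transition, assuming the configured minimum FWHM."""

    points_per_peak: Mapping[str, float]   # keyed by (species | annotation) id
    min_points: float | None
    below_minimum: tuple[str, ...]


def _entry_id(e: ScheduledTransition) -> str:
    return f"{e.transition.species_name} | {e.transition.annotation}"


def concurrency_check(
    schedule: Sequence[ScheduledTransition],
    config: ScheduleConfig = ScheduleConfig(),
) -> ConcurrencyProfile:
    """Points-per-peak = assumed FWHM / worst cycle time inside each window."""
    if not schedule:
        return ConcurrencyProfile({}, None, ())
    lo = min(e.window[0] for e in schedule)
    hi = max(e.window[1] for e in schedule)
    grid = np.arange(lo, hi + _GRID_STEP_MIN, _GRID_STEP_MIN)
    active = _active_matrix(schedule, grid)
    dwells = np.array([e.dwell_ms for e in schedule])
    load_ms = dwells @ active + active.sum(axis=0) * config.pause_ms
    fwhm_s = config.min_fwhm_min * 60.0
    ppp: dict[str, float] = {}
    for i, e in enumerate(schedule):
        cycle_ms = float(load_ms[active[i]].max())
        ppp[_entry_id(e)] = fwhm_s / (cycle_ms / 1000.0)
    below = tuple(k for k, v in ppp.items() if v < config.min_points_per_peak)
    return ConcurrencyProfile(ppp, min(ppp.values()), below)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_COLUMNS = [
    "Q1", "Q3", "rt_min", "window_half_width_min", "dwell_ms", "species",
    "annotation", "tier", "CE", "DP", "CXP", "polarity",
]


def export_schedule(
    schedule: Sequence[ScheduledTransition],
    out_prefix: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Vendor-neutral acquisition tables, one per polarity.

    Rows are sorted by (RT, Q1); duplicate (Q1, Q3, RT) rows are rejected.
    With ``out_prefix`` the tables are written to
    ``<prefix>_positive.csv`` / ``<prefix>_negative.csv``.
    """
    if not schedule:
        raise ValueError("empty schedule")
    rows = [
        {
            "Q1": e.transition.q1,
            "Q3": e.transition.q3,
            "rt_min": e.rt_center_min,
            "window_half_width_min": e.half_width_min,
            "dwell_ms": e.dwell_ms,
            "species": e.transition.species_name,
            "annotation": e.transition.annotation,
            "tier": e.tier,
            "CE": e.transition.ce,
            "DP": e.transition.dp,
            "CXP": e.transition.cxp,
            "polarity": e.transition.polarity,
        }
        for e in schedule
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if df.duplicated(subset=["Q1", "Q3", "rt_min"]).any():
        dup = df[df.duplicated(subset=["Q1", "Q3", "rt_min"], keep=False)]
        raise ValueError(
            f"duplicate (Q1, Q3, RT) rows in schedule: "
            f"{dup[['Q1', 'Q3', 'rt_min']].drop_duplicates().to_dict('records')}"
        )
    out: dict[str, pd.DataFrame] = {}
    for polarity, part in df.groupby("polarity", sort=True):
        part = part.sort_values(["rt_min", "Q1"], kind="mergesort").reset_index(drop=True)
        out[polarity] = part
        if out_prefix is not None:
            path = Path(f"{out_prefix}_{polarity}.csv")
            path.parent.mkdir(parents=True, exist_ok=True)
            part.to_csv(path, index=False)
    return out


def read_schedule(paths: Iterable[str | Path]) -> list[ScheduledTransition]:
    """Read exported acquisition tables back into scheduled transitions."""
    entries: list[ScheduledTransition] = []
    for path in paths:
        df = pd.read_csv(path)
        for row in df.itertuples(index=False):
            t = MRMTransition(
                species_name=row.species,
                q1=float(row.Q1),
                q3=float(row.Q3),
                polarity=row.polarity,
                annotation=row.annotation,
                ce=None if pd.isna(row.CE) else float(row.CE),
                dp=None if pd.isna(row.DP) else float(row.DP),
                cxp=None if pd.isna(row.CXP) else float(row.CXP),
                dwell_ms=None,
            )
            entries.append(
                ScheduledTransition(
                    transition=t,
                    rt_center_min=float(row.rt_min),
                    half_width_min=float(row.window_half_width_min),
                    dwell_ms=float(row.dwell_ms),
                    tier=row.tier,
                )
            )
    entries.sort(key=lambda e: (e.rt_center_min, e.transition.q1, e.transition.q3))
    return entries
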