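"""Synthetic study generator for the odd-chain lipidomics pipeline.

Emulates everything a desk run of the pipeline needs: a deuterated
internal-standard panel whose retention times lie on per-subclass ECN
curves, and a three-group tissue study (distant-normal / adjacent / tumor,
called CC-A / CC-B / CC-C, n = 12 each) with planted group effects — TAG
species elevated in the adjacent group and a phospholipid subset (PA, PC,
PG) depressed there, the qualitative remodeling pattern the method is built
to detect — plus pooled-QC replicate injections with multiplicative
instrument noise and solvent-blank injections.

Noise model: peak areas are multiplicative log-normal (the standard model
for MRM peak areas); retention times carry additive Gaussian noise.  Every
sample has a global drift factor shared between analytes and internal
standards, so IS normalization cancels it by construction.  All randomness
flows from the single config seed; a fixed seed gives byte-identical
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_core import LibraryConfig, LipidSpecies, enumerate_odd_library
from .ecn_rt import CalibrationPoint
from .mrm_builder import ISRecord, assign_acquisition_params

__all__ = [
    "SimulationConfig",
    "StudyData",
    "default_study_library",
    "simulate_calibration_panel",
    "simulate_is_panel",
    "simulate_study",
    "simulate_qc_matrix",
    "write_fixtures",
    "read_fixtures",
]

# Per-subclass acquisition defaults for simulated internal standards.
_IS_PARAMS: Mapping[str, tuple[float, float, float]] = {
    # subclass: (CE volts, DP volts, dwell ms)
    "TAG": (38.0, 100.0, 5.0), "DAG": (30.0, 80.0, 5.0), "MAG": (25.0, 60.0, 5.0),
    "PA": (-40.0, -90.0, 5.0), "PC": (-45.0, -100.0, 5.0), "PE": (-42.0, -95.0, 5.0),
    "PG": (-40.0, -90.0, 5.0), "PI": (-48.0, -110.0, 5.0), "PS": (-44.0, -100.0, 5.0),
    "LPC": (-38.0, -80.0, 5.0), "LPE": (-36.0, -80.0, 5.0),
    "SM": (30.0, 90.0, 5.0), "Cer": (32.0, 85.0, 5.0), "dhCer": (32.0, 85.0, 5.0),
    "HexCer": (34.0, 90.0, 5.0), "LacCer": (36.0, 95.0, 5.0), "FFA": (-20.0, -60.0, 5.0),
}

# True per-subclass ECN curve coefficients (relative RT vs CN/cn_norm).
_DEFAULT_ECN: Mapping[str, tuple[float, float, float]] = {
    "TAG": (0.10, 1.00, -0.25), "DAG": (0.08, 1.00, -0.25),
    "PA": (0.06, 1.00, -0.25), "PC": (0.09, 1.00, -0.25),
    "PE": (0.07, 1.00, -0.25), "PG": (0.05, 1.00, -0.25),
    "PI": (0.04, 1.00, -0.25), "PS": (0.06, 1.00, -0.25),
}
_CN_NORM = 60.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults follow the emulated study design: three groups of 12 tissue
    samples, 10 consecutive pooled-QC injections with 7 % multiplicative
    noise, solvent blanks at a small fraction of the study signal, and RT
    noise of 1 % of the gradient on the calibration standards.
    """

    seed: int = 0
    groups: tuple[str, ...] = ("CC-A", "CC-B", "CC-C")
    n_per_group: int = 12
    qc_injections: int = 10
    n_blanks: int = 3
    qc_sigma: float = 0.07            # log-scale multiplicative QC noise
    biological_sigma: float = 0.25    # log-scale between-sample variation
    drift_sigma: float = 0.05         # per-sample global drift
    blank_fraction: float = 0.05      # blank signal / median study signal
    rt_noise_min: float = 0.17        # calibration RT noise (1% of gradient)
    rt_obs_noise_min: float = 0.05    # observed-peak RT noise
    gradient_minutes: float = 17.0
    baseline_log_mean: float = np.log(1e5)
    baseline_log_sigma: float = 1.0
    is_area: float = 1e5
    tag_fold: float = 2.0             # TAG effect in the adjacent group
    phospholipid_fold: float = 0.5    # PA/PC/PG effect in the adjacent group
    affected_group: str = "CC-B"
    up_subclasses: tuple[str, ...] = ("TAG",)
    down_subclasses: tuple[str, ...] = ("PA", "PC", "PG")
    ecn_coefficients: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_ECN)
    )

    def __post_init__(self) -> None:
        if self.tag_fold <= 0 or self.phospholipid_fold <= 0:
            raise ValueError("planted fold changes must be positive")


def default_study_library() -> list[LipidSpecies]:
    """Compact odd-chain library used for the simulated study.

    Odd acyls 15:0/15:1/17:0/17:1 with even partners 16 and 18 over TAG,
    DAG and the six diacyl phospholipid classes — a few hundred species,
    enough to exercise every pipeline stage at desk scale.
    """
    config = LibraryConfig(
        subclasses=("TAG", "DAG", "PA", "PC", "PE", "PG", "PI", "PS"),
        odd_carbons=(15, 17),
        even_carbons=(16, 18),
        double_bonds=(0, 1),
    )
    return enumerate_odd_library(config)


def _true_rt(config: SimulationConfig, subclass: str, cn: float) -> float:
    a, b, c = config.ecn_coefficients.get(subclass, (0.08, 1.00, -0.25))
    x = cn / _CN_NORM
    return config.gradient_minutes * (a + b * x + c * x * x)


# ---------------------------------------------------------------------------
# Calibration / IS panel
# ---------------------------------------------------------------------------

def simulate_calibration_panel(
    seed: int,
    subclass: str = "TAG",
    n_points: int = 12,
    cn_range: tuple[int, int] = (30, 60),
    rel_rt_range: tuple[float, float] = (0.3, 0.9),
    noise_fraction: float = 0.01,
    gradient_minutes: float = 17.0,
) -> list[CalibrationPoint]:
    """An IS-like calibration panel on a concave quadratic ECN curve.

    Carbon numbers span ``cn_range``; the true relative RT is a concave
    quadratic mapped onto ``rel_rt_range`` of the gradient; Gaussian noise
    with sd ``noise_fraction`` of the gradient length is added.
    """
    rng = np.random.default_rng(seed)
    cns = np.linspace(cn_range[0], cn_range[1], n_points).round().astype(int)
    x = cns / cn_range[1]
    # concave quadratic in x, rescaled to cover rel_rt_range
    raw = 1.6 * x - 0.6 * x * x
    lo, hi = raw.min(), raw.max()
    rel = rel_rt_range[0] + (raw - lo) * (rel_rt_range[1] - rel_rt_range[0]) / (hi - lo)
    rt = rel * gradient_minutes + rng.normal(
        0.0, noise_fraction * gradient_minutes, size=n_points
    )
    rt = np.clip(rt, 0.05, gradient_minutes)
    return [
        CalibrationPoint(
            species=f"{subclass} {cn}:0", subclass=subclass, carbons=int(cn),
            double_bonds=0, rt_min=float(r), source="IS",
        )
        for cn, r in zip(cns, rt)
    ]


def simulate_is_panel(
    config: SimulationConfig,
    subclasses: Sequence[str] = ("TAG", "DAG", "PA", "PC", "PE", "PG", "PI", "PS"),
) -> tuple[list[ISRecord], list[CalibrationPoint]]:
    """Deuterated-IS panel with RTs on the true per-subclass ECN curves.

    Each subclass gets six saturated standards across its CN range plus
    three monounsaturated ones (enough to fit both strata), with subclass-
    default CE/DP/dwell.  Deterministic under the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cn_grid = {
        "TAG": np.arange(45, 57, 2), "DAG": np.arange(30, 42, 2),
    }
    records: list[ISRecord] = []
    points: list[CalibrationPoint] = []
    for sub in subclasses:
        cns = cn_grid.get(sub, np.arange(30, 42, 2))
        strata = [(0, cns), (1, cns[:3])]
        for db, cn_list in strata:
            for cn in cn_list:
                rt = _true_rt(config, sub, cn) - 0.12 * db
                rt += float(rng.normal(0.0, config.rt_noise_min))
                rt = float(np.clip(rt, 0.05, config.gradient_minutes))
                ce, dp, dwell = _IS_PARAMS[sub]
                name = f"IS {sub} {int(cn)}:{db}-d7"
                records.append(
                    ISRecord(
                        name=name, subclass=sub, carbons=int(cn), double_bonds=db,
                        rt_min=rt, ce=ce, dp=dp, dwell_ms=dwell,
                    )
                )
                points.append(
                    CalibrationPoint(
                        species=name, subclass=sub, carbons=int(cn),
                        double_bonds=db, rt_min=rt, source="IS",
                    )
                )
    return records, points


# ---------------------------------------------------------------------------
# Study peak tables
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """A simulated study: peak table, design, IS assignments and ground truth."""

    peaks: pd.DataFrame               # peak-table dialect (sample, role, ...)
    design: pd.DataFrame              # sample, role, group, injection order
    is_panel: list[ISRecord]
    calibration: list[CalibrationPoint]
    is_assignments: dict[str, str]    # species name -> IS name
    truth: pd.DataFrame               # component, subclass, planted fold
    true_rt: dict[str, float]         # species name -> noise-free RT


def simulate_study(
    config: SimulationConfig,
    library: Sequence[LipidSpecies] | None = None,
) -> StudyData:
    """Simulate the full study peak table with planted group effects.

    Analyte areas are log-normal around a per-species baseline, multiplied
    by the planted group fold and a per-sample drift factor shared with the
    matched IS (so normalization cancels drift).  QC injections resample the
    pooled mean with multiplicative noise; blanks sit at a small fraction of
    the study signal with low S/N.
    """
    if library is None:
        library = default_study_library()
    if not library:
        raise ValueError("empty library")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    is_panel, calibration = simulate_is_panel(config)

    names = [s.acyl_name for s in library]
    subclass = {s.acyl_name: s.subclass for s in library}
    folds = {}
    for s in library:
        if s.subclass in config.up_subclasses:
            folds[s.acyl_name] = config.tag_fold
        elif s.subclass in config.down_subclasses:
            folds[s.acyl_name] = config.phospholipid_fold
        else:
            folds[s.acyl_name] = 1.0
    baseline = {
        n: float(np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sigma)))
        for n in names
    }
    true_rt = {
        s.acyl_name: _true_rt(config, s.subclass, s.total_carbons)
        - 0.12 * s.total_double_bonds
        for s in library
    }
    assignments: dict[str, str] = {}
    for s in library:
        matched = assign_acquisition_params(s, is_panel).matched_is
        if matched is not None:
            assignments[s.acyl_name] = matched.name
    is_rt = {r.name: r.rt_min for r in is_panel}

    samples: list[tuple[str, str, str]] = []  # (sample, role, group)
    for g in config.groups:
        for i in range(config.n_per_group):
            samples.append((f"{g}-{i + 1:02d}", "study", g))
    for i in range(config.qc_injections):
        samples.append((f"QC-{i + 1:02d}", "QC", "QC"))
    for i in range(config.n_blanks):
        samples.append((f"BLANK-{i + 1:02d}", "blank", "blank"))

    rows: list[dict] = []
    pooled_mean = {n: baseline[n] * np.mean([
        folds[n] if g == config.affected_group else 1.0 for g in config.groups
    ]) for n in names}

    for sample, role, group in samples:
        if role == "study":
            drift = float(np.exp(rng.normal(0.0, config.drift_sigma)))
        elif role == "QC":
            drift = float(np.exp(rng.normal(0.0, config.drift_sigma / 2)))
        else:
            drift = 1.0
        for n in names:
            if role == "study":
                fold = folds[n] if group == config.affected_group else 1.0
                area = (
                    baseline[n] * fold * drift
                    * float(np.exp(rng.normal(0.0, config.biological_sigma)))
                )
                sn = float(rng.uniform(30.0, 300.0))
            elif role == "QC":
                area = (
                    pooled_mean[n] * drift
                    * float(np.exp(rng.normal(0.0, config.qc_sigma)))
                )
                sn = float(rng.uniform(30.0, 300.0))
            else:
                area = (
                    config.blank_fraction * baseline[n]
                    * float(np.exp(rng.normal(0.0, 0.3)))
                )
                sn = float(rng.uniform(1.0, 5.0))
            rows.append(
                {
                    "sample": sample, "role": role, "component": n,
                    "area": area,
                    "rt": true_rt[n] + float(rng.normal(0.0, config.rt_obs_noise_min)),
                    "fwhm": float(rng.uniform(0.1, 0.7)),
                    "sn": sn,
                }
            )
        for record in is_panel:
            rows.append(
                {
                    "sample": sample, "role": role, "component": record.name,
                    "area": config.is_area * drift,
                    "rt": record.rt_min + float(rng.normal(0.0, config.rt_obs_noise_min)),
                    "fwhm": float(rng.uniform(0.1, 0.5)),
                    "sn": float(rng.uniform(100.0, 500.0)),
                }
            )

    peaks = pd.DataFrame(
        rows, columns=["sample", "role", "component", "area", "rt", "fwhm", "sn"]
    )
    design = pd.DataFrame(
        [
            {"sample": s, "role": r, "group": g, "injection_order": i + 1}
            for i, (s, r, g) in enumerate(samples)
        ],
        columns=["sample", "role", "group", "injection_order"],
    )
    truth = pd.DataFrame(
        {
            "component": names,
            "subclass": [subclass[n] for n in names],
            "fold": [folds[n] for n in names],
            "affected_group": config.affected_group,
        }
    )
    return StudyData(
        peaks=peaks, design=design, is_panel=is_panel, calibration=calibration,
        is_assignments=assignments, truth=truth, true_rt=true_rt,
    )


def simulate_qc_matrix(
    seed: int,
    n_species: int = 100,
    n_injections: int = 10,
    sigma: float = 0.07,
) -> pd.DataFrame:
    """IS-normalized QC matrix with pure multiplicative log-normal noise.

    Each species' normalized area over consecutive injections is its true
    level times exp(N(0, sigma)) — the minimal model of instrument noise
    that survives IS normalization.
    """
    rng = np.random.default_rng(seed)
    levels = np.exp(rng.normal(0.0, 1.0, size=n_species))
    noise = np.exp(rng.normal(0.0, sigma, size=(n_species, n_injections)))
    data = levels[:, None] * noise
    return pd.DataFrame(
        data,
        index=[f"species-{i + 1:03d}" for i in range(n_species)],
        columns=[f"QC-{j + 1:02d}" for j in range(n_injections)],
    )


# ---------------------------------------------------------------------------
# Fixture round trips
# ---------------------------------------------------------------------------

def write_fixtures(study: StudyData, directory: str | Path) -> dict[str, Path]:
    """Write the study as the delimited tables the other modules read."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": directory / "peaks.csv",
        "design": directory / "design.csv",
        "is_panel": directory / "is_panel.csv",
        "calibration": directory / "calibration.csv",
        "is_assignments": directory / "is_assignments.csv",
        "truth": directory / "truth.csv",
    }
    study.peaks.to_csv(paths["peaks"], index=False)
    study.design.to_csv(paths["design"], index=False)
    pd.DataFrame(
        [
            {
                "name": r.name, "subclass": r.subclass, "carbons": r.carbons,
                "double_bonds": r.double_bonds, "rt_min": r.rt_min,
                "ce": r.ce, "dp": r.dp, "dwell_ms": r.dwell_ms,
            }
            for r in study.is_panel
        ]
    ).to_csv(paths["is_panel"], index=False)
    pd.DataFrame(
        [
            {
                "species": p.species, "subclass": p.subclass, "carbons": p.carbons,
                "double_bonds": p.double_bonds, "rt_min": p.rt_min, "source": p.source,
            }
            for p in study.calibration
        ]
    ).to_csv(paths["calibration"], index=False)
    pd.DataFrame(
        [{"component": k, "is_component": v} for k, v in study.is_assignments.items()]
    ).to_csv(paths["is_assignments"], index=False)
    study.truth.to_csv(paths["truth"], index=False)
    return paths


def read_fixtures(directory: str | Path) -> dict[str, object]:
    """Read fixture tables back (inverse of write_fixtures)."""
    directory = Path(directory)
    peaks = pd.read_csv(directory / "peaks.csv", float_precision="round_trip")
    design = pd.read_csv(directory / "design.csv", float_precision="round_trip")
    is_df = pd.read_csv(directory / "is_panel.csv", float_precision="round_trip")
    is_panel = [
        ISRecord(
            name=r.name, subclass=r.subclass, carbons=int(r.carbons),
            double_bonds=int(r.double_bonds), rt_min=float(r.rt_min),
            ce=float(r.ce), dp=float(r.dp), dwell_ms=float(r.dwell_ms),
        )
        for r in is_df.itertuples(index=False)
    ]
    cal_df = pd.read_csv(directory / "calibration.csv", float_precision="round_trip")
    calibration = [
        CalibrationPoint(
            species=r.species, subclass=r.subclass, carbons=int(r.carbons),
            double_bonds=int(r.double_bonds), rt_min=float(r.rt_min),
            source=r.source,
        )
        for r in cal_df.itertuples(index=False)
    ]
    assign_df = pd.read_csv(directory / "is_assignments.csv")
    assignments = dict(zip(assign_df["component"], assign_df["is_component"]))
    truth = pd.read_csv(directory / "truth.csv")
    return {
        "peaks": peaks, "design": design, "is_panel": is_panel,
        "calibration": calibration, "is_assignments": assignments, "truth": truth,
    }
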