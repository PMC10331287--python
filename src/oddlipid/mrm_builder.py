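"""MRM transition building from class-specific fragmentation rules.

Triple-quadrupole targeted lipidomics monitors precursor → product ion pairs
(Q1/Q3).  The rules implemented here:

* TAG ionize as ammonium adducts [M+NH4]+ and fragment by neutral loss of one
  fatty acid plus ammonia, so the neutral loss identifies the acyl (nominal
  259/287/315 Da for 15:0/17:0/19:0; 2 Da lower per double bond).
* DAG ([M+NH4]+) lose one acyl chain to a protonated, dehydrated
  monoacylglycerol daughter ion (nominal 299/327/355 for 15:0/17:0/19:0).
* Glycerophospholipids fragment in negative mode to the carboxylate anions
  [FA-H]- of their sn-1/sn-2 chains — one transition per distinct acyl.
* SM yields the phosphocholine head fragment (m/z 184.0733); ceramides the
  dehydrated d18:1 long-chain-base ion (264.2686; 266.2842 for the d18:0
  base); FFA are monitored as [M-H]- pseudo-transitions.

Acquisition parameters (CE/DP/dwell) are inherited from the nearest internal
standard of the same subclass, and species are validated by requiring their
multiple transitions to co-elute.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .chem_core import (
    SUBCLASSES,
    ElementalFormula,
    FattyAcyl,
    LipidSpecies,
    acyl_formula,
    lipid_formula,
    make_species,
    monoisotopic_mass,
)

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "Adduct",
    "ADDUCTS",
    "MRMTransition",
    "ISRecord",
    "CoelutionVerdict",
    "CoelutionResult",
    "precursor_mz",
    "tag_dag_transitions",
    "phospholipid_transitions",
    "sphingo_ffa_transitions",
    "build_transitions",
    "isomer_candidates",
    "assign_acquisition_params",
    "validate_by_coelution",
    "transitions_table",
]

ELECTRON_MASS = 0.000549
PROTON_MASS = 1.007276  # H minus electron

_NH3 = ElementalFormula(N=1, H=3)
_H2O = ElementalFormula(H=2, O=1)
NH3_MASS = monoisotopic_mass(_NH3)
H2O_MASS = monoisotopic_mass(_H2O)
H_MASS = 1.0078250319

# SM head-group fragment: protonated phosphocholine C5H15NO4P+.
PHOSPHOCHOLINE_FRAGMENT = (
    monoisotopic_mass(ElementalFormula(C=5, H=15, N=1, O=4, P=1)) - ELECTRON_MASS
)


@dataclass(frozen=True)
class Adduct:
    """An ionization adduct: label, neutral mass delta and charge sign."""

    label: str
    delta: float
    charge_sign: int  # +1 or -1

    def mz(self, neutral_mass: float) -> float:
        """Ion m/z including the electron-mass correction for the charge."""
        if neutral_mass <= 0:
            raise ValueError("neutral mass must be positive")
        return neutral_mass + self.delta - self.charge_sign * ELECTRON_MASS


ADDUCTS: Mapping[str, Adduct] = {
    "[M+NH4]+": Adduct("[M+NH4]+", NH3_MASS + H_MASS, +1),
    "[M+H]+": Adduct("[M+H]+", H_MASS, +1),
    "[M-H]-": Adduct("[M-H]-", -H_MASS, -1),
    "[M+CH3COO]-": Adduct(
        "[M+CH3COO]-",
        monoisotopic_mass(ElementalFormula(C=2, H=3, O=2)),
        -1,
    ),
}

# Default negative-mode precursor adduct per phospholipid subclass.  PC and
# LPC form acetate adducts in ammonium-acetate mobile phase; the rest
# deprotonate.  Overridable per call.
_DEFAULT_GPL_ADDUCT: Mapping[str, str] = {
    "PA": "[M-H]-", "PC": "[M+CH3COO]-", "PE": "[M-H]-", "PG": "[M-H]-",
    "PI": "[M-H]-", "PS": "[M-H]-", "LPC": "[M+CH3COO]-", "LPE": "[M-H]-",
}


@dataclass(frozen=True)
class MRMTransition:
    """One precursor → product ion pair for a species."""

    species_name: str
    q1: float
    q3: float
    polarity: str
    annotation: str
    ce: float | None = None
    dp: float | None = None
    cxp: float | None = None
    dwell_ms: float | None = None

    def __post_init__(self) -> None:
        if self.q1 <= 0 or self.q3 <= 0:
            raise ValueError("Q1 and Q3 must be positive")


@dataclass(frozen=True)
class ISRecord:
    """A deuterated internal standard with its observed RT and tuned parameters."""

    name: str
    subclass: str
    carbons: int        # total acyl carbons (sum composition)
    double_bonds: int
    rt_min: float
    ce: float
    dp: float
    dwell_ms: float

    def __post_init__(self) -> None:
        if self.rt_min <= 0:
            raise ValueError("IS retention time must be positive")


def precursor_mz(species: LipidSpecies, adduct: Adduct | str) -> float:
    """Precursor m/z of a species under an adduct, checked for polarity."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    expected = +1 if species.polarity == "positive" else -1
    if adduct.charge_sign != expected:
        raise ValueError(
            f"{adduct.label} is incompatible with {species.subclass} "
            f"({species.polarity}-mode subclass)"
        )
    return round(adduct.mz(species.neutral_mass), 4)


def _round4(x: float) -> float:
    return round(x, 4)


def tag_dag_transitions(species: LipidSpecies) -> list[MRMTransition]:
    """Neutral-loss / daughter-ion transitions for TAG, DAG and MAG."""
    if species.subclass not in ("TAG", "DAG", "MAG"):
        raise ValueError(f"expected TAG/DAG/MAG, got {species.subclass}")
    q1 = precursor_mz(species, "[M+NH4]+")
    out: list[MRMTransition] = []
    distinct = sorted(set(species.acyls))
    if species.subclass == "TAG":
        for acyl in distinct:
            nl = monoisotopic_mass(acyl_formula(acyl)) + NH3_MASS
            out.append(
                MRMTransition(
                    species_name=species.acyl_name,
                    q1=q1,
                    q3=_round4(q1 - nl),
                    polarity="positive",
                    annotation=f"NL FA{acyl}+NH3 ({round(nl)})",
                )
            )
    elif species.subclass == "DAG":
        for acyl in distinct:
            # daughter retains this acyl as a protonated dehydrated MAG
            mag = lipid_formula("MAG", [acyl])
            q3 = monoisotopic_mass(mag) + PROTON_MASS - H2O_MASS
            out.append(
                MRMTransition(
                    species_name=species.acyl_name,
                    q1=q1,
                    q3=_round4(q3),
                    polarity="positive",
                    annotation=f"[MAG {acyl}+H-H2O]+ ({round(q3)})",
                )
            )
    else:  # MAG
        q3 = species.neutral_mass + H_MASS - ELECTRON_MASS - H2O_MASS
        out.append(
            MRMTransition(
                species_name=species.acyl_name,
                q1=q1,
                q3=_round4(q3),
                polarity="positive",
                annotation="[M+H-H2O]+",
            )
        )
    return out


def phospholipid_transitions(
    species: LipidSpecies,
    precursor_adducts: Mapping[str, str] | None = None,
) -> list[MRMTransition]:
    """Negative-mode carboxylate-anion transitions for glycerophospholipids.

    Diacyl species yield one transition per distinct acyl (two for mixed
    compositions, one when both chains are identical — the annotation then
    lists both sn sites); lyso species yield one.
    """
    if species.subclass not in _DEFAULT_GPL_ADDUCT:
        raise ValueError(f"expected a glycerophospholipid, got {species.subclass}")
    adduct_label = (precursor_adducts or _DEFAULT_GPL_ADDUCT)[species.subclass]
    q1 = precursor_mz(species, adduct_label)
    out: list[MRMTransition] = []
    distinct = sorted(set(species.acyls))
    for acyl in distinct:
        q3 = monoisotopic_mass(acyl_formula(acyl)) - H_MASS + ELECTRON_MASS
        n_sites = species.acyls.count(acyl)
        if len(species.acyls) == 1:
            site = "sn-1"
        elif n_sites == 2:
            site = "sn-1/sn-2"
        else:
            site = "sn-1" if acyl == distinct[0] else "sn-2"
        out.append(
            MRMTransition(
                species_name=species.acyl_name,
                q1=q1,
                q3=_round4(q3),
                polarity="negative",
                annotation=f"carboxylate FA{acyl} ({site})",
            )
        )
    return out


def sphingo_ffa_transitions(species: LipidSpecies) -> list[MRMTransition]:
    """Head-group / long-chain-base transitions for sphingolipids; FFA pseudo-MRM."""
    sub = species.subclass
    if sub == "FFA":
        mz = _round4(species.neutral_mass - H_MASS + ELECTRON_MASS)
        return [
            MRMTransition(
                species_name=species.acyl_name,
                q1=mz,
                q3=mz,
                polarity="negative",
                annotation="[M-H]- pseudo-transition",
            )
        ]
    if sub not in ("SM", "Cer", "dhCer", "HexCer", "LacCer"):
        raise ValueError(f"expected a sphingolipid or FFA, got {sub}")
    q1 = precursor_mz(species, "[M+H]+")
    if sub == "SM":
        q3 = PHOSPHOCHOLINE_FRAGMENT
        annotation = "phosphocholine 184.0733"
    else:
        base = species.info.sphingoid_base
        base_formula = (
            ElementalFormula(C=18, H=39, N=1, O=2)
            if base.double_bonds == 0
            else ElementalFormula(C=18, H=37, N=1, O=2)
        )
        q3 = monoisotopic_mass(base_formula) + H_MASS - ELECTRON_MASS - 2 * H2O_MASS
        annotation = f"LCB d{base} [M+H-2H2O]+"
    return [
        MRMTransition(
            species_name=species.acyl_name,
            q1=q1,
            q3=_round4(q3),
            polarity="positive",
            annotation=annotation,
        )
    ]


def build_transitions(
    species: LipidSpecies,
    precursor_adducts: Mapping[str, str] | None = None,
) -> list[MRMTransition]:
    """Dispatch to the subclass-appropriate fragmentation rule."""
    family = species.info.family
    if family == "glycerolipid":
        return tag_dag_transitions(species)
    if family == "phospholipid":
        return phospholipid_transitions(species, precursor_adducts)
    return sphingo_ffa_transitions(species)


# ---------------------------------------------------------------------------
# Isomer enumeration
# ---------------------------------------------------------------------------

def isomer_candidates(
    subclass: str,
    total_carbons: int,
    total_double_bonds: int,
    pool: Sequence[FattyAcyl],
    require_odd: bool = True,
) -> list[tuple[FattyAcyl, ...]]:
    """All acyl multisets from the pool matching a sum composition.

    A sum composition like TAG 51:3 admits many acyl combinations
    (15:0-15:1-21:2, 15:0-17:0-19:3, 15:0-17:1-19:2, ...); this enumerates
    them exhaustively and duplicate-free, requiring at least one odd-pool
    acyl when ``require_odd``.
    """
    if not pool:
        raise ValueError("empty acyl pool")
    arity = SUBCLASSES[subclass].arity
    pool = sorted(set(pool))
    out = []
    for combo in itertools.combinations_with_replacement(pool, arity):
        if sum(a.carbons for a in combo) != total_carbons:
            continue
        if sum(a.double_bonds for a in combo) != total_double_bonds:
            continue
        if require_odd and not any(a.in_odd_pool for a in combo):
            continue
        out.append(combo)
    return sorted(out)


# ---------------------------------------------------------------------------
# Acquisition-parameter inheritance from internal standards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamAssignment:
    """CE/DP/dwell for a species, inherited from a matched IS (or flagged)."""

    species_name: str
    matched_is: ISRecord | None
    unparameterized: bool

    @property
    def ce(self) -> float | None:
        return None if self.matched_is is None else self.matched_is.ce

    @property
    def dp(self) -> float | None:
        return None if self.matched_is is None else self.matched_is.dp

    @property
    def dwell_ms(self) -> float | None:
        return None if self.matched_is is None else self.matched_is.dwell_ms


def assign_acquisition_params(
    species: LipidSpecies, is_panel: Sequence[ISRecord]
) -> ParamAssignment:
    """Inherit CE/DP/dwell from the nearest same-subclass internal standard.

    Nearest by |ΔC| on total acyl carbons, then |Δ double bonds|, ties broken
    toward the lower-carbon IS.  A subclass with no IS is flagged
    unparameterized — never silently defaulted.
    """
    if not is_panel:
        raise ValueError("empty internal-standard panel")
    same = [r for r in is_panel if r.subclass == species.subclass]
    if not same:
        return ParamAssignment(species.acyl_name, None, True)
    c = sum(a.carbons for a in species.acyls)
    d = sum(a.double_bonds for a in species.acyls)
    best = min(
        same,
        key=lambda r: (abs(r.carbons - c), abs(r.double_bonds - d), r.carbons),
    )
    return ParamAssignment(species.acyl_name, best, False)


# ---------------------------------------------------------------------------
# Multi-transition co-elution validation
# ---------------------------------------------------------------------------

class CoelutionVerdict(Enum):
    VALIDATED = "VALIDATED"
    NOT_VALIDATED = "NOT_VALIDATED"
    UNTESTABLE = "UNTESTABLE"
    ISOMERS = "ISOMERS"


@dataclass(frozen=True)
class CoelutionResult:
    verdict: CoelutionVerdict
    max_delta_rt: float | None = None
    offending_channels: tuple[str, ...] = ()
    isomer_groups: tuple[tuple[tuple[str, float], ...], ...] = ()


def validate_by_coelution(
    channel_rts: Mapping[str, Sequence[float] | float],
    tol_min: float = 0.1,
    channel_sn: Mapping[str, float] | None = None,
    sn_min: float = 10.0,
) -> CoelutionResult:
    """Validate a species by co-elution of its MRM transitions.

    ``channel_rts`` maps each transition (channel) to its observed RT(s).
    A species is VALIDATED when every pairwise RT difference is within
    ``tol_min`` and every channel passes the S/N floor.  A channel showing
    multiple peaks (doublets) triggers isomer grouping: peaks across all
    channels are clustered by RT, and each cluster is reported as a putative
    isomer.  A single-transition species is UNTESTABLE, not a failure.
    """
    peaks: list[tuple[str, float]] = []
    for channel, rts in channel_rts.items():
        if isinstance(rts, (int, float)):
            rts = [float(rts)]
        for rt in rts:
            peaks.append((channel, float(rt)))
    channels = sorted({c for c, _ in peaks})
    if len(channels) < 2:
        return CoelutionResult(CoelutionVerdict.UNTESTABLE)

    if channel_sn is not None:
        failing = tuple(c for c in channels if channel_sn.get(c, 0.0) < sn_min)
        if failing:
            return CoelutionResult(
                CoelutionVerdict.NOT_VALIDATED, offending_channels=failing
            )

    multi = any(
        sum(1 for c, _ in peaks if c == channel) > 1 for channel in channels
    )
    if multi:
        # cluster all peaks by RT; gaps > tol start a new isomer group
        ordered = sorted(peaks, key=lambda p: p[1])
        groups: list[list[tuple[str, float]]] = [[ordered[0]]]
        for peak in ordered[1:]:
            if peak[1] - groups[-1][-1][1] <= tol_min:
                groups[-1].append(peak)
            else:
                groups.append([peak])
        return CoelutionResult(
            CoelutionVerdict.ISOMERS,
            isomer_groups=tuple(tuple(g) for g in groups),
        )

    rts = [rt for _, rt in peaks]
    spread = max(rts) - min(rts)
    if spread <= tol_min:
        return CoelutionResult(CoelutionVerdict.VALIDATED, max_delta_rt=spread)
    center = sorted(rts)[len(rts) // 2]
    offending = tuple(
        c for c, rt in peaks if abs(rt - center) == max(abs(r - center) for r in rts)
    )
    return CoelutionResult(
        CoelutionVerdict.NOT_VALIDATED,
        max_delta_rt=spread,
        offending_channels=offending,
    )


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def transitions_table(transitions: Iterable[MRMTransition]):
    """Transition list as a DataFrame in the vendor-neutral MRM-list layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "Q1": t.q1,
                "Q3": t.q3,
                "polarity": t.polarity,
                "species": t.species_name,
                "annotation": t.annotation,
                "CE": t.ce,
                "DP": t.dp,
                "CXP": t.cxp,
                "dwell_ms": t.dwell_ms,
            }
            for t in transitions
        ]
    )
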