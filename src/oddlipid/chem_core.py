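"""Chemistry core: fatty acyls, elemental formulas, lipid species and library enumeration.

Odd-chain fatty acids (OCFAs, e.g. 15:0, 17:0) occur at trace levels in
mammalian tissue, mostly esterified into complex lipids.  This module
enumerates the odd-chain fatty-acyl lipid space — free fatty acids,
glycerolipids, glycerophospholipids and sphingolipids built from an odd acyl
pool (13:0 … 23:0, plus their mono- and di-unsaturated forms) with optional
even-chain partners — and computes exact elemental compositions and
monoisotopic masses for every species.

Formula construction is standard condensation chemistry: a glycerol or
glycerophosphate backbone plus the free fatty acids, minus one water per
ester bond; sphingolipids are built on a fixed d18:1 sphingoid base
(d18:0 for dihydroceramide) with the variable chain in the N-acyl position.
Double bonds are positional-agnostic: one double bond subtracts 2 H
(2 Da nominal), two subtract 4 H.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "MONOISOTOPIC_MASS",
    "FattyAcyl",
    "ElementalFormula",
    "SubclassInfo",
    "SUBCLASSES",
    "LipidSpecies",
    "LibraryConfig",
    "LipidNameError",
    "acyl_formula",
    "lipid_formula",
    "monoisotopic_mass",
    "nominal_mass",
    "make_species",
    "enumerate_odd_library",
    "parse_name",
    "format_name",
    "library_table",
]

# Monoisotopic atomic masses (Da).
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.000000,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
}

# Integer (nominal) masses for the 2/4 Da unsaturation-defect arithmetic.
_NOMINAL_MASS: Mapping[str, int] = {"C": 12, "H": 1, "N": 14, "O": 16, "P": 31}

ODD_ACYL_POOL = (13, 15, 17, 19, 21, 23)
EVEN_PARTNER_POOL = (12, 14, 16, 18, 20, 22)


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """An acyl chain characterized by carbon count and number of double bonds."""

    carbons: int
    double_bonds: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"acyl needs >= 2 carbons, got {self.carbons}")
        if not 0 <= self.double_bonds <= self.carbons // 2 - 1:
            raise ValueError(
                f"{self.carbons}:{self.double_bonds} exceeds the chemically "
                f"possible unsaturation for this chain length"
            )

    @property
    def is_odd(self) -> bool:
        return self.carbons % 2 == 1

    @property
    def in_odd_pool(self) -> bool:
        return self.carbons in ODD_ACYL_POOL

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class ElementalFormula:
    """Atom counts over C/H/N/O/P; arithmetic never yields a negative count."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0

    def __post_init__(self) -> None:
        for el in "CHNOP":
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count in formula")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            *(getattr(self, el) + getattr(other, el) for el in "CHNOP")
        )

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            *(getattr(self, el) - getattr(other, el) for el in "CHNOP")
        )

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula(*(getattr(self, el) * k for el in "CHNOP"))

    __rmul__ = __mul__

    def hill(self) -> str:
        """Formula string in Hill order (C, H, then alphabetical)."""
        parts = []
        for el in ("C", "H", "N", "O", "P"):
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Sum of atom counts times monoisotopic atomic masses, in Da."""
    return sum(getattr(formula, el) * m for el, m in MONOISOTOPIC_MASS.items())


def nominal_mass(formula: ElementalFormula) -> int:
    """Integer nominal mass (lightest-isotope integer masses)."""
    return sum(getattr(formula, el) * m for el, m in _NOMINAL_MASS.items())


def acyl_formula(acyl: FattyAcyl) -> ElementalFormula:
    """Free fatty-acid composition CnH(2n-2d)O2 of an acyl chain."""
    return ElementalFormula(C=acyl.carbons, H=2 * acyl.carbons - 2 * acyl.double_bonds, O=2)


# Building blocks for condensation chemistry.
H2O = ElementalFormula(H=2, O=1)
GLYCEROL = ElementalFormula(C=3, H=8, O=3)
GLYCEROPHOSPHATE = ElementalFormula(C=3, H=9, O=6, P=1)
CHOLINE = ElementalFormula(C=5, H=13, N=1, O=1)
ETHANOLAMINE = ElementalFormula(C=2, H=7, N=1, O=1)
INOSITOL = ElementalFormula(C=6, H=12, O=6)
SERINE = ElementalFormula(C=3, H=7, N=1, O=3)
SPHINGOSINE = ElementalFormula(C=18, H=37, N=1, O=2)      # d18:1
SPHINGANINE = ElementalFormula(C=18, H=39, N=1, O=2)      # d18:0
PHOSPHOCHOLINE = ElementalFormula(C=5, H=14, N=1, O=4, P=1)
HEXOSE = ElementalFormula(C=6, H=12, O=6)
ANHYDROHEXOSE = ElementalFormula(C=6, H=10, O=5)

_PHOSPHOLIPID_HEADS: Mapping[str, ElementalFormula] = {
    "PC": CHOLINE,
    "PE": ETHANOLAMINE,
    "PG": GLYCEROL,
    "PI": INOSITOL,
    "PS": SERINE,
}


@dataclass(frozen=True)
class SubclassInfo:
    """Arity, default detection polarity and backbone family of a lipid subclass."""

    name: str
    arity: int          # number of variable acyl chains
    polarity: str       # default detection polarity: "positive" | "negative"
    family: str         # "fa" | "glycerolipid" | "phospholipid" | "sphingolipid"
    sphingoid_base: FattyAcyl | None = None  # (18,1)-like descriptor for d18:x


SUBCLASSES: Mapping[str, SubclassInfo] = {
    "FFA": SubclassInfo("FFA", 1, "negative", "fa"),
    "MAG": SubclassInfo("MAG", 1, "positive", "glycerolipid"),
    "DAG": SubclassInfo("DAG", 2, "positive", "glycerolipid"),
    "TAG": SubclassInfo("TAG", 3, "positive", "glycerolipid"),
    "PA": SubclassInfo("PA", 2, "negative", "phospholipid"),
    "PC": SubclassInfo("PC", 2, "negative", "phospholipid"),
    "PE": SubclassInfo("PE", 2, "negative", "phospholipid"),
    "PG": SubclassInfo("PG", 2, "negative", "phospholipid"),
    "PI": SubclassInfo("PI", 2, "negative", "phospholipid"),
    "PS": SubclassInfo("PS", 2, "negative", "phospholipid"),
    "LPC": SubclassInfo("LPC", 1, "negative", "phospholipid"),
    "LPE": SubclassInfo("LPE", 1, "negative", "phospholipid"),
    "SM": SubclassInfo("SM", 1, "positive", "sphingolipid", FattyAcyl(18, 1)),
    "Cer": SubclassInfo("Cer", 1, "positive", "sphingolipid", FattyAcyl(18, 1)),
    "dhCer": SubclassInfo("dhCer", 1, "positive", "sphingolipid", FattyAcyl(18, 0)),
    "HexCer": SubclassInfo("HexCer", 1, "positive", "sphingolipid", FattyAcyl(18, 1)),
    "LacCer": SubclassInfo("LacCer", 1, "positive", "sphingolipid", FattyAcyl(18, 1)),
}


def lipid_formula(subclass: str, acyls: Sequence[FattyAcyl]) -> ElementalFormula:
    """Elemental formula of a lipid species from its subclass and acyl chains.

    Glycerolipids condense glycerol with the free acids (one water per ester
    bond); glycerophospholipids start from glycero-3-phosphate and attach the
    head alcohol with one more condensation; sphingolipids amidate the fixed
    sphingoid base.
    """
    info = SUBCLASSES.get(subclass)
    if info is None:
        raise ValueError(f"unknown lipid subclass: {subclass!r}")
    if len(acyls) != info.arity:
        raise ValueError(
            f"{subclass} takes {info.arity} acyl(s), got {len(acyls)}"
        )
    fa_sum = ElementalFormula()
    for a in acyls:
        fa_sum = fa_sum + acyl_formula(a)
    n = len(acyls)

    if subclass == "FFA":
        return fa_sum
    if subclass in ("MAG", "DAG", "TAG"):
        return GLYCEROL + fa_sum - n * H2O
    if subclass == "PA":
        return GLYCEROPHOSPHATE + fa_sum - 2 * H2O
    if subclass in _PHOSPHOLIPID_HEADS:
        pa = GLYCEROPHOSPHATE + fa_sum - 2 * H2O
        return pa + _PHOSPHOLIPID_HEADS[subclass] - H2O
    if subclass in ("LPC", "LPE"):
        head = CHOLINE if subclass == "LPC" else ETHANOLAMINE
        return GLYCEROPHOSPHATE + fa_sum - H2O + head - H2O
    # Sphingolipids: N-acylation of the base, then optional head condensation.
    base = SPHINGANINE if subclass == "dhCer" else SPHINGOSINE
    cer = base + fa_sum - H2O
    if subclass in ("Cer", "dhCer"):
        return cer
    if subclass == "SM":
        return cer + PHOSPHOCHOLINE - H2O
    if subclass == "HexCer":
        return cer + HEXOSE - H2O
    if subclass == "LacCer":
        return cer + 2 * ANHYDROHEXOSE
    raise ValueError(f"unknown lipid subclass: {subclass!r}")  # pragma: no cover


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species at acyl-composition resolution (no sn or double-bond positions)."""

    subclass: str
    acyls: tuple[FattyAcyl, ...]
    formula: ElementalFormula = field(compare=False)
    neutral_mass: float = field(compare=False)

    @property
    def info(self) -> SubclassInfo:
        return SUBCLASSES[self.subclass]

    @property
    def total_carbons(self) -> int:
        """Sum-composition carbon number; includes the sphingoid base for sphingolipids."""
        c = sum(a.carbons for a in self.acyls)
        if self.info.sphingoid_base is not None:
            c += self.info.sphingoid_base.carbons
        return c

    @property
    def total_double_bonds(self) -> int:
        d = sum(a.double_bonds for a in self.acyls)
        if self.info.sphingoid_base is not None:
            d += self.info.sphingoid_base.double_bonds
        return d

    @property
    def polarity(self) -> str:
        return self.info.polarity

    @property
    def sum_name(self) -> str:
        """Sum-composition shorthand, e.g. 'TAG 45:0' or 'Cer d18:1/17:0'."""
        if self.info.sphingoid_base is not None:
            base = self.info.sphingoid_base
            return f"{self.subclass} d{base.carbons}:{base.double_bonds}/{self.acyls[0]}"
        c = sum(a.carbons for a in self.acyls)
        d = sum(a.double_bonds for a in self.acyls)
        return f"{self.subclass} {c}:{d}"

    @property
    def acyl_name(self) -> str:
        """Acyl-resolved shorthand, e.g. 'PI 17:0/18:1'."""
        if self.info.sphingoid_base is not None:
            return self.sum_name
        return f"{self.subclass} " + "/".join(str(a) for a in self.acyls)

    @property
    def has_odd_acyl(self) -> bool:
        return any(a.in_odd_pool for a in self.acyls)

    def __str__(self) -> str:
        return self.acyl_name


def make_species(subclass: str, acyls: Iterable[FattyAcyl]) -> LipidSpecies:
    """Construct a species with canonically sorted acyls, formula and mass."""
    acyl_tuple = tuple(sorted(acyls))
    formula = lipid_formula(subclass, acyl_tuple)
    return LipidSpecies(
        subclass=subclass,
        acyls=acyl_tuple,
        formula=formula,
        neutral_mass=monoisotopic_mass(formula),
    )


# ---------------------------------------------------------------------------
# Library enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryConfig:
    """Configuration of the in-silico odd-chain library.

    The odd acyl pool is mandatory: every emitted species carries at least
    one odd-pool acyl.  The even partner pool fills the remaining positions
    of multi-acyl species (mixed species such as PI 17:0/18:1).
    """

    subclasses: tuple[str, ...] = tuple(SUBCLASSES)
    odd_carbons: tuple[int, ...] = ODD_ACYL_POOL
    even_carbons: tuple[int, ...] = EVEN_PARTNER_POOL
    double_bonds: tuple[int, ...] = (0, 1, 2)

    def acyl_pool(self) -> list[FattyAcyl]:
        pool = [
            FattyAcyl(c, d)
            for c in (*self.odd_carbons, *self.even_carbons)
            for d in self.double_bonds
        ]
        return sorted(set(pool))


def enumerate_odd_library(config: LibraryConfig) -> list[LipidSpecies]:
    """Enumerate all library species implied by the configuration.

    Species are unique by (subclass, acyl multiset), each contains at least
    one odd-pool acyl, and the output is sorted by (subclass, total carbons,
    total double bonds, acyls).
    """
    if not config.subclasses:
        raise ValueError("library configuration names no subclasses")
    unknown = [s for s in config.subclasses if s not in SUBCLASSES]
    if unknown:
        raise ValueError(f"unknown subclasses: {unknown}")
    pool = config.acyl_pool()
    odd = [a for a in pool if a.carbons in config.odd_carbons]
    if not odd:
        raise ValueError("odd acyl pool is empty")
    species: list[LipidSpecies] = []
    for sub in config.subclasses:
        arity = SUBCLASSES[sub].arity
        for combo in itertools.combinations_with_replacement(pool, arity):
            if not any(a.carbons in config.odd_carbons for a in combo):
                continue
            species.append(make_species(sub, combo))
    species.sort(
        key=lambda s: (s.subclass, s.total_carbons, s.total_double_bonds, s.acyls)
    )
    return species


# ---------------------------------------------------------------------------
# Shorthand names: parsing and formatting
# ---------------------------------------------------------------------------

class LipidNameError(ValueError):
    """A malformed shorthand name; carries the character position of the fault."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_ACYL_RE = re.compile(r"(\d+):(\d+)")
_SUM_RE = re.compile(
    r"^(?P<sub>[A-Za-z]+)\s*\(?\s*(?P<c>\d+):(?P<d>\d+)\s*\)?"
    r"(?:\s*-\s*FA\s*(?P<mc>\d+):(?P<md>\d+))?\s*$"
)
_SLASH_RE = re.compile(
    r"^(?P<sub>[A-Za-z]+)\s*\(?\s*(?P<chains>(?:d?\d+:\d+)(?:\s*/\s*d?\d+:\d+)+)\s*\)?\s*$"
)


@dataclass(frozen=True)
class ParsedName:
    """Decoded shorthand: either acyl-resolved chains or a sum composition."""

    subclass: str
    acyls: tuple[FattyAcyl, ...] | None = None        # slash dialect
    sum_carbons: int | None = None                    # sum dialect
    sum_double_bonds: int | None = None
    marker_acyl: FattyAcyl | None = None              # e.g. the FA17:0 in TAG 51:3-FA17:0

    @property
    def canonical(self) -> str:
        if self.acyls is not None:
            info = SUBCLASSES[self.subclass]
            chains = list(self.acyls)
            if info.sphingoid_base is not None:
                base = info.sphingoid_base
                head = f"d{base.carbons}:{base.double_bonds}"
                return f"{self.subclass} {head}/" + "/".join(str(a) for a in chains)
            return f"{self.subclass} " + "/".join(str(a) for a in chains)
        name = f"{self.subclass} {self.sum_carbons}:{self.sum_double_bonds}"
        if self.marker_acyl is not None:
            name += f"-FA{self.marker_acyl}"
        return name


def parse_name(name: str) -> ParsedName:
    """Parse either shorthand dialect into its components.

    Accepts the acyl-resolved slash form ("PI 17:0/18:1", "PI (17:0/18:1)",
    "Cer d18:1/17:0") and the sum form with an optional marker acyl
    ("TAG 51:3", "TAG51:3-FA17:0").  Whitespace and parentheses are
    normalized away.
    """
    text = name.strip()
    if not text:
        raise LipidNameError("empty lipid name", 0)
    m = _SLASH_RE.match(text)
    if m:
        sub = m.group("sub")
        if sub not in SUBCLASSES:
            raise LipidNameError(f"unknown subclass {sub!r}", 0)
        info = SUBCLASSES[sub]
        chains = re.split(r"\s*/\s*", m.group("chains"))
        acyls: list[FattyAcyl] = []
        for chain in chains:
            sphingoid = chain.startswith("d")
            body = chain[1:] if sphingoid else chain
            am = _ACYL_RE.fullmatch(body)
            if am is None:
                raise LipidNameError(f"malformed chain {chain!r}", text.find(chain))
            c, d = int(am.group(1)), int(am.group(2))
            if sphingoid:
                if info.sphingoid_base is None:
                    raise LipidNameError(
                        f"sphingoid base in non-sphingolipid {sub}", text.find(chain)
                    )
                if (c, d) != (info.sphingoid_base.carbons, info.sphingoid_base.double_bonds):
                    raise LipidNameError(
                        f"unsupported sphingoid base d{c}:{d} for {sub}", text.find(chain)
                    )
                continue
            try:
                acyls.append(FattyAcyl(c, d))
            except ValueError as exc:
                raise LipidNameError(str(exc), text.find(chain)) from exc
        if info.sphingoid_base is not None and len(chains) != 2:
            raise LipidNameError(f"{sub} expects base/acyl form", 0)
        if len(acyls) != info.arity:
            raise LipidNameError(
                f"{sub} takes {info.arity} acyl(s), name has {len(acyls)}", 0
            )
        return ParsedName(subclass=sub, acyls=tuple(sorted(acyls)))
    m = _SUM_RE.match(text)
    if m:
        sub = m.group("sub")
        if sub not in SUBCLASSES:
            raise LipidNameError(f"unknown subclass {sub!r}", 0)
        c, d = int(m.group("c")), int(m.group("d"))
        if c <= 0:
            raise LipidNameError("sum carbon number must be positive", text.find(m.group("c")))
        marker = None
        if m.group("mc"):
            try:
                marker = FattyAcyl(int(m.group("mc")), int(m.group("md")))
            except ValueError as exc:
                raise LipidNameError(str(exc), text.find("FA")) from exc
        info = SUBCLASSES[sub]
        if info.arity == 1 and info.sphingoid_base is None and marker is None:
            # single-acyl subclass: the sum composition IS the acyl
            try:
                return ParsedName(sub, acyls=(FattyAcyl(c, d),))
            except ValueError as exc:
                raise LipidNameError(str(exc), 0) from exc
        return ParsedName(sub, sum_carbons=c, sum_double_bonds=d, marker_acyl=marker)
    raise LipidNameError(f"unrecognized lipid name {text!r}", 0)


def format_name(species: LipidSpecies) -> str:
    """Canonical acyl-resolved shorthand for a species (inverse of parse_name)."""
    return species.acyl_name


def species_from_name(name: str) -> LipidSpecies:
    """Build a species from an acyl-resolved shorthand name."""
    parsed = parse_name(name)
    if parsed.acyls is None:
        raise LipidNameError(
            "sum-level name does not determine acyl chains; use the slash form", 0
        )
    return make_species(parsed.subclass, parsed.acyls)


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def library_table(species: Sequence[LipidSpecies]):
    """Library as a DataFrame (name, subclass, acyls, Hill formula, neutral mass)."""
    import pandas as pd

    rows = [
        {
            "name": s.acyl_name,
            "sum_name": s.sum_name,
            "subclass": s.subclass,
            "acyls": "/".join(str(a) for a in s.acyls),
            "formula": s.formula.hill(),
            "neutral_mass": round(s.neutral_mass, 6),
            "polarity": s.polarity,
        }
        for s in species
    ]
    return pd.DataFrame(rows)


def species_from_table_row(row) -> LipidSpecies:
    """Reconstruct a species from a library-table row."""
    acyls = [
        FattyAcyl(int(c), int(d))
        for c, d in (a.split(":") for a in str(row["acyls"]).split("/"))
    ]
    return make_species(str(row["subclass"]), acyls)
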