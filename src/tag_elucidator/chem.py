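"""Exact molecular-formula arithmetic for glyceride ions.

Monoisotopic masses, fatty-acyl and triacylglyceride formula construction,
and alkali-metal adduct m/z computation. Everything downstream (composition
search, CID/OzID prediction) is arithmetic on the quantities defined here.

Conventions
-----------
* Masses are monoisotopic, in Da, from a fixed CODATA-derived table.
* All ions are singly charged cations; the electron mass is subtracted
  when forming an adduct ion (m/z = M + cation - e).
* Reported m/z values use one of two rounding modes: ``"table"`` (two
  decimals) or ``"text"`` (nearest integer).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .errors import ConfigError, FormulaError

# Monoisotopic atomic masses (Da), CODATA/AME-derived, >= 7 significant
# decimals. Kept in one place so golden-value tests stay stable.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Li": 7.01600455,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

ELECTRON_MASS: float = 0.00054857991

#: Neutral composition added when forming each supported cation adduct.
CATION_COMPOSITION: dict[str, dict[str, int]] = {
    "H": {"H": 1},
    "Li": {"Li": 1},
    "Na": {"Na": 1},
    "K": {"K": 1},
    "NH4": {"N": 1, "H": 4},
}

# Convenience constants used throughout fragment arithmetic.
MASS_H2O = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]
MASS_CH2 = ATOMIC_MASS["C"] + 2 * ATOMIC_MASS["H"]
MASS_O = ATOMIC_MASS["O"]
MASS_PROTON = ATOMIC_MASS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map with additive monoisotopic mass semantics."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, count in self.counts.items():
            if element not in ATOMIC_MASS:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if not isinstance(count, int) or count < 0:
                raise FormulaError(
                    f"element count must be a non-negative integer: {element}={count!r}"
                )
            if count > 0:
                clean[element] = count
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) - count
            if merged[element] < 0:
                raise FormulaError(
                    f"subtraction drives {element} count below zero"
                )
        return MolecularFormula(merged)

    def __mul__(self, k: int) -> "MolecularFormula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError("formula multiplier must be a non-negative integer")
        return MolecularFormula({e: c * k for e, c in self.counts.items()})

    __rmul__ = __mul__

    def __str__(self) -> str:
        return format_formula(self)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C31H52O6"``.

    Raises :class:`FormulaError` naming the offending token on malformed
    input (negative counts, unknown elements, stray characters).
    """
    if not text:
        return MolecularFormula({})
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _FORMULA_TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {text[pos:]!r}"
            )
        element, digits = match.groups()
        if element not in ATOMIC_MASS:
            raise FormulaError(f"malformed formula {text!r}: unknown element {element!r}")
        count = int(digits) if digits else 1
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
    return MolecularFormula(counts)


def format_formula(f: MolecularFormula) -> str:
    """Render in Hill order: C first, H second, then alphabetical."""
    if not f.counts:
        return ""
    order = [e for e in ("C", "H") if e in f.counts]
    order += sorted(e for e in f.counts if e not in ("C", "H"))
    return "".join(
        e if f.counts[e] == 1 else f"{e}{f.counts[e]}" for e in order
    )


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Sum of count-weighted monoisotopic atomic masses, in Da."""
    try:
        return sum(count * ATOMIC_MASS[element] for element, count in f.counts.items())
    except KeyError as exc:  # pragma: no cover - blocked by formula validation
        raise ConfigError(f"element missing from atomic-mass table: {exc}") from exc


@dataclass(frozen=True)
class AdductSpec:
    """Singly charged cation adduct ([M + X]+ with X in H/Li/Na/K/NH4)."""

    cation: str
    charge: int = 1

    def __post_init__(self) -> None:
        if self.cation not in CATION_COMPOSITION:
            raise ConfigError(
                f"unsupported cation {self.cation!r}; supported: "
                f"{sorted(CATION_COMPOSITION)}"
            )
        if self.charge != 1:
            raise ConfigError("only singly charged cation adducts are supported")

    @property
    def cation_mass(self) -> float:
        """Mass of the charged cation (neutral composition minus electron)."""
        neutral = MolecularFormula(CATION_COMPOSITION[self.cation])
        return monoisotopic_mass(neutral) - ELECTRON_MASS


@dataclass(frozen=True)
class FattyAcyl:
    """A fatty acyl chain: carbon count, unsaturation, optional annotation.

    ``db_positions`` uses n-x counting (x carbons from the methyl
    terminus); ``db_geometries`` entries are ``"cis"``, ``"trans"`` or
    ``"unknown"``; ``branched`` marks methyl branching (which does not
    change the elemental formula).
    """

    n_carbons: int
    n_double_bonds: int
    db_positions: tuple[int, ...] | None = None
    db_geometries: tuple[str, ...] | None = None
    branched: bool = False

    def __post_init__(self) -> None:
        if self.n_carbons < 2:
            raise FormulaError("fatty acyl needs at least 2 carbons")
        if not 0 <= self.n_double_bonds <= self.n_carbons - 1:
            raise FormulaError(
                f"{self.n_carbons}:{self.n_double_bonds} violates "
                "0 <= double bonds <= carbons - 1"
            )
        if self.db_positions is not None:
            positions = tuple(self.db_positions)
            if len(positions) != self.n_double_bonds:
                raise FormulaError(
                    "db_positions length must equal the double-bond count"
                )
            for x in positions:
                if not 2 <= x <= self.n_carbons - 1:
                    raise FormulaError(
                        f"double-bond position n-{x} impossible for a "
                        f"{self.n_carbons}-carbon chain"
                    )
            object.__setattr__(self, "db_positions", positions)
        if self.db_geometries is not None:
            geometries = tuple(self.db_geometries)
            if len(geometries) != self.n_double_bonds:
                raise FormulaError(
                    "db_geometries length must equal the double-bond count"
                )
            for g in geometries:
                if g not in ("cis", "trans", "unknown"):
                    raise FormulaError(f"unknown double-bond geometry {g!r}")
            object.__setattr__(self, "db_geometries", geometries)

    @property
    def key(self) -> tuple[int, int]:
        """Sort key by (carbons, double bonds)."""
        return (self.n_carbons, self.n_double_bonds)

    def __str__(self) -> str:
        return f"{self.n_carbons}:{self.n_double_bonds}"


SN_ASSIGNMENTS = (
    "fully-resolved",
    "long-chain-at-sn-1/3",
    "long-chain-at-sn-2",
    "unresolved",
)


@dataclass(frozen=True)
class TagStructure:
    """Three fatty acyl slots on a glycerol backbone.

    When ``sn_assignment`` resolves backbone positions, slot order encodes
    sn-1/sn-2/sn-3; otherwise order is not meaningful.
    """

    acyls: tuple[FattyAcyl, FattyAcyl, FattyAcyl]
    sn_assignment: str = "unresolved"

    def __post_init__(self) -> None:
        acyls = tuple(self.acyls)
        if len(acyls) != 3:
            raise FormulaError("a triacylglyceride has exactly three acyl slots")
        object.__setattr__(self, "acyls", acyls)
        if self.sn_assignment not in SN_ASSIGNMENTS:
            raise FormulaError(
                f"sn_assignment must be one of {SN_ASSIGNMENTS}"
            )

    @property
    def long_chain(self) -> FattyAcyl:
        return max(self.acyls, key=lambda a: a.key)

    def composition(self) -> tuple[FattyAcyl, ...]:
        """Acyl multiset in canonical (descending) order, annotation-free."""
        bare = (
            FattyAcyl(a.n_carbons, a.n_double_bonds) for a in self.acyls
        )
        return tuple(sorted(bare, key=lambda a: a.key, reverse=True))


_GLYCEROL = MolecularFormula({"C": 3, "H": 8, "O": 3})
_WATER = MolecularFormula({"H": 2, "O": 1})


def acyl_formula(a: FattyAcyl) -> MolecularFormula:
    """Elemental formula of the free fatty acid: CnH(2n-2d)O2."""
    return MolecularFormula(
        {"C": a.n_carbons, "H": 2 * a.n_carbons - 2 * a.n_double_bonds, "O": 2}
    )


def tag_formula(t: TagStructure | tuple[FattyAcyl, ...]) -> MolecularFormula:
    """Formula of the intact TAG: glycerol + three free acids - 3 H2O.

    Accepts either a :class:`TagStructure` or a bare 3-tuple of acyls;
    the result is invariant under acyl permutation.
    """
    acyls = t.acyls if isinstance(t, TagStructure) else tuple(t)
    if len(acyls) != 3:
        raise FormulaError("a triacylglyceride has exactly three acyl slots")
    total = _GLYCEROL
    for a in acyls:
        total = total + acyl_formula(a)
    return total - 3 * _WATER


def ion_mz(f: MolecularFormula, adduct: AdductSpec) -> float:
    """m/z of the singly charged [M + cation]+ ion."""
    return monoisotopic_mass(f) + adduct.cation_mass


def round_mz(mz: float, mode: str = "table") -> float:
    """Round an m/z for reporting.

    ``"table"`` gives two decimals (calculated-mass tables); ``"text"``
    gives the nearest integer (in-text ion labels).
    """
    if mode == "table":
        return round(mz, 2)
    if mode == "text":
        return float(round(mz))
    raise ConfigError(f"unknown m/z reporting mode {mode!r}")
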