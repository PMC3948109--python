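"""Invert an observed exact mass into candidate compositions.

Two searches: a generic elemental-composition search over a bounded
C/H/O(/N) box, and an acyl-chain composition search constrained to the
one-long-plus-two-short triacylglyceride motif.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from .chem import (
    ATOMIC_MASS,
    AdductSpec,
    FattyAcyl,
    MolecularFormula,
    format_formula,
    ion_mz,
    monoisotopic_mass,
    tag_formula,
)
from .errors import ConfigError, DataError

_DEFAULT_BOUNDS = {"C": 40, "H": 80, "O": 8}
_MAX_COMBINATIONS = 10_000_000


@dataclass(frozen=True)
class FormulaCandidate:
    """One elemental composition compatible with an observed m/z."""

    formula: MolecularFormula
    dbe: float
    ppm_error: float


def double_bond_equivalents(f: MolecularFormula) -> float:
    """Rings plus double bonds implied by a CHNO formula: (2C + 2 + N - H)/2."""
    return (2 * f["C"] + 2 + f["N"] - f["H"]) / 2


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, observed vs theoretical, in ppm."""
    return (observed - theoretical) / theoretical * 1e6


def search_formulas(
    mz: float,
    adduct: AdductSpec,
    tol_ppm: float = 20.0,
    bounds: dict[str, int] | None = None,
    require_integer_dbe: bool = False,
) -> list[FormulaCandidate]:
    """Exhaustively enumerate elemental compositions matching ``mz``.

    The neutral-mass box is spanned by per-element maximum counts in
    ``bounds`` (defaults C<=40, H<=80, O<=8). Hydrogen is solved from the
    residual mass rather than looped, which keeps the search exhaustive
    over the same box at a fraction of the cost. Candidates are sorted by
    absolute ppm error, ties broken by formula string.

    ``require_integer_dbe`` additionally drops candidates whose
    double-bond-equivalent count is negative or non-integral.
    """
    if tol_ppm <= 0:
        raise ConfigError("tol_ppm must be positive")
    if mz < adduct.cation_mass * (1 - tol_ppm * 1e-6):
        raise DataError(
            f"observed m/z {mz} is below the {adduct.cation} cation mass "
            f"{adduct.cation_mass:.5f}"
        )
    bounds = dict(_DEFAULT_BOUNDS if bounds is None else bounds)
    for element in bounds:
        if element not in ATOMIC_MASS:
            raise ConfigError(f"unknown element in bounds: {element!r}")
    n_combinations = math.prod(b + 1 for b in bounds.values())
    if n_combinations > _MAX_COMBINATIONS:
        raise ConfigError(
            f"bounds span {n_combinations} combinations (> {_MAX_COMBINATIONS}); "
            "tighten per-element maxima or split the search"
        )

    target = mz - adduct.cation_mass
    tol_da = target * tol_ppm * 1e-6
    h_max = bounds.get("H", 0)
    heavy = sorted(e for e in bounds if e != "H")

    candidates: list[FormulaCandidate] = []

    def recurse(index: int, counts: dict[str, int], mass: float) -> None:
        if mass > target + tol_da:
            return
        if index == len(heavy):
            residual = target - mass
            # all H counts whose total lands inside the window
            h_lo = math.ceil((residual - tol_da) / ATOMIC_MASS["H"])
            h_hi = math.floor((residual + tol_da) / ATOMIC_MASS["H"])
            for h in range(max(h_lo, 0), min(h_hi, h_max) + 1):
                counts_h = {**counts, "H": h}
                formula = MolecularFormula(counts_h)
                theoretical = monoisotopic_mass(formula)
                if theoretical == 0.0:
                    continue
                err = ppm_error(target, theoretical)
                if abs(err) > tol_ppm:
                    continue
                dbe = double_bond_equivalents(formula)
                if require_integer_dbe and (dbe < 0 or dbe != int(dbe)):
                    continue
                candidates.append(FormulaCandidate(formula, dbe, err))
            return
        element = heavy[index]
        for count in range(bounds[element] + 1):
            recurse(
                index + 1,
                {**counts, element: count},
                mass + count * ATOMIC_MASS[element],
            )

    recurse(0, {}, 0.0)

    # bare cation: the empty neutral formula matches when mz is the cation mass
    if abs(mz - adduct.cation_mass) / adduct.cation_mass * 1e6 <= tol_ppm:
        candidates.append(FormulaCandidate(MolecularFormula({}), 0.0, 0.0))

    candidates.sort(key=lambda c: (abs(c.ppm_error), format_formula(c.formula)))
    return candidates


@dataclass(frozen=True)
class CompositionConstraints:
    """The one-long-two-short acyl motif as an enumeration box."""

    n_long: int = 1
    long_carbons: tuple[int, int] = (16, 18)
    long_db: tuple[int, int] = (0, 2)
    n_short: int = 2
    short_carbons: tuple[int, int] = (2, 5)
    short_db: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if self.n_long + self.n_short != 3:
            raise ConfigError("n_long + n_short must equal 3")
        for name, (lo, hi) in (
            ("long_carbons", self.long_carbons),
            ("long_db", self.long_db),
            ("short_carbons", self.short_carbons),
            ("short_db", self.short_db),
        ):
            if lo > hi:
                raise ConfigError(f"empty range for {name}: ({lo}, {hi})")

    def long_chains(self) -> list[FattyAcyl]:
        return _chain_box(self.long_carbons, self.long_db)

    def short_chains(self) -> list[FattyAcyl]:
        return _chain_box(self.short_carbons, self.short_db)


def _chain_box(carbons: tuple[int, int], dbs: tuple[int, int]) -> list[FattyAcyl]:
    out = []
    for n in range(carbons[0], carbons[1] + 1):
        for d in range(dbs[0], dbs[1] + 1):
            if d <= n - 1:
                out.append(FattyAcyl(n, d))
    return out


@dataclass(frozen=True)
class AcylComposition:
    """A candidate acyl multiset with its precursor mass error."""

    acyls: tuple[FattyAcyl, ...]
    ppm_error: float
    theoretical_mz: float
    # mass-isomeric branch patterns (tiglic vs linear 5:1) are not resolvable
    # from exact mass; orthogonal evidence may assert branching downstream
    branched: str = "unknown"

    @property
    def total_double_bonds(self) -> int:
        return sum(a.n_double_bonds for a in self.acyls)

    def __str__(self) -> str:
        return "/".join(str(a) for a in self.acyls)


def enumerate_acyl_compositions(
    mz: float,
    adduct: AdductSpec,
    tol_ppm: float = 20.0,
    constraints: CompositionConstraints = CompositionConstraints(),
) -> list[AcylComposition]:
    """Enumerate acyl multisets whose TAG adduct ion matches ``mz``.

    Exhaustive over the constraint box; sorted by absolute ppm error, then
    fewer total double bonds, then descending acyl order (deterministic).
    """
    if tol_ppm <= 0:
        raise ConfigError("tol_ppm must be positive")
    seen: set[tuple[tuple[int, int], ...]] = set()
    out: list[AcylComposition] = []
    for long_chain in constraints.long_chains():
        for shorts in combinations_with_replacement(
            constraints.short_chains(), constraints.n_short
        ):
            acyls = tuple(
                sorted((long_chain, *shorts), key=lambda a: a.key, reverse=True)
            )
            signature = tuple(a.key for a in acyls)
            if signature in seen:
                continue
            seen.add(signature)
            theoretical = ion_mz(tag_formula(acyls), adduct)
            err = ppm_error(mz, theoretical)
            if abs(err) <= tol_ppm:
                out.append(AcylComposition(acyls, err, theoretical))
    out.sort(
        key=lambda c: (
            abs(c.ppm_error),
            c.total_double_bonds,
            tuple(a.key for a in c.acyls),
        )
    )
    return out


def nearest_miss_ppm(
    mz: float,
    adduct: AdductSpec,
    constraints: CompositionConstraints = CompositionConstraints(),
) -> float:
    """Smallest |ppm error| over the whole constraint box (diagnostics)."""
    best = math.inf
    for long_chain in constraints.long_chains():
        for shorts in combinations_with_replacement(
            constraints.short_chains(), constraints.n_short
        ):
            theoretical = ion_mz(tag_formula((long_chain, *shorts)), adduct)
            best = min(best, abs(ppm_error(mz, theoretical)))
    return best
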