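"""OzID double-bond localization and geometry scoring.

Gas-phase ozonolysis of a double bond x carbons from the methyl terminus
yields an aldehyde ion shifted by -x*CH2 + O from the precursor and a
Criegee ion one further oxygen up. The aldehyde:Criegee abundance ratio
differs between cis and trans alkenes, so geometry can be called against
calibrated reference ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import MASS_CH2, MASS_O, FattyAcyl
from .errors import DataError
from .io.peaklist import Spectrum


@dataclass(frozen=True)
class OzidProductPair:
    """Aldehyde/Criegee ion pair diagnostic for one n-x double bond."""

    n_x: int
    aldehyde_mz: float
    criegee_mz: float
    aldehyde_intensity: float | None = None
    criegee_intensity: float | None = None


def predict_ozid_products(
    precursor_mz: float, positions: list[int]
) -> list[OzidProductPair]:
    """One aldehyde/Criegee pair per hypothesized n-x position.

    For branched short chains (tiglate n-2) the methyl branch stays on
    the charged fragment, so the same -x*CH2 + O arithmetic applies.
    """
    pairs = []
    for x in positions:
        if x < 2:
            raise DataError(
                f"n-{x} is not a valid double-bond position (x must be >= 2)"
            )
        aldehyde = precursor_mz - x * MASS_CH2 + MASS_O
        if aldehyde <= 0:
            raise DataError(f"aldehyde m/z non-positive for position n-{x}")
        pairs.append(OzidProductPair(x, aldehyde, aldehyde + MASS_O))
    return pairs


@dataclass(frozen=True)
class LocalizedPosition:
    """A double-bond position with its level of spectral support."""

    n_x: int
    status: str  # "supported" (aldehyde only) or "confirmed" (both ions)
    pair: OzidProductPair


def localize_double_bonds(
    spectrum: Spectrum,
    precursor_mz: float,
    candidate_positions: list[int] | None = None,
    tol_mz: float = 0.3,
) -> list[LocalizedPosition]:
    """Find n-x positions whose predicted ions appear in the spectrum.

    A position is *supported* when its aldehyde ion matches and
    *confirmed* when the Criegee ion matches too. Multiple positions may
    be reported (positional isomer mixtures). Empty result means the
    localization is undetermined.
    """
    if spectrum.stage != "OzID":
        raise DataError(
            f"localize_double_bonds needs an OzID spectrum, got {spectrum.stage!r}"
        )
    if candidate_positions is None:
        candidate_positions = list(range(2, 18))
    out: list[LocalizedPosition] = []
    for pair in predict_ozid_products(precursor_mz, sorted(set(candidate_positions))):
        aldehyde_hit = spectrum.match(pair.aldehyde_mz, tol_mz)
        if aldehyde_hit is None:
            continue
        criegee_hit = spectrum.match(pair.criegee_mz, tol_mz)
        matched_pair = OzidProductPair(
            pair.n_x,
            pair.aldehyde_mz,
            pair.criegee_mz,
            aldehyde_hit[1],
            criegee_hit[1] if criegee_hit else None,
        )
        status = "confirmed" if criegee_hit else "supported"
        out.append(LocalizedPosition(pair.n_x, status, matched_pair))
    return out


@dataclass(frozen=True)
class GeometryCall:
    """cis/trans call for one localized double bond."""

    n_x: int
    call: str  # "cis" | "trans" | "undetermined"
    observed_ratio: float | None
    reference_ratio: float | None
    reason: str


def classify_geometry(
    pairs: list[OzidProductPair],
    references: dict[str, float] | None,
    rel_tol: float = 0.5,
) -> list[GeometryCall]:
    """Call geometry from observed aldehyde:Criegee abundance ratios.

    A geometry is called when the observed ratio lies within ``rel_tol``
    (relative) of exactly one reference ratio; otherwise undetermined.
    References are user-supplied calibration against standards of known
    geometry, not shipped constants.
    """
    calls = []
    for pair in pairs:
        if not references:
            calls.append(
                GeometryCall(pair.n_x, "undetermined", None, None, "no reference configured")
            )
            continue
        if pair.aldehyde_intensity is None or pair.criegee_intensity is None:
            calls.append(
                GeometryCall(
                    pair.n_x, "undetermined", None, None, "missing matched intensities"
                )
            )
            continue
        if pair.criegee_intensity <= 0:
            calls.append(
                GeometryCall(
                    pair.n_x,
                    "undetermined",
                    None,
                    None,
                    "zero Criegee intensity: ratio undefined",
                )
            )
            continue
        observed = pair.aldehyde_intensity / pair.criegee_intensity
        hits = {
            geometry: reference
            for geometry, reference in references.items()
            if abs(observed - reference) <= rel_tol * reference
        }
        if len(hits) == 1:
            geometry, reference = next(iter(hits.items()))
            calls.append(
                GeometryCall(
                    pair.n_x,
                    geometry,
                    observed,
                    reference,
                    f"ratio {observed:.2f} within {rel_tol:.0%} of {geometry} reference",
                )
            )
        else:
            why = "no reference matched" if not hits else "multiple references matched"
            calls.append(GeometryCall(pair.n_x, "undetermined", observed, None, why))
    return calls


def attribute_positions(
    positions: list[LocalizedPosition], acyls: tuple[FattyAcyl, ...]
) -> dict[int, list[FattyAcyl]]:
    """Map each localized n-x to the acyls it is chemically possible on.

    x must satisfy 2 <= x <= chain length - 1 and the chain must be
    unsaturated. More than one compatible acyl means the attribution is
    ambiguous and is flagged upstream.
    """
    distinct: dict[tuple[int, int], FattyAcyl] = {}
    for a in acyls:
        distinct.setdefault(a.key, a)
    out: dict[int, list[FattyAcyl]] = {}
    for position in positions:
        out[position.n_x] = [
            a
            for a in distinct.values()
            if a.n_double_bonds >= 1 and 2 <= position.n_x <= a.n_carbons - 1
        ]
    return out
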