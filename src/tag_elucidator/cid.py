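"""CID product-ion prediction, spectrum annotation and sn-position inference.

Alkali-metal TAG adducts fragment by loss of each fatty acyl substituent
through two channels: loss of the free acid (keeping the metal on the
charged fragment) and loss of the metal carboxylate (the fragment retains
a proton instead). Relative loss abundances carry backbone information:
losses from the sn-2 position are suppressed relative to sn-1/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean

from .chem import (
    ATOMIC_MASS,
    AdductSpec,
    FattyAcyl,
    acyl_formula,
    ion_mz,
    monoisotopic_mass,
    tag_formula,
)
from .composition import AcylComposition, ppm_error
from .errors import DataError
from .io.peaklist import Spectrum

CHANNELS = ("neutral-acid-loss", "metalated-acid-loss")


@dataclass(frozen=True)
class CidFragment:
    parent_acyl: FattyAcyl
    channel: str
    mz: float
    matched_mz: float | None = None
    matched_intensity: float | None = None

    @property
    def matched(self) -> bool:
        return self.matched_intensity is not None


def predict_cid_fragments(
    candidate: tuple[FattyAcyl, ...],
    precursor_mz: float,
    adduct: AdductSpec,
    tol_ppm: float = 20.0,
) -> list[CidFragment]:
    """Two loss channels per distinct acyl; duplicate acyls collapse.

    Raises :class:`DataError` with the ppm discrepancy when the precursor
    m/z is inconsistent with the candidate composition.
    """
    theoretical = ion_mz(tag_formula(candidate), adduct)
    discrepancy = ppm_error(precursor_mz, theoretical)
    if abs(discrepancy) > tol_ppm:
        raise DataError(
            f"precursor m/z {precursor_mz} inconsistent with candidate "
            f"{'/'.join(map(str, candidate))} (theoretical {theoretical:.5f}, "
            f"{discrepancy:+.1f} ppm > {tol_ppm} ppm)"
        )
    fragments: list[CidFragment] = []
    for acyl in _distinct(candidate):
        acid_mass = monoisotopic_mass(acyl_formula(acyl))
        neutral_loss_mz = precursor_mz - acid_mass
        # losing the metal carboxylate: the cation leaves, a proton stays
        metalated_loss_mz = (
            precursor_mz
            - acid_mass
            - _cation_atom_mass(adduct)
            + ATOMIC_MASS["H"]
        )
        fragments.append(CidFragment(acyl, "neutral-acid-loss", neutral_loss_mz))
        fragments.append(CidFragment(acyl, "metalated-acid-loss", metalated_loss_mz))
    return fragments


def _cation_atom_mass(adduct: AdductSpec) -> float:
    # neutral-atom mass of the departing metal; electron terms cancel in
    # the loss arithmetic
    from .chem import CATION_COMPOSITION, MolecularFormula

    return monoisotopic_mass(MolecularFormula(CATION_COMPOSITION[adduct.cation]))


def _distinct(acyls: tuple[FattyAcyl, ...]) -> list[FattyAcyl]:
    seen: dict[tuple[int, int], FattyAcyl] = {}
    for a in sorted(acyls, key=lambda a: a.key, reverse=True):
        seen.setdefault(a.key, a)
    return list(seen.values())


@dataclass(frozen=True)
class CidAnnotation:
    """One candidate's CID evidence: matched fragments and a match score."""

    candidate: AcylComposition
    fragments: tuple[CidFragment, ...]
    score: float
    flags: tuple[str, ...] = ()

    def matched_by_acyl(self) -> dict[FattyAcyl, list[CidFragment]]:
        out: dict[FattyAcyl, list[CidFragment]] = {}
        for fragment in self.fragments:
            out.setdefault(fragment.parent_acyl, []).append(fragment)
        return out


def annotate_cid(
    spectrum: Spectrum,
    candidates: list[AcylComposition],
    tol_mz: float = 0.3,
    tol_ppm: float = 20.0,
) -> tuple[list[CidAnnotation], list[tuple[float, float]]]:
    """Score candidates against an observed CID spectrum.

    Per distinct acyl: both channels matched scores 1.0, one channel 0.5;
    the candidate score is the mean over its distinct acyls. Returns the
    ranked annotations and the observed peaks left unmatched by the
    top-ranked candidate.
    """
    if spectrum.stage != "CID":
        raise DataError(f"annotate_cid needs a CID spectrum, got stage {spectrum.stage!r}")
    if not candidates:
        raise DataError("no candidates to annotate")
    if spectrum.adduct is None:
        raise DataError("CID spectrum carries no adduct metadata")

    annotations: list[CidAnnotation] = []
    for candidate in candidates:
        precursor = spectrum.precursor_mz or candidate.theoretical_mz
        predicted = predict_cid_fragments(
            candidate.acyls, precursor, spectrum.adduct, tol_ppm
        )
        matched_fragments: list[CidFragment] = []
        per_acyl_hits: dict[tuple[int, int], int] = {}
        for fragment in predicted:
            hit = spectrum.match(fragment.mz, tol_mz)
            if hit is not None:
                fragment = CidFragment(
                    fragment.parent_acyl, fragment.channel, fragment.mz, hit[0], hit[1]
                )
                per_acyl_hits[fragment.parent_acyl.key] = (
                    per_acyl_hits.get(fragment.parent_acyl.key, 0) + 1
                )
            matched_fragments.append(fragment)
        n_distinct = len(_distinct(candidate.acyls))
        score = sum(
            1.0 if hits == 2 else 0.5 for hits in per_acyl_hits.values()
        ) / n_distinct
        flags = ()
        if len(spectrum) == 0:
            flags = ("no evidence",)
        annotations.append(
            CidAnnotation(candidate, tuple(matched_fragments), score, flags)
        )

    annotations.sort(
        key=lambda ann: (
            -ann.score,
            abs(ann.candidate.ppm_error),
            ann.candidate.total_double_bonds,
            tuple(a.key for a in ann.candidate.acyls),
        )
    )
    unmatched = _unmatched_peaks(spectrum, annotations[0], tol_mz) if annotations else []
    return annotations, unmatched


def _unmatched_peaks(
    spectrum: Spectrum, top: CidAnnotation, tol_mz: float
) -> list[tuple[float, float]]:
    predicted_mzs = [f.mz for f in top.fragments]
    return [
        peak
        for peak in spectrum.peaks
        if all(abs(peak[0] - mz) > tol_mz for mz in predicted_mzs)
    ]


@dataclass(frozen=True)
class SnEvidence:
    """Backbone-position inference from relative loss abundances."""

    per_acyl_abundance: dict[str, float]
    sn_assignment: str
    confidence_ratio: float | None
    reason: str
    # the numeric sn-2 threshold is a configurable default, not a
    # literature constant; reports must surface it
    decision_ratio: float = 0.5


def infer_sn_positions(
    annotation: CidAnnotation, decision_ratio: float = 0.5
) -> SnEvidence:
    """Propose a backbone assignment from per-acyl mean loss abundances.

    The acyl with minimal mean relative loss abundance is proposed for
    sn-2 when its abundance is below ``decision_ratio`` times the minimum
    of the other acyls'. sn-1 and sn-3 are never distinguished.
    """
    by_acyl = annotation.matched_by_acyl()
    matched = {
        acyl: [f for f in frags if f.matched] for acyl, frags in by_acyl.items()
    }
    missing = [str(acyl) for acyl, frags in matched.items() if not frags]
    if missing:
        return SnEvidence(
            per_acyl_abundance={},
            sn_assignment="unresolved",
            confidence_ratio=None,
            reason=f"no matched fragments for acyl(s): {', '.join(missing)}",
            decision_ratio=decision_ratio,
        )

    base = max(
        f.matched_intensity for frags in matched.values() for f in frags
    )
    if base <= 0:
        return SnEvidence(
            {}, "unresolved", None, "all matched intensities are zero", decision_ratio
        )
    abundance = {
        acyl: mean(f.matched_intensity / base for f in frags)
        for acyl, frags in matched.items()
    }
    if len(abundance) < 2:
        return SnEvidence(
            {str(a): v for a, v in abundance.items()},
            "unresolved",
            None,
            "a single distinct acyl carries no positional contrast",
            decision_ratio,
        )

    lowest = min(abundance, key=lambda a: (abundance[a], a.key))
    others_min = min(v for a, v in abundance.items() if a is not lowest)
    ratio = abundance[lowest] / others_min if others_min > 0 else 0.0
    long_chain = max(abundance, key=lambda a: a.key)

    if ratio < decision_ratio:
        assignment = (
            "long-chain-at-sn-2" if lowest is long_chain else "long-chain-at-sn-1/3"
        )
        reason = (
            f"{lowest} losses suppressed ({ratio:.2f} < {decision_ratio} x others)"
        )
    else:
        assignment = "unresolved"
        reason = (
            f"no acyl suppressed below the decision ratio "
            f"(min ratio {ratio:.2f} >= {decision_ratio})"
        )
    return SnEvidence(
        per_acyl_abundance={str(a): v for a, v in abundance.items()},
        sn_assignment=assignment,
        confidence_ratio=ratio,
        reason=reason,
        decision_ratio=decision_ratio,
    )
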