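"""End-to-end structure elucidation.

Chains composition search -> CID annotation -> sn inference -> OzID
double-bond localization -> geometry scoring into one ranked,
evidence-carrying report. Stages degrade gracefully: absent spectra leave
their evidence fields undetermined, never fabricated. Conflicts (an OzID
position impossible for a candidate's chains) are surfaced as flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .chem import AdductSpec
from .cid import CidAnnotation, SnEvidence, annotate_cid, infer_sn_positions
from .composition import AcylComposition, enumerate_acyl_compositions, nearest_miss_ppm
from .errors import DataError
from .io.config import PipelineConfig
from .io.peaklist import Spectrum
from .ozid import (
    GeometryCall,
    LocalizedPosition,
    attribute_positions,
    classify_geometry,
    localize_double_bonds,
)

REPORT_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class CandidateReport:
    composition: AcylComposition
    cid_score: float | None
    sn_evidence: SnEvidence | None
    positions: tuple[LocalizedPosition, ...]
    position_attribution: dict[int, list[str]]
    geometry_calls: tuple[GeometryCall, ...]
    flags: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "composition": str(self.composition),
            "acyls": [str(a) for a in self.composition.acyls],
            "ppm_error": round(self.composition.ppm_error, 3),
            "branched": self.composition.branched,
            "cid_score": self.cid_score,
            "sn_assignment": (
                self.sn_evidence.sn_assignment if self.sn_evidence else "undetermined"
            ),
            "sn_evidence": (
                {
                    "per_acyl_abundance": {
                        k: round(v, 4)
                        for k, v in self.sn_evidence.per_acyl_abundance.items()
                    },
                    "confidence_ratio": (
                        round(self.sn_evidence.confidence_ratio, 4)
                        if self.sn_evidence.confidence_ratio is not None
                        else None
                    ),
                    "decision_ratio": self.sn_evidence.decision_ratio,
                    "reason": self.sn_evidence.reason,
                }
                if self.sn_evidence
                else None
            ),
            "db_positions": [
                {
                    "n_x": p.n_x,
                    "status": p.status,
                    "aldehyde_mz": round(p.pair.aldehyde_mz, 5),
                    "criegee_mz": round(p.pair.criegee_mz, 5),
                    "attributed_to": self.position_attribution.get(p.n_x, []),
                }
                for p in self.positions
            ],
            "geometry_calls": [
                {
                    "n_x": g.n_x,
                    "call": g.call,
                    "observed_ratio": (
                        round(g.observed_ratio, 4) if g.observed_ratio is not None else None
                    ),
                    "reference_ratio": g.reference_ratio,
                    "reason": g.reason,
                }
                for g in self.geometry_calls
            ],
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class ElucidationReport:
    precursor_mz: float
    adduct: AdductSpec
    candidates: tuple[CandidateReport, ...]
    config: PipelineConfig
    flags: tuple[str, ...] = ()
    nearest_miss_ppm: float | None = None
    unmatched_cid_peaks: tuple[tuple[float, float], ...] = ()

    @property
    def top(self) -> CandidateReport | None:
        return self.candidates[0] if self.candidates else None

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "precursor_mz": self.precursor_mz,
            "adduct": self.adduct.cation,
            "config_hash": self.config.config_hash(),
            "tolerances": {
                "tol_ppm": self.config.tol_ppm,
                "fragment_tol_mz": self.config.fragment_tol_mz,
                "sn2_ratio": self.config.sn2_ratio,
                "geometry_rel_tol": self.config.geometry_rel_tol,
            },
            "flags": list(self.flags),
            "nearest_miss_ppm": (
                round(self.nearest_miss_ppm, 2)
                if self.nearest_miss_ppm is not None
                else None
            ),
            "unmatched_cid_peaks": [
                [round(mz, 5), intensity] for mz, intensity in self.unmatched_cid_peaks
            ],
            "candidates": [c.to_dict() for c in self.candidates],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def summary(self) -> str:
        """Short human-readable digest of the ranked candidates."""
        lines = [
            f"precursor m/z {self.precursor_mz:.4f} [M+{self.adduct.cation}]+ "
            f"(config {self.config.config_hash()})"
        ]
        if not self.candidates:
            lines.append(
                "  no composition candidate within tolerance"
                + (
                    f" (nearest miss {self.nearest_miss_ppm:.1f} ppm)"
                    if self.nearest_miss_ppm is not None
                    else ""
                )
            )
        for i, c in enumerate(self.candidates, start=1):
            score = "n/a" if c.cid_score is None else f"{c.cid_score:.2f}"
            positions = (
                ", ".join(f"n-{p.n_x} ({p.status})" for p in c.positions)
                or "undetermined"
            )
            sn = c.sn_evidence.sn_assignment if c.sn_evidence else "undetermined"
            lines.append(
                f"  #{i} {c.composition} | {c.composition.ppm_error:+.1f} ppm | "
                f"CID score {score} | sn: {sn} | db: {positions}"
            )
            for flag in c.flags:
                lines.append(f"     ! {flag}")
        return "\n".join(lines)


def elucidate(
    precursor_mz: float,
    adduct: AdductSpec,
    cid_spectrum: Spectrum | None = None,
    ozid_spectrum: Spectrum | None = None,
    config: PipelineConfig | None = None,
) -> ElucidationReport:
    """Run the full elucidation cascade for one precursor ion.

    Candidates come from the acyl-composition search; CID evidence ranks
    them (composite key: CID score, then |ppm error|, then fewer double
    bonds); OzID decorates them with double-bond positions and geometry
    calls but never changes the ranking.
    """
    config = config or PipelineConfig()
    compositions = enumerate_acyl_compositions(
        precursor_mz, adduct, config.tol_ppm, config.constraints
    )
    if not compositions:
        return ElucidationReport(
            precursor_mz=precursor_mz,
            adduct=adduct,
            candidates=(),
            config=config,
            flags=("no composition candidate within tolerance",),
            nearest_miss_ppm=nearest_miss_ppm(precursor_mz, adduct, config.constraints),
        )

    report_flags: list[str] = []
    unmatched: tuple[tuple[float, float], ...] = ()
    annotations: list[CidAnnotation]
    if cid_spectrum is not None:
        spectrum = _with_metadata(cid_spectrum, precursor_mz, adduct)
        ranked, unmatched_list = annotate_cid(
            spectrum, compositions, config.fragment_tol_mz, config.tol_ppm
        )
        annotations = ranked
        unmatched = tuple(unmatched_list)
        if len(spectrum) == 0:
            report_flags.append("empty CID spectrum: no fragmentation evidence")
    else:
        annotations = [
            CidAnnotation(candidate, (), 0.0, ()) for candidate in compositions
        ]
        report_flags.append("no CID spectrum provided")

    candidates = []
    for annotation in annotations:
        sn_evidence: SnEvidence | None = None
        if cid_spectrum is not None and len(cid_spectrum) > 0:
            sn_evidence = infer_sn_positions(annotation, config.sn2_ratio)

        positions: tuple[LocalizedPosition, ...] = ()
        attribution: dict[int, list[str]] = {}
        geometry_calls: tuple[GeometryCall, ...] = ()
        flags: list[str] = list(annotation.flags)
        if ozid_spectrum is not None:
            ozid = _with_metadata(ozid_spectrum, precursor_mz, adduct)
            max_chain = max(a.n_carbons for a in annotation.candidate.acyls)
            localized = localize_double_bonds(
                ozid,
                precursor_mz,
                list(range(2, max_chain)),
                config.fragment_tol_mz,
            )
            positions = tuple(localized)
            acyl_map = attribute_positions(localized, annotation.candidate.acyls)
            attribution = {
                x: [str(a) for a in acyls] for x, acyls in acyl_map.items()
            }
            for x, names in attribution.items():
                if not names:
                    flags.append(
                        f"ozid-position-impossible: n-{x} fits no acyl of this candidate"
                    )
                elif len(names) > 1:
                    flags.append(
                        f"ozid-position-ambiguous: n-{x} fits {'/'.join(names)}"
                    )
            if not localized:
                flags.append("ozid: no double-bond position supported (undetermined)")
            geometry_calls = tuple(
                classify_geometry(
                    [p.pair for p in localized],
                    config.geometry_references,
                    config.geometry_rel_tol,
                )
            )

        candidates.append(
            CandidateReport(
                composition=annotation.candidate,
                cid_score=annotation.score if cid_spectrum is not None else None,
                sn_evidence=sn_evidence,
                positions=positions,
                position_attribution=attribution,
                geometry_calls=geometry_calls,
                flags=tuple(flags),
            )
        )

    return ElucidationReport(
        precursor_mz=precursor_mz,
        adduct=adduct,
        candidates=tuple(candidates),
        config=config,
        flags=tuple(report_flags),
        unmatched_cid_peaks=unmatched,
    )


def _with_metadata(
    spectrum: Spectrum, precursor_mz: float, adduct: AdductSpec
) -> Spectrum:
    if spectrum.adduct is not None and spectrum.precursor_mz is not None:
        return spectrum
    return Spectrum(
        stage=spectrum.stage,
        peaks=spectrum.peaks,
        precursor_mz=spectrum.precursor_mz or precursor_mz,
        adduct=spectrum.adduct or adduct,
        source=spectrum.source,
    )
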