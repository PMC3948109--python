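"""Quantification and behavioral statistics.

Reference-peak normalization of spectra, TLC band normalization, and
mate-choice preference scores with exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats as sps

from .errors import DataError
from .io.peaklist import Spectrum


@dataclass(frozen=True)
class NormalizedProfile:
    """Per-target intensities relative to a reference peak."""

    reference_mz: float
    reference_intensity: float
    values: dict[float, float] = field(default_factory=dict)


def normalize_to_reference(
    peaks: Spectrum,
    reference_mz: float,
    target_mzs: list[float],
    tol_mz: float = 0.3,
) -> NormalizedProfile:
    """Divide each matched target intensity by the reference intensity.

    Unmatched targets get relative intensity 0; an absent reference is an
    error (the profile would be undefined).
    """
    if tol_mz <= 0:
        raise DataError("tol_mz must be positive")
    reference = peaks.match(reference_mz, tol_mz)
    if reference is None or reference[1] <= 0:
        raise DataError(f"reference not found: no peak within {tol_mz} of {reference_mz}")
    values = {}
    for target in target_mzs:
        hit = peaks.match(target, tol_mz)
        values[target] = hit[1] / reference[1] if hit else 0.0
    return NormalizedProfile(reference_mz, reference[1], values)


def tlc_normalize(
    band_intensities: dict[str, float], control_band: str
) -> dict[str, float]:
    """Divide each band intensity by the lane's control band intensity."""
    if control_band not in band_intensities:
        raise DataError(f"control band {control_band!r} not present in lane")
    control = band_intensities[control_band]
    if control <= 0:
        raise DataError("control band intensity must be positive")
    return {band: value / control for band, value in band_intensities.items()}


@dataclass(frozen=True)
class ChoiceAssay:
    """Counts from a two-target choice assay (plus no-choice trials)."""

    n_choice_a: int
    n_choice_b: int
    n_no_choice: int = 0

    def __post_init__(self) -> None:
        if min(self.n_choice_a, self.n_choice_b, self.n_no_choice) < 0:
            raise DataError("choice counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.n_choice_a + self.n_choice_b + self.n_no_choice

    @property
    def n_choosers(self) -> int:
        return self.n_choice_a + self.n_choice_b


@dataclass(frozen=True)
class PreferenceResult:
    score: float | None
    p_value: float | None
    n_choosers: int
    note: str = ""


def preference_score(assay: ChoiceAssay) -> PreferenceResult:
    """Preference score (A - B)/(A + B) with a two-sided exact binomial test.

    No-choice trials are excluded from the denominator. The p-value comes
    from exact enumeration of the binomial under p0 = 0.5 over the
    choosers. With zero choosers the score is undefined and reported as
    such (None), not raised.
    """
    n = assay.n_choosers
    if n == 0:
        return PreferenceResult(None, None, 0, "no choosers: score undefined")
    score = (assay.n_choice_a - assay.n_choice_b) / n
    p = sps.binomtest(assay.n_choice_a, n, 0.5, alternative="two-sided").pvalue
    return PreferenceResult(score, float(p), n)


def fisher_exact_2x2(table: list[list[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table (odds ratio, p)."""
    if len(table) != 2 or any(len(row) != 2 for row in table):
        raise DataError("fisher_exact_2x2 needs a 2x2 table")
    if any(cell < 0 for row in table for cell in row):
        raise DataError("counts must be non-negative")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)
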