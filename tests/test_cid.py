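import random

import pytest

from tag_elucidator import (
    AdductSpec,
    FattyAcyl,
    annotate_cid,
    enumerate_acyl_compositions,
    infer_sn_positions,
    ion_mz,
    predict_cid_fragments,
    tag_formula,
)
from tag_elucidator.chem import ATOMIC_MASS, ELECTRON_MASS, MASS_PROTON
from tag_elucidator.errors import DataError
from tag_elucidator.io.peaklist import Spectrum

OLEIC_DITIGLATE = (FattyAcyl(18, 1), FattyAcyl(5, 1), FattyAcyl(5, 1))
PRECURSOR_543 = 543.36561


class TestPredictCidFragments:
    def test_oleic_ditiglate_fragment_mzs(self, sodium):
        fragments = predict_cid_fragments(OLEIC_DITIGLATE, PRECURSOR_543, sodium)
        by_key = {(str(f.parent_acyl), f.channel): f.mz for f in fragments}
        # neutral-loss arithmetic from acid masses C5H8O2 = 100.05243,
        # C18H34O2 = 282.25588
        assert by_key[("5:1", "neutral-acid-loss")] == pytest.approx(443.31318, abs=2e-5)
        assert by_key[("5:1", "metalated-acid-loss")] == pytest.approx(421.33123, abs=2e-5)
        assert by_key[("18:1", "neutral-acid-loss")] == pytest.approx(261.10973, abs=2e-5)
        assert by_key[("18:1", "metalated-acid-loss")] == pytest.approx(239.12778, abs=2e-5)

    def test_duplicate_acyls_collapse(self, sodium):
        triacetin = tuple(FattyAcyl(2, 0) for _ in range(3))
        precursor = ion_mz(tag_formula(triacetin), sodium)
        fragments = predict_cid_fragments(triacetin, precursor, sodium)
        assert len(fragments) == 2
        assert len({f.mz for f in fragments}) == 2

    @pytest.mark.parametrize(
        "acyls",
        [
            OLEIC_DITIGLATE,
            (FattyAcyl(16, 0), FattyAcyl(4, 1), FattyAcyl(3, 0)),
            (FattyAcyl(18, 2), FattyAcyl(5, 1), FattyAcyl(5, 0)),
        ],
    )
    def test_fragment_count_is_twice_distinct_acyls(self, acyls, sodium):
        precursor = ion_mz(tag_formula(acyls), sodium)
        fragments = predict_cid_fragments(acyls, precursor, sodium)
        assert len(fragments) == 2 * len({a.key for a in acyls})

    @pytest.mark.parametrize("cation", ["Li", "Na", "K"])
    def test_channel_offset_is_cation_minus_proton(self, cation):
        adduct = AdductSpec(cation)
        precursor = ion_mz(tag_formula(OLEIC_DITIGLATE), adduct)
        fragments = predict_cid_fragments(OLEIC_DITIGLATE, precursor, adduct)
        offset = (adduct.cation_mass + ELECTRON_MASS) - ATOMIC_MASS["H"]
        expected = adduct.cation_mass - MASS_PROTON
        assert offset == pytest.approx(expected, abs=1e-9)
        by_acyl = {}
        for f in fragments:
            by_acyl.setdefault(str(f.parent_acyl), {})[f.channel] = f.mz
        for channels in by_acyl.values():
            assert channels["neutral-acid-loss"] - channels[
                "metalated-acid-loss"
            ] == pytest.approx(expected, abs=1e-9)

    def test_inconsistent_precursor_reports_ppm(self, sodium):
        with pytest.raises(DataError, match="ppm"):
            predict_cid_fragments(OLEIC_DITIGLATE, 545.0, sodium)


def _cid_spectrum(peaks, sodium, precursor=PRECURSOR_543):
    return Spectrum("CID", tuple(peaks), precursor_mz=precursor, adduct=sodium)


class TestAnnotateCid:
    def test_paper_peak_set_assigns_oleic_ditiglate(self, sodium):
        spectrum = _cid_spectrum(
            [(443.313, 900.0), (421.331, 1000.0), (261.110, 300.0), (239.128, 350.0)],
            sodium,
        )
        candidates = enumerate_acyl_compositions(PRECURSOR_543, sodium, 20.0)
        ranked, unmatched = annotate_cid(spectrum, candidates, 0.3)
        assert str(ranked[0].candidate) == "18:1/5:1/5:1"
        assert ranked[0].score == 1.0
        assert unmatched == []

    def test_partial_match_scores_half_per_channel(self, sodium):
        spectrum = _cid_spectrum([(443.313, 900.0), (261.110, 300.0)], sodium)
        candidates = enumerate_acyl_compositions(PRECURSOR_543, sodium, 20.0)
        ranked, _ = annotate_cid(spectrum, candidates, 0.3)
        top = next(a for a in ranked if str(a.candidate) == "18:1/5:1/5:1")
        assert top.score == 0.5  # one channel each for 18:1 and 5:1

    def test_empty_spectrum_flags_no_evidence(self, sodium):
        spectrum = _cid_spectrum([], sodium)
        candidates = enumerate_acyl_compositions(PRECURSOR_543, sodium, 20.0)
        ranked, _ = annotate_cid(spectrum, candidates, 0.3)
        assert all(a.score == 0.0 for a in ranked)
        assert all("no evidence" in a.flags for a in ranked)

    def test_unmatched_observed_peaks_reported(self, sodium):
        spectrum = _cid_spectrum(
            [(443.313, 900.0), (421.331, 1000.0), (261.110, 300.0), (239.128, 350.0),
             (350.0, 50.0)],
            sodium,
        )
        candidates = enumerate_acyl_compositions(PRECURSOR_543, sodium, 20.0)
        _, unmatched = annotate_cid(spectrum, candidates, 0.3)
        assert unmatched == [(350.0, 50.0)]

    def test_requires_cid_stage_and_candidates(self, sodium):
        precursor = Spectrum("precursor", ((543.4, 1.0),), adduct=sodium)
        with pytest.raises(DataError):
            annotate_cid(precursor, [], 0.3)


class TestInferSnPositions:
    def _annotation(self, peaks, sodium):
        spectrum = _cid_spectrum(peaks, sodium)
        candidates = enumerate_acyl_compositions(PRECURSOR_543, sodium, 20.0)
        ranked, _ = annotate_cid(spectrum, candidates, 0.3)
        return next(a for a in ranked if str(a.candidate) == "18:1/5:1/5:1")

    def test_suppressed_short_chain_puts_long_at_sn13(self, sodium):
        peaks = [
            (443.313, 100.0), (421.331, 250.0),  # 5:1 losses suppressed
            (261.110, 700.0), (239.128, 1000.0),
        ]
        evidence = infer_sn_positions(self._annotation(peaks, sodium))
        assert evidence.sn_assignment == "long-chain-at-sn-1/3"

    def test_suppressed_long_chain_proposed_at_sn2(self, sodium):
        peaks = [
            (443.313, 700.0), (421.331, 1000.0),
            (261.110, 100.0), (239.128, 250.0),  # 18:1 losses suppressed
        ]
        evidence = infer_sn_positions(self._annotation(peaks, sodium))
        assert evidence.sn_assignment == "long-chain-at-sn-2"

    def test_comparable_abundances_unresolved(self, sodium):
        peaks = [
            (443.313, 900.0), (421.331, 1000.0),
            (261.110, 850.0), (239.128, 950.0),
        ]
        evidence = infer_sn_positions(self._annotation(peaks, sodium))
        assert evidence.sn_assignment == "unresolved"

    def test_missing_fragments_unresolved_with_reason(self, sodium):
        peaks = [(443.313, 900.0), (421.331, 1000.0)]  # no 18:1 losses at all
        evidence = infer_sn_positions(self._annotation(peaks, sodium))
        assert evidence.sn_assignment == "unresolved"
        assert "18:1" in evidence.reason

    def test_permutation_invariance_over_peak_order(self, sodium):
        peaks = [
            (443.313, 100.0), (421.331, 250.0),
            (261.110, 700.0), (239.128, 1000.0),
        ]
        reference = infer_sn_positions(self._annotation(peaks, sodium))
        shuffled = list(peaks)
        random.Random(3).shuffle(shuffled)
        other = infer_sn_positions(self._annotation(shuffled, sodium))
        assert other.sn_assignment == reference.sn_assignment
        assert other.per_acyl_abundance == reference.per_acyl_abundance
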