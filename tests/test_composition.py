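"""Composition search against independent brute-force oracles."""

import numpy as np
import pytest

from tag_elucidator import (
    AdductSpec,
    CompositionConstraints,
    FattyAcyl,
    MolecularFormula,
    enumerate_acyl_compositions,
    format_formula,
    ion_mz,
    search_formulas,
    tag_formula,
)
from tag_elucidator.chem import ATOMIC_MASS
from tag_elucidator.errors import ConfigError, DataError


def oracle_search(mz, adduct, tol_ppm, bounds):
    """Independent nested-loop enumeration over the full C/H/O box."""
    target = mz - adduct.cation_mass
    hits = set()
    for c in range(bounds.get("C", 0) + 1):
        for h in range(bounds.get("H", 0) + 1):
            for o in range(bounds.get("O", 0) + 1):
                mass = c * ATOMIC_MASS["C"] + h * ATOMIC_MASS["H"] + o * ATOMIC_MASS["O"]
                if mass > 0 and abs(target - mass) / mass * 1e6 <= tol_ppm:
                    hits.add(format_formula(MolecularFormula({"C": c, "H": h, "O": o})))
    return hits


class TestSearchFormulas:
    def test_contains_target_with_dbe(self, potassium):
        candidates = search_formulas(559.3396, potassium, 20.0, {"C": 40, "H": 80, "O": 8})
        by_formula = {format_formula(c.formula): c for c in candidates}
        assert "C31H52O6" in by_formula
        assert by_formula["C31H52O6"].dbe == 6
        assert abs(by_formula["C31H52O6"].ppm_error) <= 20

    def test_matches_bruteforce_oracle(self, potassium):
        bounds = {"C": 35, "H": 70, "O": 8}
        for mz in (559.3396, 433.2197, 300.1):
            ours = {
                format_formula(c.formula)
                for c in search_formulas(mz, potassium, 20.0, bounds)
                if c.formula.counts
            }
            assert ours == oracle_search(mz, potassium, 20.0, bounds)

    def test_bare_cation_matches_empty_formula(self, sodium):
        candidates = search_formulas(22.98922, sodium, 20.0, {"C": 2, "H": 4, "O": 1})
        assert any(not c.formula.counts for c in candidates)

    def test_below_cation_mass_is_error(self, potassium):
        with pytest.raises(DataError):
            search_formulas(10.0, potassium)

    def test_oversized_bounds_refused(self, sodium):
        with pytest.raises(ConfigError, match="combinations"):
            search_formulas(500.0, sodium, 20.0, {"C": 500, "H": 500, "O": 100})

    def test_soundness_all_within_tolerance(self, sodium):
        for c in search_formulas(543.3656, sodium, 20.0):
            if c.formula.counts:
                theoretical = ion_mz(c.formula, sodium)
                assert abs(543.3656 - theoretical) / theoretical * 1e6 <= 20.0

    def test_monotone_in_tolerance(self, sodium):
        wide = {format_formula(c.formula) for c in search_formulas(543.3656, sodium, 20.0)}
        narrow = {format_formula(c.formula) for c in search_formulas(543.3656, sodium, 5.0)}
        assert narrow <= wide

    def test_integer_dbe_filter(self, sodium):
        candidates = search_formulas(
            543.3656, sodium, 20.0, require_integer_dbe=True
        )
        assert all(c.dbe >= 0 and c.dbe == int(c.dbe) for c in candidates)

    def test_sorted_by_abs_ppm(self, sodium):
        errors = [abs(c.ppm_error) for c in search_formulas(543.3656, sodium, 20.0)]
        assert errors == sorted(errors)


def oracle_acyl_search(mz, adduct, tol_ppm, constraints):
    """Independent brute force over the whole acyl constraint box."""
    hits = set()
    lc, ld = constraints.long_carbons, constraints.long_db
    sc, sd = constraints.short_carbons, constraints.short_db
    for nl in range(lc[0], lc[1] + 1):
        for dl in range(ld[0], min(ld[1], nl - 1) + 1):
            for n1 in range(sc[0], sc[1] + 1):
                for d1 in range(sd[0], min(sd[1], n1 - 1) + 1):
                    for n2 in range(sc[0], sc[1] + 1):
                        for d2 in range(sd[0], min(sd[1], n2 - 1) + 1):
                            acyls = tuple(
                                sorted(
                                    [(nl, dl), (n1, d1), (n2, d2)], reverse=True
                                )
                            )
                            theoretical = ion_mz(
                                tag_formula(tuple(FattyAcyl(*a) for a in acyls)),
                                adduct,
                            )
                            if abs(mz - theoretical) / theoretical * 1e6 <= tol_ppm:
                                hits.add(acyls)
    return hits


class TestEnumerateAcylCompositions:
    def test_sodiated_543_contains_oleic_ditiglate(self, sodium):
        hits = {
            tuple(a.key for a in c.acyls)
            for c in enumerate_acyl_compositions(543.37, sodium, 20.0)
        }
        assert ((18, 1), (5, 1), (5, 1)) in hits

    def test_potassiated_561_contains_stearic(self, potassium):
        hits = {
            tuple(a.key for a in c.acyls)
            for c in enumerate_acyl_compositions(561.36, potassium, 20.0)
        }
        assert ((18, 0), (5, 1), (5, 1)) in hits

    def test_triacetin_only_hit_in_widened_box(self, sodium):
        precursor = ion_mz(tag_formula(tuple(FattyAcyl(2, 0) for _ in range(3))), sodium)
        widened = CompositionConstraints(
            long_carbons=(2, 18), long_db=(0, 2), short_carbons=(2, 18), short_db=(0, 1)
        )
        hits = enumerate_acyl_compositions(precursor, sodium, 20.0, widened)
        assert [tuple(a.key for a in c.acyls) for c in hits] == [
            ((2, 0), (2, 0), (2, 0))
        ]

    def test_set_equality_with_oracle_on_random_precursors(self, sodium):
        rng = np.random.default_rng(7)
        constraints = CompositionConstraints()
        for _ in range(25):
            mz = float(rng.uniform(350.0, 600.0))
            ours = {
                tuple(a.key for a in c.acyls)
                for c in enumerate_acyl_compositions(mz, sodium, 20.0, constraints)
            }
            assert ours == oracle_acyl_search(mz, sodium, 20.0, constraints)

    def test_soundness(self, sodium):
        for c in enumerate_acyl_compositions(543.37, sodium, 20.0):
            recomputed = ion_mz(tag_formula(c.acyls), sodium)
            assert abs(543.37 - recomputed) / recomputed * 1e6 <= 20.0

    def test_monotone_in_tolerance(self, sodium):
        wide = {str(c) for c in enumerate_acyl_compositions(543.37, sodium, 30.0)}
        narrow = {str(c) for c in enumerate_acyl_compositions(543.37, sodium, 10.0)}
        assert narrow <= wide

    def test_deterministic_ordering(self, sodium):
        first = [str(c) for c in enumerate_acyl_compositions(543.37, sodium, 20.0)]
        second = [str(c) for c in enumerate_acyl_compositions(543.37, sodium, 20.0)]
        assert first == second
        errors = [abs(c.ppm_error) for c in enumerate_acyl_compositions(543.37, sodium)]
        assert errors == sorted(errors)

    def test_branch_flag_is_unknown(self, sodium):
        assert all(
            c.branched == "unknown"
            for c in enumerate_acyl_compositions(543.37, sodium, 20.0)
        )

    def test_bad_constraints(self):
        with pytest.raises(ConfigError):
            CompositionConstraints(n_long=2)
        with pytest.raises(ConfigError):
            CompositionConstraints(long_carbons=(18, 16))
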