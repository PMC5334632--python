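import numpy as np
import pytest

from apascreen.formula import parse_formula
from apascreen.screening import (
    Annotation,
    EicTrace,
    PrecursorHit,
    ScreenParams,
    annotate_run,
    charge_from_isotopes,
    confirm_fragments,
    detect_eic_peaks,
    extract_eic,
    find_precursors,
    score_annotation,
)
from apascreen.simulate import (
    CohortSpec,
    MseRun,
    Spectrum,
    compound_rt,
    simulate_isotope_pattern,
    simulate_mse_run,
)

THP_MZ = 98.096974388
PYR_MZ = 106.0656742604


class TestEic:
    def test_diagnostic_trace_localized(self, lib, clean_spec):
        c = lib["Haliclamine C"]
        run = simulate_mse_run([(c, 1.0)], clean_spec, "t", seed=0)
        trace = extract_eic(run, 2, THP_MZ, 10)
        nz = trace.rt[trace.intensity > 0]
        assert nz.size > 0
        assert np.all(np.abs(nz - compound_rt(c.name)) < 0.3)
        # no pyridinium moiety present -> all-zero trace
        empty = extract_eic(run, 2, PYR_MZ, 10)
        assert not np.any(empty.intensity > 0)

    def test_wider_tolerance_is_pointwise_monotone(self, lib):
        spec = CohortSpec(seed=2, n_background_features=200, noise_peak_rate=20)
        run = simulate_mse_run([(lib.entries[0], 1.0)], spec, "t", seed=2)
        narrow = extract_eic(run, 1, 218.1909, 10)
        wide = extract_eic(run, 1, 218.1909, 20)
        assert np.all(wide.intensity >= narrow.intensity)

    def test_unknown_function_rejected(self, lib, clean_spec):
        run = simulate_mse_run([(lib.entries[0], 1.0)], clean_spec, "t", seed=0)
        with pytest.raises(ValueError):
            extract_eic(run, 3, 100.0, 10)


class TestPeakDetection:
    def test_single_compound_single_peak(self, lib, clean_spec):
        c = lib["Haliclamine D"]
        run = simulate_mse_run([(c, 1.0)], clean_spec, "t", seed=0)
        peaks = detect_eic_peaks(extract_eic(run, 2, THP_MZ, 10))
        assert len(peaks) == 1
        assert abs(peaks[0].rt_apex - compound_rt(c.name)) <= clean_spec.rt_grid_step

    def test_zero_trace_no_peaks(self):
        trace = EicTrace(100.0, 10, 2, np.linspace(0, 5, 50), np.zeros(50))
        assert detect_eic_peaks(trace) == []

    def test_two_separated_compounds_two_peaks(self, lib, clean_spec):
        pair = [lib["Haliclamine C"], lib["Haliclamine D"]]
        assert abs(compound_rt(pair[0].name) - compound_rt(pair[1].name)) > 1.0
        run = simulate_mse_run([(c, 1.0) for c in pair], clean_spec, "t", seed=0)
        peaks = detect_eic_peaks(extract_eic(run, 2, THP_MZ, 10))
        assert len(peaks) == 2


class TestChargeFromIsotopes:
    def _pattern_spectrum(self, formula, charge):
        pat = simulate_isotope_pattern(parse_formula(formula), charge, 3)
        return Spectrum(rt=1.0, function=1,
                        mz=np.array([p.mz for p in pat]),
                        intensity=np.array([p.intensity for p in pat]) * 1e5)

    def test_correct_charge_confirmed(self):
        s = self._pattern_spectrum("C30H48N2", 2)
        assert charge_from_isotopes(s, s.mz[0], 2, 10)

    def test_wrong_charge_rejected(self):
        s = self._pattern_spectrum("C30H48N2", 2)
        assert not charge_from_isotopes(s, s.mz[0], 1, 10)

    def test_lone_peak_rejected_for_all_charges(self):
        s = Spectrum(rt=1.0, function=1, mz=np.array([218.1909]),
                     intensity=np.array([1e5]))
        assert not any(charge_from_isotopes(s, 218.1909, z, 10) for z in (1, 2, 3))


class TestFindPrecursors:
    def test_jitter_free_hit_with_zero_ppm(self, lib, clean_spec):
        p = lib["Cyclostellettamine P"]
        run = simulate_mse_run([(p, 1.0)], clean_spec, "t", seed=0)
        rt = compound_rt(p.name)
        hits = find_precursors(run, (rt - 0.3, rt + 0.3), lib, 10)
        dication = [h for h in hits if h.ion_label == "[M]2+"
                    and h.compound.name == p.name]
        assert dication and abs(dication[0].ppm_error) < 1e-6
        assert dication[0].isotope_confirmed
        singly = [h for h in hits if h.ion_label == "[M+H]+"
                  and h.compound.name == p.name]
        assert singly and abs(singly[0].observed_mz - 437.3896) < 5e-5

    def test_displaced_peak_not_matched(self, lib):
        mz = 218.1909 * (1 + 20e-6)
        run = MseRun("t", [
            Spectrum(rt=1.0, function=1, mz=np.array([mz]), intensity=np.array([1e5])),
            Spectrum(rt=1.0, function=2, mz=np.array([]), intensity=np.array([])),
        ])
        assert find_precursors(run, (0.5, 1.5), lib, 10) == []


class TestConfirmFragments:
    def test_haliclamine_d_fragments(self, lib, clean_spec):
        d = lib["Haliclamine D"]
        run = simulate_mse_run([(d, 1.0)], clean_spec, "t", seed=0)
        rt = compound_rt(d.name)
        matched = {f.formula.serialize() for f in
                   confirm_fragments(run, (rt - 0.3, rt + 0.3), d)}
        assert {"C15H28N", "C16H30N"} <= matched

    def test_absent_compound_empty(self, lib, clean_spec):
        d = lib["Haliclamine D"]
        run = simulate_mse_run([(lib["Cyclostellettamine P"], 1.0)], clean_spec, "t", seed=0)
        rt = compound_rt(d.name)
        assert confirm_fragments(run, (rt - 0.3, rt + 0.3), d) == []

    def test_cyclostellettamine_p_diagnostic_and_oniums(self, lib, clean_spec):
        p = lib["Cyclostellettamine P"]
        run = simulate_mse_run([(p, 1.0)], clean_spec, "t", seed=0)
        rt = compound_rt(p.name)
        matched = confirm_fragments(run, (rt - 0.3, rt + 0.3), p)
        mzs = sorted(round(f.mz, 4) for f in matched)
        assert mzs == [106.0657, 204.1752, 232.2065]


def _brute_force_compounds(run, library, ppm_tol=10.0, rt_window=0.3):
    """Independent oracle: test every (function-1 peak, library ion) pair,
    then require the compound's diagnostic and one F fragment in function 2
    near the matching peak's retention time."""
    found = set()
    fn2 = run.function_spectra(2)

    def fn2_has(mz, rt):
        for s in fn2:
            if abs(s.rt - rt) <= rt_window and len(s):
                if np.any(np.abs(s.mz - mz) / mz * 1e6 <= ppm_tol):
                    return True
        return False

    for s in run.function_spectra(1):
        for mz in s.mz:
            for hit in library.lookup(float(mz), ppm_tol):
                comp = hit.compound
                if not any(fn2_has(d.mz, s.rt) for d in comp.diagnostics):
                    continue
                if not any(fn2_has(f.mz, s.rt) for f in comp.fragment_ions):
                    continue
                found.add(comp.name)
    return found


class TestAnnotateRun:
    def test_thirteen_compounds_recovered_default_noise(self, lib):
        spec = CohortSpec(seed=11)
        run = simulate_mse_run([(c, 1.0) for c in lib.entries], spec, "S1", seed=11)
        names = {a.compound.name for a in annotate_run(run, lib)}
        assert len(names) == 13

    def test_background_only_run_clean(self, lib):
        spec = CohortSpec(seed=11)
        run = simulate_mse_run([], spec, "BG", seed=12)
        assert annotate_run(run, lib) == []

    def test_haliclamines_reached_via_thp_trace(self, lib, clean_spec):
        haliclamines = [c for c in lib.entries if c.apa_class == "haliclamine"]
        run = simulate_mse_run([(c, 1.0) for c in haliclamines], clean_spec, "t", seed=0)
        anns = annotate_run(run, lib)
        by_name = {a.compound.name: a for a in anns}
        assert set(by_name) == {c.name for c in haliclamines}
        for name, ann in by_name.items():
            moieties = {d.parent_moiety for d in ann.diagnostic_matches}
            if name == "Haliclamine A":
                assert "Pyr" in moieties  # the one haliclamine with Pyr-type fragments
            else:
                assert moieties == {"THP"}

    def test_brute_force_oracle_equivalence(self, lib, clean_spec):
        compounds = [lib["Cyclostellettamine P"], lib["Haliclamine C"]]
        run = simulate_mse_run([(c, 1.0) for c in compounds], clean_spec, "t", seed=0)
        n_peaks = sum(len(s) for s in run.spectra)
        assert n_peaks <= 200
        expected = _brute_force_compounds(run, lib)
        got = {a.compound.name for a in annotate_run(run, lib)}
        assert got == expected == {c.name for c in compounds}

    def test_ppm_tolerance_monotonicity(self, lib):
        spec = CohortSpec(seed=5, mz_jitter_ppm_sd=6.0)
        run = simulate_mse_run([(c, 1.0) for c in lib.entries], spec, "S1", seed=5)
        sets = []
        for tol in (3.0, 10.0, 20.0):
            params = ScreenParams(ppm_tol=tol, eic_ppm_tol=tol)
            sets.append({a.compound.name for a in annotate_run(run, lib, params)})
        assert sets[0] <= sets[1] <= sets[2]

    def test_jitter_free_ppm_error_zero(self, lib, clean_spec):
        run = simulate_mse_run([(lib.entries[0], 1.0)], clean_spec, "t", seed=0)
        anns = annotate_run(run, lib)
        assert anns and abs(anns[0].best_hit.ppm_error) < 1e-6


class TestScoring:
    def _annotation(self, lib, ppm_error, n_diag, n_frag, iso):
        comp = lib["Cyclostellettamine P"]  # 2 predicted F fragments
        hit = PrecursorHit(comp, "[M]2+", 2, 218.1909, ppm_error, iso)
        return Annotation(
            compound=comp, rt=5.0, precursor_hits=[hit],
            diagnostic_matches=comp.diagnostics[:n_diag],
            fragment_matches=comp.fragment_ions[:n_frag],
        )

    def test_perfect_match_scores_four(self, lib):
        a = self._annotation(lib, 0.0, 1, 2, True)
        assert score_annotation(a) == pytest.approx(4.0)

    def test_worst_case_scores_zero(self, lib):
        a = self._annotation(lib, 10.0, 0, 0, False)
        assert score_annotation(a, ppm_tol=10.0) == pytest.approx(0.0)

    def test_mixed_case(self, lib):
        a = self._annotation(lib, 5.0, 1, 2, True)
        assert score_annotation(a, ppm_tol=10.0) == pytest.approx(3.5)

    def test_negative_weights_rejected(self, lib):
        a = self._annotation(lib, 0.0, 1, 2, True)
        with pytest.raises(ValueError):
            score_annotation(a, weights=(-1, 1, 1, 1))
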