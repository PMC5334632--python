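"""MS^E screening for 3-APA compounds.

The screening logic mirrors how a data-independent (two-function)
acquisition is mined for this alkaloid class:

1. extract ion chromatograms (EICs) of the two moiety diagnostic
   fragments (m/z 98.0970 for tetrahydropyridine, 106.0657 for
   pyridinium) from the high-energy function;
2. detect EIC peaks; each peak defines a retention-time window where a
   3-APA is eluting;
3. within each window, match low-energy (function 1) peaks against the
   compound library by exact mass at a ppm tolerance, verifying the
   claimed charge state from the carbon isotope spacing;
4. confirm the class-specific F1/F2 onium fragments (and diagnostics)
   in the high-energy function;
5. score and report annotations.

By default an annotation is accepted only when it has a precursor hit,
at least one diagnostic match and at least one F1/F2 fragment match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .library import ApaCompound, FragmentIon, MassLibrary, diagnostic_fragments
from .peakutil import local_maxima, nearest_minima_bounds
from .simulate import ISOTOPE_SPACING, MseRun, Spectrum

__all__ = [
    "EicTrace",
    "EicPeak",
    "PrecursorHit",
    "Annotation",
    "ScreenParams",
    "extract_eic",
    "detect_eic_peaks",
    "charge_from_isotopes",
    "find_precursors",
    "confirm_fragments",
    "annotate_run",
    "score_annotation",
]


@dataclass
class EicTrace:
    target_mz: float
    ppm_tol: float
    function: int
    rt: np.ndarray
    intensity: np.ndarray

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.rt, self.intensity))


@dataclass(frozen=True)
class EicPeak:
    rt_apex: float
    intensity_apex: float
    rt_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.rt_bounds
        if not (lo <= self.rt_apex <= hi):
            raise ValueError("bounds must contain the apex")


@dataclass(frozen=True)
class PrecursorHit:
    compound: ApaCompound
    ion_label: str
    charge: int
    observed_mz: float
    ppm_error: float
    isotope_confirmed: bool
    intensity: float = 0.0


@dataclass
class Annotation:
    compound: ApaCompound
    rt: float
    precursor_hits: list[PrecursorHit]
    diagnostic_matches: list[FragmentIon]
    fragment_matches: list[FragmentIon]
    score: float = 0.0

    @property
    def best_hit(self) -> PrecursorHit:
        return min(self.precursor_hits, key=lambda h: abs(h.ppm_error))


@dataclass(frozen=True)
class ScreenParams:
    """Tunable screening thresholds (defaults follow the 10 ppm regime)."""

    ppm_tol: float = 10.0
    eic_ppm_tol: float = 10.0
    min_eic_intensity: float = 0.0
    min_prominence_fraction: float = 0.25
    isotope_ratio_bounds: tuple[float, float] = (0.1, 0.9)
    require_diagnostic: bool = True
    require_fragment: bool = True
    score_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)


def extract_eic(run: MseRun, function: int, target_mz: float, ppm_tol: float) -> EicTrace:
    """Summed intensity of peaks within ``ppm_tol`` of ``target_mz`` per scan."""
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be > 0")
    spectra = run.function_spectra(function)
    if not spectra:
        raise ValueError(f"run has no spectra for function {function}")
    spectra = sorted(spectra, key=lambda s: s.rt)
    half = target_mz * ppm_tol * 1e-6
    rt = np.array([s.rt for s in spectra])
    inten = np.zeros(rt.size)
    for i, s in enumerate(spectra):
        if len(s) == 0:
            continue
        lo = np.searchsorted(s.mz, target_mz - half, side="left")
        hi = np.searchsorted(s.mz, target_mz + half, side="right")
        if hi > lo:
            inten[i] = s.intensity[lo:hi].sum()
    return EicTrace(target_mz=target_mz, ppm_tol=ppm_tol, function=function,
                    rt=rt, intensity=inten)


def detect_eic_peaks(
    trace: EicTrace,
    min_intensity: float = 0.0,
    min_prominence_fraction: float = 0.25,
) -> list[EicPeak]:
    """Local maxima above ``min_intensity`` with prominence at least
    ``min_prominence_fraction`` x apex; bounds at the nearest minima."""
    if min_intensity < 0 or min_prominence_fraction < 0:
        raise ValueError("thresholds must be >= 0")
    y = trace.intensity
    if y.size == 0 or not np.any(y > 0):
        return []
    peaks = []
    for i in local_maxima(y, min_intensity):
        apex = y[i]
        lo, hi = nearest_minima_bounds(y, i)
        prominence = apex - max(y[lo], y[hi])
        if prominence < min_prominence_fraction * apex:
            continue
        peaks.append(EicPeak(
            rt_apex=float(trace.rt[i]),
            intensity_apex=float(apex),
            rt_bounds=(float(trace.rt[lo]), float(trace.rt[hi])),
        ))
    return peaks


def charge_from_isotopes(
    spectrum: Spectrum,
    mz: float,
    claimed_charge: int,
    ppm_tol: float,
    ratio_bounds: tuple[float, float] = (0.1, 0.9),
) -> bool:
    """Verify a charge state from the carbon isotope spacing.

    True iff a peak exists at ``mz + 1.003355/claimed_charge`` within
    tolerance whose intensity relative to the monoisotopic peak lies
    inside ``ratio_bounds``.
    """
    if claimed_charge not in (1, 2, 3):
        raise ValueError("claimed_charge must be 1, 2 or 3")
    if len(spectrum) == 0:
        return False
    half = mz * ppm_tol * 1e-6
    lo = np.searchsorted(spectrum.mz, mz - half, side="left")
    hi = np.searchsorted(spectrum.mz, mz + half, side="right")
    if hi <= lo:
        return False
    mono = spectrum.intensity[lo:hi].max()
    if mono <= 0:
        return False
    target = mz + ISOTOPE_SPACING / claimed_charge
    half = target * ppm_tol * 1e-6
    lo = np.searchsorted(spectrum.mz, target - half, side="left")
    hi = np.searchsorted(spectrum.mz, target + half, side="right")
    if hi <= lo:
        return False
    iso = spectrum.intensity[lo:hi].max()
    ratio = iso / mono
    return ratio_bounds[0] <= ratio <= ratio_bounds[1]


def find_precursors(
    run: MseRun,
    rt_window: tuple[float, float],
    library: MassLibrary,
    ppm_tol: float,
    isotope_ratio_bounds: tuple[float, float] = (0.1, 0.9),
) -> list[PrecursorHit]:
    """Match function-1 peaks inside the rt window against library ions.

    Every (peak, library ion) pair within ``ppm_tol`` yields a hit with
    its signed ppm error and isotope-based charge confirmation; hits
    are sorted by |ppm error|.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be > 0")
    lo, hi = rt_window
    hits: dict[tuple[str, str], PrecursorHit] = {}
    for s in run.function_spectra(1):
        if not (lo <= s.rt <= hi) or len(s) == 0:
            continue
        for mz, inten in zip(s.mz, s.intensity):
            for lib_hit in library.lookup(float(mz), ppm_tol):
                confirmed = charge_from_isotopes(
                    s, float(mz), lib_hit.charge, ppm_tol, isotope_ratio_bounds
                )
                key = (lib_hit.compound.name, lib_hit.ion_label)
                prev = hits.get(key)
                hit = PrecursorHit(
                    compound=lib_hit.compound, ion_label=lib_hit.ion_label,
                    charge=lib_hit.charge, observed_mz=float(mz),
                    ppm_error=lib_hit.ppm_error, isotope_confirmed=confirmed,
                    intensity=float(inten),
                )
                if prev is None or inten > prev.intensity:
                    hits[key] = hit
    return sorted(hits.values(), key=lambda h: abs(h.ppm_error))


def confirm_fragments(
    run: MseRun,
    rt_window: tuple[float, float],
    compound: ApaCompound,
    ppm_tol: float = 10.0,
) -> list[FragmentIon]:
    """Predicted fragments of the compound found in function 2 within the window."""
    lo, hi = rt_window
    matched = []
    for frag in compound.predicted_fragments:
        half = frag.mz * ppm_tol * 1e-6
        found = False
        for s in run.function_spectra(2):
            if not (lo <= s.rt <= hi) or len(s) == 0:
                continue
            a = np.searchsorted(s.mz, frag.mz - half, side="left")
            b = np.searchsorted(s.mz, frag.mz + half, side="right")
            if b > a:
                found = True
                break
        if found:
            matched.append(frag)
    return matched


def score_annotation(a: Annotation, weights: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
                     ppm_tol: float = 10.0) -> float:
    """Composite evidence score.

    score = w_ppm*(1 - |ppm|/tol) + w_diag*(# diagnostics matched)
          + w_frag*(# F fragments matched / # predicted) + w_iso*(isotope ok)
    """
    w_ppm, w_diag, w_frag, w_iso = weights
    if any(w < 0 for w in weights):
        raise ValueError("weights must be >= 0")
    best = a.best_hit
    n_pred = len(a.compound.fragment_ions)
    frag_term = (len(a.fragment_matches) / n_pred) if n_pred else 0.0
    return (
        w_ppm * max(0.0, 1.0 - abs(best.ppm_error) / ppm_tol)
        + w_diag * len(a.diagnostic_matches)
        + w_frag * frag_term
        + w_iso * (1.0 if best.isotope_confirmed else 0.0)
    )


def annotate_run(
    run: MseRun,
    library: MassLibrary,
    params: ScreenParams = ScreenParams(),
) -> list[Annotation]:
    """Full screening pipeline on one run; see module docstring.

    Returns one annotation per (compound, diagnostic EIC peak) passing
    the acceptance rule, ranked by score then |ppm error|.  When two
    library entries match the same peak, both are kept.
    """
    annotations: dict[tuple[str, float], Annotation] = {}
    for diag in diagnostic_fragments():
        trace = extract_eic(run, 2, diag.mz, params.eic_ppm_tol)
        for peak in detect_eic_peaks(trace, params.min_eic_intensity,
                                     params.min_prominence_fraction):
            window = peak.rt_bounds
            hits = find_precursors(run, window, library, params.ppm_tol,
                                   params.isotope_ratio_bounds)
            by_compound: dict[str, list[PrecursorHit]] = {}
            for h in hits:
                by_compound.setdefault(h.compound.name, []).append(h)
            for name, comp_hits in by_compound.items():
                compound = comp_hits[0].compound
                matched = confirm_fragments(run, window, compound, params.ppm_tol)
                diag_matched = [f for f in matched if f.role == "diagnostic"]
                frag_matched = [f for f in matched if f.role in ("F1", "F2")]
                if params.require_diagnostic and not diag_matched:
                    continue
                if params.require_fragment and not frag_matched:
                    continue
                ann = Annotation(
                    compound=compound, rt=peak.rt_apex,
                    precursor_hits=comp_hits,
                    diagnostic_matches=diag_matched,
                    fragment_matches=frag_matched,
                )
                ann.score = score_annotation(ann, params.score_weights, params.ppm_tol)
                key = (name, round(peak.rt_apex, 3))
                prev = annotations.get(key)
                if prev is None or ann.score > prev.score:
                    annotations[key] = ann
    out = list(annotations.values())
    out.sort(key=lambda a: (-a.score, abs(a.best_hit.ppm_error), a.compound.name))
    return out
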