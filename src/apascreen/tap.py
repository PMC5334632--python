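"""Drift-time resolution of coeluting isobars (pseudo-MS3).

In time-aligned-parallel (TAP) fragmentation, precursor fragments are
separated in an ion-mobility cell and fragmented again afterwards, so
each secondary spectrum is keyed by the drift time of its primary
fragment.  Two isobaric primary ions that differ in conformation (for
a cyclic bis-pyridinium: a ring-opened versus a compact macrocycle)
separate in drift time, and each drift population can be assigned its
own fragmentation spectrum.

Classification of a drift population at precursor m/z x (charge 2):

* ``ring-opened`` if its pseudo-MS3 spectrum contains the macrocycle
  ring-opening fragment at 2x + m(H) - m(C2H6N), i.e. the singly
  charged molecular ion minus the C2H6N neutral (44.0500 Da);
* ``compact/onium`` if it contains both predicted onium fragments of
  the best library match at that m/z;
* ``unclassified`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formula import ATOMIC_MASSES, monoisotopic_mass, parse_formula
from .library import MassLibrary, curated_library
from .peakutil import local_maxima, nearest_minima_bounds
from .simulate import Spectrum, TapRun

__all__ = [
    "DriftPeak",
    "PseudoMs3Spectrum",
    "TapParams",
    "driftogram",
    "detect_drift_peaks",
    "associate_secondary",
    "resolve_isobars",
    "RING_OPENING_LOSS",
]

#: Neutral loss opening the macrocycle, Da (C2H6N).
RING_OPENING_LOSS = monoisotopic_mass(parse_formula("C2H6N"))


@dataclass(frozen=True)
class DriftPeak:
    mz: float
    drift_time_apex: float
    drift_bounds: tuple[float, float]
    intensity: float

    def __post_init__(self) -> None:
        lo, hi = self.drift_bounds
        if not (lo <= self.drift_time_apex <= hi):
            raise ValueError("bounds must contain the apex")
        if self.drift_time_apex < 0:
            raise ValueError("drift time must be >= 0")


@dataclass
class PseudoMs3Spectrum:
    parent: DriftPeak
    peaks: Spectrum  # secondary fragments, sorted by m/z

    def contains(self, mz: float, tol_da: float, min_relative: float = 0.0) -> bool:
        """True if a peak lies within ``tol_da`` of ``mz`` and reaches
        ``min_relative`` x the spectrum base peak (guards against drift
        cross-talk from neighboring populations)."""
        if len(self.peaks) == 0:
            return False
        lo = np.searchsorted(self.peaks.mz, mz - tol_da, side="left")
        hi = np.searchsorted(self.peaks.mz, mz + tol_da, side="right")
        if hi <= lo:
            return False
        return self.peaks.intensity[lo:hi].max() >= min_relative * self.peaks.intensity.max()


@dataclass(frozen=True)
class TapParams:
    mz_tol_da: float = 0.05
    min_intensity: float = 0.0
    min_separation_ms: float = 0.5
    classify_tol_da: float = 0.05
    min_signature_relative: float = 0.05
    merge_width_da: float = 0.01
    library_ppm_tol: float = 50.0


def driftogram(tap: TapRun, mz: float, mz_tol_da: float) -> list[tuple[float, float]]:
    """Intensity versus drift time of primary peaks within the m/z window."""
    if mz_tol_da <= 0:
        raise ValueError("mz_tol_da must be > 0")
    acc: dict[float, float] = {}
    for pmz, drift, inten in tap.primary_peaks:
        if abs(pmz - mz) <= mz_tol_da:
            acc[drift] = acc.get(drift, 0.0) + inten
    drifts = sorted({d for _, d, _ in tap.primary_peaks})
    return [(d, acc.get(d, 0.0)) for d in drifts]


def detect_drift_peaks(
    trace: list[tuple[float, float]],
    min_intensity: float = 0.0,
    min_separation_ms: float = 0.5,
    mz: float = 0.0,
) -> list[DriftPeak]:
    """Local maxima above threshold, at least ``min_separation_ms`` apart.

    When two maxima are closer than the separation, the higher apex is
    kept.  Bounds are placed at the nearest flanking minima.
    """
    if min_intensity < 0 or min_separation_ms < 0:
        raise ValueError("thresholds must be >= 0")
    if not trace:
        return []
    drift = np.array([d for d, _ in trace])
    y = np.array([v for _, v in trace])
    if not np.any(y > 0):
        return []
    candidates = []
    for i in local_maxima(y, min_intensity):
        lo, hi = nearest_minima_bounds(y, i)
        candidates.append(DriftPeak(
            mz=mz, drift_time_apex=float(drift[i]),
            drift_bounds=(float(drift[lo]), float(drift[hi])),
            intensity=float(y[i]),
        ))
    # suppress peaks closer than min_separation to a stronger one
    candidates.sort(key=lambda p: -p.intensity)
    kept: list[DriftPeak] = []
    for cand in candidates:
        if all(abs(cand.drift_time_apex - k.drift_time_apex) >= min_separation_ms
               for k in kept):
            kept.append(cand)
    kept.sort(key=lambda p: p.drift_time_apex)
    return kept


def associate_secondary(
    tap: TapRun, parent: DriftPeak, merge_width_da: float = 0.01
) -> PseudoMs3Spectrum:
    """Union of secondary spectra whose drift bins fall inside the
    parent's drift bounds, intensity-merged per m/z."""
    lo, hi = parent.drift_bounds
    mzs: list[np.ndarray] = []
    intens: list[np.ndarray] = []
    for drift_bin, spec in tap.secondary_spectra:
        if lo <= drift_bin <= hi and len(spec) > 0:
            mzs.append(spec.mz)
            intens.append(spec.intensity)
    if not mzs:
        empty = Spectrum(rt=0.0, function=2, mz=np.array([]), intensity=np.array([]))
        return PseudoMs3Spectrum(parent=parent, peaks=empty)
    mz = np.concatenate(mzs)
    inten = np.concatenate(intens)
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    # merge centroids within the merge width
    merged_mz, merged_int = [], []
    for m, v in zip(mz, inten):
        if merged_mz and m - merged_mz[-1] <= merge_width_da:
            w = merged_int[-1] + v
            merged_mz[-1] = (merged_mz[-1] * merged_int[-1] + m * v) / w
            merged_int[-1] = w
        else:
            merged_mz.append(float(m))
            merged_int.append(float(v))
    peaks = Spectrum(rt=0.0, function=2, mz=np.array(merged_mz),
                     intensity=np.array(merged_int))
    return PseudoMs3Spectrum(parent=parent, peaks=peaks)


def _ring_opening_target(mz: float) -> float:
    return 2.0 * mz + ATOMIC_MASSES["H"] - RING_OPENING_LOSS


def resolve_isobars(
    tap: TapRun,
    mz: float,
    mz_tol_da: float = 0.05,
    params: TapParams = TapParams(),
    library: MassLibrary | None = None,
) -> list[tuple[DriftPeak, PseudoMs3Spectrum, str]]:
    """Resolve coeluting isobars at an m/z by drift time and classify each.

    Pipeline: driftogram -> drift peaks -> per-peak pseudo-MS3 ->
    classification (``ring-opened`` / ``compact/onium`` /
    ``unclassified``, see module docstring).
    """
    library = library if library is not None else curated_library()
    trace = driftogram(tap, mz, mz_tol_da)
    peaks = detect_drift_peaks(trace, params.min_intensity, params.min_separation_ms, mz=mz)
    onium_targets: list[float] = []
    for hit in library.lookup(mz, params.library_ppm_tol):
        frags = hit.compound.fragment_ions
        if frags:
            onium_targets = [f.mz for f in frags]
            break
    ring_target = _ring_opening_target(mz)
    out = []
    for peak in peaks:
        ms3 = associate_secondary(tap, peak, params.merge_width_da)
        if ms3.contains(ring_target, params.classify_tol_da,
                        params.min_signature_relative):
            label = "ring-opened"
        elif onium_targets and all(
            ms3.contains(t, params.classify_tol_da, params.min_signature_relative)
            for t in onium_targets
        ):
            label = "compact/onium"
        else:
            label = "unclassified"
        out.append((peak, ms3, label))
    return out
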