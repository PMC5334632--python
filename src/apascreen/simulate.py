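"""Synthetic MS^E cohorts, TAP drift datasets and feature tables.

The generator emulates the statistical structure the screening and
prioritization stages assume: a cohort of (by default) 28 sponge
extracts of which three carry the thirteen curated 3-APA compounds;
two-function MS^E runs on a shared retention-time grid (function 1 =
low collision energy, intact multiply charged precursors with carbon
isotope patterns; function 2 = high collision energy, moiety
diagnostic fragments plus the class F1/F2 onium fragments); shared
log-normal background features with per-sample multiplicative noise;
Gaussian ppm mass jitter; sporadic shot-noise peaks; an MTS viability
table in which the alkaloid-bearing extracts are cytotoxic; and a
time-aligned-parallel (TAP) dataset containing two coeluting isobars
at m/z 218.19 with distinct ion-mobility drift times.

Every ``simulate_*`` function is a pure function of its spec and seed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .formula import ElementalFormula
from .library import ApaCompound, curated_library

__all__ = [
    "CentroidPeak",
    "Spectrum",
    "MseRun",
    "TapRun",
    "CohortSpec",
    "BioactivityRecord",
    "FeatureTable",
    "ISOTOPE_SPACING",
    "C13_ABUNDANCE",
    "simulate_isotope_pattern",
    "simulate_mse_run",
    "simulate_cohort",
    "simulate_tap_isobars",
    "build_feature_table",
    "compound_rt",
]

#: Mass difference between successive carbon isotopologues, Da.
ISOTOPE_SPACING = 1.003355
#: Natural abundance of 13C (per-carbon heavy-isotope probability).
C13_ABUNDANCE = 0.0107


class CentroidPeak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """A centroided scan: peaks sorted strictly ascending in m/z."""

    rt: float
    function: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.function not in (1, 2):
            raise ValueError(f"function must be 1 or 2, got {self.function}")
        if self.rt < 0:
            raise ValueError("rt must be >= 0")
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size:
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            # merge coincident centroids so ordering is strictly ascending
            if np.any(np.diff(self.mz) <= 0):
                uniq, inverse = np.unique(self.mz, return_inverse=True)
                summed = np.zeros_like(uniq)
                np.add.at(summed, inverse, self.intensity)
                self.mz, self.intensity = uniq, summed
            if np.any(self.mz <= 0) or np.any(self.intensity < 0):
                raise ValueError("mz must be > 0 and intensities >= 0")

    @property
    def peaks(self) -> list[CentroidPeak]:
        return [CentroidPeak(m, i) for m, i in zip(self.mz, self.intensity)]

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class MseRun:
    """A retention-time-ordered pair of spectrum streams (functions 1 and 2)."""

    sample_id: str
    spectra: list[Spectrum]
    metadata: dict = field(default_factory=dict)

    def function_spectra(self, function: int) -> list[Spectrum]:
        if function not in (1, 2):
            raise ValueError(f"no such function: {function}")
        return [s for s in self.spectra if s.function == function]

    @property
    def rt_grid(self) -> np.ndarray:
        return np.array(sorted({s.rt for s in self.spectra}))


@dataclass
class TapRun:
    """Pseudo-MS3 dataset: drift-resolved primary fragments with
    drift-time-tagged secondary spectra."""

    precursor_mz: float
    primary_peaks: list[tuple[float, float, float]]  # (mz, drift ms, intensity)
    secondary_spectra: list[tuple[float, Spectrum]]  # (drift bin center, spectrum)

    def __post_init__(self) -> None:
        if any(d < 0 for _, d, _ in self.primary_peaks):
            raise ValueError("drift times must be >= 0")


@dataclass
class BioactivityRecord:
    sample_id: str
    viability_percent: float
    active: bool | None = None

    def __post_init__(self) -> None:
        if self.viability_percent < 0:
            raise ValueError(f"viability must be >= 0 for {self.sample_id}")


@dataclass
class FeatureTable:
    """features: (feature_id, mz, rt); matrix: samples x features."""

    features: pd.DataFrame
    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.features["feature_id"]) != list(self.matrix.columns):
            raise ValueError("matrix columns must match feature ids")
        if self.features["feature_id"].duplicated().any():
            raise ValueError("duplicate feature ids")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.index)


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the screening cohort: 28 extracts, three of them
    alkaloid-bearing, ~2100 shared background features, 3 ppm mass
    jitter, 21-minute runs over m/z 50-1200.
    """

    n_samples: int = 28
    apa_sample_ids: tuple[str, ...] = ("S1", "S5", "S8")
    abundance_profiles: dict | None = None  # sample -> {compound name: rel abundance}
    n_background_features: int = 2100
    background_lognormal_mu: float = 10.0
    background_lognormal_sigma: float = 1.0
    sample_noise_log10_sd: float = 0.15
    mz_jitter_ppm_sd: float = 3.0
    rt_jitter_sd: float = 0.05
    noise_peak_rate: float = 50.0
    seed: int = 0
    run_length_min: float = 21.0
    rt_grid_step: float = 0.05
    rt_peak_sigma: float = 0.06
    mass_range: tuple[float, float] = (50.0, 1200.0)
    apa_base_intensity: float = 1.0e6

    def __post_init__(self) -> None:
        for name in ("n_background_features", "mz_jitter_ppm_sd", "rt_jitter_sd",
                     "noise_peak_rate", "sample_noise_log10_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_isotope_pattern(
    ion_formula: ElementalFormula, charge: int, n_peaks: int = 3, base_mz: float | None = None
) -> list[CentroidPeak]:
    """Carbon isotopologue envelope of an ion, relative to the monoisotopic peak.

    Peaks sit at ``mz + k * 1.003355 / charge``; relative intensities
    follow a binomial model over the carbon count with per-carbon
    heavy-isotope probability 0.0107 (N/O heavy isotopes are ignored).
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    from .formula import ion_mz  # local import to avoid cycle at module load

    mz0 = ion_mz(ion_formula, charge) if base_mz is None else base_mz
    n_c = ion_formula["C"]
    p = C13_ABUNDANCE
    peaks = []
    for k in range(n_peaks):
        rel = math.comb(n_c, k) * (p / (1 - p)) ** k if k <= n_c else 0.0
        peaks.append(CentroidPeak(mz0 + k * ISOTOPE_SPACING / charge, rel))
    return peaks


def compound_rt(name: str, lo: float = 2.0, hi: float = 16.0) -> float:
    """Deterministic retention time from a hash of the compound name."""
    digest = hashlib.sha1(name.encode()).digest()
    frac = int.from_bytes(digest[:8], "big") / 2**64
    return lo + frac * (hi - lo)


# relative response of the 1st/2nd/3rd ion species of a compound
_ION_WEIGHTS = (1.0, 0.5, 0.3)
# function-2 responses relative to the compound's base intensity
_DIAGNOSTIC_WEIGHT = 0.8
_FRAGMENT_WEIGHT = 0.6
_ATTENUATED_PRECURSOR = 0.2


def _background_features(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared background feature definitions (mz, rt, base intensity).

    Drawn from the cohort seed only, so every sample sees the same
    features; per-sample variation is applied at run-simulation time.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 101]))
    n = spec.n_background_features
    mz = rng.uniform(*spec.mass_range, size=n)
    rt = rng.uniform(1.0, spec.run_length_min - 1.0, size=n)
    inten = rng.lognormal(spec.background_lognormal_mu, spec.background_lognormal_sigma, size=n)
    return mz, rt, inten


def _profile(rt0: float, spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Grid indices and Gaussian elution weights around rt0 (apex weight 1)."""
    step = spec.rt_grid_step
    n_grid = int(round(spec.run_length_min / step)) + 1
    sigma = spec.rt_peak_sigma
    lo = max(0, int(math.floor((rt0 - 2.5 * sigma) / step)))
    hi = min(n_grid - 1, int(math.ceil((rt0 + 2.5 * sigma) / step)))
    idx = np.arange(lo, hi + 1)
    t = idx * step
    w = np.exp(-0.5 * ((t - rt0) / sigma) ** 2)
    return idx, w


def _simulate_mse_run(
    compounds: Sequence[tuple[ApaCompound, float]],
    spec: CohortSpec,
    sample_id: str,
    seed: int,
) -> tuple[MseRun, list[dict]]:
    if any(a < 0 for _, a in compounds):
        raise ValueError("abundances must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 7]))
    step = spec.rt_grid_step
    n_grid = int(round(spec.run_length_min / step)) + 1
    buckets: dict[int, dict[int, list[tuple[float, float]]]] = {1: {}, 2: {}}

    def put(function: int, grid_idx: int, mz: float, intensity: float) -> None:
        if intensity <= 0:
            return
        buckets[function].setdefault(int(grid_idx), []).append((mz, intensity))

    def jitter(mz: float) -> float:
        if spec.mz_jitter_ppm_sd == 0:
            return mz
        return mz * (1.0 + rng.normal(0.0, spec.mz_jitter_ppm_sd) * 1e-6)

    truth: list[dict] = []

    # --- injected compounds -------------------------------------------------
    for compound, abundance in compounds:
        rt0 = compound_rt(compound.name)
        if spec.rt_jitter_sd > 0:
            rt0 = max(0.5, rt0 + rng.normal(0.0, spec.rt_jitter_sd))
        if abundance == 0:
            continue
        idx, w = _profile(rt0, spec)
        base = abundance * spec.apa_base_intensity
        # function 1: all ion species with isotope envelopes
        for rank, ion in enumerate(compound.ion_species):
            weight = _ION_WEIGHTS[min(rank, len(_ION_WEIGHTS) - 1)]
            mz_obs = jitter(ion.mz)
            pattern = simulate_isotope_pattern(ion.ion_formula, ion.charge, 3, base_mz=mz_obs)
            for g, pw in zip(idx, w):
                for pk in pattern:
                    put(1, g, pk.mz, base * weight * pk.intensity * pw)
            truth.append({
                "sample_id": sample_id, "compound": compound.name,
                "ion_label": ion.label, "charge": ion.charge, "function": 1,
                "mz_true": ion.mz, "mz_observed": mz_obs, "rt_true": rt0,
                "abundance": abundance,
            })
        # function 2: diagnostics + F1/F2 + attenuated precursor
        for frag in compound.predicted_fragments:
            weight = _DIAGNOSTIC_WEIGHT if frag.role == "diagnostic" else _FRAGMENT_WEIGHT
            mz_obs = jitter(frag.mz)
            for g, pw in zip(idx, w):
                put(2, g, mz_obs, base * weight * pw)
            truth.append({
                "sample_id": sample_id, "compound": compound.name,
                "ion_label": frag.role, "charge": frag.charge, "function": 2,
                "mz_true": frag.mz, "mz_observed": mz_obs, "rt_true": rt0,
                "abundance": abundance,
            })
        lead = compound.ion_species[0]
        mz_obs = jitter(lead.mz)
        for g, pw in zip(idx, w):
            put(2, g, mz_obs, base * _ATTENUATED_PRECURSOR * pw)

    # --- shared background features ----------------------------------------
    if spec.n_background_features > 0:
        bg_mz, bg_rt, bg_base = _background_features(spec)
        factors = np.power(10.0, rng.normal(0.0, spec.sample_noise_log10_sd, bg_mz.size))
        for mz0, rt0, inten in zip(bg_mz, bg_rt, bg_base * factors):
            idx, w = _profile(rt0, spec)
            mz_obs = jitter(mz0)
            for g, pw in zip(idx, w):
                put(1, g, mz_obs, inten * pw)

    # --- shot noise ---------------------------------------------------------
    if spec.noise_peak_rate > 0:
        for function in (1, 2):
            n_noise = rng.poisson(spec.noise_peak_rate)
            mzs = rng.uniform(*spec.mass_range, size=n_noise)
            gs = rng.integers(0, n_grid, size=n_noise)
            intens = rng.exponential(5.0e3, size=n_noise)
            for mz0, g, inten in zip(mzs, gs, intens):
                put(function, int(g), mz0, inten)

    spectra = []
    for function in (1, 2):
        for g in range(n_grid):
            entries = buckets[function].get(g, [])
            mz = np.array([m for m, _ in entries])
            inten = np.array([i for _, i in entries])
            spectra.append(Spectrum(rt=g * step, function=function, mz=mz, intensity=inten))
    run = MseRun(
        sample_id=sample_id,
        spectra=spectra,
        metadata={
            "run_length_min": spec.run_length_min,
            "mass_range": list(spec.mass_range),
            "rt_grid_step": spec.rt_grid_step,
            "seed": int(seed),
        },
    )
    return run, truth


def simulate_mse_run(
    compounds: Sequence[tuple[ApaCompound, float]],
    spec: CohortSpec,
    sample_id: str = "S1",
    seed: int = 0,
) -> MseRun:
    """Simulate one two-function MS^E run (see module docstring)."""
    run, _ = _simulate_mse_run(compounds, spec, sample_id, seed)
    return run


# Fig.-7-style default abundance profiles for the three alkaloid carriers:
# carrier 1 and 2 share a profile, with carrier 1 richer in
# cyclostellettamine Q and the haliclamines; carrier 3 is divergent,
# richer in most compounds except the five listed.
_HALICLAMINES = ("Haliclamine A", "Haliclamine C", "Haliclamine D",
                 "Haliclamine E", "Haliclamine H")
_S8_DEPLETED = ("Cyclostellettamine N", "Cyclostellettamine P", "Haliclamine E",
                "Viscosaline B2", "Viscosamine C")


def _default_profiles(apa_ids: Sequence[str], names: Sequence[str]) -> dict:
    profiles: dict[str, dict[str, float]] = {}
    styles = ["s1", "s5", "s8"]
    for i, sid in enumerate(apa_ids):
        style = styles[i % 3]
        prof = {}
        for name in names:
            if style == "s1":
                val = 1.0
                if name == "Cyclostellettamine Q":
                    val = 2.2
                elif name == "Cyclostellettamine P":
                    val = 1.6
                elif name in _HALICLAMINES:
                    val = 1.8
            elif style == "s5":
                val = 1.0
            else:  # s8: divergent profile
                val = 0.25 if name in _S8_DEPLETED else 2.0
            prof[name] = val
        profiles[sid] = prof
    return profiles


# Reference viability anchors (% of solvent control) used to seed the
# synthetic MTS table: three alkaloid carriers, five other cytotoxic
# extracts, remainder inactive.
_APA_VIABILITY_ANCHORS = (8.0, 31.0, 22.0)
_OTHER_ACTIVE_ANCHORS = (29.0, 51.0, 18.0, 31.0, 13.0)


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[MseRun], list[BioactivityRecord], pd.DataFrame]:
    """Simulate a cohort of MS^E runs with bioactivity and ground truth.

    Alkaloid-bearing samples receive the thirteen curated compounds
    scaled by their abundance profiles; all other samples receive
    background only.  The ground-truth table lists every injected ion
    (true and observed m/z, retention time, abundance).
    """
    sample_ids = [f"S{i + 1}" for i in range(spec.n_samples)]
    missing = [s for s in spec.apa_sample_ids if s not in sample_ids]
    if missing:
        raise ValueError(f"apa_sample_ids not in cohort: {missing}")
    library = curated_library()
    names = [c.name for c in library.entries]
    profiles = spec.abundance_profiles or _default_profiles(spec.apa_sample_ids, names)

    ss = np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 11])
    run_seeds = ss.generate_state(spec.n_samples)
    via_rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 202]))

    runs: list[MseRun] = []
    truth_rows: list[dict] = []
    for sid, rseed in zip(sample_ids, run_seeds):
        if sid in spec.apa_sample_ids:
            prof = profiles.get(sid, {})
            compounds = [(c, float(prof.get(c.name, 1.0))) for c in library.entries]
        else:
            compounds = []
        run, truth = _simulate_mse_run(compounds, spec, sid, int(rseed) & 0x7FFFFFFF)
        runs.append(run)
        truth_rows.extend(truth)

    records: list[BioactivityRecord] = []
    other_active = [s for s in sample_ids if s not in spec.apa_sample_ids][:5]
    apa_rank = {sid: i for i, sid in enumerate(spec.apa_sample_ids)}
    for sid in sample_ids:
        if sid in apa_rank:
            anchor = _APA_VIABILITY_ANCHORS[apa_rank[sid] % 3]
            value = float(np.clip(via_rng.normal(anchor, 3.0), 1.0, 49.0))
        elif sid in other_active:
            anchor = _OTHER_ACTIVE_ANCHORS[other_active.index(sid) % 5]
            value = float(max(via_rng.normal(anchor, 3.0), 1.0))
        else:
            value = float(via_rng.uniform(55.0, 100.0))
        records.append(BioactivityRecord(sample_id=sid, viability_percent=value))

    truth_df = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "compound", "ion_label", "charge", "function",
                 "mz_true", "mz_observed", "rt_true", "abundance"],
    )
    return runs, records, truth_df


def simulate_tap_isobars(
    seed: int = 0,
    drift_low: float = 4.0,
    drift_high: float = 5.5,
    drift_sigma: float = 0.35,
    drift_grid_step: float = 0.1,
    drift_range: tuple[float, float] = (0.0, 12.0),
    mz_jitter_ppm_sd: float = 3.0,
) -> TapRun:
    """Synthetic TAP fragmentation dataset for the m/z 218.19 isobar pair.

    The doubly charged precursor of the (9,11)-chain cyclostellettamine
    yields two drift-separated populations at the precursor m/z: a
    ring-opened species (lower drift time) whose secondary spectrum
    contains the macrocycle-opening fragment at m/z 393.34 (singly
    charged molecular ion minus the C2H6N neutral), and a compact
    species (higher drift time) whose secondary spectrum contains both
    onium fragments (m/z 204.18 and 232.21).  The onium fragments and
    the ring-opening fragment also appear as primary drift peaks.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 31]))
    lib = curated_library()
    p = lib["Cyclostellettamine P"]
    mz_2plus = next(i.mz for i in p.ion_species if i.charge == 2)
    mz_1plus = next(i.mz for i in p.ion_species if i.charge == 1)
    f1, f2 = (f.mz for f in p.fragment_ions)
    diag = 106.0656742604
    from .formula import monoisotopic_mass, parse_formula

    ring_open = mz_1plus - monoisotopic_mass(parse_formula("C2H6N"))

    def jit(mz: float) -> float:
        if mz_jitter_ppm_sd == 0:
            return mz
        return mz * (1.0 + rng.normal(0.0, mz_jitter_ppm_sd) * 1e-6)

    # (primary mz, drift apex, intensity, secondary peaks [(mz, rel)])
    species = [
        (jit(mz_2plus), drift_low, 1.0e5,
         [(jit(ring_open), 0.6), (jit(diag), 0.3)]),
        (jit(mz_2plus), drift_high, 1.2e5,
         [(jit(f1), 0.7), (jit(f2), 0.7), (jit(diag), 0.3)]),
        (jit(ring_open), 7.2, 4.0e4, [(jit(f1), 0.4), (jit(f2), 0.4)]),
        (jit(f1), 3.0, 6.0e4, [(jit(diag), 0.5)]),
        (jit(f2), 3.4, 6.0e4, [(jit(diag), 0.5)]),
    ]

    lo, hi = drift_range
    bins = np.arange(lo, hi + 1e-9, drift_grid_step)
    primary: list[tuple[float, float, float]] = []
    secondary_acc: dict[int, list[tuple[float, float]]] = {}
    for mz0, apex, inten, sec in species:
        w = np.exp(-0.5 * ((bins - apex) / drift_sigma) ** 2)
        keep = w > 1e-3
        for b, wt in zip(np.nonzero(keep)[0], w[keep]):
            primary.append((mz0, float(bins[b]), float(inten * wt)))
            for smz, srel in sec:
                secondary_acc.setdefault(int(b), []).append((smz, inten * wt * srel))
    primary.sort(key=lambda t: (t[1], t[0]))
    secondary = []
    for b in sorted(secondary_acc):
        entries = secondary_acc[b]
        spec2 = Spectrum(rt=0.0, function=2,
                         mz=np.array([m for m, _ in entries]),
                         intensity=np.array([i for _, i in entries]))
        secondary.append((float(bins[b]), spec2))
    return TapRun(precursor_mz=mz_2plus, primary_peaks=primary, secondary_spectra=secondary)


def build_feature_table(
    runs: Sequence[MseRun],
    mz_bin_ppm: float = 10.0,
    rt_bin: float = 0.2,
    deisotope: bool = True,
) -> FeatureTable:
    """Greedy cross-run feature finding on function-1 peaks.

    Peaks are clustered seed-first (strongest unassigned peak defines a
    feature; all unassigned peaks within the ppm and rt windows join
    it) and intensity-summed per sample.  With ``deisotope``, features
    sitting at a carbon-isotope position (mz - k*1.003355/z for z in
    {1,2,3}, k >= 1) of a stronger coeluting feature are removed.
    Features are ordered by median intensity, descending.
    """
    if not runs:
        raise ValueError("at least one run is required")
    if mz_bin_ppm <= 0 or rt_bin <= 0:
        raise ValueError("bins must be positive")
    sample_ids = [r.sample_id for r in runs]
    mz_all, rt_all, int_all, samp_all = [], [], [], []
    for si, run in enumerate(runs):
        for s in run.function_spectra(1):
            if len(s) == 0:
                continue
            mz_all.append(s.mz)
            int_all.append(s.intensity)
            rt_all.append(np.full(len(s), s.rt))
            samp_all.append(np.full(len(s), si, dtype=int))
    if not mz_all:
        empty_feats = pd.DataFrame(columns=["feature_id", "mz", "rt"])
        return FeatureTable(empty_feats, pd.DataFrame(index=sample_ids))
    mz = np.concatenate(mz_all)
    rt = np.concatenate(rt_all)
    inten = np.concatenate(int_all)
    samp = np.concatenate(samp_all)

    order_mz = np.argsort(mz, kind="stable")
    mz_s, rt_s, int_s, samp_s = mz[order_mz], rt[order_mz], inten[order_mz], samp[order_mz]
    assigned = np.zeros(mz_s.size, dtype=bool)
    seeds = np.argsort(int_s, kind="stable")[::-1]

    feat_mz, feat_rt = [], []
    rows: list[np.ndarray] = []  # member indices per feature
    for s_idx in seeds:
        if assigned[s_idx]:
            continue
        m0, t0 = mz_s[s_idx], rt_s[s_idx]
        half = m0 * mz_bin_ppm * 1e-6
        lo = np.searchsorted(mz_s, m0 - half, side="left")
        hi = np.searchsorted(mz_s, m0 + half, side="right")
        window = np.arange(lo, hi)
        members = window[(~assigned[window])
                         & (np.abs(rt_s[window] - t0) <= rt_bin + 1e-9)]
        assigned[members] = True
        w = int_s[members]
        tot = w.sum()
        feat_mz.append(float((mz_s[members] * w).sum() / tot) if tot > 0 else m0)
        feat_rt.append(float((rt_s[members] * w).sum() / tot) if tot > 0 else t0)
        rows.append(members)

    feat_mz_arr = np.array(feat_mz)
    feat_rt_arr = np.array(feat_rt)
    n_feat = feat_mz_arr.size
    matrix = np.zeros((len(runs), n_feat))
    for j, members in enumerate(rows):
        np.add.at(matrix[:, j], samp_s[members], int_s[members])

    keep = np.ones(n_feat, dtype=bool)
    if deisotope:
        totals = matrix.sum(axis=0)
        order = np.argsort(feat_mz_arr, kind="stable")
        mz_sorted = feat_mz_arr[order]
        for j in range(n_feat):
            target_found = False
            for z in (1, 2, 3):
                for k in (1, 2, 3):
                    target = feat_mz_arr[j] - k * ISOTOPE_SPACING / z
                    if target <= 0:
                        continue
                    half = target * mz_bin_ppm * 1e-6
                    lo = np.searchsorted(mz_sorted, target - half, side="left")
                    hi = np.searchsorted(mz_sorted, target + half, side="right")
                    for g in order[lo:hi]:
                        if (g != j and keep[g]
                                and abs(feat_rt_arr[g] - feat_rt_arr[j]) <= rt_bin + 1e-9
                                and totals[g] > totals[j]):
                            target_found = True
                            break
                    if target_found:
                        break
                if target_found:
                    break
            if target_found:
                keep[j] = False

    idx_keep = np.nonzero(keep)[0]
    med = np.median(matrix[:, idx_keep], axis=0)
    order_out = idx_keep[np.argsort(-med, kind="stable")]
    width = max(5, len(str(order_out.size)))
    ids = [f"F{i + 1:0{width}d}" for i in range(order_out.size)]
    features = pd.DataFrame({
        "feature_id": ids,
        "mz": feat_mz_arr[order_out],
        "rt": feat_rt_arr[order_out],
    })
    mat = pd.DataFrame(matrix[:, order_out], index=sample_ids, columns=ids)
    return FeatureTable(features, mat)
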