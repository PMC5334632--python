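"""Bioactivity-aligned prioritization of metabolomic features.

Workflow: MTS viability calls (an extract is cytotoxic when viability
drops below 50% of the solvent control) -> feature-table normalization
(sum, log10, unit variance) -> PCA -> k-means (k=2) on the first two
score dimensions.  The smaller cluster is proposed as the candidate
specimen set when it is uniformly bioactive and more active than the
rest; the features driving the separation are then ranked by loading
magnitude and matched against the alkaloid library by exact mass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .library import LibraryHit, MassLibrary
from .simulate import BioactivityRecord, FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityCall",
    "PcaResult",
    "ClusterPriority",
    "PriorityFeature",
    "AbundanceMatrix",
    "PrioritizeParams",
    "call_activity",
    "compute_viability",
    "normalize_table",
    "pca",
    "prioritize_cluster",
    "prioritize_features",
    "abundance_heatmap",
]


@dataclass(frozen=True)
class ActivityCall:
    sample_id: str
    viability_percent: float
    active: bool
    threshold_used: float


def call_activity(record: BioactivityRecord, threshold_percent: float = 50.0) -> ActivityCall:
    """Cytotoxicity call: active iff viability is strictly below the threshold."""
    if record.viability_percent < 0:
        raise ValueError(f"negative viability for {record.sample_id}")
    return ActivityCall(
        sample_id=record.sample_id,
        viability_percent=record.viability_percent,
        active=record.viability_percent < threshold_percent,
        threshold_used=threshold_percent,
    )


def compute_viability(
    absorbance_sample: float | Sequence[float],
    absorbance_control: float | Sequence[float],
) -> float:
    """Percent viability relative to the solvent control.

    Replicate absorbances are averaged before taking the ratio.
    """
    sample = float(np.mean(np.atleast_1d(absorbance_sample)))
    control = float(np.mean(np.atleast_1d(absorbance_control)))
    if control <= 0:
        raise ValueError("control absorbance must be > 0")
    return 100.0 * sample / control


def normalize_table(table: FeatureTable) -> pd.DataFrame:
    """Sum normalization, log10 transform, unit-variance scaling.

    1. each sample is divided by its total intensity;
    2. zeros are replaced by half the smallest positive normalized
       value, then log10 is taken;
    3. each feature is centered to mean 0 and scaled to sd 1; features
       with zero variance are dropped (logged).
    """
    mat = table.matrix.astype(float)
    if (mat.values < 0).any():
        raise ValueError("intensities must be >= 0")
    totals = mat.sum(axis=1)
    zero_samples = totals[totals <= 0].index.tolist()
    if zero_samples:
        raise ValueError(f"all-zero sample(s): {zero_samples}")
    frac = mat.div(totals, axis=0)
    positive = frac.values[frac.values > 0]
    if positive.size == 0:
        raise ValueError("feature table has no positive intensities")
    floor = positive.min() / 2.0
    logged = np.log10(frac.where(frac > 0, floor))
    sd = logged.std(axis=0, ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index.tolist()
    if constant:
        logger.warning("dropping %d constant feature(s): %s%s",
                       len(constant), constant[:5], "..." if len(constant) > 5 else "")
        logged = logged.drop(columns=constant)
        sd = sd.drop(index=constant)
    return (logged - logged.mean(axis=0)) / sd


@dataclass
class PcaResult:
    """PCA of a samples x features matrix via SVD of the centered data.

    ``loadings`` columns are orthonormal; the sign convention makes
    each loading vector's largest-magnitude entry positive.
    """

    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # features x components
    explained_variance_fraction: np.ndarray


def pca(normalized: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    n, p = normalized.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(f"n_components must be <= {max_comp}")
    x = normalized.values - normalized.values.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = (s ** 2).sum()
    explained = (s ** 2) / total if total > 0 else np.zeros_like(s)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u[:, :n_components] * s[:n_components]
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=normalized.index, columns=comp_names),
        loadings=pd.DataFrame(vt[:n_components].T, index=normalized.columns,
                              columns=comp_names),
        explained_variance_fraction=explained[:n_components],
    )


@dataclass(frozen=True)
class PrioritizeParams:
    """Candidate-cluster gating parameters.

    ``min_share``: minimum between-cluster variance share for a score
    dimension to count as separating the clusters.
    ``min_active_fraction``: minimum fraction of cytotoxic samples in
    the candidate cluster (1.0 = uniformly bioactive), on top of the
    requirement that it be more active than the other cluster.
    """

    min_share: float = 0.5
    min_active_fraction: float = 1.0
    n_restarts: int = 20
    random_state: int = 0


@dataclass
class ClusterPriority:
    candidates: list[str]
    separating_components: list[str]
    labels: pd.Series = field(repr=False)
    active_fraction_candidates: float = float("nan")
    active_fraction_rest: float = float("nan")


def prioritize_cluster(
    pca_result: PcaResult,
    activity: Sequence[ActivityCall],
    params: PrioritizeParams = PrioritizeParams(),
) -> ClusterPriority:
    """Propose a candidate specimen cluster aligned with cytotoxicity.

    k-means with k=2 on the first two score dimensions; the smaller
    cluster becomes the candidate set when its active fraction exceeds
    the other cluster's and reaches ``min_active_fraction``; otherwise
    the candidate set is empty.
    """
    scores = pca_result.scores.iloc[:, :2]
    active = {a.sample_id: a.active for a in activity}
    missing = [s for s in scores.index if s not in active]
    if missing:
        raise ValueError(f"activity calls missing for samples: {missing}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=2, n_init=params.n_restarts,
                    random_state=params.random_state)
        labels = pd.Series(km.fit_predict(scores.values), index=scores.index)
    sizes = labels.value_counts()
    if len(sizes) < 2 or sizes.iloc[0] == sizes.iloc[1]:
        return ClusterPriority([], [], labels)
    small = sizes.idxmin()
    in_small = labels == small
    frac_small = np.mean([active[s] for s in labels.index[in_small]])
    frac_rest = np.mean([active[s] for s in labels.index[~in_small]])
    separating = []
    for comp in scores.columns:
        x = scores[comp].values
        overall = x.var()
        if overall == 0:
            continue
        m = x.mean()
        between = sum(
            (labels == g).sum() * (x[(labels == g).values].mean() - m) ** 2
            for g in sizes.index
        ) / x.size
        if between / overall > params.min_share:
            separating.append(comp)
    if frac_small > frac_rest and frac_small >= params.min_active_fraction:
        candidates = sorted(labels.index[in_small])
    else:
        candidates = []
    return ClusterPriority(
        candidates=list(candidates),
        separating_components=separating,
        labels=labels,
        active_fraction_candidates=float(frac_small),
        active_fraction_rest=float(frac_rest),
    )


@dataclass(frozen=True)
class PriorityFeature:
    feature_id: str
    mz: float
    rt: float
    loading_magnitude: float
    matches: tuple[LibraryHit, ...]


def prioritize_features(
    pca_result: PcaResult,
    priority: ClusterPriority,
    library: MassLibrary,
    features: FeatureTable,
    ppm_tol: float = 10.0,
    top_k: int = 50,
) -> list[PriorityFeature]:
    """Rank features by |loading| on the separating components and match
    them against the library by exact mass."""
    if not priority.candidates:
        raise ValueError("candidate set is empty; nothing to prioritize")
    comps = priority.separating_components or list(pca_result.loadings.columns[:1])
    mags = pca_result.loadings[comps].abs().max(axis=1).sort_values(ascending=False)
    meta = features.features.set_index("feature_id")
    out = []
    for fid, mag in mags.head(top_k).items():
        mz = float(meta.loc[fid, "mz"])
        rt = float(meta.loc[fid, "rt"])
        hits = tuple(library.lookup(mz, ppm_tol)) if ppm_tol > 0 else ()
        out.append(PriorityFeature(fid, mz, rt, float(mag), hits))
    return out


@dataclass
class AbundanceMatrix:
    """Compounds x samples relative abundances (raw or per-compound z-scored)."""

    values: pd.DataFrame
    scaling: str  # "raw" | "zscore"


def abundance_heatmap(
    annotations_by_sample: dict[str, Sequence],
    scaling: str = "raw",
) -> AbundanceMatrix:
    """Per-(compound, sample) precursor intensity matrix for heat-mapping.

    ``annotations_by_sample`` maps sample id to its list of screening
    annotations.  Missing (compound, sample) pairs are 0; compounds
    absent everywhere are dropped.  With ``scaling="zscore"``, rows are
    z-scored per compound (skipped with a warning for a single sample).
    """
    if not annotations_by_sample:
        raise ValueError("at least one annotated sample is required")
    if scaling not in ("raw", "zscore"):
        raise ValueError(f"unknown scaling {scaling!r}")
    samples = list(annotations_by_sample)
    cells: dict[str, dict[str, float]] = {}
    for sid, anns in annotations_by_sample.items():
        for ann in anns:
            inten = max((h.intensity for h in ann.precursor_hits), default=0.0)
            row = cells.setdefault(ann.compound.name, {})
            row[sid] = max(row.get(sid, 0.0), inten)
    mat = pd.DataFrame(cells).T.reindex(columns=samples).fillna(0.0)
    mat = mat.loc[(mat > 0).any(axis=1)]
    if scaling == "zscore":
        if len(samples) < 2:
            logger.warning("z-scoring disabled: need >= 2 samples")
            return AbundanceMatrix(mat, "raw")
        sd = mat.std(axis=1, ddof=0)
        center = mat.sub(mat.mean(axis=1), axis=0)
        mat = center.div(sd.where(sd > 0, 1.0), axis=0)
        return AbundanceMatrix(mat, "zscore")
    return AbundanceMatrix(mat, "raw")
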