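import logging

import numpy as np
import pandas as pd
import pytest

from apascreen.prioritize import (
    ClusterPriority,
    abundance_heatmap,
    call_activity,
    compute_viability,
    normalize_table,
    pca,
    prioritize_cluster,
    prioritize_features,
)
from apascreen.screening import annotate_run
from apascreen.simulate import (
    BioactivityRecord,
    CohortSpec,
    FeatureTable,
    build_feature_table,
    simulate_cohort,
    simulate_mse_run,
)

# the eight-extract reference viability table (% of solvent control)
TABLE1 = {"S1": 8, "S2": 29, "S3": 51, "S4": 18, "S5": 31, "S6": 31, "S7": 13, "S8": 22}


class TestActivity:
    def test_reference_viability_calls(self):
        """At the strict <50% rule, S3 (51% viability, i.e. a 49% decrease)
        is not called active even though it sits in the cytotoxic table."""
        calls = {sid: call_activity(BioactivityRecord(sid, v)).active
                 for sid, v in TABLE1.items()}
        assert calls == {"S1": True, "S2": True, "S3": False, "S4": True,
                         "S5": True, "S6": True, "S7": True, "S8": True}

    def test_threshold_recorded_and_boundary(self):
        call = call_activity(BioactivityRecord("x", 50.0))
        assert not call.active and call.threshold_used == 50.0
        assert call_activity(BioactivityRecord("x", 49.999)).active
        assert not call_activity(BioactivityRecord("x", 100.0)).active

    def test_configurable_threshold(self):
        assert call_activity(BioactivityRecord("S3", 51.0), threshold_percent=52).active

    def test_negative_viability_rejected(self):
        with pytest.raises(ValueError):
            BioactivityRecord("x", -1.0)


class TestViability:
    def test_ratio(self):
        assert compute_viability(0.08, 1.00) == pytest.approx(8.0)
        assert compute_viability(1.0, 1.0) == pytest.approx(100.0)

    def test_replicates_averaged_before_ratio(self):
        assert compute_viability([0.30, 0.32, 0.31], [1.0, 1.0, 1.0]) == pytest.approx(31.0)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            compute_viability(0.5, 0.0)


def _toy_table(matrix, samples=None):
    matrix = np.asarray(matrix, dtype=float)
    ids = [f"F{j}" for j in range(matrix.shape[1])]
    feats = pd.DataFrame({"feature_id": ids,
                          "mz": 100.0 + np.arange(matrix.shape[1]),
                          "rt": np.ones(matrix.shape[1])})
    samples = samples or [f"S{i + 1}" for i in range(matrix.shape[0])]
    return FeatureTable(feats, pd.DataFrame(matrix, index=samples, columns=ids))


class TestNormalization:
    def test_unit_variance_and_zero_mean(self):
        rng = np.random.default_rng(0)
        table = _toy_table(rng.lognormal(3, 1, size=(6, 20)))
        norm = normalize_table(table)
        assert np.allclose(norm.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(norm.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_sum_normalization_scale_invariance(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(3, 1, size=(5, 15))
        scaled = base.copy()
        scaled[2] *= 7.5
        a = normalize_table(_toy_table(base))
        b = normalize_table(_toy_table(scaled))
        assert np.allclose(a.values, b.values, atol=1e-10)

    def test_constant_feature_dropped_with_warning(self, caplog):
        mat = np.random.default_rng(2).lognormal(3, 1, size=(4, 5))
        mat[:, 2] = 0.0  # all-zero feature is constant after floor imputation
        with caplog.at_level(logging.WARNING, logger="apascreen.prioritize"):
            norm = normalize_table(_toy_table(mat))
        assert norm.shape[1] == 4
        assert any("constant" in r.message for r in caplog.records)

    def test_all_zero_sample_named_in_error(self):
        mat = np.ones((3, 4))
        mat[1] = 0.0
        with pytest.raises(ValueError, match="S2"):
            normalize_table(_toy_table(mat))


def _pca_oracle(x):
    """Covariance eigendecomposition oracle for small matrices."""
    xc = x - x.mean(axis=0, keepdims=True)
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


class TestPca:
    def test_explained_fractions_complete(self):
        rng = np.random.default_rng(3)
        norm = pd.DataFrame(rng.normal(size=(8, 5)))
        res = pca(norm)
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(res.explained_variance_fraction) <= 1e-12)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(4)
        res = pca(pd.DataFrame(rng.normal(size=(7, 6))))
        gram = res.loadings.values.T @ res.loadings.values
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(5, 4))
        x[3] = x[1]
        res = pca(pd.DataFrame(x))
        assert np.allclose(res.scores.iloc[1], res.scores.iloc[3], atol=1e-10)

    def test_toy_matrix_against_hand_oracle(self):
        # already-centered toy matrix; covariance [[1, .5], [.5, 1]] has
        # eigenvalues 1.5 and 0.5, so PC1 carries 3/4 of the variance
        norm = pd.DataFrame([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])
        res = pca(norm)
        assert res.explained_variance_fraction[0] == pytest.approx(0.75, abs=1e-10)

    def test_oracle_equivalence_small_matrices(self):
        """Scores and loadings match a brute-force covariance
        eigendecomposition (up to the fixed sign convention) to 1e-8."""
        rng = np.random.default_rng(6)
        for n, p in [(5, 3), (8, 8), (10, 4)]:
            x = rng.normal(size=(n, p))
            res = pca(pd.DataFrame(x))
            evals, evecs = _pca_oracle(x)
            k = res.loadings.shape[1]
            total = evals.sum() * (n - 1)
            np.testing.assert_allclose(
                res.explained_variance_fraction,
                evals[:k] * (n - 1) / total, atol=1e-8)
            for j in range(k):
                v = evecs[:, j]
                if v[np.argmax(np.abs(v))] < 0:
                    v = -v
                np.testing.assert_allclose(res.loadings.values[:, j], v, atol=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pca(pd.DataFrame([[1.0, 2.0]]))


def _cohort_pipeline(spec):
    runs, bio, truth = simulate_cohort(spec)
    table = build_feature_table(runs)
    calls = [call_activity(r) for r in bio]
    res = pca(normalize_table(table))
    return prioritize_cluster(res, calls), res, table, truth


class TestPrioritizeCluster:
    def test_default_cohort_recovers_apa_samples(self):
        priority, res, _, _ = _cohort_pipeline(CohortSpec(seed=0))
        assert priority.candidates == ["S1", "S5", "S8"]
        assert priority.separating_components  # at least one separating PC

    def test_no_signal_cohort_yields_empty(self):
        priority, *_ = _cohort_pipeline(CohortSpec(seed=0, apa_sample_ids=()))
        assert priority.candidates == []

    def test_scattered_actives_mostly_empty(self):
        """Without a chemical signal the active extracts stay scattered among
        the inactive specimens and no cluster is prioritized (>= 9/10 seeds)."""
        empty = sum(
            _cohort_pipeline(CohortSpec(seed=seed, apa_sample_ids=()))[0].candidates == []
            for seed in range(10)
        )
        assert empty >= 9

    def test_missing_activity_rejected(self):
        rng = np.random.default_rng(7)
        res = pca(pd.DataFrame(rng.normal(size=(4, 3)),
                               index=["S1", "S2", "S3", "S4"]))
        calls = [call_activity(BioactivityRecord("S1", 10.0))]
        with pytest.raises(ValueError, match="S2"):
            prioritize_cluster(res, calls)


class TestPrioritizeFeatures:
    def test_apa_ions_dominate_top_features(self, lib):
        priority, res, table, truth = _cohort_pipeline(CohortSpec(seed=1))
        feats = prioritize_features(res, priority, lib, table, ppm_tol=10, top_k=50)
        matched = [f for f in feats if f.matches]
        assert len(matched) >= 25
        # matched features coincide with injected precursor ions
        injected = truth.loc[truth["function"] == 1, "mz_observed"].values
        hits = sum(np.any(np.abs(injected - f.mz) / f.mz * 1e6 < 10) for f in matched)
        assert hits >= len(matched) * 0.9

    def test_background_top_features_unmatched(self, lib):
        _, res, table, _ = _cohort_pipeline(CohortSpec(seed=2, apa_sample_ids=()))
        fake = ClusterPriority(["S1"], ["PC1"], pd.Series(dtype=int))
        feats = prioritize_features(res, fake, lib, table, ppm_tol=10, top_k=20)
        assert sum(1 for f in feats if f.matches) == 0

    def test_zero_tolerance_no_matches(self, lib):
        priority, res, table, _ = _cohort_pipeline(CohortSpec(seed=1))
        feats = prioritize_features(res, priority, lib, table, ppm_tol=0, top_k=20)
        assert all(not f.matches for f in feats)

    def test_empty_candidates_rejected(self, lib):
        _, res, table, _ = _cohort_pipeline(CohortSpec(seed=2, apa_sample_ids=()))
        empty = ClusterPriority([], [], pd.Series(dtype=int))
        with pytest.raises(ValueError):
            prioritize_features(res, empty, lib, table)


@pytest.fixture(scope="module")
def annotations(lib):
    spec = CohortSpec(seed=4, n_background_features=0, noise_peak_rate=0)
    profiles = {
        "S1": {c.name: 2.0 if c.name == "Cyclostellettamine Q" else 1.0
               for c in lib.entries},
        "S5": {c.name: 1.0 for c in lib.entries},
    }
    out = {}
    for sid in ("S1", "S5"):
        run = simulate_mse_run(
            [(c, profiles[sid][c.name]) for c in lib.entries], spec, sid, seed=4)
        out[sid] = annotate_run(run, lib)
    return out


class TestAbundanceHeatmap:
    def test_relative_abundance_ordering(self, annotations):
        mat = abundance_heatmap(annotations).values
        assert mat.loc["Cyclostellettamine Q", "S1"] > mat.loc["Cyclostellettamine Q", "S5"]

    def test_zscore_rows(self, annotations):
        res = abundance_heatmap(annotations, scaling="zscore")
        assert res.scaling == "zscore"
        assert np.allclose(res.values.mean(axis=1), 0, atol=1e-9)

    def test_single_sample_zscore_falls_back(self, annotations, caplog):
        single = {"S1": annotations["S1"]}
        with caplog.at_level(logging.WARNING, logger="apascreen.prioritize"):
            res = abundance_heatmap(single, scaling="zscore")
        assert res.scaling == "raw"

    def test_absent_compound_dropped(self, annotations):
        mat = abundance_heatmap(annotations).values
        assert (mat > 0).any(axis=1).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            abundance_heatmap({})
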