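import numpy as np
import pytest

from measelect import (
    FeatureMatrix,
    build_feature_matrix,
    electrode_exclusion_curve,
    extract_patterns,
    kmeans_classify,
    kmeans_pc_classify,
    svc_classify,
)

from conftest import patterns_from_counts, quick_recording


def _fm(x, n_per_class=None, feature="tsc"):
    x = np.asarray(x, dtype=float)
    n = x.shape[0] // 2 if n_per_class is None else n_per_class
    labels = np.array(["S1"] * n + ["S2"] * (x.shape[0] - n), dtype=object)
    return FeatureMatrix(x, labels, feature)


def _gaussian_clouds(rng, d=2.0, n=30, dim=2):
    a = rng.normal(0.0, 1.0, (n, dim))
    b = rng.normal(d, 1.0, (n, dim))
    return _fm(np.vstack([a, b]))


class TestKmeansClassify:
    def test_separated_clouds_perfect(self):
        rng = np.random.default_rng(0)
        fm = _gaussian_clouds(rng, d=10.0)
        assert kmeans_classify(fm).accuracy == 100.0

    def test_identical_rows_chance(self):
        fm = _fm(np.ones((30, 3)))
        assert kmeans_classify(fm).accuracy == pytest.approx(50.0, abs=10.0)

    def test_boundary_oracle_two_gaussians(self):
        # analytic oracle: clustering boundary at the midpoint of two unit-SD
        # Gaussians separated by 2 sigma classifies 100*Phi(1) = 84.13 %
        from scipy.stats import norm

        rng = np.random.default_rng(1)
        accs = []
        for _ in range(50):
            x = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)])[:, None]
            accs.append(kmeans_classify(_fm(x)).accuracy)
        assert abs(np.mean(accs) - 100 * norm.cdf(1.0)) < 5.0

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        fm = FeatureMatrix(x, np.array(["S1"] * 10, dtype=object), "tsc")
        with pytest.raises(ValueError, match="2 classes"):
            kmeans_classify(fm)


class TestKmeansPcClassify:
    def test_identical_rows_exactly_chance(self):
        fm = _fm(np.ones((30, 3)))
        assert kmeans_pc_classify(fm).accuracy == 50.0

    def test_separable_classes_perfect(self):
        rng = np.random.default_rng(2)
        assert kmeans_pc_classify(_gaussian_clouds(rng, d=10.0)).accuracy == 100.0

    def test_resubstitution_labelled_in_details(self):
        rng = np.random.default_rng(3)
        rep = kmeans_pc_classify(_gaussian_clouds(rng))
        assert rep.details["mode"] == "resubstitution"

    def test_holdout_mode(self):
        rng = np.random.default_rng(4)
        rep = kmeans_pc_classify(_gaussian_clouds(rng, d=10.0), holdout_frac=0.3)
        assert rep.details["mode"] == "holdout"
        assert rep.accuracy == 100.0

    def test_pc_beats_plain_kmeans_with_moderate_effects(self):
        # paired simulation: with moderate site effects, supplying the class
        # centroids should not hurt
        wins = 0
        n_rep = 40
        for i in range(n_rep):
            spikes, stims, _ = quick_recording(
                n_electrodes=8, seed=300 + i, spontaneous=True,
                selective_electrodes=(1, 2, 3), rate_gain=1.6,
            )
            fm = build_feature_matrix(extract_patterns(spikes, stims), "tsc")
            wins += kmeans_pc_classify(fm).accuracy >= kmeans_classify(fm).accuracy
        assert wins / n_rep >= 0.9


class TestSvcClassify:
    def test_linearly_separable_perfect(self):
        rng = np.random.default_rng(5)
        assert svc_classify(_gaussian_clouds(rng, d=10.0)).accuracy == 100.0

    def test_xor_beats_linear_methods(self):
        # four tight clusters in XOR arrangement: RBF-SVC solves it, the
        # nearest-centroid rule cannot (identical class centroids)
        rng = np.random.default_rng(6)
        corners_a = [(0, 0), (1, 1)]
        corners_b = [(0, 1), (1, 0)]
        xa = np.vstack([rng.normal(c, 0.05, (15, 2)) for c in corners_a])
        xb = np.vstack([rng.normal(c, 0.05, (15, 2)) for c in corners_b])
        fm = _fm(np.vstack([xa, xb]))
        assert svc_classify(fm).accuracy > 95.0
        assert abs(kmeans_pc_classify(fm).accuracy - 50.0) <= 15.0

    def test_label_permutation_chance(self):
        rng = np.random.default_rng(7)
        accs = []
        for i in range(15):
            x = rng.normal(size=(60, 4))
            fm = _fm(x)
            accs.append(svc_classify(fm, random_state=i).accuracy)
        assert abs(np.mean(accs) - 50.0) < 8.0

    def test_per_fold_detail(self):
        rng = np.random.default_rng(8)
        rep = svc_classify(_gaussian_clouds(rng, d=10.0))
        assert len(rep.per_fold) == 5

    def test_too_few_rows_per_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(6, 2))
        fm = _fm(x, n_per_class=3)
        with pytest.raises(ValueError, match="at least 5"):
            svc_classify(fm)


class TestBuildFeatureMatrix:
    def test_shapes_and_labels(self):
        spikes, stims, _ = quick_recording(n_electrodes=8, seed=9)
        pats = extract_patterns(spikes, stims)
        for feature, ncol in [("activation", 8), ("tsc", 8), ("first_bin", 8), ("full", 120)]:
            fm = build_feature_matrix(pats, feature)
            assert fm.x.shape == (60, ncol)
            assert set(fm.labels) == {"S1", "S2"}

    def test_missing_activation_imputed_with_window_end(self):
        counts = [np.zeros((2, 15), dtype=int) for _ in range(4)]
        for c in counts:
            c[0, 3] = 1  # electrode 1 fires, electrode 2 silent
        pats = patterns_from_counts(counts, ["S1", "S2", "S1", "S2"])
        fm = build_feature_matrix(pats, "activation")
        assert np.all(fm.x[:, 1] == 300.0)

    def test_electrode_subset_by_mask(self):
        spikes, stims, _ = quick_recording(n_electrodes=8, seed=10)
        pats = extract_patterns(spikes, stims)
        mask = np.zeros(8, dtype=bool)
        mask[[0, 4]] = True
        fm = build_feature_matrix(pats, "tsc", electrodes=mask)
        assert fm.x.shape[1] == 2
        np.testing.assert_array_equal(fm.electrode_ids, [1, 5])


class TestElectrodeExclusionCurve:
    @staticmethod
    def _patterns_and_overlaps(seed=0):
        spikes, stims, _ = quick_recording(
            n_electrodes=16, seed=seed, spontaneous=True,
            selective_electrodes=tuple(range(1, 6)), rate_gain=2.5,
        )
        pats = extract_patterns(spikes, stims)
        from measelect import overlap

        tsc = np.stack([p.total_spike_count for p in pats])
        mask_a = np.array([p.site == "S1" for p in pats])
        overlaps = np.array(
            [overlap(tsc[mask_a, e], tsc[~mask_a, e]).overlap_percent for e in range(16)]
        )
        return pats, overlaps

    def test_curve_length_n_minus_one(self):
        pats, overlaps = self._patterns_and_overlaps()
        curve = electrode_exclusion_curve(pats, overlaps, "drop_lowest")
        assert len(curve.accuracy) == 16 - 1
        assert curve.n_retained[0] == 16 and curve.n_retained[-1] == 2
        assert curve.removed_before[0] is None

    def test_drop_highest_keeps_informative_electrodes(self):
        pats, overlaps = self._patterns_and_overlaps()
        hi = electrode_exclusion_curve(pats, overlaps, "drop_highest")
        lo = electrode_exclusion_curve(pats, overlaps, "drop_lowest")
        small = hi.n_retained <= 6
        assert hi.accuracy[small].mean() >= lo.accuracy[small].mean()

    def test_nan_overlaps_excluded(self):
        pats, overlaps = self._patterns_and_overlaps()
        overlaps[3] = np.nan
        curve = electrode_exclusion_curve(pats, overlaps, "drop_lowest")
        assert len(curve.accuracy) == 15 - 1
        assert 4 not in [r for r in curve.removed_before if r is not None]

    def test_too_few_electrodes_rejected(self):
        pats, overlaps = self._patterns_and_overlaps()
        bad = np.full_like(overlaps, np.nan)
        bad[:2] = 10.0
        with pytest.raises(ValueError, match="at least 3"):
            electrode_exclusion_curve(pats, bad)

    def test_bad_direction_rejected(self):
        pats, overlaps = self._patterns_and_overlaps()
        with pytest.raises(ValueError, match="direction"):
            electrode_exclusion_curve(pats, overlaps, "sideways")
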