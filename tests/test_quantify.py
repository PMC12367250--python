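"""Quantification: volumes, circumference vs analytic shapes, K-means IMAT."""

import numpy as np
import pytest

from bodycomp.imgio import LabelMask
from bodycomp.phantom import PhantomParams, generate_phantom
from bodycomp.quantify import (circumference_of, composition_profile, grade_bins,
                               imat_percentage, kmeans_imat, profile_from_truth,
                               threshold_search_1d, volume_of)
from bodycomp.schema import ABDOMEN, THIGH


def _mask(labels, spacing=(1.0, 1.0, 1.0), region="thigh"):
    schema = THIGH if region == "thigh" else ABDOMEN
    return LabelMask(np.asarray(labels, dtype=np.int32), schema, spacing)


class TestVolume:
    def test_unit_voxels(self):
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        labels.ravel()[:1000] = 1
        assert volume_of(_mask(labels), {1}) == pytest.approx(1.0)

    def test_anisotropic_voxel(self):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[0, 0, 0] = 1
        m = _mask(labels, spacing=(10.0, 0.82, 0.82))
        assert volume_of(m, {1}) == pytest.approx(0.0067240, abs=1e-7)

    def test_invariant_to_other_label_permutation(self, rng):
        labels = rng.integers(0, 5, (6, 12, 12)).astype(np.int32)
        m = _mask(labels)
        v1 = volume_of(m, {1})
        permuted = labels.copy()
        permuted[labels == 3], permuted[labels == 4] = 4, 3
        assert volume_of(_mask(permuted), {1}) == v1


class TestCircumference:
    def test_digitized_circle_within_2pct(self):
        labels = np.zeros((1, 128, 128), dtype=np.int32)
        rr, cc = np.mgrid[0:128, 0:128]
        labels[0][(rr - 64) ** 2 + (cc - 64) ** 2 <= 50 ** 2] = 1
        got = circumference_of(_mask(labels), {1})
        assert got == pytest.approx(2 * np.pi * 50, rel=0.02)

    def test_square_under_documented_convention(self):
        # 10x10 px square: the sigma-1 contour smoothing rounds the four
        # corners, measuring ~36.6 mm against the sharp-corner 40 mm
        labels = np.zeros((1, 32, 32), dtype=np.int32)
        labels[0, 10:20, 10:20] = 1
        got = circumference_of(_mask(labels), {1})
        assert got == pytest.approx(36.6, abs=0.5)

    def test_linear_in_spacing(self):
        labels = np.zeros((1, 32, 32), dtype=np.int32)
        labels[0, 10:20, 10:20] = 1
        base = circumference_of(_mask(labels), {1})
        doubled = circumference_of(_mask(labels, spacing=(1.0, 2.0, 2.0)), {1})
        assert doubled == pytest.approx(2 * base, rel=1e-9)

    def test_mean_over_slices_and_single_slice(self, thigh_case):
        fem = thigh_case.truth.schema.ids_of("femur")
        mean_c = circumference_of(thigh_case.truth, fem)
        one_c = circumference_of(thigh_case.truth, fem, slice_index=0)
        assert mean_c == pytest.approx(one_c, rel=1e-6)  # identical slices

    def test_empty_compartment_rejected(self):
        with pytest.raises(ValueError):
            circumference_of(_mask(np.zeros((1, 16, 16), dtype=np.int32)), {1})


class TestKMeans:
    def test_well_separated_bimodal_is_exact(self):
        vals = np.concatenate([np.full(80, 100.0), np.full(20, 1000.0)])
        img = vals.reshape(1, 10, 10)
        mask = np.ones((1, 10, 10), dtype=bool)
        res, imat = kmeans_imat(img, mask, seed=3)
        assert np.allclose(res.centers, [100.0, 1000.0])
        assert int(imat.sum()) == 20
        assert np.array_equal(imat, img >= 500)

    def test_constant_intensities_degenerate(self):
        img = np.full((1, 8, 8), 5.0)
        mask = np.ones((1, 8, 8), dtype=bool)
        res, imat = kmeans_imat(img, mask, seed=0)
        assert res.degenerate and not imat.any()
        assert imat_percentage(res, mask) == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            kmeans_imat(np.zeros((1, 4, 4)), np.zeros((1, 4, 4), dtype=bool))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_threshold_search_on_bimodal(self, seed):
        r = np.random.default_rng(seed)
        n_hi = int(r.integers(50, 400))
        vals = np.concatenate([r.normal(100, 15, 2000), r.normal(900, 40, n_hi)])
        img = vals.reshape(1, 1, -1)
        mask = np.ones_like(img, dtype=bool)
        res, imat = kmeans_imat(img, mask, seed=seed)
        centers, assign = threshold_search_1d(vals)
        assert np.array_equal(res.assignments, assign)
        assert np.allclose(res.centers, centers)

    def test_agrees_with_sklearn_reference(self):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        r = np.random.default_rng(8)
        vals = np.concatenate([r.normal(100, 15, 800), r.normal(900, 50, 200)])
        img = vals.reshape(1, 1, -1)
        res, _ = kmeans_imat(img, np.ones_like(img, dtype=bool), seed=0)
        km = sklearn_cluster.KMeans(n_clusters=2, n_init=10, random_state=0)
        km.fit(vals.reshape(-1, 1))
        ref = np.sort(km.cluster_centers_.ravel())
        assert np.allclose(res.centers, ref, rtol=1e-6)

    def test_wcss_non_increasing(self, rng):
        vals = rng.normal(0, 1, 500) + 5 * (rng.random(500) > 0.7)
        img = vals.reshape(1, 1, -1)
        res, _ = kmeans_imat(img, np.ones_like(img, dtype=bool), seed=1)
        h = res.wcss_history
        assert all(a >= b - 1e-9 for a, b in zip(h, h[1:]))

    def test_noiseless_phantom_recovery(self, noiseless_thigh):
        case = noiseless_thigh
        muscle = case.muscle_mask()
        res, imat = kmeans_imat(case.volume.fat, muscle, seed=0)
        recovered = imat_percentage(res, muscle) / 100.0
        planted = case.imat_truth.sum() / muscle.sum()
        assert recovered == pytest.approx(planted, abs=0.02)
        assert np.all(muscle[imat])  # imat mask stays inside muscle


class TestImatPercentage:
    def test_count_ratio(self):
        vals = np.concatenate([np.zeros(80), np.ones(20) * 100])
        img = vals.reshape(1, 10, 10)
        mask = np.ones((1, 10, 10), dtype=bool)
        res, _ = kmeans_imat(img, mask, seed=0)
        assert imat_percentage(res, mask) == pytest.approx(20.0)

    def test_empty_muscle_rejected(self):
        res, _ = kmeans_imat(np.arange(16, dtype=float).reshape(1, 4, 4),
                             np.ones((1, 4, 4), dtype=bool), seed=0)
        with pytest.raises(ValueError):
            imat_percentage(res, np.zeros((1, 4, 4), dtype=bool))


class TestGradeBins:
    def test_examples(self):
        assert grade_bins(0.0) == 0
        assert grade_bins(10.0, (5.0, 25.0)) == 1
        assert grade_bins(30.0, (5.0, 25.0)) == 2

    def test_monotone(self):
        grades = [grade_bins(p, (5, 25)) for p in np.linspace(0, 60, 200)]
        assert all(a <= b for a, b in zip(grades, grades[1:]))

    def test_bad_cuts_rejected(self):
        with pytest.raises(ValueError):
            grade_bins(1.0, (25.0, 5.0))


class TestCompositionProfile:
    def test_matches_reference_on_truth_mask(self, noiseless_thigh):
        case = noiseless_thigh
        prof = composition_profile(case.volume, case.truth, seed=0)
        ref = profile_from_truth(case)
        for name in ref.volumes_ml:
            if name == "IMAT":
                continue  # clustered, checked separately with tolerance
            assert prof.volumes_ml[name] == pytest.approx(ref.volumes_ml[name])
        assert prof.imat_percent == pytest.approx(ref.imat_percent, abs=2.0)
        assert prof.circumference_mm == pytest.approx(ref.circumference_mm)

    def test_merge_identities_exact(self, abdomen_case):
        prof = composition_profile(abdomen_case.volume, abdomen_case.truth, seed=0)
        v = prof.volumes_ml
        assert v["SAT"] == pytest.approx(v["sSAT"] + v["dSAT"], abs=1e-12)
        assert v["VAT"] == pytest.approx(v["IPAT"] + v["RPAT"], abs=1e-12)

    def test_abdominal_imat_clusters_core_muscle_only(self, abdomen_case):
        prof = composition_profile(abdomen_case.volume, abdomen_case.truth,
                                   seed=0, keep_imat_mask=True)
        cm = abdomen_case.truth.labels == ABDOMEN.id_of("CM")
        assert np.all(cm[prof.imat_mask])
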