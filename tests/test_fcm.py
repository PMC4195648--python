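"""Fuzzy C-means clustering, hardening, region merging and skin/wall
stripping."""

import numpy as np
import pytest

from adipoquant import (
    LevelSetField,
    ValidationError,
    fcm,
    harden,
    merge_regions,
    strip_skin_wall,
)
from adipoquant.fcm import RegionPartition, _init_centroids
from conftest import circle_sdf


def fcm_reference(values, n_classes, m=2.0, tol=1e-5, max_iter=300):
    """Textbook FCM coded as explicit loops over points and classes,
    independent of the vectorized module implementation. Same deterministic
    quantile initialization so results are directly comparable."""
    x = list(map(float, values))
    n = len(x)
    centroids = list(_init_centroids(np.asarray(x), n_classes))
    exponent = 2.0 / (m - 1.0)
    objective = []
    u = [[1.0 / n_classes] * n_classes for _ in range(n)]
    for _ in range(max_iter):
        for i in range(n):
            dists = [abs(x[i] - c) for c in centroids]
            if any(d < 1e-12 for d in dists):
                hits = [1.0 if d < 1e-12 else 0.0 for d in dists]
                s = sum(hits)
                u[i] = [h / s for h in hits]
                continue
            for k in range(n_classes):
                denom = sum((dists[k] / dists[j]) ** exponent for j in range(n_classes))
                u[i][k] = 1.0 / denom
        objective.append(
            sum(
                (u[i][k] ** m) * (x[i] - centroids[k]) ** 2
                for i in range(n)
                for k in range(n_classes)
            )
        )
        new_centroids = []
        for k in range(n_classes):
            num = sum((u[i][k] ** m) * x[i] for i in range(n))
            den = sum((u[i][k] ** m) for i in range(n))
            new_centroids.append(num / den)
        shift = max(abs(a - b) for a, b in zip(new_centroids, centroids))
        centroids = new_centroids
        if shift < tol:
            break
    order = np.argsort(centroids)
    return (
        np.array([[u[i][k] for k in order] for i in range(n)]),
        np.array([centroids[k] for k in order]),
        objective,
    )


class TestFCM:
    def test_well_separated_groups_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.1, 0.001, 30)
        b = rng.normal(0.9, 0.001, 30)
        mm = fcm(np.concatenate([a, b]), n_classes=2)
        assert mm.centroids[0] == pytest.approx(a.mean(), rel=0.01)
        assert mm.centroids[1] == pytest.approx(b.mean(), rel=0.01)
        assert (mm.memberships[:30, 0] >= 0.99).all()
        assert (mm.memberships[30:, 1] >= 0.99).all()

    def test_single_class_centroid_is_mean(self):
        x = np.array([0.1, 0.4, 0.7, 0.2])
        mm = fcm(x, n_classes=1)
        assert mm.centroids[0] == pytest.approx(x.mean())
        np.testing.assert_allclose(mm.memberships, 1.0)

    @pytest.mark.parametrize("n_classes", [3, 5])
    def test_matches_textbook_oracle(self, n_classes):
        rng = np.random.default_rng(42)
        x = rng.random(50)
        mm = fcm(x, n_classes=n_classes, fuzzifier_m=2.0)
        u_ref, c_ref, obj_ref = fcm_reference(x, n_classes)
        np.testing.assert_allclose(mm.centroids, c_ref, rtol=1e-6)
        np.testing.assert_allclose(mm.memberships, u_ref, atol=1e-6)
        # invariants: membership rows sum to one, objective non-increasing
        np.testing.assert_allclose(mm.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(mm.objective) <= 1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        x = rng.random(40)
        perm = rng.permutation(40)
        mm1 = fcm(x, 3)
        mm2 = fcm(x[perm], 3)
        np.testing.assert_allclose(mm2.memberships, mm1.memberships[perm], atol=1e-12)
        np.testing.assert_allclose(mm2.centroids, mm1.centroids, atol=1e-12)

    def test_repeat_runs_bit_identical(self):
        x = np.random.default_rng(1).random(60)
        mm1, mm2 = fcm(x, 4), fcm(x, 4)
        np.testing.assert_array_equal(mm1.memberships, mm2.memberships)
        np.testing.assert_array_equal(mm1.centroids, mm2.centroids)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            fcm(np.array([1.0, 1.0, 1.0]), n_classes=2)  # too few distinct
        with pytest.raises(ValidationError):
            fcm(np.arange(5.0), n_classes=2, fuzzifier_m=1.0)


class TestHarden:
    def test_argmax_assignment(self):
        mask = np.ones((1, 2), bool)
        mm = fcm(np.array([0.1, 0.9]), 2)
        part = harden(mm, mask, np.array([[0.1, 0.9]]))
        assert part.labels[0, 0] == 0 and part.labels[0, 1] == 1

    def test_tie_breaks_toward_brighter_centroid(self):
        from adipoquant.fcm import MembershipMatrix

        mm = MembershipMatrix(
            memberships=np.array([[0.5, 0.5], [0.7, 0.3]]),
            centroids=np.array([0.2, 0.8]),
            fuzzifier_m=2.0,
            n_iters=1,
            objective=[0.0],
        )
        mask = np.ones((1, 2), bool)
        part = harden(mm, mask, np.array([[0.5, 0.1]]))
        assert part.labels[0, 0] == 1  # tie -> higher-centroid class
        assert part.labels[0, 1] == 0

    def test_phantom_sat_side_brightest_class_covers_fat_ring(self, clean_phantom):
        img, truth = clean_phantom
        k = 1
        sl = img.get_slice(k)
        t = truth.labels[:, :, k]
        sat_side = np.isin(t, [1, 3])  # subcutaneous ring + skin/wall shell
        mm = fcm(sl[sat_side], 3)
        part = harden(mm, sat_side, sl)
        bright = part.labels == 2
        sat_true = t == 1
        assert (bright & sat_true).sum() / sat_true.sum() > 0.9


class TestMergeRegions:
    def _partition(self, means, counts, adjacency):
        labels = np.full((1, 1), -1)  # placeholder grid, not used by the rule
        return RegionPartition(
            labels=labels,
            class_means=np.asarray(means, dtype=float),
            class_counts=np.asarray(counts),
            adjacency=np.asarray(adjacency),
        )

    def test_intensity_and_adjacency_rule(self):
        # classes 0/1 bright and touching; class 2 dark
        labels = np.array([[0, 0, 1, 1, 2, 2]])
        part = RegionPartition(
            labels=labels,
            class_means=np.array([0.9, 0.85, 0.2]),
            class_counts=np.array([2, 2, 2]),
            adjacency=np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]]),
        )
        out = merge_regions(part, intensity_gap=0.1)
        np.testing.assert_array_equal(out, [[1, 1, 1, 1, 0, 0]])

    def test_non_adjacent_class_excluded_even_if_bright(self):
        labels = np.array([[1, 1, 2, 2, 0, 0]])
        part = RegionPartition(
            labels=labels,
            class_means=np.array([0.88, 0.9, 0.2]),
            class_counts=np.array([2, 2, 2]),
            adjacency=np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]]),
        )
        # anchor is class 1; class 0 bright but only touches dark class 2
        out = merge_regions(part, intensity_gap=0.1)
        np.testing.assert_array_equal(out, [[1, 1, 0, 0, 0, 0]])

    def test_vat_phantom_merged_mask_dice(self, default_phantom):
        from adipoquant import dice

        img, truth = default_phantom
        k = 1
        sl = img.get_slice(k)
        t = truth.labels[:, :, k]
        vat_side = np.isin(t, [2, 4])  # interior: visceral fat + organs
        mm = fcm(sl[vat_side], 5)
        part = harden(mm, vat_side, sl)
        merged = merge_regions(part, intensity_gap=0.15)
        assert dice(merged, t == 2) >= 0.85


class TestStripSkinWall:
    def _setup(self):
        yy, xx = np.mgrid[0:80, 0:80]
        r = np.hypot(yy - 40, xx - 40)
        body = r <= 35
        sat = (r > 25) & (r <= 33)  # ring between skin and wall
        wall_phi = LevelSetField(circle_sdf((80, 80), (40, 40), 25.0))
        return sat, body, wall_phi

    def test_zero_depths_identity(self):
        sat, body, phi = self._setup()
        out = strip_skin_wall(sat, body, phi, skin_depth=0, wall_depth=0)
        np.testing.assert_array_equal(out, sat)

    def test_matched_depths_remove_skin_and_wall_bands(self):
        yy, xx = np.mgrid[0:80, 0:80]
        r = np.hypot(yy - 40, xx - 40)
        body = r <= 35
        # fat mask polluted with 2-px skin and 3-px wall shells
        polluted = (r > 22) & (r <= 35)
        phi = LevelSetField(circle_sdf((80, 80), (40, 40), 25.0))
        out = strip_skin_wall(polluted, body, phi, skin_depth=2, wall_depth=3)
        skin_true = body & (r > 33)
        wall_true = (r > 22) & (r <= 25)
        residual = (out & (skin_true | wall_true)).sum()
        assert residual / max(out.sum(), 1) < 0.01

    def test_empty_mask_warns_and_returns_empty(self):
        sat, body, phi = self._setup()
        with pytest.warns(UserWarning):
            out = strip_skin_wall(np.zeros_like(sat), body, phi)
        assert not out.any()

    def test_excessive_depths_warn(self):
        sat, body, phi = self._setup()
        with pytest.warns(UserWarning, match="removed every"):
            strip_skin_wall(sat, body, phi, skin_depth=50, wall_depth=50)
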