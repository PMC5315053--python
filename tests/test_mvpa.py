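"""MVPA stage: z-scoring, sphere geometry, schemes, cross-decoding,
searchlight-oracle equivalence and validity-aware smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hubspoke.mvpa as mvpa_mod
from hubspoke.core import CONDITIONS, VolumeGrid
from hubspoke.glm import BetaPattern
from hubspoke.mvpa import (
    AccuracyMap,
    SearchlightSpec,
    crossval_cross_decode,
    fold_plan,
    make_scheme,
    searchlight,
    smooth_map,
    sphere_offsets,
    zscore_patterns,
)

from conftest import random_patterns


class TestZscore:
    def test_mean_zero_sd_one_per_voxel_per_run(self):
        z = random_patterns(seed=1)
        mean = z.data.mean(axis=1)
        sd = z.data.std(axis=1)
        assert np.max(np.abs(mean)) < 1e-10
        assert np.max(np.abs(sd - 1)) < 1e-10

    def test_idempotent(self):
        z = random_patterns(seed=2)
        z2 = zscore_patterns(z)
        assert np.allclose(z.data, z2.data, atol=1e-12)

    def test_constant_voxel_zeroed_and_flagged(self):
        pattern = random_patterns(seed=3, zscore=False)
        pattern.data[:, :, 0, 0, 0] = 7.0
        z = zscore_patterns(pattern)
        assert np.all(z.data[:, :, 0, 0, 0] == 0)
        assert z.flagged[0, 0, 0]
        assert not z.flagged[1, 1, 1]

    def test_single_condition_rejected(self):
        pattern = random_patterns(seed=4, zscore=False)
        single = BetaPattern(
            data=pattern.data[:, :1],
            conditions=[CONDITIONS[0]],
            grid=pattern.grid,
            mask=pattern.mask,
        )
        with pytest.raises(ValueError):
            zscore_patterns(single)


class TestSphereOffsets:
    def test_lattice_counts_match_bruteforce(self):
        # independent oracle: exhaustive lattice walk
        def brute(radius, vox):
            count = 0
            r = int(np.ceil(radius / min(vox))) + 1
            for i in range(-r, r + 1):
                for j in range(-r, r + 1):
                    for k in range(-r, r + 1):
                        d2 = (i * vox[0]) ** 2 + (j * vox[1]) ** 2 + (k * vox[2]) ** 2
                        count += d2 <= radius**2 + 1e-9
            return count

        assert len(sphere_offsets(6.0, (2, 2, 2))) == brute(6.0, (2, 2, 2)) == 123
        assert len(sphere_offsets(6.0, (3, 3, 3))) == brute(6.0, (3, 3, 3)) == 33

    def test_zero_radius_is_center_only(self):
        off = sphere_offsets(0.0)
        assert off.shape == (1, 3) and np.all(off == 0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        radius=st.floats(0.0, 10.0),
        vox=st.tuples(*[st.floats(1.0, 4.0)] * 3),
    )
    def test_symmetry_and_center(self, radius, vox):
        off = sphere_offsets(radius, vox)
        assert (off == 0).all(axis=1).any()
        as_set = {tuple(o) for o in off}
        assert {tuple(-o) for o in off} == as_set  # point symmetry


class TestSchemes:
    def test_semantic_has_two_directions(self):
        scheme = make_scheme("semantic_feature")
        assert len(scheme.directions) == 2
        for d in scheme.directions:
            assert d.classes == ("AUD", "VIS")

    def test_perceptual_train_nonwords_test_words(self):
        scheme = make_scheme("perceptual")
        (d,) = scheme.directions
        assert set(d.train) == {"Spoken-NON", "Written-NON"}
        assert set(d.test) == {
            "Spoken-AUD", "Spoken-VIS", "Written-AUD", "Written-VIS",
        }
        assert d.classes == ("Spoken", "Written")

    def test_train_test_disjoint_everywhere(self):
        for kind in ("semantic_feature", "perceptual"):
            for d in make_scheme(kind).directions:
                assert not set(d.train) & set(d.test)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_scheme("magic")


class TestCrossDecode:
    def test_fold_accounting(self, monkeypatch):
        calls = {"n": 0}
        orig = mvpa_mod.train_linear_svm

        def counting(*a, **k):
            calls["n"] += 1
            return orig(*a, **k)

        monkeypatch.setattr(mvpa_mod, "train_linear_svm", counting)
        z = random_patterns(seed=5)
        voxels = np.ones(z.grid.shape, dtype=bool)
        assert len(fold_plan(4, make_scheme("semantic_feature"))) == 8
        assert len(fold_plan(4, make_scheme("perceptual"))) == 4
        calls["n"] = 0
        crossval_cross_decode(z, voxels, make_scheme("semantic_feature"))
        assert calls["n"] == 8
        calls["n"] = 0
        crossval_cross_decode(z, voxels, make_scheme("perceptual"))
        assert calls["n"] == 4

    def test_planted_format_independent_pattern_decodes_perfectly(self):
        # identical class patterns across spoken/written, no noise
        rng = np.random.default_rng(6)
        shape = (3, 3, 3)
        pat = {"AUD": rng.standard_normal(shape), "VIS": rng.standard_normal(shape)}
        data = np.zeros((4, len(CONDITIONS), *shape))
        for j, cond in enumerate(CONDITIONS):
            feat = cond.split("-")[1]
            if feat in pat:
                data[:, j] = pat[feat]
        bp = BetaPattern(
            data=data, conditions=list(CONDITIONS),
            grid=VolumeGrid.centered(shape), mask=np.ones(shape, bool),
        )
        z = zscore_patterns(bp)
        acc = crossval_cross_decode(z, np.ones(shape, bool), make_scheme("semantic_feature"))
        assert acc == 1.0

    def test_null_accuracy_at_chance_over_200_simulations(self):
        accs = [
            crossval_cross_decode(
                random_patterns(shape=(3, 3, 3), seed=1000 + i),
                np.ones((3, 3, 3), bool),
                make_scheme("semantic_feature"),
            )
            for i in range(200)
        ]
        accs = np.asarray(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.5) < 3 * se

    def test_two_run_two_voxel_instance_matches_hand_enumeration(self):
        # 2 runs x 2 voxels, semantic scheme. AUD maps to +1 and VIS to -1 on
        # voxel 0 everywhere except run 1's written conditions, where both
        # sit on the negative side (AUD at -0.5, VIS at -1). Every
        # 2-point training set is separable, so each trained boundary is the
        # perpendicular bisector of its class exemplars; enumerating the four
        # fold x direction evaluations by hand:
        #   test run 0, spoken->written: train spoken run 1 (consistent),
        #     test written run 0 (consistent)               -> 2/2
        #   test run 0, written->spoken: train written run 1 (bisector at
        #     x0 = -0.75), both spoken run 0 samples fall on
        #     their own side                                -> 2/2
        #   test run 1, spoken->written: train spoken run 0 (consistent);
        #     written run 1 AUD (-0.5) lands on the VIS side -> 1/2
        #   test run 1, written->spoken: train written run 0 (consistent),
        #     test spoken run 1 (consistent)                -> 2/2
        # mean accuracy = (1 + 1 + 0.5 + 1) / 4 = 0.875
        shape = (2, 1, 1)
        data = np.zeros((2, len(CONDITIONS), *shape))
        vals = {
            (0, "Spoken-AUD"): (1.0, 0.1), (0, "Spoken-VIS"): (-1.0, -0.1),
            (0, "Written-AUD"): (1.0, 0.1), (0, "Written-VIS"): (-1.0, -0.1),
            (1, "Spoken-AUD"): (1.0, 0.1), (1, "Spoken-VIS"): (-1.0, -0.1),
            (1, "Written-AUD"): (-0.5, 0.0), (1, "Written-VIS"): (-1.0, -0.1),
            (0, "Spoken-NON"): (0.0, 0.0), (0, "Written-NON"): (0.0, 0.0),
            (1, "Spoken-NON"): (0.0, 0.0), (1, "Written-NON"): (0.0, 0.0),
        }
        for (run, cond), (v0, v1) in vals.items():
            j = CONDITIONS.index(cond)
            data[run, j, 0, 0, 0] = v0
            data[run, j, 1, 0, 0] = v1
        bp = BetaPattern(
            data=data, conditions=list(CONDITIONS),
            grid=VolumeGrid.centered(shape), mask=np.ones(shape, bool),
        )
        acc = crossval_cross_decode(bp, np.ones(shape, bool), make_scheme("semantic_feature"))
        assert acc == pytest.approx(0.875)

    def test_fewer_than_two_runs_rejected(self):
        z = random_patterns(seed=7)
        one_run = BetaPattern(
            data=z.data[:1], conditions=z.conditions, grid=z.grid,
            mask=z.mask, zscored=True,
        )
        with pytest.raises(ValueError):
            crossval_cross_decode(one_run, np.ones(z.grid.shape, bool), make_scheme("perceptual"))


class TestSearchlight:
    def test_matches_per_voxel_oracle_on_tiny_grid(self):
        shape = (6, 6, 6)
        z = random_patterns(shape=shape, seed=8)
        rng = np.random.default_rng(9)
        mask = rng.random(shape) < 0.6
        mask[0, 0, 0] = True
        spec = SearchlightSpec(radius=4.0, min_voxels=2)
        scheme = make_scheme("semantic_feature")
        amap = searchlight(z, mask, spec, scheme)
        offsets = sphere_offsets(spec.radius, z.grid.voxel_size)
        for center in np.argwhere(mask):
            nb = center + offsets
            ok = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
            nb = nb[ok]
            inside = nb[mask[nb[:, 0], nb[:, 1], nb[:, 2]]]
            c = tuple(center)
            if len(inside) < spec.min_voxels:
                assert not amap.valid[c]
                continue
            expected = crossval_cross_decode(
                z, (inside[:, 0], inside[:, 1], inside[:, 2]), scheme
            )
            assert amap.valid[c]
            assert amap.values[c] == pytest.approx(expected, abs=0)

    def test_outside_mask_invalid(self):
        z = random_patterns(shape=(5, 5, 5), seed=10)
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = mask[2, 2, 3] = mask[2, 3, 2] = True
        amap = searchlight(z, mask, SearchlightSpec(radius=4.0), make_scheme("perceptual"))
        assert not amap.valid[~mask].any()
        assert np.isnan(amap.values[~mask]).all()

    def test_deterministic(self):
        z = random_patterns(shape=(5, 5, 5), seed=11)
        mask = np.ones((5, 5, 5), bool)
        a = searchlight(z, mask, SearchlightSpec(radius=3.0), make_scheme("perceptual"))
        b = searchlight(z, mask, SearchlightSpec(radius=3.0), make_scheme("perceptual"))
        assert np.array_equal(a.values, b.values, equal_nan=True)
        assert np.array_equal(a.valid, b.valid)

    def test_requires_zscored_patterns(self):
        raw = random_patterns(seed=12, zscore=False)
        with pytest.raises(ValueError, match="z-scored"):
            searchlight(raw, np.ones(raw.grid.shape, bool))


class TestSmoothing:
    def test_constant_valid_map_unchanged(self):
        grid = VolumeGrid.centered((8, 8, 8))
        rng = np.random.default_rng(13)
        valid = rng.random((8, 8, 8)) < 0.7
        values = np.where(valid, 0.6, np.nan)
        amap = AccuracyMap(grid=grid, values=values, valid=valid)
        out = smooth_map(amap, fwhm=6.0)
        assert np.allclose(out.values[valid], 0.6, atol=1e-10)
        assert np.isnan(out.values[~valid]).all()

    def test_zero_fwhm_identity(self):
        z = random_patterns(shape=(4, 4, 4), seed=14)
        vals = z.data[0, 0]
        out = smooth_map(vals, 0.0, voxel_size=(2, 2, 2))
        assert np.allclose(out, vals, atol=0)

    def test_impulse_matches_discretized_gaussian(self):
        shape = (15, 15, 15)
        values = np.zeros(shape)
        values[7, 7, 7] = 1.0
        fwhm, vox = 6.0, 2.0
        out = smooth_map(values, fwhm, voxel_size=(vox,) * 3, valid=np.ones(shape, bool))
        sigma_vox = fwhm / np.sqrt(8 * np.log(2)) / vox
        ax = np.arange(shape[0]) - 7
        g1 = np.exp(-(ax**2) / (2 * sigma_vox**2))
        g1 /= g1.sum()
        expected = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        assert np.allclose(out, expected, atol=1e-6)
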