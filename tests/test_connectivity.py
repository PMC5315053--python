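"""Connectivity stage: seed geometry, CompCor, confound regression,
Fisher-z seed maps, paired contrasts and template overlap."""

import numpy as np
import pandas as pd
import pytest

from hubspoke.connectivity import (
    SeedROI,
    build_confounds,
    compcor,
    network_overlap,
    regress_confounds,
    seed_contrast,
    seed_map,
    sphere_roi_mask,
)
from hubspoke.core import BoldRun, VolumeGrid
from hubspoke.phantom import make_phantom_truth, simulate_rest_subject


def white_run(shape=(8, 8, 8), n=180, seed=0, tr=3.0):
    rng = np.random.default_rng(seed)
    return BoldRun(
        grid=VolumeGrid.centered(shape), tr=tr,
        data=100.0 + rng.standard_normal((*shape, n)),
    )


class TestSeedGeometry:
    def test_tiny_radius_single_voxel(self):
        grid = VolumeGrid.centered((9, 9, 9))
        mask = sphere_roi_mask(SeedROI("pt", (0.0, 0.0, 0.0), 0.1), grid)
        assert mask.sum() == 1

    def test_three_mm_radius_on_two_mm_grid_matches_lattice_count(self):
        # brute-force lattice oracle: integer offsets with (2i)^2 + (2j)^2 +
        # (2k)^2 <= 9, i.e. i^2+j^2+k^2 <= 2.25 — the center, 6 face
        # neighbours and 12 edge diagonals (norm^2 = 2) = 19 voxels
        count = sum(
            1
            for i in range(-2, 3)
            for j in range(-2, 3)
            for k in range(-2, 3)
            if i * i + j * j + k * k <= 2.25
        )
        grid = VolumeGrid.centered((9, 9, 9))
        mask = sphere_roi_mask(SeedROI("seed", (0.0, 0.0, 0.0), 3.0), grid)
        assert mask.sum() == count == 19

    def test_translation_by_voxel_pitch_preserves_count(self):
        grid = VolumeGrid.centered((11, 11, 11))
        a = sphere_roi_mask(SeedROI("a", (0.0, 0.0, 0.0), 3.0), grid)
        b = sphere_roi_mask(SeedROI("b", (2.0, 0.0, 0.0), 3.0), grid)
        assert a.sum() == b.sum()

    def test_center_outside_grid_rejected(self):
        grid = VolumeGrid.centered((9, 9, 9))
        with pytest.raises(ValueError):
            sphere_roi_mask(SeedROI("far", (100.0, 0.0, 0.0), 3.0), grid)


class TestCompcor:
    def planted_run(self, seed=0, physio_sd=1.0, noise_sd=0.05):
        rng = np.random.default_rng(seed)
        shape, n = (6, 6, 6), 150
        physio = rng.standard_normal(n) * physio_sd
        data = 100.0 + noise_sd * rng.standard_normal((*shape, n))
        wm = np.zeros(shape, bool)
        wm[:2] = True
        csf = np.zeros(shape, bool)
        csf[-1] = True
        data[wm | csf] += physio
        run = BoldRun(grid=VolumeGrid.centered(shape), tr=3.0, data=data)
        return run, wm, csf, physio

    def test_recovers_planted_physiological_signal(self):
        run, wm, csf, physio = self.planted_run(1)
        comp = compcor(run, wm, csf, k=3)
        r = np.corrcoef(comp["compcor_1"], physio)[0, 1]
        assert abs(r) > 0.99

    def test_components_orthonormal(self):
        run, wm, csf, _ = self.planted_run(2, noise_sd=1.0)
        comp = compcor(run, wm, csf, k=5).to_numpy()
        gram = comp.T @ comp
        assert np.allclose(gram, np.eye(5), atol=1e-8)

    def test_noise_only_top_share_consistent_with_marchenko_pastur_null(self):
        # oracle: simulate the null distribution of the top-eigenvalue share
        # for white-noise standardized voxel time series of matching size
        run, wm, csf, _ = self.planted_run(3, physio_sd=0.0, noise_sd=1.0)
        comp = compcor(run, wm, csf, k=1)
        mask = wm | csf
        ts = run.data[mask]
        ts = (ts - ts.mean(axis=1, keepdims=True)) / ts.std(axis=1, keepdims=True)
        s = np.linalg.svd(ts.T, compute_uv=False)
        share = s[0] ** 2 / np.sum(s**2)
        # component 1 must be the top left-singular vector (up to sign)
        u1 = np.linalg.svd(ts.T, full_matrices=False)[0][:, 0]
        assert min(
            np.max(np.abs(comp["compcor_1"] - u1)),
            np.max(np.abs(comp["compcor_1"] + u1)),
        ) < 1e-8
        rng = np.random.default_rng(4)
        null_shares = []
        for _ in range(60):
            z = rng.standard_normal(ts.shape)
            z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
            sn = np.linalg.svd(z.T, compute_uv=False)
            null_shares.append(sn[0] ** 2 / np.sum(sn**2))
        lo, hi = np.quantile(null_shares, [0.0, 1.0])
        assert lo * 0.9 <= share <= hi * 1.1

    def test_empty_masks_rejected(self):
        run, _, _, _ = self.planted_run(5)
        empty = np.zeros(run.grid.shape, bool)
        with pytest.raises(ValueError):
            compcor(run, empty, empty)

    def test_rank_deficit_warns_and_truncates(self):
        shape, n = (4, 4, 4), 50
        t = np.linspace(0, 1, n)
        data = np.full((*shape, n), 100.0) + np.sin(2 * np.pi * t)  # rank-1 signal
        run = BoldRun(grid=VolumeGrid.centered(shape), tr=3.0, data=data)
        wm = np.zeros(shape, bool)
        wm[0] = True
        with pytest.warns(UserWarning, match="rank"):
            comp = compcor(run, wm, np.zeros(shape, bool), k=5)
        assert comp.shape[1] < 5


class TestRegressConfounds:
    def test_residuals_orthogonal_to_confounds(self):
        run = white_run(seed=6)
        rng = np.random.default_rng(7)
        conf = pd.DataFrame(rng.standard_normal((run.n_scans, 4)), columns=list("abcd"))
        clean = regress_confounds(run, conf, band=None)
        Y = clean.data.reshape(-1, run.n_scans)
        inner = Y @ conf.to_numpy()
        assert np.max(np.abs(inner)) < 1e-6 * np.linalg.norm(run.data)

    def test_injected_confound_removed(self):
        rng = np.random.default_rng(8)
        shape, n = (6, 6, 6), 180
        confound = rng.standard_normal(n)
        loadings = rng.standard_normal(shape)
        data = 100.0 + loadings[..., None] * confound + 0.5 * rng.standard_normal((*shape, n))
        run = BoldRun(grid=VolumeGrid.centered(shape), tr=3.0, data=data)
        clean = regress_confounds(run, pd.DataFrame({"c": confound}), band=None)
        Y = clean.data.reshape(-1, n)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        c = confound - confound.mean()
        r = (Yc @ c) / (np.linalg.norm(Yc, axis=1) * np.linalg.norm(c) + 1e-30)
        assert np.max(np.abs(r)) < 0.05

    def test_projection_idempotent_before_filtering(self):
        run = white_run(seed=9)
        rng = np.random.default_rng(10)
        conf = pd.DataFrame(rng.standard_normal((run.n_scans, 3)), columns=list("xyz"))
        once = regress_confounds(run, conf, band=None)
        twice = regress_confounds(once, conf, band=None)
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_collinear_confounds_dropped_with_warning(self):
        run = white_run(seed=11)
        rng = np.random.default_rng(12)
        a = rng.standard_normal(run.n_scans)
        conf = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.warns(UserWarning, match="collinear"):
            regress_confounds(run, conf, band=None)

    def test_band_filter_removes_fast_and_slow_components(self):
        n, tr = 200, 3.0
        t = np.arange(n) * tr
        slow = np.sin(2 * np.pi * t / 500.0)   # period 500 s, below high-pass
        fast = np.sin(2 * np.pi * t * 0.15)    # 0.15 Hz, above low-pass
        keep = np.sin(2 * np.pi * t * 0.04)    # in band
        shape = (2, 2, 2)
        data = np.broadcast_to(100.0 + slow + fast + keep, (*shape, n)).copy()
        run = BoldRun(grid=VolumeGrid.centered(shape), tr=tr, data=data)
        clean = regress_confounds(run, None, band=(100.0, 2.8))
        out = clean.data[0, 0, 0]
        for comp, should_keep in ((slow, False), (fast, False), (keep, True)):
            share = abs(np.dot(out - out.mean(), comp)) / np.dot(comp, comp)
            assert (share > 0.5) == should_keep


class TestSeedMap:
    def test_seed_interior_flagged_and_capped(self):
        run = white_run(seed=13)
        mask = np.zeros(run.grid.shape, bool)
        mask[4, 4, 4] = True
        cmap = seed_map(run, mask, "self")
        assert cmap.seed_mask[4, 4, 4]
        assert np.isfinite(cmap.z[4, 4, 4])
        assert abs(cmap.z[4, 4, 4]) <= np.arctanh(0.999999) + 1e-9

    def test_white_noise_mean_z_within_null_tolerance(self):
        run = white_run(shape=(10, 10, 10), n=180, seed=14)
        mask = np.zeros(run.grid.shape, bool)
        mask[0, 0, 0] = True
        cmap = seed_map(run, mask, "null")
        z = cmap.z[cmap.valid & ~cmap.seed_mask]
        n_vox = z.size
        assert n_vox >= 999
        tol = 3.0 * (1.0 / np.sqrt(180 - 3)) / np.sqrt(n_vox)
        assert abs(np.mean(z)) < tol

    def test_fisher_z_null_variance_matches_theory(self):
        run = white_run(shape=(12, 12, 12), n=180, seed=15)
        mask = np.zeros(run.grid.shape, bool)
        mask[0, 0, 0] = True
        z = seed_map(run, mask, "null").z
        var = np.nanvar(z[~mask])
        assert abs(var - 1.0 / (180 - 3)) < 0.1 / (180 - 3)

    def test_zero_variance_seed_rejected(self):
        shape = (4, 4, 4)
        data = np.full((*shape, 50), 100.0)
        data[2:] += np.random.default_rng(16).standard_normal((2, 4, 4, 50))
        run = BoldRun(grid=VolumeGrid.centered(shape), tr=3.0, data=data)
        mask = np.zeros(shape, bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="zero variance"):
            seed_map(run, mask)

    def test_network_voxels_couple_to_their_seed(self, small_atlas):
        truth = make_phantom_truth(small_atlas, seed=17)
        run = simulate_rest_subject(truth, n_timepoints=180, seed=18)
        seed_mask = np.zeros(small_atlas.grid.shape, bool)
        idx = np.argwhere(truth.network_territories[0])[:5]
        seed_mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        cmap = seed_map(run, seed_mask, "net1")
        in1 = truth.network_territories[0] & ~seed_mask
        in2 = truth.network_territories[1]
        from scipy.stats import mannwhitneyu

        stat = mannwhitneyu(cmap.z[in1], cmap.z[in2], alternative="greater")
        assert np.mean(cmap.z[in1]) > np.mean(cmap.z[in2])
        assert stat.pvalue < 1e-3


class TestSeedContrast:
    def make_cohort(self, seed, n=6, shape=(7, 7, 7), offset=0.0):
        rng = np.random.default_rng(seed)
        grid = VolumeGrid.centered(shape)
        maps = []
        for s in range(n):
            run = BoldRun(
                grid=grid, tr=3.0,
                data=100 + rng.standard_normal((*shape, 60)),
            )
            mask = np.zeros(shape, bool)
            mask[0, 0, 0] = True
            m = seed_map(run, mask, "s", subject=s)
            m.z = m.z + offset
            maps.append(m)
        return maps

    def test_identical_inputs_give_empty_cluster_table(self):
        maps = self.make_cohort(19)
        res = seed_contrast(maps, maps, n_perm=150, seed=3)
        assert len(res.clusters) == 0

    def test_swapping_sides_negates_the_stat_map(self):
        a = self.make_cohort(20)
        b = self.make_cohort(21, offset=0.05)
        r_ab = seed_contrast(a, b, n_perm=120, seed=4)
        r_ba = seed_contrast(b, a, n_perm=120, seed=4)
        both = r_ab.valid & r_ba.valid
        assert np.allclose(r_ab.z_map[both], -r_ba.z_map[both], atol=1e-9)

    def test_unpaired_inputs_rejected(self):
        a = self.make_cohort(22)
        with pytest.raises(ValueError, match="unpaired"):
            seed_contrast(a, a[:-1])


class TestNetworkOverlap:
    def test_identity_with_one_disjoint_template(self):
        shape = (6, 6, 6)
        t1 = np.zeros(shape, bool)
        t1[:3] = True
        t2 = ~t1
        table = network_overlap(t1, {"one": t1, "two": t2}).set_index("network")
        assert table.loc["one", "proportion"] == 1.0
        assert table.loc["two", "proportion"] == 0.0

    def test_constructed_half_overlap(self):
        shape = (4, 4, 4)
        tpl = np.zeros(shape, bool)
        tpl[:2] = True
        mapped = np.zeros(shape, bool)
        mapped[1:3] = True  # half inside the template
        table = network_overlap(mapped, {"tpl": tpl}).set_index("network")
        assert table.loc["tpl", "proportion"] == 0.5

    def test_disjoint_proportions_sum_below_one(self):
        rng = np.random.default_rng(23)
        shape = (6, 6, 6)
        mapped = rng.random(shape) < 0.4
        t1 = np.zeros(shape, bool)
        t1[:2] = True
        t2 = np.zeros(shape, bool)
        t2[4:] = True
        table = network_overlap(mapped, {"a": t1, "b": t2})
        assert table["proportion"].sum() <= 1.0 + 1e-12

    def test_empty_map_flagged(self):
        shape = (4, 4, 4)
        table = network_overlap(np.zeros(shape, bool), {"t": np.ones(shape, bool)})
        assert table.attrs["empty_map"]
        assert table["overlap_voxels"].eq(0).all()
        assert table["proportion"].isna().all()


def test_confound_table_assembly():
    comp = pd.DataFrame({"compcor_1": np.arange(5.0)})
    motion = np.ones((5, 6))
    table = build_confounds(comp, motion)
    assert list(table.columns) == ["compcor_1"] + [f"motion_{i}" for i in range(1, 7)]
    with pytest.raises(ValueError):
        build_confounds(None, None)
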