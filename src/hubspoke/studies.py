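"""Cohort-level phantom studies.

These functions wire the full analysis chain together at desk scale and are
the package's main entry points for validation studies and demos:

* :func:`null_searchlight_accuracy` — the searchlight's calibration under a
  null phantom in which multivoxel patterns are independent of the condition
  labels (mean sphere accuracy should sit at chance);
* :func:`group_fwe_calibration` — empirical family-wise error of the
  sign-flip cluster test on simulated null cohorts;
* :func:`dissociation_study` — recovery of the planted hub/modality double
  dissociation by the two cross-decoding searchlights, group cluster tests
  and the 2x2 repeated-measures ANOVA;
* :func:`connectivity_study` — recovery of the two seed-anchored resting
  networks by seed contrasts, and the effect of CompCor on off-network
  spurious connectivity under a shared physiological confound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .connectivity import (
    SeedROI,
    build_confounds,
    compcor,
    regress_confounds,
    seed_contrast,
    seed_map,
    sphere_roi_mask,
)
from .core import CONDITIONS, VolumeGrid
from .glm import fit_task_subject
from .group import AnovaResult, dissociation_anova, group_chance_test
from .mvpa import (
    AccuracyMap,
    SearchlightSpec,
    make_scheme,
    searchlight,
    smooth_map,
    zscore_patterns,
)
from .phantom import (
    AtlasConfig,
    RegionAtlas,
    Role,
    TaskNoise,
    TruthConfig,
    generate_block_design,
    make_phantom_atlas,
    make_phantom_truth,
    null_truth_config,
    simulate_rest_subject,
    simulate_task_subject,
    small_atlas_config,
)

SCHEMES = ("semantic_feature", "perceptual")


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic child seeds (< 2**31) from one master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def simulate_subject_patterns(
    truth,
    seed: int,
    tr: float = 2.0,
    noise: TaskNoise | None = None,
    n_runs: int = 4,
    block_duration: float = 18.0,
    mask: np.ndarray | None = None,
    subject=None,
):
    """One phantom subject end to end: design -> BOLD -> GLM -> z-scored betas."""
    s_design, s_sim = _spawn_seeds(seed, 2)
    design = generate_block_design(
        n_runs=n_runs, block_duration=block_duration, seed=int(s_design)
    )
    runs = simulate_task_subject(truth, design, tr=tr, noise=noise, seed=int(s_sim))
    if mask is None:
        mask = truth.atlas.brain_mask
    _, pattern = fit_task_subject(
        runs, design, conditions=CONDITIONS, mask=mask, subject=subject
    )
    return zscore_patterns(pattern)


# ---------------------------------------------------------------------------
# Null calibration


def null_searchlight_accuracy(
    n_datasets: int = 200,
    seed: int = 0,
    atlas_config: AtlasConfig | None = None,
    mask_role: Role = Role.SEMANTIC_HUB,
    scheme: str = "semantic_feature",
    radius: float = 6.0,
    noise: TaskNoise | None = None,
) -> np.ndarray:
    """Mean searchlight accuracy per dataset under the label-independent null.

    Each dataset is a full 4-run phantom session whose data contain no
    condition-dependent structure; the searchlight runs over the hub region
    and the per-dataset mean of the valid sphere accuracies is returned.
    Under the null this distribution is centred on chance (0.5).
    """
    atlas = make_phantom_atlas(atlas_config)
    mask = atlas.mask(mask_role)
    scheme_obj = make_scheme(scheme)
    spec = SearchlightSpec(radius=radius)
    cfg = null_truth_config()
    seeds = _spawn_seeds(seed, n_datasets * 2).reshape(n_datasets, 2)
    means = np.empty(n_datasets)
    for i in range(n_datasets):
        truth = make_phantom_truth(atlas, cfg, seed=int(seeds[i, 0]))
        patterns = simulate_subject_patterns(
            truth, seed=int(seeds[i, 1]), noise=noise, mask=mask, subject=i
        )
        amap = searchlight(patterns, mask, spec, scheme_obj)
        means[i] = np.nanmean(amap.values[amap.valid])
    return means


def group_fwe_calibration(
    n_cohorts: int = 200,
    n_subjects: int = 12,
    shape=(14, 14, 14),
    noise_sd: float = 0.05,
    smooth_sigma: float = 1.5,
    chance: float = 0.5,
    cluster_forming_z: float = 2.3,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical FWE of the cluster permutation test on null cohorts.

    Subject maps are smoothed Gaussian noise centred on chance (spatial
    correlation mimicking smoothed accuracy maps, no true effect anywhere);
    the returned ``fwe_rate`` is the fraction of cohorts in which any
    cluster survives correction at ``alpha``, which should not exceed the
    nominal level beyond Monte-Carlo error.
    """
    grid = VolumeGrid.centered(shape)
    valid = np.ones(shape, dtype=bool)
    rng = np.random.default_rng(seed)
    group_seeds = _spawn_seeds(seed + 1, n_cohorts)
    hits = 0
    for c in range(n_cohorts):
        maps = []
        for _ in range(n_subjects):
            noise = gaussian_filter(rng.standard_normal(shape), smooth_sigma)
            sd = noise.std()
            maps.append(chance + noise / sd * noise_sd)
        res = group_chance_test(
            (grid, np.stack(maps), valid),
            chance=chance,
            cluster_forming_z=cluster_forming_z,
            n_perm=n_perm,
            seed=int(group_seeds[c]),
        )
        if len(res.significant(alpha)):
            hits += 1
    return {"fwe_rate": hits / n_cohorts, "n_cohorts": n_cohorts, "alpha": alpha}


# ---------------------------------------------------------------------------
# Dissociation recovery


@dataclass
class DissociationStudyResult:
    """Cohort searchlight + ANOVA outcome against the planted ground truth."""

    atlas: RegionAtlas
    group_results: dict          # scheme -> GroupResult
    coverage: dict               # scheme -> {region name -> covered fraction}
    subject_maps: dict           # scheme -> list of smoothed AccuracyMap
    roi_table: pd.DataFrame      # subject x region x classifier accuracies
    anova: AnovaResult
    alpha: float

    def dissociated(
        self, min_coverage: float = 0.5, max_off_coverage: float = 0.2
    ) -> bool:
        """True when the planted double dissociation is fully recovered:
        each scheme's significant clusters cover its own region and spare the
        other, the region x classifier interaction is significant, and both
        simple effects point in the planted directions."""
        cov_s = self.coverage["semantic_feature"]
        cov_p = self.coverage["perceptual"]
        hub, mod = "semantic_hub", "modality_region"
        clusters_ok = (
            cov_s[hub] >= min_coverage
            and cov_s[mod] <= max_off_coverage
            and cov_p[mod] >= min_coverage
            and cov_p[hub] <= max_off_coverage
        )
        inter_ok = self.anova.effects.loc["interaction", "p"] < self.alpha
        post = self.anova.posthoc.set_index("classifier")
        # contrast is modality_region - semantic_hub (sorted level order)
        simple_ok = (
            post.loc["perceptual", "p"] < self.alpha
            and post.loc["perceptual", "mean_diff"] > 0
            and post.loc["semantic_feature", "p"] < self.alpha
            and post.loc["semantic_feature", "mean_diff"] < 0
        )
        return bool(clusters_ok and inter_ok and simple_ok)


def roi_mean_accuracy(amap: AccuracyMap, roi: np.ndarray) -> float:
    """Mean valid searchlight accuracy inside an ROI."""
    sel = amap.valid & np.asarray(roi, dtype=bool)
    if not sel.any():
        return np.nan
    return float(np.nanmean(amap.values[sel]))


def dissociation_study(
    seed: int = 0,
    n_subjects: int = 12,
    atlas_config: AtlasConfig | None = None,
    truth_config: TruthConfig | None = None,
    noise: TaskNoise | None = None,
    radius: float = 6.0,
    fwhm: float = 6.0,
    cluster_forming_z: float = 2.3,
    n_perm: int = 500,
    alpha: float = 0.05,
) -> DissociationStudyResult:
    """Run the full task pipeline on one phantom cohort.

    Both cross-decoding searchlights are run over the union of the two
    planted ATL-like regions; smoothed accuracy maps enter the group cluster
    test against chance, and region-mean accuracies enter the 2x2
    repeated-measures ANOVA (region x classifier).
    """
    atlas_config = atlas_config or small_atlas_config()
    atlas = make_phantom_atlas(atlas_config)
    hub = atlas.mask(Role.SEMANTIC_HUB)
    mod = atlas.mask(Role.MODALITY_REGION)
    mask = hub | mod
    spec = SearchlightSpec(radius=radius)
    subject_seeds = _spawn_seeds(seed, n_subjects * 2).reshape(n_subjects, 2)
    group_seeds = _spawn_seeds(seed + 1, len(SCHEMES))

    subject_maps = {s: [] for s in SCHEMES}
    roi_rows = []
    for s in range(n_subjects):
        truth = make_phantom_truth(atlas, truth_config, seed=int(subject_seeds[s, 0]))
        patterns = simulate_subject_patterns(
            truth, seed=int(subject_seeds[s, 1]), noise=noise, mask=mask, subject=s
        )
        for scheme_name in SCHEMES:
            amap = searchlight(patterns, mask, spec, make_scheme(scheme_name))
            subject_maps[scheme_name].append(smooth_map(amap, fwhm))
            for region_name, roi in (("semantic_hub", hub), ("modality_region", mod)):
                roi_rows.append(
                    {
                        "subject": s,
                        "region": region_name,
                        "classifier": scheme_name,
                        "accuracy": roi_mean_accuracy(amap, roi),
                    }
                )

    group_results, coverage = {}, {}
    for j, scheme_name in enumerate(SCHEMES):
        res = group_chance_test(
            subject_maps[scheme_name],
            chance=0.5,
            cluster_forming_z=cluster_forming_z,
            n_perm=n_perm,
            seed=int(group_seeds[j]),
        )
        sig = res.significant_mask(alpha)
        group_results[scheme_name] = res
        coverage[scheme_name] = {
            "semantic_hub": float(np.sum(sig & hub) / hub.sum()),
            "modality_region": float(np.sum(sig & mod) / mod.sum()),
        }

    roi_table = pd.DataFrame(roi_rows)
    return DissociationStudyResult(
        atlas=atlas,
        group_results=group_results,
        coverage=coverage,
        subject_maps=subject_maps,
        roi_table=roi_table,
        anova=dissociation_anova(roi_table),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Connectivity recovery


@dataclass
class ConnectivityStudyResult:
    atlas: RegionAtlas
    contrasts: dict              # 'network_1>network_2' etc -> GroupResult
    territory_coverage: dict     # network index -> covered fraction of exclusive territory
    offnet_abs_z: dict           # {'compcor': mean |z|, 'no_compcor': mean |z|}
    seed_names: tuple
    alpha: float

    def recovered(self, min_coverage: float = 0.5) -> bool:
        return all(v >= min_coverage for v in self.territory_coverage.values())


def connectivity_study(
    seed: int = 0,
    n_subjects: int = 12,
    atlas_config: AtlasConfig | None = None,
    truth_config: TruthConfig | None = None,
    rest_params=None,
    n_timepoints: int = 180,
    tr: float = 3.0,
    k_compcor: int = 5,
    seed_radius_mm: float = 3.0,
    cluster_forming_z: float = 2.3,
    n_perm: int = 300,
    alpha: float = 0.05,
) -> ConnectivityStudyResult:
    """Seed connectivity recovery on one resting phantom cohort.

    Each subject's rest run is cleaned twice — with CompCor + motion
    confounds, and with motion only — and Fisher-z seed maps are computed
    for spherical seeds at the two network anchors. The paired seed
    contrasts (each network's seed > the other) are tested at the group
    level, and recovery is scored as the covered fraction of each network's
    exclusive territory (territory voxels outside both seed spheres).
    """
    atlas_config = atlas_config or small_atlas_config()
    atlas = make_phantom_atlas(atlas_config)
    truth0 = make_phantom_truth(atlas, truth_config, seed=0)
    centers = truth0.network_seed_centers()
    seeds_roi = [
        SeedROI("network_1_seed", centers[0], seed_radius_mm),
        SeedROI("network_2_seed", centers[1], seed_radius_mm),
    ]
    seed_masks = [sphere_roi_mask(s, atlas.grid) for s in seeds_roi]
    wm, csf = atlas.mask(Role.WHITE_MATTER), atlas.mask(Role.CSF)
    subject_seeds = _spawn_seeds(seed, n_subjects * 2).reshape(n_subjects, 2)
    group_seeds = _spawn_seeds(seed + 1, 2)

    maps_cc = {0: [], 1: []}
    maps_plain = {0: [], 1: []}
    for s in range(n_subjects):
        truth = make_phantom_truth(atlas, truth_config, seed=int(subject_seeds[s, 0]))
        run = simulate_rest_subject(
            truth, n_timepoints=n_timepoints, tr=tr, params=rest_params,
            seed=int(subject_seeds[s, 1]),
        )
        cc = compcor(run, wm, csf, k=k_compcor)
        conf_cc = build_confounds(cc, run.motion_params)
        conf_plain = build_confounds(None, run.motion_params)
        clean_cc = regress_confounds(run, conf_cc)
        clean_plain = regress_confounds(run, conf_plain)
        for j, smask in enumerate(seed_masks):
            maps_cc[j].append(seed_map(clean_cc, smask, seeds_roi[j].name, subject=s))
            maps_plain[j].append(seed_map(clean_plain, smask, seeds_roi[j].name, subject=s))

    contrasts = {}
    coverage = {}
    for j in (0, 1):
        other = 1 - j
        res = seed_contrast(
            maps_cc[j], maps_cc[other],
            cluster_forming_z=cluster_forming_z, n_perm=n_perm,
            seed=int(group_seeds[j]),
        )
        contrasts[f"network_{j + 1}>network_{other + 1}"] = res
        territory = truth0.network_territories[j] & ~seed_masks[0] & ~seed_masks[1]
        sig = res.significant_mask(alpha)
        coverage[j + 1] = float(np.sum(sig & territory) / territory.sum())

    offnet = atlas.brain_mask & ~truth0.network_territories[0] & ~truth0.network_territories[1]
    def _mean_abs_z(maps):
        return float(np.mean([np.nanmean(np.abs(m.z[offnet & m.valid])) for m in maps]))
    offnet_abs_z = {
        "compcor": _mean_abs_z(maps_cc[0] + maps_cc[1]),
        "no_compcor": _mean_abs_z(maps_plain[0] + maps_plain[1]),
    }
    return ConnectivityStudyResult(
        atlas=atlas,
        contrasts=contrasts,
        territory_coverage=coverage,
        offnet_abs_z=offnet_abs_z,
        seed_names=tuple(s.name for s in seeds_roi),
        alpha=alpha,
    )
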