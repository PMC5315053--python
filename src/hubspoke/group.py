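"""Group inference shared by the MVPA and connectivity stages.

One-sample tests against a reference level (chance accuracy, or zero
connectivity difference) with cluster-level family-wise-error correction by
sign-flipping permutation: the maximum-cluster-mass statistic of each
permuted cohort builds the null distribution, which controls FWE at the
cluster level without Gaussian-random-field assumptions. The same machinery
also provides the 2x2 repeated-measures ANOVA used to test the regional
dissociation of classifier accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from .core import VolumeGrid
from .mvpa import AccuracyMap


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t statistics to standard-normal quantiles, tail-accurately."""
    t = np.asarray(t, dtype=float)
    sf = special.stdtr(df, -np.abs(t))
    z = -special.ndtri(np.clip(sf, 1e-300, 1.0))
    return np.sign(t) * z


def _z_to_t_threshold(z: float, df: int) -> float:
    """t value whose upper tail probability matches that of z."""
    return float(special.stdtrit(df, special.ndtr(z)))


@dataclass
class GroupResult:
    """Cluster-corrected one-sample group test result."""

    z_map: np.ndarray
    valid: np.ndarray
    clusters: pd.DataFrame
    grid: VolumeGrid
    params: dict

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.clusters[self.clusters["p_corrected"] < alpha]

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        mask = np.zeros(self.z_map.shape, dtype=bool)
        labels = self.params["_cluster_labels"]
        for lab in self.significant(alpha)["label"]:
            mask |= labels == lab
        return mask


def _cluster_stats(t_flat, z_flat, idx, shape, t_thr, structure):
    """Label suprathreshold clusters; return (labels_3d, list of (label, mass, size, peak))."""
    supra = t_flat >= t_thr
    vol = np.zeros(shape, dtype=bool)
    vol[idx[0][supra], idx[1][supra], idx[2][supra]] = True
    labels, n_lab = ndimage.label(vol, structure=structure)
    out = []
    if n_lab:
        z_vol = np.zeros(shape)
        z_vol[idx[0][supra], idx[1][supra], idx[2][supra]] = z_flat[supra]
        for lab in range(1, n_lab + 1):
            members = labels == lab
            mass = float(z_vol[members].sum())
            size = int(members.sum())
            peak = np.unravel_index(np.argmax(np.where(members, z_vol, -np.inf)), shape)
            out.append((lab, mass, size, peak))
    return labels, out


def group_chance_test(
    maps,
    chance: float = 0.5,
    cluster_forming_z: float = 2.3,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> GroupResult:
    """One-sample group test of subject maps against a reference level.

    A voxelwise one-sample t statistic of (value - chance) is converted to a
    z map; clusters are formed at ``z >= cluster_forming_z`` (26-connectivity)
    and assigned family-wise-error corrected p values from the permutation
    distribution of the maximum cluster mass under random sign flips of the
    per-subject difference maps. One-sided (greater than reference).
    """
    if isinstance(maps[0], AccuracyMap):
        grid = maps[0].grid
        data = np.stack([m.values for m in maps])
        valid = np.all([m.valid for m in maps], axis=0)
    else:
        grid, data, valid = maps  # (grid, (n, x, y, z) array, valid mask)
        data = np.asarray(data, dtype=float)
        valid = np.asarray(valid, dtype=bool)
    n = data.shape[0]
    if n < 5:
        raise ValueError("group test needs >= 5 subjects")
    params = {
        "chance": chance,
        "cluster_forming_z": cluster_forming_z,
        "n_perm": n_perm,
        "seed": seed,
        "warnings": [],
    }
    if n_perm < 100:
        params["warnings"].append(f"n_perm={n_perm} < 100: corrected p values are coarse")
        warnings.warn(params["warnings"][-1])

    shape = data.shape[1:]
    valid = valid & np.all(np.isfinite(data), axis=0)
    d = data - chance
    sd = d.std(axis=0, ddof=1)
    valid = valid & (sd > 0)
    idx = np.nonzero(valid)
    D = d[:, idx[0], idx[1], idx[2]]  # (n, V)
    df = n - 1
    t_thr = _z_to_t_threshold(cluster_forming_z, df)
    structure = np.ones((3, 3, 3), dtype=bool)

    def t_stat(mat):
        m = mat.mean(axis=0)
        s = mat.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(s > 0, m / (s / np.sqrt(n)), 0.0)

    t_obs = t_stat(D)
    z_obs = _t_to_z(t_obs, df)
    labels, clusters = _cluster_stats(t_obs, z_obs, idx, shape, t_thr, structure)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        t_p = t_stat(D * signs[:, None])
        supra = t_p >= t_thr
        if not np.any(supra):
            continue
        z_p = _t_to_z(t_p[supra], df)
        vol = np.zeros(shape, dtype=bool)
        vol[idx[0][supra], idx[1][supra], idx[2][supra]] = True
        lab_p, n_lab = ndimage.label(vol, structure=structure)
        if n_lab:
            z_vol = np.zeros(shape)
            z_vol[idx[0][supra], idx[1][supra], idx[2][supra]] = z_p
            null_max[p] = ndimage.sum_labels(z_vol, lab_p, index=range(1, n_lab + 1)).max()

    z_vol = np.full(shape, np.nan)
    z_vol[idx] = z_obs
    rows = []
    for lab, mass, size, peak in clusters:
        p_corr = (1.0 + np.sum(null_max >= mass)) / (n_perm + 1.0)
        peak_mm = grid.voxel_to_mm(peak)
        rows.append(
            {
                "label": lab,
                "size_voxels": size,
                "mass": mass,
                "peak_x_mm": peak_mm[0],
                "peak_y_mm": peak_mm[1],
                "peak_z_mm": peak_mm[2],
                "peak_z_stat": float(z_vol[peak]),
                "p_corrected": p_corr,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "label", "size_voxels", "mass",
            "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_z_stat", "p_corrected",
        ],
    ).sort_values("mass", ascending=False, ignore_index=True)

    params["_cluster_labels"] = labels
    return GroupResult(z_map=z_vol, valid=valid, clusters=table, grid=grid, params=params)


# ---------------------------------------------------------------------------
# Dissociation ANOVA


@dataclass
class AnovaResult:
    """2x2 repeated-measures ANOVA on ROI accuracies.

    For a two-level within-subject factor each F statistic on (1, n-1)
    degrees of freedom equals the squared paired t of the corresponding
    contrast score; post-hoc paired t tests give the two simple effects of
    region within each classifier.
    """

    effects: pd.DataFrame  # index: region, classifier, interaction
    posthoc: pd.DataFrame
    region_levels: tuple
    classifier_levels: tuple
    n_subjects: int


def _contrast_f(scores: np.ndarray):
    n = scores.shape[0]
    var = scores.var(ddof=1)
    if var == 0:
        return (np.nan, np.nan) if np.isclose(scores.mean(), 0) else (np.inf, 0.0)
    t = scores.mean() / np.sqrt(var / n)
    F = t**2
    p = float(stats.f.sf(F, 1, n - 1))
    return float(F), p


def dissociation_anova(table: pd.DataFrame) -> AnovaResult:
    """2x2 within-subject ANOVA of accuracy over region x classifier.

    ``table`` must hold one row per subject x region x classifier with
    columns ``subject, region, classifier, accuracy`` (a complete crossed
    design, >= 3 subjects). With identical values in all cells the error
    variance is zero and every F is reported as undefined (NaN).
    """
    required = {"subject", "region", "classifier", "accuracy"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    regions = tuple(sorted(table["region"].unique()))
    classifiers = tuple(sorted(table["classifier"].unique()))
    subjects = sorted(table["subject"].unique())
    if len(regions) != 2 or len(classifiers) != 2:
        raise ValueError("design must be 2 regions x 2 classifiers")
    if len(subjects) < 3:
        raise ValueError("ANOVA needs >= 3 subjects")

    cells = {}
    missing = []
    for r in regions:
        for c in classifiers:
            sub = table[(table["region"] == r) & (table["classifier"] == c)]
            sub = sub.set_index("subject")["accuracy"]
            if not set(subjects) <= set(sub.index):
                missing.append((r, c, sorted(set(subjects) - set(sub.index))))
            cells[(r, c)] = sub.reindex(subjects).to_numpy(dtype=float)
    if missing:
        raise ValueError(f"incomplete design; missing cells: {missing}")

    a = np.stack(
        [[cells[(r, c)] for c in classifiers] for r in regions]
    )  # (region, classifier, subject)
    region_scores = a[0].mean(axis=0) - a[1].mean(axis=0)
    clf_scores = a[:, 0].mean(axis=0) - a[:, 1].mean(axis=0)
    inter_scores = (a[0, 0] - a[0, 1]) - (a[1, 0] - a[1, 1])

    rows = {}
    for name, scores in (
        ("region", region_scores),
        ("classifier", clf_scores),
        ("interaction", inter_scores),
    ):
        F, p = _contrast_f(scores)
        rows[name] = {"F": F, "p": p, "df1": 1, "df2": len(subjects) - 1}
    effects = pd.DataFrame(rows).T

    posthoc_rows = []
    for c in classifiers:
        diff = cells[(regions[0], c)] - cells[(regions[1], c)]
        t, p = stats.ttest_rel(cells[(regions[0], c)], cells[(regions[1], c)])
        posthoc_rows.append(
            {
                "classifier": c,
                "contrast": f"{regions[0]} - {regions[1]}",
                "mean_diff": float(diff.mean()),
                "t": float(t),
                "p": float(p),
                "df": len(subjects) - 1,
            }
        )
    return AnovaResult(
        effects=effects,
        posthoc=pd.DataFrame(posthoc_rows),
        region_levels=regions,
        classifier_levels=classifiers,
        n_subjects=len(subjects),
    )
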