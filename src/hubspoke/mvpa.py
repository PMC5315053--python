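"""Cross-modal searchlight MVPA.

Implements the study's core computation: per-run z-scoring of condition beta
patterns, spherical searchlight geometry, the two cross-classification
schemes (semantic-feature and perceptual) with leave-one-run-out folds,
accuracy maps and validity-aware smoothing. Group inference lives in
:mod:`hubspoke.group`.

Cross-decoding means the classifier is trained and tested on *disjoint*
condition sets — e.g. trained to separate auditory- from visual-feature words
presented as speech and tested on the same distinction for written words —
so only representations shared across the two sets can drive above-chance
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import VolumeGrid
from .glm import BetaPattern
from .svm import train_linear_svm

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# z-scoring

def zscore_patterns(patterns: BetaPattern) -> BetaPattern:
    """z-score betas per voxel within each run, across that run's conditions.

    After the transform each voxel's values across the run's condition maps
    have mean 0 and (population) sd 1. Voxels with zero across-condition
    variance in any run are set to 0 there and flagged.
    """
    if patterns.data.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 conditions per run")
    data = patterns.data
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    zero_var = sd[:, 0] <= 1e-300  # (runs, x, y, z)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (data - mean) / sd, 0.0)
    flagged = patterns.flagged | np.any(zero_var, axis=0)
    return replace(patterns, data=z, zscored=True, flagged=flagged)


# ---------------------------------------------------------------------------
# Searchlight geometry

def sphere_offsets(radius: float, voxel_size=(2.0, 2.0, 2.0)) -> np.ndarray:
    """Integer voxel offsets whose center-to-center mm distance is <= radius.

    Includes (0, 0, 0); lexicographically ordered. A 6 mm radius on the 2 mm
    grid yields 123 offsets (the sphere size used throughout the analyses).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    voxel_size = np.asarray(voxel_size, dtype=float)
    reach = np.floor(radius / voxel_size).astype(int)
    axes = [np.arange(-r, r + 1) for r in reach]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = np.sum((grid * voxel_size) ** 2, axis=1) <= radius**2 + 1e-9
    return grid[keep]  # meshgrid order is lexicographic


@dataclass(frozen=True)
class SearchlightSpec:
    radius: float = 6.0
    min_voxels: int = 2
    chance_level: float = 0.5

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if not 0 < self.chance_level < 1:
            raise ValueError("chance level must be in (0, 1)")


# ---------------------------------------------------------------------------
# Classification schemes

@dataclass(frozen=True)
class Direction:
    """One train->test generalization direction.

    ``train`` and ``test`` map condition labels to class labels; the two
    condition sets are disjoint so the test set is never seen in training.
    """

    train: dict
    test: dict

    def __post_init__(self):
        if set(self.train) & set(self.test):
            raise ValueError("train and test condition sets must be disjoint")
        train_classes = sorted(set(self.train.values()))
        test_classes = sorted(set(self.test.values()))
        if len(train_classes) != 2 or train_classes != test_classes:
            raise ValueError("both classes must appear on each side of a direction")

    @property
    def classes(self):
        return tuple(sorted(set(self.train.values())))


@dataclass(frozen=True)
class ClassifierScheme:
    name: str
    directions: tuple
    C: float = 1.0
    chance: float = 0.5

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")


def make_scheme(kind: str, C: float = 1.0) -> ClassifierScheme:
    """The two cross-classification schemes.

    ``semantic_feature``: discriminate auditory- vs visual-feature words,
    trained on spoken and tested on written words and vice versa (two
    directions, averaged) — only format-independent semantic information is
    informative.

    ``perceptual``: discriminate spoken vs written presentation, trained on
    non-words and tested on (all four) word conditions — only semantics-free
    format information is informative.
    """
    if kind == "semantic_feature":
        spoken = {"Spoken-AUD": "AUD", "Spoken-VIS": "VIS"}
        written = {"Written-AUD": "AUD", "Written-VIS": "VIS"}
        directions = (
            Direction(train=spoken, test=written),
            Direction(train=written, test=spoken),
        )
    elif kind == "perceptual":
        directions = (
            Direction(
                train={"Spoken-NON": "Spoken", "Written-NON": "Written"},
                test={
                    "Spoken-AUD": "Spoken",
                    "Spoken-VIS": "Spoken",
                    "Written-AUD": "Written",
                    "Written-VIS": "Written",
                },
            ),
        )
    else:
        raise ValueError(f"unknown scheme kind {kind!r}")
    return ClassifierScheme(name=kind, directions=directions, C=C)


def fold_plan(n_runs: int, scheme: ClassifierScheme) -> list:
    """All (held-out run, direction index) train/test evaluations.

    Leave-one-run-out over ``n_runs`` crossed with the scheme's directions:
    the semantic scheme on 4 runs yields 8 evaluations, the perceptual 4.
    """
    if n_runs < 2:
        raise ValueError("leave-one-run-out needs >= 2 runs")
    return [(r, d) for r in range(n_runs) for d in range(len(scheme.directions))]


# ---------------------------------------------------------------------------
# Cross-validated cross-decoding

def _direction_indices(conditions, direction: Direction):
    cond_idx = {c: i for i, c in enumerate(conditions)}
    classes = direction.classes
    missing = [c for c in (*direction.train, *direction.test) if c not in cond_idx]
    if missing:
        raise ValueError(f"conditions missing from the patterns: {missing}")
    tr_idx = np.array([cond_idx[c] for c in direction.train])
    tr_y = np.array([classes.index(direction.train[c]) for c in direction.train])
    te_idx = np.array([cond_idx[c] for c in direction.test])
    te_y = np.array([classes.index(direction.test[c]) for c in direction.test])
    return tr_idx, tr_y, te_idx, te_y


def _decode_features(feats: np.ndarray, conditions, scheme: ClassifierScheme) -> float:
    """Mean accuracy over folds x directions for a (runs, conds, k) feature array."""
    n_runs = feats.shape[0]
    plan = []
    for direction in scheme.directions:
        plan.append(_direction_indices(conditions, direction))
    accs = []
    for test_run in range(n_runs):
        train_runs = [r for r in range(n_runs) if r != test_run]
        for tr_idx, tr_y, te_idx, te_y in plan:
            Xtr = feats[np.ix_(train_runs, tr_idx)].reshape(-1, feats.shape[2])
            ytr = np.tile(tr_y, len(train_runs))
            model = train_linear_svm(Xtr, ytr, C=scheme.C)
            pred = model.predict(feats[test_run][te_idx])
            accs.append(float(np.mean(pred == te_y)))
    return float(np.mean(accs))


def crossval_cross_decode(patterns: BetaPattern, voxels, scheme: ClassifierScheme) -> float:
    """Leave-one-run-out cross-decoding accuracy on a voxel subset.

    For every direction and every fold the classifier is trained on the
    direction's train conditions from the training runs (one sample per
    condition per run) and tested on its test conditions from the held-out
    run; the returned value is the unweighted mean over folds x directions.
    """
    if patterns.n_runs < 2:
        raise ValueError("cross-validation needs >= 2 runs")
    if isinstance(voxels, np.ndarray) and voxels.dtype == bool:
        feats = patterns.data[:, :, voxels]
    else:
        feats = patterns.data[:, :, voxels[0], voxels[1], voxels[2]]
    if feats.shape[2] == 0:
        raise ValueError("empty voxel subset")
    return _decode_features(feats, patterns.conditions, scheme)


# ---------------------------------------------------------------------------
# Searchlight

@dataclass
class AccuracyMap:
    """Voxelwise accuracy (or statistic) volume with a validity mask."""

    grid: VolumeGrid
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("values shape does not match grid")
        if self.valid.shape != tuple(self.grid.shape):
            raise ValueError("valid shape does not match grid")


def searchlight(
    patterns: BetaPattern,
    mask: np.ndarray,
    spec: SearchlightSpec | None = None,
    scheme: ClassifierScheme | None = None,
) -> AccuracyMap:
    """Spherical searchlight cross-decoding over every voxel of ``mask``.

    Each sphere is clipped to the mask; centers whose clipped sphere holds
    fewer than ``spec.min_voxels`` voxels are marked invalid. The sphere's
    cross-validated accuracy is assigned to its central voxel.
    """
    spec = spec or SearchlightSpec()
    scheme = scheme or make_scheme("semantic_feature")
    if not patterns.zscored:
        raise ValueError("searchlight expects z-scored patterns (see zscore_patterns)")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty searchlight mask")
    shape = tuple(patterns.grid.shape)
    centers = np.argwhere(mask)
    col_of = np.full(shape, -1, dtype=np.int64)
    col_of[mask] = np.arange(centers.shape[0])
    F = np.ascontiguousarray(patterns.data[:, :, mask])  # (runs, conds, M)
    offsets = sphere_offsets(spec.radius, patterns.grid.voxel_size)

    values = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    dims = np.asarray(shape)
    conditions = patterns.conditions
    for center in centers:
        nb = center + offsets
        ok = np.all((nb >= 0) & (nb < dims), axis=1)
        cols = col_of[nb[ok, 0], nb[ok, 1], nb[ok, 2]]
        cols = cols[cols >= 0]
        if cols.size < spec.min_voxels:
            continue
        acc = _decode_features(F[:, :, cols], conditions, scheme)
        values[tuple(center)] = acc
        valid[tuple(center)] = True
    return AccuracyMap(grid=patterns.grid, values=values, valid=valid)


# ---------------------------------------------------------------------------
# Smoothing

def smooth_map(map_or_values, fwhm: float, voxel_size=None, valid=None):
    """Validity-aware Gaussian smoothing (sigma = fwhm / sqrt(8 ln 2) per axis,
    in mm). Invalid voxels neither contribute to nor receive smoothed values;
    the kernel is renormalized over the valid support.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if isinstance(map_or_values, AccuracyMap):
        amap = map_or_values
        out_values = smooth_map(
            amap.values, fwhm, voxel_size=amap.grid.voxel_size, valid=amap.valid
        )
        return AccuracyMap(grid=amap.grid, values=out_values, valid=amap.valid.copy())
    values = np.asarray(map_or_values, dtype=float)
    if voxel_size is None:
        raise ValueError("voxel_size required when smoothing a bare array")
    if valid is None:
        valid = np.isfinite(values)
    valid = np.asarray(valid, dtype=bool)
    if fwhm == 0:
        out = np.full(values.shape, np.nan)
        out[valid] = values[valid]
        return out
    sigma = [fwhm * FWHM_TO_SIGMA / v for v in np.asarray(voxel_size, dtype=float)]
    num = gaussian_filter(np.where(valid, values, 0.0), sigma=sigma)
    den = gaussian_filter(valid.astype(float), sigma=sigma)
    out = np.full(values.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[valid] = num[valid] / den[valid]
    return out
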