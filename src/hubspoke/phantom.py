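"""Synthetic task and resting-state fMRI phantoms.

The phantom plants the hub-and-spoke hypothesis as generative ground truth:

* a ``semantic_hub`` region whose multivoxel pattern depends only on the
  semantic feature type of a word (auditory vs visual features), identically
  for spoken and written presentation — an amodal code;
* a ``modality_region`` whose pattern depends only on presentation format
  (spoken vs written), identically for meaningful and meaningless items;
* two sensory spoke regions that carry both codes;
* white-matter and CSF compartments that share a physiological confound with
  gray matter at rest, plus two seed-anchored latent resting networks with
  disjoint high-loading territories.

Every downstream stage of the pipeline (GLM, searchlight MVPA, group
inference, seed connectivity, decoding) is testable against this ground truth
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .core import CONDITIONS, BoldRun, VolumeGrid, condition_feature, condition_format


class Role(IntEnum):
    """Integer labels of the phantom region atlas."""

    BACKGROUND = 0
    SEMANTIC_HUB = 1
    MODALITY_REGION = 2
    AUDITORY_SPOKE = 3
    VISUAL_SPOKE = 4
    WHITE_MATTER = 5
    CSF = 6


GRAY_ROLES = (Role.SEMANTIC_HUB, Role.MODALITY_REGION, Role.AUDITORY_SPOKE, Role.VISUAL_SPOKE)
COMPARTMENT_ROLES = (Role.WHITE_MATTER, Role.CSF)


class PackingError(ValueError):
    """Requested region sizes cannot be placed disjointly on the grid."""


@dataclass
class RegionAtlas:
    """Labelled phantom anatomy on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    labels: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.labels.shape != tuple(self.grid.shape):
            raise ValueError("labels shape does not match grid")
        if self.brain_mask.shape != tuple(self.grid.shape):
            raise ValueError("brain_mask shape does not match grid")

    def mask(self, role: Role) -> np.ndarray:
        return self.labels == int(role)

    def region_size(self, role: Role) -> int:
        return int(np.sum(self.labels == int(role)))

    def validate(self) -> None:
        for role in GRAY_ROLES:
            if np.any(self.mask(role) & ~self.brain_mask):
                raise ValueError(f"{role.name} extends outside the brain mask")
        for role in COMPARTMENT_ROLES:
            if np.any(self.mask(role) & self.brain_mask):
                raise ValueError(f"{role.name} overlaps the brain (gray) mask")


@dataclass(frozen=True)
class RegionSpec:
    center_mm: tuple[float, float, float]
    n_voxels: int


@dataclass(frozen=True)
class AtlasConfig:
    """Geometry of the phantom anatomy.

    Defaults place four gray blobs well apart inside an ellipsoidal "brain"
    on a 28^3 grid at 2 mm isotropic spacing (the analysis grid the pipeline
    assumes), with WM/CSF compartments outside the gray ellipsoid.
    """

    grid_shape: tuple[int, int, int] = (28, 28, 28)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_semiaxes_mm: tuple[float, float, float] = (24.0, 24.0, 19.0)
    regions: dict = field(
        default_factory=lambda: {
            Role.SEMANTIC_HUB: RegionSpec((-12.0, -12.0, -4.0), 150),
            Role.MODALITY_REGION: RegionSpec((12.0, 12.0, 4.0), 150),
            Role.AUDITORY_SPOKE: RegionSpec((-12.0, 12.0, 4.0), 100),
            Role.VISUAL_SPOKE: RegionSpec((12.0, -12.0, -4.0), 100),
            Role.WHITE_MATTER: RegionSpec((24.0, 24.0, 0.0), 120),
            Role.CSF: RegionSpec((-24.0, -24.0, 0.0), 80),
        }
    )


def small_atlas_config() -> AtlasConfig:
    """Compact 20^3 atlas used for cohort-scale recovery studies."""
    return AtlasConfig(
        grid_shape=(20, 20, 20),
        brain_semiaxes_mm=(16.0, 16.0, 13.0),
        regions={
            Role.SEMANTIC_HUB: RegionSpec((-8.0, -8.0, -3.0), 100),
            Role.MODALITY_REGION: RegionSpec((8.0, 8.0, 3.0), 100),
            Role.AUDITORY_SPOKE: RegionSpec((-8.0, 8.0, 3.0), 60),
            Role.VISUAL_SPOKE: RegionSpec((8.0, -8.0, -3.0), 60),
            Role.WHITE_MATTER: RegionSpec((16.0, 16.0, 0.0), 80),
            Role.CSF: RegionSpec((-16.0, -16.0, 0.0), 50),
        },
    )


def _nearest_voxels(candidates: np.ndarray, center_mm, n: int, grid: VolumeGrid, what: str):
    """Indices of the n candidate voxels nearest (in mm) to ``center_mm``.

    Ties are broken lexicographically on (i, j, k) so the result is fully
    deterministic.
    """
    idx = np.argwhere(candidates)
    if idx.shape[0] < n:
        raise PackingError(
            f"cannot place {what}: {n} voxels requested, only {idx.shape[0]} available"
        )
    mm = grid.voxel_to_mm(idx)
    dist = np.linalg.norm(mm - np.asarray(center_mm, dtype=float), axis=1)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], dist))
    return idx[order[:n]]


def make_phantom_atlas(config: AtlasConfig | None = None, seed: int = 0) -> RegionAtlas:
    """Build the phantom region atlas.

    Regions are grown as quasi-spherical blobs of exactly the requested voxel
    count around their configured centers; gray regions are drawn from inside
    the brain ellipsoid, WM/CSF from outside it, and voxels are never assigned
    twice. The construction is deterministic (``seed`` is accepted for
    interface symmetry with the simulators).

    Raises
    ------
    PackingError
        If the requested voxel counts do not fit disjointly.
    """
    config = config or AtlasConfig()
    grid = VolumeGrid.centered(config.grid_shape, config.voxel_size)
    coords = grid.voxel_coords_mm()
    semi = np.asarray(config.brain_semiaxes_mm, dtype=float)
    brain = np.sum((coords / semi) ** 2, axis=-1) <= 1.0

    labels = np.zeros(grid.shape, dtype=np.int16)
    taken = np.zeros(grid.shape, dtype=bool)
    for role in (*GRAY_ROLES, *COMPARTMENT_ROLES):
        spec = config.regions[role]
        pool = (brain if role in GRAY_ROLES else ~brain) & ~taken
        idx = _nearest_voxels(pool, spec.center_mm, spec.n_voxels, grid, role.name)
        labels[idx[:, 0], idx[:, 1], idx[:, 2]] = int(role)
        taken[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    atlas = RegionAtlas(grid=grid, labels=labels, brain_mask=brain)
    atlas.validate()
    return atlas


# ---------------------------------------------------------------------------
# Block design


def generate_block_design(
    n_runs: int = 4,
    conditions=CONDITIONS,
    reps_per_condition: int = 2,
    block_duration: float = 18.0,
    jitter: tuple[float, float] = (4.0, 8.0),
    lead_in: float = 10.0,
    seed: int = 0,
    blocks_per_run: int | None = None,
    max_tries: int = 10_000,
) -> pd.DataFrame:
    """Pseudo-random block design: each condition ``reps_per_condition`` times
    per run, no immediate repetition, jittered inter-block gaps.

    Sequences are built by rejection sampling (shuffle until no two adjacent
    blocks share a condition) with a retry cap. Returns a BIDS-events-style
    table with columns ``onset, duration, trial_type, run``.
    """
    conditions = list(conditions)
    n_blocks = len(conditions) * reps_per_condition
    if blocks_per_run is not None and blocks_per_run != n_blocks:
        raise ValueError(
            f"blocks_per_run={blocks_per_run} != |conditions| x reps = {n_blocks}"
        )
    if len(conditions) == 1 and reps_per_condition >= 2:
        raise ValueError("no repetition-free sequence exists for a single condition")
    if jitter[0] > jitter[1] or jitter[0] < 0:
        raise ValueError(f"invalid jitter bounds {jitter}")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(conditions)), reps_per_condition)

    rows = []
    for run in range(n_runs):
        for attempt in range(max_tries):
            order = rng.permutation(pool)
            if not np.any(order[1:] == order[:-1]):
                break
        else:
            raise RuntimeError(f"no valid block order found in {max_tries} tries")
        t = float(lead_in)
        for b in range(n_blocks):
            rows.append(
                {
                    "onset": round(t, 6),
                    "duration": float(block_duration),
                    "trial_type": conditions[order[b]],
                    "run": run,
                }
            )
            gap = rng.uniform(jitter[0], jitter[1])
            t += block_duration + gap
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "run"])


# ---------------------------------------------------------------------------
# Ground truth


@dataclass(frozen=True)
class TruthConfig:
    """Response amplitudes and rest-network structure of the phantom.

    Pattern amplitudes are in baseline-percent-like signal units (baseline is
    100 arbitrary units, so an amplitude of 2 is a ~2% peak BOLD response
    spread over a unit-norm region pattern). ``feature_amp`` scales the
    semantic (AUD vs VIS) pattern, ``format_amp`` the presentation-format
    (spoken vs written) pattern.
    """

    feature_amp: dict = field(
        default_factory=lambda: {
            Role.SEMANTIC_HUB: 1.0,
            Role.MODALITY_REGION: 0.0,
            Role.AUDITORY_SPOKE: 0.75,
            Role.VISUAL_SPOKE: 0.75,
        }
    )
    format_amp: dict = field(
        default_factory=lambda: {
            Role.SEMANTIC_HUB: 0.0,
            Role.MODALITY_REGION: 1.0,
            Role.AUDITORY_SPOKE: 1.0,
            Role.VISUAL_SPOKE: 1.0,
        }
    )
    #: Uniform (univariate) response of each region to each condition; the hub
    #: entry depends only on feature type, the modality entry only on format,
    #: mirroring the univariate dissociation the pattern code also carries.
    #: Magnitudes are kept small relative to the noise so region decoding
    #: lands in the moderate-accuracy regime rather than at ceiling.
    mean_response: dict = field(
        default_factory=lambda: {
            Role.SEMANTIC_HUB: {"AUD": -0.30, "VIS": -0.15, "NON": 0.0},
            Role.MODALITY_REGION: {"Spoken": 0.30, "Written": 0.15},
            Role.AUDITORY_SPOKE: {"Spoken": 0.30, "Written": 0.15},
            Role.VISUAL_SPOKE: {"Spoken": 0.15, "Written": 0.30},
        }
    )
    #: Voxels added around each network anchor (hub -> network 1,
    #: modality region -> network 2) to form its exclusive rest territory.
    territory_extra: int = 150
    #: Loading of territory voxels on their latent rest network.
    network_amp: float = 1.0
    #: Rest-confound loading of gray-matter voxels and of WM/CSF compartments.
    gray_confound: float = 0.5
    compartment_confound: float = 1.5


def null_truth_config() -> TruthConfig:
    """Truth with no condition-dependent pattern or mean response anywhere.

    Used for null-calibration studies: task data then contain only baseline,
    drift and noise, independent of the condition labels.
    """
    zero = {r: 0.0 for r in GRAY_ROLES}
    return TruthConfig(
        feature_amp=dict(zero),
        format_amp=dict(zero),
        mean_response={
            Role.SEMANTIC_HUB: {"AUD": 0.0, "VIS": 0.0, "NON": 0.0},
            Role.MODALITY_REGION: {"Spoken": 0.0, "Written": 0.0},
            Role.AUDITORY_SPOKE: {"Spoken": 0.0, "Written": 0.0},
            Role.VISUAL_SPOKE: {"Spoken": 0.0, "Written": 0.0},
        },
    )


def _unit_pattern(rng: np.random.Generator, n: int) -> np.ndarray:
    """Zero-mean, unit-norm random pattern over n voxels (n >= 2)."""
    for _ in range(100):
        v = rng.standard_normal(n)
        v -= v.mean()
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            return v / norm
    raise RuntimeError("failed to draw a non-degenerate pattern")


@dataclass
class PhantomTruth:
    """Planted generative ground truth for one phantom subject.

    ``patterns[(role, key)]`` holds a fixed zero-mean unit-norm voxel-pattern
    vector over the region's voxels, with ``key`` one of ``feature:AUD``,
    ``feature:VIS``, ``format:Spoken``, ``format:Written``. The hub's
    response uses only the feature patterns, the modality region's only the
    format patterns, and the spokes both — the generative embodiment of an
    amodal hub with modality-specific spokes.
    """

    atlas: RegionAtlas
    config: TruthConfig
    patterns: dict
    network_loadings: list
    network_territories: list
    confound_loadings: np.ndarray
    seed: int

    def region_pattern(self, role: Role, key: str) -> np.ndarray:
        return self.patterns[(role, key)]

    def amplitude(self, role: Role, condition: str) -> float:
        """Overall pattern response scale of ``role`` to ``condition``."""
        feat = condition_feature(condition)
        a = 0.0
        if feat != "NON":
            a += abs(self.config.feature_amp[role])
        a += abs(self.config.format_amp[role])
        return a

    def mean_response(self, role: Role, condition: str) -> float:
        table = self.config.mean_response[role]
        if role == Role.SEMANTIC_HUB:
            return table[condition_feature(condition)]
        return table[condition_format(condition)]

    def condition_response(self, condition: str) -> np.ndarray:
        """3D map of the noiseless response amplitude to one condition."""
        resp = np.zeros(self.atlas.grid.shape)
        feat = condition_feature(condition)
        fmt = condition_format(condition)
        for role in GRAY_ROLES:
            region = self.atlas.mask(role)
            vec = np.full(int(region.sum()), self.mean_response(role, condition))
            if feat != "NON" and self.config.feature_amp[role] != 0.0:
                vec = vec + self.config.feature_amp[role] * self.patterns[(role, f"feature:{feat}")]
            if self.config.format_amp[role] != 0.0:
                vec = vec + self.config.format_amp[role] * self.patterns[(role, f"format:{fmt}")]
            resp[region] = vec
        return resp

    def network_seed_centers(self) -> list:
        """mm centers of the two network anchor regions (hub, modality)."""
        centers = []
        for role in (Role.SEMANTIC_HUB, Role.MODALITY_REGION):
            idx = np.argwhere(self.atlas.mask(role))
            centers.append(tuple(self.atlas.grid.voxel_to_mm(idx.mean(axis=0))))
        return centers


def make_phantom_truth(
    atlas: RegionAtlas, config: TruthConfig | None = None, seed: int = 0
) -> PhantomTruth:
    """Draw one subject's pattern vectors and rest-network structure.

    Patterns are drawn once per subject and reused across runs. Network 1 is
    anchored at the semantic hub, network 2 at the modality region; each
    network's territory is its anchor region plus the nearest
    ``territory_extra`` unlabelled brain voxels, so the two high-loading
    territories are disjoint.
    """
    config = config or TruthConfig()
    rng = np.random.default_rng(seed)

    patterns = {}
    for role in GRAY_ROLES:
        n = atlas.region_size(role)
        for key in ("feature:AUD", "feature:VIS", "format:Spoken", "format:Written"):
            patterns[(role, key)] = _unit_pattern(rng, n)

    # Rest networks: anchor region + surrounding shell of unlabelled brain.
    taken = atlas.labels != int(Role.BACKGROUND)
    loadings, territories = [], []
    for role in (Role.SEMANTIC_HUB, Role.MODALITY_REGION):
        region = atlas.mask(role)
        idx = np.argwhere(region)
        center = atlas.grid.voxel_to_mm(idx.mean(axis=0))
        pool = atlas.brain_mask & ~taken
        extra = _nearest_voxels(pool, center, config.territory_extra, atlas.grid,
                                f"network territory of {role.name}")
        territory = region.copy()
        territory[extra[:, 0], extra[:, 1], extra[:, 2]] = True
        taken |= territory
        load = np.zeros(atlas.grid.shape)
        load[territory] = config.network_amp
        loadings.append(load)
        territories.append(territory)

    confound = np.zeros(atlas.grid.shape)
    confound[atlas.brain_mask] = config.gray_confound
    for role in COMPARTMENT_ROLES:
        confound[atlas.mask(role)] = config.compartment_confound

    return PhantomTruth(
        atlas=atlas,
        config=config,
        patterns=patterns,
        network_loadings=loadings,
        network_territories=territories,
        confound_loadings=confound,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Task simulation


@dataclass(frozen=True)
class TaskNoise:
    """Noise model of the task simulator.

    ``white_sd`` is the stationary standard deviation of the AR(1)-filtered
    Gaussian noise; ``ar1`` its lag-1 autocorrelation; ``drift`` the
    peak-to-peak amplitude of a linear scanner drift over the run.
    """

    white_sd: float = 1.0
    ar1: float = 0.35
    drift: float = 4.0

    def __post_init__(self):
        if self.white_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not -1 < self.ar1 < 1:
            raise ValueError("AR(1) coefficient must be in (-1, 1)")


def _ar1_noise(rng: np.random.Generator, shape, sd: float, phi: float) -> np.ndarray:
    """AR(1) noise along axis 0 with stationary standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1.0 - phi**2) if phi != 0 else sd
    e = rng.standard_normal(shape) * innov_sd
    if phi == 0:
        return e
    e[0] = rng.standard_normal(shape[1:]) * sd  # stationary start
    for t in range(1, shape[0]):  # vectorized over voxels
        e[t] += phi * e[t - 1]
    return e


def _motion_walk(rng: np.random.Generator, n_scans: int) -> np.ndarray:
    """Smooth random-walk motion parameters (3 translations mm, 3 rotations rad)."""
    steps = rng.standard_normal((n_scans, 6)) * np.array([0.02] * 3 + [4e-4] * 3)
    walk = np.cumsum(steps, axis=0)
    # light smoothing for realism
    kernel = np.array([0.25, 0.5, 0.25])
    return np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, walk)


def simulate_task_subject(
    truth: PhantomTruth,
    design: pd.DataFrame,
    tr: float = 2.0,
    noise: TaskNoise | None = None,
    baseline: float = 100.0,
    n_scans: int | None = None,
    pad_end: float = 16.0,
    hrf=None,
    seed: int = 0,
) -> list:
    """Simulate all runs of one task session.

    Per voxel the signal is ``baseline + sum_c response_c(voxel) *
    (boxcar_c (*) HRF)(t) + drift(t) + AR(1) noise`` — the exact forward model
    the GLM stage inverts, so with noise and drift disabled ordinary least
    squares recovers the planted responses to machine precision.
    """
    from .glm import HrfParams, condition_regressors

    noise = noise or TaskNoise()
    hrf = hrf or HrfParams()
    grid = truth.atlas.grid
    shape = tuple(grid.shape)
    n_vox = int(np.prod(shape))
    rng = np.random.default_rng(seed)

    runs = []
    for run_id in sorted(design["run"].unique()):
        events = design[design["run"] == run_id]
        last = float((events["onset"] + events["duration"]).max())
        T = n_scans or int(np.ceil((last + pad_end) / tr))
        if last > T * tr:
            raise ValueError(f"run {run_id}: design extends past the run end")
        regs, names = condition_regressors(events, T, tr, hrf)
        B = np.stack(
            [truth.condition_response(c).reshape(n_vox) for c in names], axis=0
        )
        data = np.full((T, n_vox), float(baseline))
        data += regs @ B
        if noise.drift != 0:
            data += noise.drift * np.linspace(-0.5, 0.5, T)[:, None]
        data += _ar1_noise(rng, (T, n_vox), noise.white_sd, noise.ar1)
        runs.append(
            BoldRun(
                grid=grid,
                tr=tr,
                data=np.ascontiguousarray(data.T.reshape(*shape, T)),
                motion_params=_motion_walk(rng, T),
            )
        )
    return runs


# ---------------------------------------------------------------------------
# Rest simulation


@dataclass(frozen=True)
class RestParams:
    """Resting-state simulator parameters.

    Latent network signals are band-limited Gaussian processes (0.01–0.08 Hz
    by default, inside the band the analysis filters retain); the shared
    physiological confound lives in a slightly wider low-frequency band.
    All latent signals have unit standard deviation.
    """

    network_band: tuple[float, float] = (0.01, 0.08)
    physio_band: tuple[float, float] = (0.01, 0.10)
    noise_sd: float = 0.7
    physio: bool = True


def _band_limited_series(rng: np.random.Generator, n: int, tr: float, band) -> np.ndarray:
    """Unit-sd, zero-mean Gaussian series band-limited to ``band`` (Hz)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(keep):
        raise ValueError(f"band {band} contains no resolvable frequency at n={n}, tr={tr}")
    spec[~keep] = 0.0
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    sd = x.std()
    if sd < 1e-12:
        raise RuntimeError("degenerate band-limited draw")
    return x / sd


def simulate_rest_subject(
    truth: PhantomTruth,
    n_timepoints: int = 180,
    tr: float = 3.0,
    params: RestParams | None = None,
    baseline: float = 100.0,
    seed: int = 0,
) -> BoldRun:
    """Simulate one resting-state run.

    Voxel signal = sum_k loading_k * latent_k(t) + confound_loading *
    physio(t) + white noise (+ baseline). WM/CSF voxels carry the
    physiological signal strongly and the latent networks not at all.
    """
    if n_timepoints < 20:
        raise ValueError("n_timepoints must be >= 20")
    params = params or RestParams()
    rng = np.random.default_rng(seed)
    grid = truth.atlas.grid
    n_vox = grid.n_voxels

    latents = [
        _band_limited_series(rng, n_timepoints, tr, params.network_band)
        for _ in truth.network_loadings
    ]
    physio = _band_limited_series(rng, n_timepoints, tr, params.physio_band)

    data = np.full((n_timepoints, n_vox), float(baseline))
    for load, lat in zip(truth.network_loadings, latents):
        data += np.outer(lat, load.reshape(n_vox))
    if params.physio:
        data += np.outer(physio, truth.confound_loadings.reshape(n_vox))
    if params.noise_sd > 0:
        data += rng.standard_normal((n_timepoints, n_vox)) * params.noise_sd

    run = BoldRun(
        grid=grid,
        tr=tr,
        data=np.ascontiguousarray(data.T.reshape(*grid.shape, n_timepoints)),
        motion_params=_motion_walk(rng, n_timepoints),
    )
    run.latents = latents  # exposed for ground-truth checks
    run.physio = physio
    return run
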