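"""Block-design GLM: HRF, design matrices, per-run OLS, tSNR, percent signal
change and fixed-effects run averaging.

The per-run condition betas produced here are the multivoxel features the
MVPA stage classifies: each beta map is the average response to the block's
exemplars, one map per condition per run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .core import BoldRun, VolumeGrid


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma hemodynamic response function parameters.

    Defaults: response peak 6 s, undershoot peak 16 s, unit dispersions,
    undershoot ratio 1/6, kernel length 32 s.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0

    def __post_init__(self):
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "undershoot_ratio",
            "length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"HRF parameter {name} must be > 0")
        if self.length <= self.undershoot_delay:
            raise ValueError("HRF length must exceed the undershoot delay")


def _hrf_values(t: np.ndarray, p: HrfParams) -> np.ndarray:
    """Unnormalized double-gamma kernel: difference of two gamma densities.

    Shapes are delay/dispersion + 1 so each gamma's mode falls exactly at its
    configured delay.
    """
    peak = gamma_dist.pdf(
        t, p.peak_delay / p.peak_dispersion + 1.0, scale=p.peak_dispersion
    )
    under = gamma_dist.pdf(
        t, p.undershoot_delay / p.undershoot_dispersion + 1.0,
        scale=p.undershoot_dispersion,
    )
    return peak - p.undershoot_ratio * under


def double_gamma_hrf(tr: float, params: HrfParams | None = None) -> np.ndarray:
    """Double-gamma HRF sampled at ``tr`` spacing on [0, length], peak scaled to 1.

    The normalization constant is the kernel's maximum on a dense internal
    grid, so the sampled kernel's scale does not depend on whether a sample
    lands exactly on the peak.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    params = params or HrfParams()
    t = np.arange(0.0, params.length + tr / 2, tr)
    dense = np.arange(0.0, params.length, 0.001)
    peak = _hrf_values(dense, params).max()
    return _hrf_values(t, params) / peak


def condition_regressors(
    events: pd.DataFrame,
    n_scans: int,
    tr: float,
    hrf: HrfParams | None = None,
    oversample: int = 16,
):
    """Boxcar-convolved condition regressors sampled at scan onsets.

    Boxcars are built at microtime resolution (``oversample`` samples per TR,
    >= 10), convolved with the double-gamma kernel sampled at the same
    resolution, and decimated to frame times t = i * tr. The kernel is
    gain-normalized (unit sample sum) so a sustained block plateaus at 1 and
    condition betas are in raw signal units.

    Returns ``(regressors, names)`` with one column per condition present,
    in sorted label order.
    """
    if oversample < 10:
        raise ValueError("microtime resolution must be >= 10 samples per TR")
    hrf = hrf or HrfParams()
    dt = tr / oversample
    n_fine = n_scans * oversample
    run_end = n_scans * tr
    for _, ev in events.iterrows():
        if ev["onset"] < 0 or ev["onset"] + ev["duration"] > run_end + 1e-9:
            raise ValueError(
                f"event (onset={ev['onset']}, duration={ev['duration']}, "
                f"trial_type={ev['trial_type']}) extends past the run end ({run_end} s)"
            )
    t_dense = np.arange(0.0, hrf.length + dt / 2, dt)
    kernel = _hrf_values(t_dense, hrf)
    kernel = kernel / kernel.sum()

    names = sorted(events["trial_type"].unique())
    cols = np.zeros((n_scans, len(names)))
    for j, cond in enumerate(names):
        box = np.zeros(n_fine)
        for _, ev in events[events["trial_type"] == cond].iterrows():
            a = int(np.round(ev["onset"] / dt))
            b = int(np.round((ev["onset"] + ev["duration"]) / dt))
            box[a : min(b, n_fine)] = 1.0
        conv = np.convolve(box, kernel)[:n_fine]
        cols[:, j] = conv[::oversample]
    return cols, names


def cosine_drift_basis(n_scans: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """DCT-II drift columns up to ``cutoff_hz`` (half-period rule).

    Column k (k = 1..K, K = floor(2 * T * cutoff)) is
    cos(pi * k * (2i + 1) / (2N)); the k-th cosine completes k half-periods
    over the run, so columns with frequency k / (2T) <= cutoff are included.
    """
    T = n_scans * tr
    k_max = int(np.floor(2 * T * cutoff_hz))
    i = np.arange(n_scans)
    basis = np.column_stack(
        [np.cos(np.pi * k * (2 * i + 1) / (2 * n_scans)) for k in range(1, k_max + 1)]
    ) if k_max >= 1 else np.zeros((n_scans, 0))
    return basis


@dataclass
class DesignMatrix:
    """Named GLM design matrix for one run."""

    frame: pd.DataFrame
    task_names: list
    confound_names: list
    tr: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.frame.to_numpy())):
            raise ValueError("design matrix contains non-finite entries")
        for name in self.task_names:
            if np.allclose(self.frame[name].to_numpy(), 0):
                raise ValueError(f"task column {name!r} is all zero")

    @property
    def n_scans(self) -> int:
        return len(self.frame)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def names(self) -> list:
        return list(self.frame.columns)


def build_design_matrix(
    events: pd.DataFrame,
    n_scans: int,
    tr: float,
    hrf: HrfParams | None = None,
    highpass_cutoff: float = 0.01,
    confounds: pd.DataFrame | None = None,
    oversample: int = 16,
) -> DesignMatrix:
    """Design matrix for one run: HRF-convolved condition boxcars, optional
    named confounds, DCT drift columns implementing the high-pass cutoff,
    and an intercept."""
    regs, names = condition_regressors(events, n_scans, tr, hrf, oversample)
    frame = pd.DataFrame(regs, columns=names)
    confound_names = []
    if confounds is not None:
        if len(confounds) != n_scans:
            raise ValueError("confound rows must equal n_scans")
        for col in confounds.columns:
            frame[col] = np.asarray(confounds[col], dtype=float)
            confound_names.append(col)
    if highpass_cutoff and highpass_cutoff > 0:
        drift = cosine_drift_basis(n_scans, tr, highpass_cutoff)
        for k in range(drift.shape[1]):
            name = f"drift_{k + 1}"
            frame[name] = drift[:, k]
            confound_names.append(name)
    frame["intercept"] = 1.0
    return DesignMatrix(frame=frame, task_names=names, confound_names=confound_names, tr=tr)


@dataclass
class GlmFit:
    """Per-run ordinary-least-squares fit."""

    betas: np.ndarray  # (n_columns, x, y, z)
    residuals: np.ndarray  # (x, y, z, t)
    dof: int
    design: DesignMatrix
    grid: VolumeGrid

    def beta(self, name: str) -> np.ndarray:
        try:
            j = self.design.names.index(name)
        except ValueError:
            raise KeyError(f"no design column named {name!r}") from None
        return self.betas[j]


def _collinear_columns(X: np.ndarray, names) -> list:
    """Names of columns involved in rank deficiency (via QR pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = piv[diag < tol] if diag.size else piv
    return [names[j] for j in sorted(bad)]


def fit_run_glm(run: BoldRun, design: DesignMatrix) -> GlmFit:
    """Voxelwise OLS fit of one run.

    Raises on a rank-deficient design, listing the collinear columns.
    """
    X = design.matrix
    if design.n_scans != run.n_scans:
        raise ValueError(
            f"design has {design.n_scans} scans but run has {run.n_scans}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]} columns); "
            f"collinear columns: {_collinear_columns(X, design.names)}"
        )
    shape = run.data.shape[:3]
    Y = run.data.reshape(-1, run.n_scans).T  # (t, v)
    betas = np.linalg.pinv(X) @ Y
    resid = Y - X @ betas
    return GlmFit(
        betas=np.ascontiguousarray(betas.reshape(X.shape[1], *shape)),
        residuals=np.ascontiguousarray(resid.T.reshape(*shape, run.n_scans)),
        dof=run.n_scans - rank,
        design=design,
        grid=run.grid,
    )


def tsnr_map(run: BoldRun, design: DesignMatrix | None = None) -> np.ndarray:
    """Temporal SNR: mean raw signal / sd of the GLM residual time series.

    With no design given, an intercept-only model is used (residual sd is
    then the ordinary temporal sd). Voxels with zero residual variance are
    undefined (NaN).
    """
    if design is None:
        frame = pd.DataFrame({"intercept": np.ones(run.n_scans)})
        design = DesignMatrix(frame=frame, task_names=[], confound_names=[], tr=run.tr)
    fit = fit_run_glm(run, design)
    mean = run.data.mean(axis=3)
    ss = np.sum(fit.residuals**2, axis=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = np.sqrt(ss / max(fit.dof, 1))
        tsnr = np.where(sd > 0, mean / sd, np.nan)
    return tsnr


def tsnr_summary(tsnr: np.ndarray, mask: np.ndarray, threshold: float = 20.0) -> dict:
    """ROI mean tSNR and the fraction of valid voxels exceeding ``threshold``."""
    vals = tsnr[np.asarray(mask, dtype=bool)]
    valid = vals[np.isfinite(vals)]
    if valid.size == 0:
        return {"mean": np.nan, "fraction_good": np.nan, "n_valid": 0, "all_undefined": True}
    return {
        "mean": float(valid.mean()),
        "fraction_good": float(np.mean(valid > threshold)),
        "n_valid": int(valid.size),
        "all_undefined": False,
    }


def percent_signal_change(fit: GlmFit, condition: str) -> np.ndarray:
    """Percent signal change of one condition.

    PSC = 100 * beta(condition) * max(condition regressor) / beta(intercept);
    voxels whose intercept beta is <= 0 are undefined (NaN). The max-regressor
    scaling convention is recorded here as the package's PSC definition.
    """
    if condition not in fit.design.task_names:
        raise KeyError(f"no condition column named {condition!r}")
    beta = fit.beta(condition)
    intercept = fit.beta("intercept")
    scale = float(np.max(fit.design.frame[condition].to_numpy()))
    with np.errstate(divide="ignore", invalid="ignore"):
        psc = np.where(intercept > 0, 100.0 * beta * scale / intercept, np.nan)
    return psc


def fixed_effects_combine(fits: list, condition: str) -> np.ndarray:
    """Subject-level condition map: unweighted mean of per-run betas.

    With equal-length, identically structured runs this coincides with a
    variance-weighted fixed-effects average.
    """
    if len(fits) < 2:
        raise ValueError("fixed-effects combination needs >= 2 runs")
    grids = {(f.grid.shape, f.grid.voxel_size, f.grid.origin) for f in fits}
    if len(grids) > 1:
        raise ValueError("runs are not on a shared grid")
    return np.mean([f.beta(condition) for f in fits], axis=0)


@dataclass
class BetaPattern:
    """Per-run, per-condition beta maps — the classifier features.

    ``data`` is (n_runs, n_conditions, x, y, z). ``flagged`` marks voxels
    zeroed during z-scoring for having no across-condition variance.
    """

    data: np.ndarray
    conditions: list
    grid: VolumeGrid
    mask: np.ndarray
    zscored: bool = False
    flagged: np.ndarray = field(default=None)
    subject: str | int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5:
            raise ValueError("BetaPattern data must be (runs, conditions, x, y, z)")
        if self.data.shape[1] != len(self.conditions):
            raise ValueError("condition axis does not match condition names")
        if self.data.shape[2:] != tuple(self.grid.shape):
            raise ValueError("spatial shape does not match grid")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.flagged is None:
            self.flagged = np.zeros(self.grid.shape, dtype=bool)

    @property
    def n_runs(self) -> int:
        return self.data.shape[0]


def extract_beta_patterns(
    fits: list, conditions, mask: np.ndarray, subject=None
) -> BetaPattern:
    """Stack per-run condition betas into a :class:`BetaPattern`."""
    conditions = list(conditions)
    data = np.stack(
        [np.stack([f.beta(c) for c in conditions], axis=0) for f in fits], axis=0
    )
    return BetaPattern(
        data=data, conditions=conditions, grid=fits[0].grid, mask=mask, subject=subject
    )


def fit_task_subject(
    runs: list,
    design: pd.DataFrame,
    conditions=None,
    hrf: HrfParams | None = None,
    highpass_cutoff: float = 0.01,
    include_motion: bool = True,
    mask: np.ndarray | None = None,
    subject=None,
):
    """Convenience: per-run GLMs for one subject plus the stacked BetaPattern.

    Returns ``(fits, pattern)``.
    """
    run_ids = sorted(design["run"].unique())
    if len(run_ids) != len(runs):
        raise ValueError(f"{len(runs)} runs but {len(run_ids)} run ids in the design")
    fits = []
    for run, run_id in zip(runs, run_ids):
        events = design[design["run"] == run_id]
        conf = None
        if include_motion and run.motion_params is not None:
            conf = pd.DataFrame(
                run.motion_params, columns=[f"motion_{i + 1}" for i in range(6)]
            )
            # a constant (zero-variance) motion trace would be collinear with
            # the intercept; drop it
            keep = [c for c in conf.columns if conf[c].std() > 1e-12]
            if len(keep) < len(conf.columns):
                warnings.warn("dropping zero-variance motion regressors")
            conf = conf[keep] if keep else None
        dm = build_design_matrix(
            events, run.n_scans, run.tr, hrf=hrf,
            highpass_cutoff=highpass_cutoff, confounds=conf,
        )
        fits.append(fit_run_glm(run, dm))
    conditions = list(conditions) if conditions is not None else sorted(
        design["trial_type"].unique()
    )
    if mask is None:
        mask = np.ones(fits[0].grid.shape, dtype=bool)
    return fits, extract_beta_patterns(fits, conditions, mask, subject=subject)
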