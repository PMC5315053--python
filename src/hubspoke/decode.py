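"""Meta-analytic spatial decoding.

Ranks a library of unthresholded term-association maps by their Pearson
spatial correlation with an input statistic map (the NeuroSynth "decoder"
operation): the top-k positively and top-k negatively correlated terms
characterize the likely functional interpretation of the map. The real
meta-analytic database is not shipped; :func:`make_synthetic_term_maps`
generates an orthogonalized synthetic term library for testing and demos.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import VolumeGrid


@dataclass
class TermMapSet:
    """Named unthresholded 3D maps on a shared grid."""

    names: list
    maps: np.ndarray  # (n_terms, x, y, z)
    grid: VolumeGrid
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if len(self.names) != len(set(self.names)):
            raise ValueError("term names must be unique")
        if len(self.names) < 2:
            raise ValueError("a term set needs >= 2 maps")
        if self.maps.shape != (len(self.names), *self.grid.shape):
            raise ValueError("maps shape does not match names/grid")

    def valid_mask(self) -> np.ndarray:
        valid = np.all(np.isfinite(self.maps), axis=0)
        if self.mask is not None:
            valid &= np.asarray(self.mask, dtype=bool)
        return valid


def spatial_term_decode(
    input_map: np.ndarray,
    terms: TermMapSet,
    k: int = 15,
    valid: np.ndarray | None = None,
) -> dict:
    """Rank term maps by spatial correlation with ``input_map``.

    Pearson r is computed over the intersection of the input's valid voxels
    (finite, plus the optional ``valid`` mask) and the term set's mask; at
    least 10 voxels must overlap. Returns ``{'positive': ..., 'negative':
    ...}`` DataFrames of the k most positively / most negatively correlated
    terms (ties broken by term name). Zero-variance terms are excluded and
    listed under ``attrs['excluded']``.
    """
    input_map = np.asarray(input_map, dtype=float)
    if input_map.shape != tuple(terms.grid.shape):
        raise ValueError("input map is not on the term set's grid")
    voxels = np.isfinite(input_map) & terms.valid_mask()
    if valid is not None:
        voxels &= np.asarray(valid, dtype=bool)
    if int(voxels.sum()) < 10:
        raise ValueError(f"only {int(voxels.sum())} overlapping valid voxels (< 10)")
    x = input_map[voxels]
    x = x - x.mean()
    x_sd = x.std()
    if x_sd <= 0:
        raise ValueError("input map has zero variance over the valid voxels")

    T = terms.maps[:, voxels]
    T = T - T.mean(axis=1, keepdims=True)
    t_sd = T.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (T @ x) / (x.size * t_sd * x_sd)
    ok = t_sd > 0
    frame = pd.DataFrame({"term": terms.names, "r": r})[ok]
    excluded = [n for n, good in zip(terms.names, ok) if not good]

    k_eff = min(k, len(frame))
    pos = frame.sort_values(["r", "term"], ascending=[False, True], ignore_index=True).head(k_eff)
    neg = frame.sort_values(["r", "term"], ascending=[True, True], ignore_index=True).head(k_eff)
    pos = pos.assign(rank=np.arange(1, len(pos) + 1), sign="positive")
    neg = neg.assign(rank=np.arange(1, len(neg) + 1), sign="negative")
    out = {"positive": pos, "negative": neg}
    pos.attrs["excluded"] = excluded
    neg.attrs["excluded"] = excluded
    return out


def make_synthetic_term_maps(
    grid: VolumeGrid,
    n_terms: int = 50,
    seed: int = 0,
    smooth_vox: float = 1.0,
    include: dict | None = None,
) -> TermMapSet:
    """Synthetic orthogonal "term" maps for decoder tests and demos.

    Smooth random volumes are orthogonalized (QR over voxels) and scaled to
    unit variance, giving an uncorrelated basis of pseudo-meta-analytic maps.
    ``include`` maps of known structure (e.g. a phantom network territory)
    are prepended un-orthogonalized under their own names.
    """
    rng = np.random.default_rng(seed)
    n_vox = grid.n_voxels
    if n_terms > n_vox:
        raise ValueError("cannot orthogonalize more terms than voxels")
    raw = rng.standard_normal((n_vox, n_terms))
    if smooth_vox > 0:
        vols = raw.T.reshape(n_terms, *grid.shape)
        vols = np.stack([gaussian_filter(v, smooth_vox) for v in vols])
        raw = vols.reshape(n_terms, n_vox).T
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)
    q = q / q.std(axis=0, keepdims=True)
    names = [f"term_{i:03d}" for i in range(n_terms)]
    maps = np.ascontiguousarray(q.T.reshape(n_terms, *grid.shape))
    if include:
        inc_names = list(include.keys())
        inc_maps = np.stack([np.asarray(include[n], dtype=float) for n in inc_names])
        names = inc_names + names
        maps = np.concatenate([inc_maps, maps], axis=0)
    return TermMapSet(names=names, maps=maps, grid=grid)
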