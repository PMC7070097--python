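"""Topographical correlation maps from convolutional activation stacks.

A convolutional layer's activations for one stimulus form an
H x W x D tensor whose first two axes retain the spatial layout of the
input image.  At every (x, y) grid cell the depth vector across
conditions yields a local pattern matrix, hence a local RDM; comparing
each local RDM with a brain ROI RDM (Spearman) produces a 2-D
correlation map that can be upsampled to image resolution — the
"topographical map" relating model spatial selectivity to an ROI.

Coordinate convention (used everywhere in this package): 0-based,
top-left origin, ``y`` indexes rows (height), ``x`` indexes columns
(width); grid cells map linearly onto the image square.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import distance_transform_edt
from scipy.stats import rankdata

from .rdm import compute_rdm, lower_triangle, spearman_rdm_similarity

__all__ = [
    "ActivationStack",
    "RDMField",
    "vectorize_layer",
    "extract_position_patterns",
    "build_rdm_field",
    "correlation_map",
    "correlation_maps",
    "upsample_map",
]


@dataclass(frozen=True)
class ActivationStack:
    """Conditions x H x W x D activation tensor for one layer."""

    values: np.ndarray
    layer_id: str = "layer"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        if v.ndim != 4:
            raise ValueError("stack must be conditions x H x W x D")
        n, H, W, D = v.shape
        if n < 2 or H < 1 or W < 1 or D < 2:
            raise ValueError("need >= 2 conditions, H, W >= 1 and D >= 2")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]

    @property
    def depth(self) -> int:
        return self.values.shape[3]


@dataclass(frozen=True)
class RDMField:
    """H x W grid of per-position RDMs.

    ``values[y, x]`` is the conditions x conditions RDM at that cell;
    degenerate cells (a zero-variance depth pattern) are NaN-filled and
    flagged false in ``valid``.
    """

    values: np.ndarray  # H x W x n x n
    valid: np.ndarray  # H x W bool
    layer_id: str = "layer"

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[0], self.values.shape[1]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[2]


def vectorize_layer(stack: ActivationStack) -> np.ndarray:
    """Flatten a stack to conditions x (H*W*D) in row-major (y, x, d) order."""
    n = stack.n_conditions
    return stack.values.reshape(n, -1)


def extract_position_patterns(stack: ActivationStack, x: int, y: int) -> np.ndarray:
    """Conditions x D depth vectors at grid cell (y=row, x=col)."""
    H, W = stack.grid_shape
    if not (0 <= x < W and 0 <= y < H):
        raise ValueError(
            f"position (x={x}, y={y}) out of range: valid x in [0, {W - 1}], "
            f"y in [0, {H - 1}]"
        )
    return stack.values[:, y, x, :]


def build_rdm_field(stack: ActivationStack) -> RDMField:
    """Per-cell RDMs over the whole grid.

    Cells where any condition's depth vector has zero variance are
    flagged invalid (NaN RDM) rather than aborting the field.
    """
    H, W = stack.grid_shape
    n = stack.n_conditions
    values = np.full((H, W, n, n), np.nan)
    valid = np.zeros((H, W), dtype=bool)
    for yy in range(H):
        for xx in range(W):
            pats = extract_position_patterns(stack, xx, yy)
            if np.any(pats.std(axis=1) == 0):
                continue
            values[yy, xx] = compute_rdm(pats)
            valid[yy, xx] = True
    return RDMField(values=values, valid=valid, layer_id=stack.layer_id)


def _triangle_ranks(field: RDMField) -> np.ndarray:
    """Average-rank-transformed lower triangles, (H*W) x n_pairs, NaN rows invalid."""
    H, W = field.grid_shape
    n = field.n_conditions
    iu = np.tril_indices(n, k=-1)
    out = np.full((H * W, iu[0].size), np.nan)
    flat_valid = field.valid.ravel().copy()
    tris = field.values.reshape(H * W, n, n)[:, iu[0], iu[1]]
    for i in np.flatnonzero(flat_valid):
        if np.ptp(tris[i]) == 0:
            flat_valid[i] = False  # constant triangle: rho undefined
            continue
        out[i] = rankdata(tris[i])
    return out


def correlation_map(field: RDMField, roi_rdm: np.ndarray) -> np.ndarray:
    """H x W Spearman map of per-cell RDMs against one ROI RDM.

    Degenerate (invalid or constant-triangle) cells propagate as NaN.
    """
    maps = correlation_maps(field, [roi_rdm])
    return maps[0]


def correlation_maps(field: RDMField, roi_rdms) -> np.ndarray:
    """Batch version: len(roi_rdms) x H x W Spearman maps.

    Cell triangles are rank-transformed once and correlated with every
    ROI RDM's ranked triangle by vectorized Pearson-on-ranks, which is
    exactly Spearman with average ranks.
    """
    H, W = field.grid_shape
    n = field.n_conditions
    for r in roi_rdms:
        if np.asarray(r).shape != (n, n):
            raise ValueError(
                f"ROI RDM shape {np.asarray(r).shape} does not match the "
                f"field's {n} conditions"
            )
    cell_ranks = _triangle_ranks(field)
    valid_rows = ~np.isnan(cell_ranks[:, 0])
    X = cell_ranks[valid_rows]
    Xc = X - X.mean(axis=1, keepdims=True)
    Xn = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)
    out = np.full((len(roi_rdms), H * W), np.nan)
    for j, roi in enumerate(roi_rdms):
        tri = lower_triangle(np.asarray(roi, float))
        if np.ptp(tri) == 0:
            continue  # constant ROI triangle: undefined everywhere
        yr = rankdata(tri)
        yc = yr - yr.mean()
        yn = yc / np.linalg.norm(yc)
        out[j, valid_rows] = Xn @ yn
    return out.reshape(len(roi_rdms), H, W)


def upsample_map(
    corr_map: np.ndarray, out_h: int, out_w: int, method: str = "bilinear"
) -> np.ndarray:
    """Upsample an H x W map to (out_h, out_w) for display.

    Bilinear (default) or nearest-neighbor, corner-aligned: output pixel
    (i, j) samples input coordinate ``(i*(H-1)/(out_h-1), j*(W-1)/(out_w-1))``.
    NaN cells are excluded from the interpolation support (filled from
    the nearest valid cell) and output pixels whose nearest input cell
    is invalid stay NaN.  Bilinear output extremes are bounded by the
    valid input extremes; downsampling is rejected.
    """
    m = np.asarray(corr_map, float)
    if m.ndim != 2:
        raise ValueError("map must be 2-D")
    H, W = m.shape
    if out_h < H or out_w < W:
        raise ValueError(
            f"refusing to downsample: requested ({out_h}, {out_w}) below ({H}, {W})"
        )
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown interpolation method {method!r}")
    if (out_h, out_w) == (H, W):
        return m.copy()

    invalid = ~np.isfinite(m)
    filled = m
    if invalid.any():
        if invalid.all():
            return np.full((out_h, out_w), np.nan)
        idx = distance_transform_edt(invalid, return_indices=True, return_distances=False)
        filled = m[tuple(idx)]

    ys = np.linspace(0, H - 1, out_h) if out_h > 1 else np.zeros(1)
    xs = np.linspace(0, W - 1, out_w) if out_w > 1 else np.zeros(1)
    if H == 1 or W == 1:
        # interpolation along a length-1 axis degenerates to repetition
        rows = np.clip(np.round(ys).astype(int), 0, H - 1)
        cols = np.clip(np.round(xs).astype(int), 0, W - 1)
        out = filled[np.ix_(rows, cols)].astype(float)
    else:
        interp = RegularGridInterpolator(
            (np.arange(H), np.arange(W)),
            filled,
            method="linear" if method == "bilinear" else "nearest",
        )
        yy, xx = np.meshgrid(ys, xs, indexing="ij")
        out = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(out_h, out_w)
    if invalid.any():
        near_r = np.clip(np.round(ys).astype(int), 0, H - 1)
        near_c = np.clip(np.round(xs).astype(int), 0, W - 1)
        mask = invalid[np.ix_(near_r, near_c)]
        out[mask] = np.nan
    return out
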