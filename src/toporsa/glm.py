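"""Minimal event-related GLM: HRF design matrices, OLS betas and residuals.

Condition events are modeled as zero-duration impulses convolved with a
canonical double-gamma hemodynamic response function (HRF) sampled on an
oversampled time grid and read out at scan times.  Ordinary least
squares gives one beta pattern per image condition plus the residual
time series used downstream for noise-covariance estimation.

No automatic intercept is added: run/constant regressors are passed
explicitly as nuisance columns, mirroring the usual per-run constant
convention of first-level fMRI models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .conditions import NULL_ID, EventSequence

_OVERSAMPLING = 16


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF shape.

    Defaults follow the standard canonical response: response peak near
    6 s, undershoot near 16 s, undershoot one sixth the peak amplitude,
    32 s support.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0


def double_gamma_hrf(times: np.ndarray, params: HRFParams | None = None) -> np.ndarray:
    """Sample the canonical double-gamma HRF at ``times`` (seconds).

    Normalized to unit peak amplitude; zero for negative times and
    beyond ``params.duration``.
    """
    params = params or HRFParams()

    def shape(t):
        return gamma_dist.pdf(
            t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
        ) - params.undershoot_ratio * gamma_dist.pdf(
            t,
            params.undershoot_delay / params.undershoot_dispersion,
            scale=params.undershoot_dispersion,
        )

    t = np.asarray(times, dtype=float)
    h = np.where((t < 0) | (t > params.duration), 0.0, shape(t))
    # normalize on a fixed dense grid so the scale is sample-independent
    peak = np.max(np.abs(shape(np.arange(0.0, params.duration, 0.01))))
    return h / peak if peak > 0 else h


@dataclass(frozen=True)
class DesignMatrix:
    """Scans x regressors design with named columns.

    ``condition_names`` flags which columns are image-condition
    regressors (the ones exported as beta patterns).
    """

    matrix: np.ndarray
    regressor_names: tuple[str, ...]
    tr: float
    condition_columns: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != len(self.regressor_names):
            raise ValueError("matrix columns must match regressor_names")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]


def build_design_matrix(
    events: EventSequence,
    n_scans: int,
    tr: float,
    hrf: HRFParams | None = None,
    nuisance: np.ndarray | None = None,
    nuisance_names: tuple[str, ...] | None = None,
    model_nulls: bool = True,
) -> DesignMatrix:
    """HRF-convolved design: condition columns, optional null and nuisance.

    Each image condition gets one column: unit impulses at its onsets on
    a grid oversampled ``16x`` relative to ``tr``, convolved with the
    sampled HRF and read out at scan times.  Null trials, when present
    and ``model_nulls`` is true, are collapsed into a single nuisance
    regressor built the same way.  ``nuisance`` columns (e.g. motion and
    run constants) are appended unchanged.
    """
    hrf = hrf or HRFParams()
    total_time = n_scans * tr
    if np.any(events.onsets >= total_time):
        raise ValueError(
            f"event onset beyond scan range: max onset {events.onsets.max():.2f}s, "
            f"scans cover [0, {total_time:.2f})s"
        )
    dt = tr / _OVERSAMPLING
    n_fine = n_scans * _OVERSAMPLING
    kernel = double_gamma_hrf(np.arange(0, hrf.duration + dt, dt), hrf)
    scan_rows = np.arange(n_scans) * _OVERSAMPLING

    def convolved_column(onsets: np.ndarray) -> np.ndarray:
        impulses = np.zeros(n_fine)
        bins = np.round(onsets / dt).astype(int)
        np.add.at(impulses, np.clip(bins, 0, n_fine - 1), 1.0)
        return np.convolve(impulses, kernel)[:n_fine][scan_rows]

    columns: list[np.ndarray] = []
    names: list[str] = []
    cond_cols: list[int] = []
    for cid in events.image_condition_ids:
        col = convolved_column(events.onsets[events.condition_ids == cid])
        if not np.any(col):
            raise ValueError(f"condition {cid} produced an all-zero column")
        cond_cols.append(len(columns))
        columns.append(col)
        names.append(f"cond{cid:03d}")
    if model_nulls and events.n_null > 0:
        columns.append(convolved_column(events.onsets[events.condition_ids == NULL_ID]))
        names.append("null")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, float))
        if nuisance.shape[0] != n_scans:
            raise ValueError("nuisance rows must equal n_scans")
        if np.any(~nuisance.any(axis=0)):
            raise ValueError("all-zero nuisance column rejected")
        if nuisance_names is None:
            nuisance_names = tuple(f"nuis{i}" for i in range(nuisance.shape[1]))
        if len(nuisance_names) != nuisance.shape[1]:
            raise ValueError("nuisance_names length mismatch")
        columns.extend(nuisance.T)
        names.extend(nuisance_names)
    return DesignMatrix(
        matrix=np.column_stack(columns),
        regressor_names=tuple(names),
        tr=tr,
        condition_columns=tuple(cond_cols),
    )


@dataclass(frozen=True)
class GLMResult:
    """OLS fit: condition beta patterns plus full residual time series."""

    betas: np.ndarray  # image conditions x voxels
    residuals: np.ndarray  # scans x voxels
    all_betas: np.ndarray  # regressors x voxels
    design: DesignMatrix


def fit_glm(timeseries: np.ndarray, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares fit of ``timeseries`` on ``design``.

    Rank-deficient designs fall back to the minimum-norm pseudo-inverse
    solution with a warning.  ``betas`` contains only the
    image-condition rows; nuisance betas stay in ``all_betas``.
    """
    Y = np.asarray(timeseries, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"scans mismatch: data has {Y.shape[0]}, design has {X.shape[0]}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"design is rank deficient ({rank}/{X.shape[1]}); "
            "using pseudo-inverse solution",
            stacklevel=2,
        )
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    residuals = Y - X @ B
    return GLMResult(
        betas=B[list(design.condition_columns)],
        residuals=residuals,
        all_betas=B,
        design=design,
    )
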