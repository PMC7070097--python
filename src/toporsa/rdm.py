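"""Representational-space machinery.

Dissimilarity here is ``1 - Pearson correlation`` between condition
response patterns, collected into a square representational
dissimilarity matrix (RDM).  RDMs from different measurement systems
(voxel betas, network units) are compared by Spearman rank correlation
of their strictly-lower-triangle entries, putting brain and model in a
common representational space.

Also provided: shrinkage estimation of the voxel noise covariance from
GLM residuals, multivariate noise normalization (whitening by the
symmetric inverse square root of that covariance), leave-one-out noise
ceilings, and classical (Torgerson) multidimensional scaling for
visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.covariance import ledoit_wolf as _sk_ledoit_wolf

__all__ = [
    "estimate_noise_covariance",
    "whiten_patterns",
    "compute_rdm",
    "spearman_rdm_similarity",
    "NoiseCeiling",
    "compute_noise_ceiling",
    "mds_embed",
    "validate_rdm",
    "write_rdm_text",
    "read_rdm_text",
    "lower_triangle",
]


def lower_triangle(rdm: np.ndarray) -> np.ndarray:
    """Strictly-lower-triangle entries of a square matrix, row-major."""
    rdm = np.asarray(rdm)
    if rdm.ndim != 2 or rdm.shape[0] != rdm.shape[1]:
        raise ValueError("expected a square matrix")
    return rdm[np.tril_indices(rdm.shape[0], k=-1)]


def estimate_noise_covariance(
    residuals: np.ndarray, shrinkage: str = "diag_shrink", ridge: float = 1e-3
) -> np.ndarray:
    """Estimate the feature x feature noise covariance from residuals.

    Methods
    -------
    ``"diag_shrink"`` (default)
        Sample covariance shrunk toward its own diagonal with a
        data-driven intensity (Schafer-Strimmer style: the ratio of the
        summed sampling variances of the off-diagonal entries to their
        summed squares).  Diagonal entries are preserved exactly and the
        result is positive definite whenever the intensity is positive,
        even with more features than timepoints.
    ``"ledoit_wolf"``
        Ledoit-Wolf shrinkage toward the scaled identity (scikit-learn).
    ``"sample_ridge"``
        Sample covariance plus ``ridge * mean-variance`` on the diagonal.
    """
    R = np.asarray(residuals, float)
    if R.ndim != 2:
        raise ValueError("residuals must be a timepoints x features matrix")
    T, F = R.shape
    if T < 2:
        raise ValueError("need at least 2 residual timepoints")
    Rc = R - R.mean(axis=0)
    S = Rc.T @ Rc / (T - 1)

    if shrinkage == "diag_shrink":
        # Sampling variance of each off-diagonal covariance entry.
        W = Rc[:, :, None] * Rc[:, None, :]  # T x F x F outer products
        var_s = T / (T - 1) ** 3 * np.sum((W - W.mean(axis=0)) ** 2, axis=0)
        off = ~np.eye(F, dtype=bool)
        denom = np.sum(S[off] ** 2)
        lam = 1.0 if denom <= 0 else float(np.clip(np.sum(var_s[off]) / denom, 0.0, 1.0))
        lam = max(lam, 1e-3)  # keep strictly positive for definiteness
        cov = (1.0 - lam) * S
        np.fill_diagonal(cov, np.diag(S))
    elif shrinkage == "ledoit_wolf":
        cov, _ = _sk_ledoit_wolf(Rc, assume_centered=True)
    elif shrinkage == "sample_ridge":
        cov = S + ridge * np.mean(np.diag(S)) * np.eye(F)
    else:
        raise ValueError(f"unknown shrinkage method {shrinkage!r}")
    return (cov + cov.T) / 2.0


def _inverse_sqrt(cov: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(cov)
    if w.min() <= 0:
        raise ValueError("covariance must be positive definite for whitening")
    return (V * (w**-0.5)) @ V.T


def whiten_patterns(patterns: np.ndarray, covariance: np.ndarray) -> np.ndarray:
    """Multivariate noise normalization: ``patterns @ cov^(-1/2)``.

    Uses the symmetric inverse square root so the operation does not
    depend on a feature ordering (as a triangular Cholesky factor
    would).  With a diagonal covariance this reduces to dividing each
    feature by its noise standard deviation.
    """
    P = np.asarray(patterns, float)
    C = np.asarray(covariance, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance must be square")
    if P.shape[1] != C.shape[0]:
        raise ValueError(
            f"dimension mismatch: patterns have {P.shape[1]} features, "
            f"covariance is {C.shape[0]} x {C.shape[1]}"
        )
    return P @ _inverse_sqrt(C)


def compute_rdm(patterns: np.ndarray) -> np.ndarray:
    """Condition x condition RDM of ``1 - Pearson`` dissimilarities.

    Correlation is taken across the feature axis.  The result is
    exactly symmetric with a zero diagonal and entries in [0, 2].
    """
    P = np.asarray(patterns, float)
    if P.ndim != 2 or P.shape[0] < 2 or P.shape[1] < 2:
        raise ValueError("patterns must be at least 2 conditions x 2 features")
    sd = P.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance pattern for condition(s) {bad.tolist()}; "
            "correlation distance is undefined"
        )
    d = 1.0 - np.corrcoef(P)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def validate_rdm(rdm: np.ndarray, atol: float = 1e-12) -> None:
    """Raise unless ``rdm`` is symmetric, zero-diagonal and within [0, 2]."""
    rdm = np.asarray(rdm, float)
    if rdm.ndim != 2 or rdm.shape[0] != rdm.shape[1]:
        raise ValueError("RDM must be square")
    if np.max(np.abs(rdm - rdm.T)) > atol:
        raise ValueError("RDM is not symmetric")
    if np.max(np.abs(np.diag(rdm))) > atol:
        raise ValueError("RDM diagonal is not zero")
    if rdm.min() < -atol or rdm.max() > 2 + atol:
        raise ValueError("RDM entries outside [0, 2]")


def spearman_rdm_similarity(rdm_a: np.ndarray, rdm_b: np.ndarray) -> float:
    """Spearman rho between the lower triangles of two RDMs.

    Ties get average ranks; the diagonal is always excluded.  If either
    triangle is constant the correlation is undefined and NaN is
    returned with a warning.
    """
    a = np.asarray(rdm_a, float)
    b = np.asarray(rdm_b, float)
    if a.shape != b.shape:
        raise ValueError(f"RDM shape mismatch: {a.shape} vs {b.shape}")
    va, vb = lower_triangle(a), lower_triangle(b)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        warnings.warn("constant RDM triangle: Spearman rho undefined", stacklevel=2)
        return float("nan")
    return float(spearmanr(va, vb).statistic)


@dataclass(frozen=True)
class NoiseCeiling:
    """Bounds on the RDM correlation attainable by the true model."""

    lower: float
    upper: float


def compute_noise_ceiling(subject_rdms: list[np.ndarray]) -> NoiseCeiling:
    """Leave-one-out noise ceiling over subjects.

    lower = mean over subjects of Spearman(subject RDM, mean RDM of the
    other subjects); upper = the same against the mean of all subjects
    (the subject's own RDM included, hence the optimistic bound).
    """
    if len(subject_rdms) < 2:
        raise ValueError("noise ceiling needs at least 2 subjects")
    stack = np.stack([np.asarray(r, float) for r in subject_rdms])
    total = stack.sum(axis=0)
    n = stack.shape[0]
    mean_all = total / n
    lowers, uppers = [], []
    for s in range(n):
        loo = (total - stack[s]) / (n - 1)
        lowers.append(spearman_rdm_similarity(stack[s], loo))
        uppers.append(spearman_rdm_similarity(stack[s], mean_all))
    return NoiseCeiling(lower=float(np.mean(lowers)), upper=float(np.mean(uppers)))


def mds_embed(rdm: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates for an RDM.

    Double-centers the squared dissimilarities, eigendecomposes, and
    returns the top ``n_dims`` coordinate axes scaled by the square
    roots of their (positive) eigenvalues.  If fewer positive
    eigenvalues exist, the output is truncated with a warning.
    """
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    D = np.asarray(rdm, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("RDM must be square")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = max(w.max(), 0.0) * n * np.finfo(float).eps
    n_pos = int(np.sum(w > tol))
    if n_dims > n_pos:
        warnings.warn(
            f"only {n_pos} positive MDS dimensions available; "
            f"truncating from {n_dims}",
            stacklevel=2,
        )
        n_dims = n_pos
    return V[:, :n_dims] * np.sqrt(w[:n_dims])


def write_rdm_text(rdm: np.ndarray, path) -> None:
    """Write an RDM as tab-delimited text with condition ids as header."""
    rdm = np.asarray(rdm, float)
    validate_rdm(rdm)
    frame = pd.DataFrame(rdm, columns=[str(i) for i in range(rdm.shape[0])])
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_rdm_text(path) -> np.ndarray:
    """Read a tab-delimited RDM and validate its invariants."""
    rdm = pd.read_csv(path, sep="\t").to_numpy(float)
    rdm = (rdm + rdm.T) / 2.0  # absorb round-trip rounding
    validate_rdm(rdm, atol=1e-9)
    return rdm
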