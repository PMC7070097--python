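"""Calibration and validation studies run on the package's own machinery.

These are the simulation experiments that characterize the statistical
behaviour of the pipeline: type-I error of the pointwise sign-flip
test, familywise error of cluster-size inference on smooth null maps,
recovery of center/periphery spatial selectivity, whitening accuracy,
and the classical-MDS round trip.  Both the test suite and the
acceptance script call these entry points, so the reported numbers are
always produced by the same code paths users run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, orthogonal_procrustes
from scipy.ndimage import gaussian_filter

from .inference import cluster_size_inference, sign_permutation_test
from .rdm import compute_rdm, estimate_noise_covariance, mds_embed, whiten_patterns
from .synthetic import (
    GroundTruthSpec,
    ar1_covariance,
    generate_activation_stacks,
    generate_condition_set,
    generate_roi_dataset,
)
from .topography import build_rdm_field, correlation_maps

__all__ = [
    "type1_error_simulation",
    "cluster_fwer_simulation",
    "TopographyRecovery",
    "topography_recovery",
    "whitening_identity_check",
    "mds_roundtrip_residual",
]


def type1_error_simulation(
    n_datasets: int = 1000,
    n_subjects: int = 15,
    map_shape: tuple[int, int] = (5, 5),
    n_permutations: int = 200,
    p_threshold: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the two-sided sign-flip test on i.i.d. null maps.

    Each dataset is subjects x map of independent standard normals (the
    null of zero mean holds exactly); returns the fraction of cells
    over all datasets with p below ``p_threshold``.  Nominal behaviour
    is a rate close to the threshold.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    total = 0
    for i in range(n_datasets):
        data = rng.standard_normal((n_subjects, *map_shape))
        res = sign_permutation_test(
            data, n_permutations=n_permutations, tail="two", seed=int(rng.integers(2**31))
        )
        rejections += int(np.sum(res.pointwise_p < p_threshold))
        total += res.pointwise_p.size
    return rejections / total


def cluster_fwer_simulation(
    n_datasets: int = 500,
    n_subjects: int = 15,
    grid: int = 13,
    smooth_sigma: float = 1.5,
    n_permutations: int = 200,
    cdt: float = 0.01,
    alpha: float = 0.05,
    connectivity: int = 8,
    seed: int = 0,
) -> float:
    """Familywise error of cluster-size inference on smooth null maps.

    Subject maps are spatially smoothed Gaussian noise (no signal
    anywhere); an error is any dataset yielding at least one cluster
    with corrected p <= alpha.  Proper FWER control keeps the rate at
    or below ``alpha`` up to Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    errors = 0
    for i in range(n_datasets):
        data = rng.standard_normal((n_subjects, grid, grid))
        data = np.stack([gaussian_filter(m, smooth_sigma) for m in data])
        res = sign_permutation_test(
            data, n_permutations=n_permutations, tail="two", seed=int(rng.integers(2**31))
        )
        clu = cluster_size_inference(res, cdt=cdt, alpha=alpha, connectivity=connectivity)
        if any(c.p_value <= alpha for c in clu.clusters):
            errors += 1
    return errors / n_datasets


@dataclass(frozen=True)
class TopographyRecovery:
    """Outcome of repeated spatial-selectivity recovery simulations."""

    n_replicates: int
    n_success: int

    @property
    def rate(self) -> float:
        return self.n_success / self.n_replicates


def _central_square(grid: int) -> tuple[int, int]:
    lo = grid // 3
    return lo, grid - lo  # half-open [lo, hi)


def topography_recovery(
    profile: str,
    n_replicates: int = 20,
    n_conditions: int = 40,
    n_subjects: int = 15,
    grid: int = 13,
    depth: int = 24,
    n_voxels: int = 60,
    n_residual_timepoints: int = 150,
    n_permutations: int = 200,
    cdt: float = 0.01,
    alpha: float = 0.05,
    seed: int = 0,
) -> TopographyRecovery:
    """Recover the injected spatial gain from the full topographic pipeline.

    Each replicate simulates an ROI and a single-layer stack sharing one
    latent category code, with ``profile`` ("center" or "periphery")
    spatial gain in the stack; subject maps are per-position RDM
    correlations against each subject's noise-normalized ROI RDM, and
    group inference is two-sided sign-flip cluster-size correction.

    Success criteria:

    * ``center`` — the significance mask is non-empty and its center of
      mass lies inside the central-third square of the grid.
    * ``periphery`` — the argmax of the group-mean map lies outside the
      central-third square (the outer ring).
    """
    if profile not in ("center", "periphery"):
        raise ValueError("profile must be 'center' or 'periphery'")
    lo, hi = _central_square(grid)
    success = 0
    for rep in range(n_replicates):
        rep_seed = seed * 100003 + rep
        conditions = generate_condition_set(n_conditions, seed=rep_seed)
        spec = GroundTruthSpec(
            spatial_gain_profile=profile,
            seed=rep_seed,
        )
        roi = generate_roi_dataset(
            conditions,
            spec,
            n_subjects=n_subjects,
            n_voxels=n_voxels,
            n_residual_timepoints=n_residual_timepoints,
        )
        subject_rdms = []
        for patterns, residuals in roi:
            cov = estimate_noise_covariance(residuals)
            subject_rdms.append(compute_rdm(whiten_patterns(patterns, cov)))
        stack = generate_activation_stacks(
            conditions, spec, n_layers=1, H=grid, W=grid, D=depth
        )[0]
        field = build_rdm_field(stack)
        maps = correlation_maps(field, subject_rdms)
        res = sign_permutation_test(
            maps, n_permutations=n_permutations, tail="two", seed=rep_seed
        )
        if profile == "center":
            clu = cluster_size_inference(res, cdt=cdt, alpha=alpha)
            mask = clu.significance_mask
            if mask.any():
                com = np.argwhere(mask).mean(axis=0)
                if lo <= com[0] < hi and lo <= com[1] < hi:
                    success += 1
        else:
            stat = np.nan_to_num(res.stat_map, nan=-np.inf)
            peak = np.unravel_index(np.argmax(stat), stat.shape)
            inside = lo <= peak[0] < hi and lo <= peak[1] < hi
            if not inside:
                success += 1
    return TopographyRecovery(n_replicates=n_replicates, n_success=success)


def whitening_identity_check(
    n_features: int = 8,
    n_samples: int = 10_000,
    rho: float = 0.6,
    seed: int = 0,
) -> float:
    """Max |off-diagonal| of the empirical covariance after whitening.

    Noise is drawn from a known AR(1) covariance and whitened by its
    symmetric inverse square root; the empirical covariance of the
    whitened draws should be close to the identity.
    """
    cov = ar1_covariance(n_features, rho=rho)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_samples, n_features)) @ cholesky(cov, lower=True).T
    white = whiten_patterns(noise, cov)
    emp = np.cov(white, rowvar=False)
    off = emp - np.diag(np.diag(emp))
    return float(np.max(np.abs(off)))


def mds_roundtrip_residual(seed: int = 0, n_points: int = 4) -> float:
    """Frobenius Procrustes residual of classical MDS on planar points.

    Draws ``n_points`` points in the plane, builds their Euclidean
    distance matrix, embeds with classical MDS in 2-D, and aligns the
    embedding to the originals by an orthogonal (rotation/reflection)
    Procrustes transform; the residual is the Frobenius norm of the
    aligned difference.
    """
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_points, 2))
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    coords = mds_embed(dist, 2)
    a = coords - coords.mean(axis=0)
    b = pts - pts.mean(axis=0)
    R, _ = orthogonal_procrustes(a, b)
    return float(np.linalg.norm(a @ R - b))
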