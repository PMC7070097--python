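"""Group-level nonparametric statistics for correlation maps and RSA summaries.

Two ingredients, both distribution-free under the null hypothesis of
zero correlation with a sign-symmetric sampling distribution:

* **Sign-flip permutation tests** — the null is built by randomly
  negating whole subject-level maps (the flip applies to a subject's
  entire map, preserving its spatial covariance).  P-values follow the
  add-one rule: the observed labeling counts as one permutation, so the
  smallest attainable p is ``1/(n_permutations + 1)``.

* **Cluster-size inference** — candidate clusters are connected
  components of cells below the cluster-defining threshold (CDT),
  formed separately on positive and negative statistics; each cluster's
  familywise-corrected p compares its size with the permutation null of
  the maximum cluster size anywhere on the map (either sign), reusing
  the very flips that produced the pointwise null.

Layerwise RSA summaries use one-sided sign-flip tests ("correlation
above zero") with Bonferroni correction over the layer x ROI family,
exhaustively enumerating all 2^N sign patterns when N is small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import generate_binary_structure, label

__all__ = [
    "SignFlipResult",
    "sign_permutation_test",
    "Cluster",
    "ClusterResult",
    "cluster_size_inference",
    "LayerRSAResult",
    "layerwise_rsa_stats",
]


@dataclass(frozen=True)
class SignFlipResult:
    """Observed statistics plus the permutation record needed downstream."""

    stat_map: np.ndarray  # mean across subjects, map-shaped
    pointwise_p: np.ndarray  # map-shaped, NaN at invalid cells
    perm_stats: np.ndarray  # n_permutations x n_cells (flattened maps)
    flips: np.ndarray  # n_permutations x n_subjects, entries +-1
    counts: np.ndarray  # retained subjects per cell, flattened
    tail: str
    seed: int

    @property
    def n_permutations(self) -> int:
        return self.perm_stats.shape[0]

    @property
    def map_shape(self) -> tuple[int, ...]:
        return self.stat_map.shape


def sign_permutation_test(
    subject_values: np.ndarray,
    n_permutations: int = 1000,
    tail: str = "two",
    seed: int = 0,
) -> SignFlipResult:
    """Cell-wise sign-flip permutation test of zero mean across subjects.

    ``subject_values`` is subjects x (map shape); NaN entries drop that
    subject at that cell only (at least 2 must remain, else the cell is
    flagged NaN).  The group statistic is the across-subject mean.
    ``tail`` is ``"two"`` (|mean|) or ``"greater"``.
    """
    V = np.asarray(subject_values, float)
    if V.ndim < 2:
        V = V[:, None]
    S = V.shape[0]
    if S < 2:
        raise ValueError("need at least 2 subjects")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if tail not in ("two", "greater"):
        raise ValueError("tail must be 'two' or 'greater'")
    map_shape = V.shape[1:]
    flat = V.reshape(S, -1)
    finite = np.isfinite(flat)
    counts = finite.sum(axis=0)
    usable = counts >= 2
    Z = np.where(finite, flat, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        obs = np.where(usable, Z.sum(axis=0) / counts, np.nan)

    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_permutations, S)) * 2 - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        perm = (flips @ Z) / counts
    perm[:, ~usable] = np.nan

    eps = 1e-12 * max(np.nanmax(np.abs(obs), initial=0.0), 1.0)
    if tail == "two":
        exceed = np.abs(perm) >= np.abs(obs)[None, :] - eps
    else:
        exceed = perm >= obs[None, :] - eps
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = (1.0 + np.nansum(exceed, axis=0)) / (n_permutations + 1.0)
    p = np.where(usable, p, np.nan)

    return SignFlipResult(
        stat_map=obs.reshape(map_shape),
        pointwise_p=p.reshape(map_shape),
        perm_stats=perm,
        flips=flips,
        counts=counts,
        tail=tail,
        seed=seed,
    )


@dataclass(frozen=True)
class Cluster:
    """One suprathreshold connected component."""

    members: np.ndarray  # k x 2 (row, col) cell indices
    size: int
    p_value: float
    peak: tuple[int, int]  # cell of max |statistic|
    sign: int  # +1 or -1


@dataclass(frozen=True)
class ClusterResult:
    """Cluster-size inference output for one group map."""

    stat_map: np.ndarray
    pointwise_p: np.ndarray
    clusters: list[Cluster]
    significance_mask: np.ndarray  # bool, union of clusters with p <= alpha
    null_max_sizes: np.ndarray  # permutation null of the max cluster size
    n_permutations: int
    cdt: float
    alpha: float
    connectivity: int
    seed: int

    def table(self):
        """Cluster summary as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "cluster_id": i,
                    "size": c.size,
                    "p_value": c.p_value,
                    "peak_row": c.peak[0],
                    "peak_col": c.peak[1],
                    "sign": c.sign,
                }
                for i, c in enumerate(self.clusters)
            ],
            columns=["cluster_id", "size", "p_value", "peak_row", "peak_col", "sign"],
        )


def _signed_clusters(stat: np.ndarray, below_cdt: np.ndarray, structure: np.ndarray):
    """Connected components of suprathreshold cells, split by statistic sign."""
    comps = []
    for sign in (1, -1):
        mask = below_cdt & np.isfinite(stat) & ((stat > 0) if sign > 0 else (stat < 0))
        labels, n = label(mask, structure=structure)
        for i in range(1, n + 1):
            cells = np.argwhere(labels == i)
            comps.append((sign, cells))
    return comps


def _max_cluster_size(stat: np.ndarray, below_cdt: np.ndarray, structure) -> int:
    best = 0
    for sign in (1, -1):
        mask = below_cdt & np.isfinite(stat) & ((stat > 0) if sign > 0 else (stat < 0))
        labels, n = label(mask, structure=structure)
        if n:
            best = max(best, int(np.bincount(labels.ravel())[1:].max()))
    return best


def cluster_size_inference(
    result: SignFlipResult,
    cdt: float = 0.01,
    alpha: float = 0.05,
    connectivity: int = 8,
) -> ClusterResult:
    """FWER-corrected cluster-size inference on a 2-D sign-flip result.

    Observed clusters are connected components (4- or 8-neighbor) of
    cells with pointwise p < ``cdt``, sign-homogeneous for two-sided
    tests.  The null distribution thresholds every permutation's map at
    the same CDT — each permuted statistic is ranked against the full
    permutation distribution cell-wise — and records the maximum
    cluster size over the map and both signs.  Cluster p-values and the
    significance mask use the add-one rule at level ``alpha``.
    """
    if not 0.0 < cdt < 1.0:
        raise ValueError("cdt must lie in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    stat = result.stat_map
    if stat.ndim != 2:
        raise ValueError("cluster inference expects a 2-D map")
    structure = (
        np.ones((3, 3), dtype=bool)
        if connectivity == 8
        else generate_binary_structure(2, 1)
    )
    H, W = stat.shape
    B = result.n_permutations

    # Exchangeable null: pool the observed labeling with the B flipped
    # labelings, rank every member's statistic cell-wise against the
    # pool (two-sided on |stat|), threshold each member's map at the
    # CDT, and record the maximum cluster size.  Because the observed
    # map is one pool member, cluster p-values are exact permutation
    # p-values with minimum 1/(B+1).
    pool = np.vstack([result.perm_stats, stat.reshape(1, -1)])  # (B+1) x C
    abspool = np.abs(pool)
    order = np.sort(np.nan_to_num(abspool, nan=-np.inf), axis=0)
    C = pool.shape[1]
    eps = 1e-12 * max(np.nanmax(abspool, initial=0.0), 1.0)
    ge_counts = np.empty_like(abspool)
    for c in range(C):
        ge_counts[:, c] = (B + 1) - np.searchsorted(
            order[:, c], abspool[:, c] - eps, side="left"
        )
    pool_p = ge_counts / (B + 1.0)
    pool_p[~np.isfinite(pool)] = np.nan
    max_sizes = np.zeros(B + 1, dtype=int)
    for b in range(B + 1):
        below = pool_p[b].reshape(H, W) < cdt
        max_sizes[b] = _max_cluster_size(pool[b].reshape(H, W), below, structure)
    null_max = max_sizes  # includes the observed member

    below_obs = np.nan_to_num(pool_p[B], nan=1.0).reshape(H, W) < cdt
    clusters = []
    mask = np.zeros((H, W), dtype=bool)
    for sign, cells in _signed_clusters(stat, below_obs, structure):
        size = len(cells)
        p = float(np.sum(null_max >= size) / (B + 1))
        peak_idx = cells[np.argmax(np.abs(stat[cells[:, 0], cells[:, 1]]))]
        clusters.append(
            Cluster(
                members=cells,
                size=size,
                p_value=p,
                peak=(int(peak_idx[0]), int(peak_idx[1])),
                sign=sign,
            )
        )
        if p <= alpha:
            mask[cells[:, 0], cells[:, 1]] = True
    clusters.sort(key=lambda c: (c.p_value, -c.size))
    return ClusterResult(
        stat_map=stat,
        pointwise_p=result.pointwise_p,
        clusters=clusters,
        significance_mask=mask,
        null_max_sizes=null_max,
        n_permutations=B,
        cdt=cdt,
        alpha=alpha,
        connectivity=connectivity,
        seed=result.seed,
    )


@dataclass(frozen=True)
class LayerRSAResult:
    """Layer x ROI RSA summary with Bonferroni-corrected significance."""

    per_subject_rho: np.ndarray  # subjects x layers x rois
    mean: np.ndarray  # layers x rois
    sem: np.ndarray  # layers x rois
    p_uncorrected: np.ndarray
    p_corrected: np.ndarray
    significant: np.ndarray  # bool
    alpha: float
    family_size: int
    noise_ceilings: dict = field(default_factory=dict)


_EXHAUSTIVE_LIMIT = 16  # enumerate all sign patterns up to 2^16 subjects


def _sign_flip_p_one_sided(
    values: np.ndarray, n_permutations: int, seed: int
) -> np.ndarray:
    """One-sided (mean > 0) sign-flip p for each column of subjects x tests.

    Exhaustive over all 2^S sign patterns when S <= 16 (the identity
    labeling is part of the enumeration, so no add-one term); Monte
    Carlo with the add-one rule otherwise.
    """
    S, K = values.shape
    obs = values.mean(axis=0)
    eps = 1e-12 * max(np.max(np.abs(obs), initial=0.0), 1.0)
    if S <= _EXHAUSTIVE_LIMIT:
        n = 2**S
        bits = (np.arange(n)[:, None] >> np.arange(S)[None, :]) & 1
        signs = bits * 2 - 1
        perm = signs @ values / S
        return (perm >= obs[None, :] - eps).mean(axis=0)
    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_permutations, S)) * 2 - 1
    perm = flips @ values / S
    return (1.0 + np.sum(perm >= obs[None, :] - eps, axis=0)) / (n_permutations + 1.0)


def layerwise_rsa_stats(
    per_subject_rhos: np.ndarray,
    alpha: float = 0.05,
    family_size: int | None = None,
    n_permutations: int = 10000,
    seed: int = 0,
    noise_ceilings: dict | None = None,
) -> LayerRSAResult:
    """Mean, SEM and Bonferroni-corrected significance of layerwise rhos.

    ``per_subject_rhos`` is subjects x layers x rois.  Each (layer, roi)
    cell is tested one-sided ("correlation above zero") with a sign-flip
    test on the untransformed rhos; Bonferroni multiplies by
    ``family_size`` (default: layers * rois).
    """
    R = np.asarray(per_subject_rhos, float)
    if R.ndim == 2:
        R = R[:, :, None]
    if R.ndim != 3:
        raise ValueError("expected subjects x layers x rois")
    S, L, K = R.shape
    if S < 2:
        raise ValueError("need at least 2 subjects")
    n_tests = L * K
    if family_size is None:
        family_size = n_tests
    elif family_size < n_tests:
        warnings.warn(
            f"family_size {family_size} smaller than the {n_tests} tests run; "
            "proceeding with the given family",
            stacklevel=2,
        )
    mean = R.mean(axis=0)
    sem = R.std(axis=0, ddof=1) / np.sqrt(S)
    p = _sign_flip_p_one_sided(R.reshape(S, -1), n_permutations, seed).reshape(L, K)
    p_corr = np.minimum(1.0, p * family_size)
    return LayerRSAResult(
        per_subject_rho=R,
        mean=mean,
        sem=sem,
        p_uncorrected=p,
        p_corrected=p_corr,
        significant=p_corr < alpha,
        alpha=alpha,
        family_size=family_size,
        noise_ceilings=noise_ceilings or {},
    )
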