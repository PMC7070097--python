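"""Synthetic study generator: conditions, events, ROI betas and layer stacks.

The generator emulates the data layout of a rapid event-related fMRI
RSA study paired with a convolutional network: 156 natural-image
conditions in 5 categories, 15 subjects, region-of-interest (ROI) beta
patterns with matching GLM-style residuals, and per-layer 3-D
activation stacks whose depth channels carry category signals modulated
by a center- or periphery-weighted spatial gain.

Ground-truth linkage
--------------------
A single latent category code (one prototype vector per category plus
per-condition jitter) is derived from ``GroundTruthSpec.code_seed`` and
injected into *both* the ROI voxel patterns and the stack channel
groups.  Brain-model correlations in downstream analyses are therefore
positive by construction for matched codes, and near zero when the
codes are generated from different seeds.

Every generator is deterministic given its spec: random streams are
keyed as ``default_rng([seed, stream_tag, index])`` so that e.g. adding
a subject never perturbs earlier subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cholesky, toeplitz

from .conditions import CATEGORIES, NULL_ID, ConditionSet, EventSequence

# Stream tags for sub-seeded generators (arbitrary fixed integers).
_STREAM_CODE = 101
_STREAM_ROI_PROJ = 202
_STREAM_SUBJECT = 203
_STREAM_RESIDUAL = 204
_STREAM_LAYER = 303
_STREAM_CONDITIONS = 7
_STREAM_EVENTS = 11

#: Latent dimensions per category in the shared code.
LATENT_DIMS_PER_CATEGORY = 4

#: Standard deviation of per-condition jitter around the category prototype.
WITHIN_CATEGORY_SD = 0.5


def ar1_covariance(n_features: int, rho: float = 0.3, sd: float = 1.0) -> np.ndarray:
    """Toeplitz AR(1)-style covariance ``sd**2 * rho**|i-j|``.

    The default voxel-noise covariance: spatially correlated enough that
    multivariate noise normalization is non-trivial, yet always positive
    definite for ``|rho| < 1``.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    return sd**2 * toeplitz(rho ** np.arange(n_features))


@dataclass(frozen=True)
class GroundTruthSpec:
    """Controllable ground truth for one simulated dataset.

    Parameters
    ----------
    category_signal_strengths:
        Per-category injection weight; larger means the category's
        latent prototype dominates the generated patterns.  Keys are the
        labels in :data:`toporsa.conditions.CATEGORIES`; missing keys
        default to 1.
    spatial_gain_profile:
        ``"center"`` (Gaussian bump at the image center),
        ``"periphery"`` (its complement) or ``"uniform"``.
    gain_scale:
        Width (in normalized image units) of the center Gaussian.
    noise_sd:
        Standard deviation multiplier of the voxel noise added to ROI
        patterns (residuals are drawn from ``noise_covariance`` itself,
        unscaled, as an estimate of the noise structure).
    noise_covariance:
        Feature x feature positive-definite voxel noise covariance, or
        ``None`` to use :func:`ar1_covariance` at generation time.
    seed:
        Master seed of this dataset's random streams.
    code_seed:
        Seed of the shared latent category code; defaults to ``seed``.
        Give two specs the same ``code_seed`` to make their datasets
        carry the same representational geometry.
    """

    category_signal_strengths: dict[str, float] = field(default_factory=dict)
    spatial_gain_profile: str = "center"
    gain_scale: float = 0.25
    noise_sd: float = 1.0
    noise_covariance: np.ndarray | None = None
    seed: int = 0
    code_seed: int | None = None

    def __post_init__(self) -> None:
        if self.spatial_gain_profile not in ("center", "periphery", "uniform"):
            raise ValueError(
                "spatial_gain_profile must be 'center', 'periphery' or 'uniform'"
            )
        if any(v < 0 for v in self.category_signal_strengths.values()):
            raise ValueError("category signal strengths must be non-negative")
        if self.noise_covariance is not None:
            _check_positive_definite(np.asarray(self.noise_covariance, float))

    @property
    def effective_code_seed(self) -> int:
        return self.seed if self.code_seed is None else self.code_seed

    def strength_vector(self) -> np.ndarray:
        return np.array(
            [float(self.category_signal_strengths.get(c, 1.0)) for c in CATEGORIES]
        )


def _check_positive_definite(cov: np.ndarray) -> None:
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    w = np.linalg.eigvalsh(cov)
    if w.min() <= 0:
        raise ValueError("covariance must be positive definite")


def spatial_gain(profile: str, scale: float, H: int, W: int) -> np.ndarray:
    """Evaluate a gain profile on the (H, W) grid of normalized (x, y).

    Cell centers map to ``x = (col + 0.5)/W``, ``y = (row + 0.5)/H`` in
    the unit square.  ``center`` peaks at 1 in the middle; ``periphery``
    is its complement; ``uniform`` is all ones.
    """
    ys = (np.arange(H) + 0.5) / H
    xs = (np.arange(W) + 0.5) / W
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    r2 = (xx - 0.5) ** 2 + (yy - 0.5) ** 2
    bump = np.exp(-r2 / (2.0 * scale**2))
    if profile == "center":
        return bump
    if profile == "periphery":
        return 1.0 - bump
    if profile == "uniform":
        return np.ones((H, W))
    raise ValueError(f"unknown gain profile {profile!r}")


def generate_condition_set(
    n_conditions: int = 156,
    category_counts: dict[str, int] | None = None,
    seed: int = 0,
) -> ConditionSet:
    """Build a condition set with the requested per-category counts.

    With ``category_counts=None`` the conditions are split near-equally
    over the five categories (e.g. 32/31/31/31/31 for 156, remainder
    going to the earliest categories).  Label order is a seeded random
    permutation so that category membership is not confounded with
    condition id.
    """
    if n_conditions < 1:
        raise ValueError("n_conditions must be positive")
    if category_counts is None:
        base, extra = divmod(n_conditions, len(CATEGORIES))
        category_counts = {
            c: base + (1 if i < extra else 0) for i, c in enumerate(CATEGORIES)
        }
    unknown = set(category_counts) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories in counts: {sorted(unknown)}")
    total = sum(category_counts.values())
    if total != n_conditions:
        raise ValueError(
            f"category_counts sum to {total}, expected n_conditions={n_conditions}"
        )
    labels = [c for c in CATEGORIES for _ in range(category_counts.get(c, 0))]
    rng = np.random.default_rng([seed, _STREAM_CONDITIONS])
    order = rng.permutation(n_conditions)
    return ConditionSet(tuple(labels[i] for i in order))


def n_null_trials(n_image: int, null_fraction: float) -> int:
    """Integer null-trial count solving n/(n_image+n) = null_fraction."""
    if not 0.0 <= null_fraction < 1.0:
        raise ValueError("null_fraction must lie in [0, 1)")
    return int(round(null_fraction * n_image / (1.0 - null_fraction)))


def generate_event_sequence(
    conditions: ConditionSet,
    null_fraction: float = 0.25,
    trial_duration: float = 0.5,
    isi: float = 2.5,
    seed: int = 0,
) -> EventSequence:
    """Randomly ordered run: each condition once, plus null trials.

    The number of null trials is the nearest-integer solution of
    ``n_null / (n_image + n_null) = null_fraction``; consecutive onsets
    are ``trial_duration + isi`` seconds apart starting at 0.
    """
    n_image = conditions.n_conditions
    n_null = n_null_trials(n_image, null_fraction)
    ids = np.concatenate([conditions.ids, np.full(n_null, NULL_ID)])
    rng = np.random.default_rng([seed, _STREAM_EVENTS])
    ids = rng.permutation(ids)
    onsets = np.arange(ids.size) * (trial_duration + isi)
    return EventSequence(
        onsets=onsets,
        condition_ids=ids,
        trial_duration=trial_duration,
        isi=isi,
        null_fraction=null_fraction,
    )


def make_latent_code(conditions: ConditionSet, code_seed: int) -> np.ndarray:
    """The shared latent category code: conditions x (5 * k) matrix.

    Each category owns a block of ``k = LATENT_DIMS_PER_CATEGORY``
    latent dimensions.  Conditions load on their own category's block
    only: prototype (standard normal per category) plus per-condition
    jitter of sd :data:`WITHIN_CATEGORY_SD`, which sets the
    within/between-category contrast of every downstream RDM.
    """
    rng = np.random.default_rng([code_seed, _STREAM_CODE])
    k = LATENT_DIMS_PER_CATEGORY
    n_cat = len(CATEGORIES)
    prototypes = rng.standard_normal((n_cat, k))
    jitter = rng.standard_normal((conditions.n_conditions, k)) * WITHIN_CATEGORY_SD
    code = np.zeros((conditions.n_conditions, n_cat * k))
    cat_idx = conditions.category_indices()
    for i, g in enumerate(cat_idx):
        code[i, g * k : (g + 1) * k] = prototypes[g] + jitter[i]
    return code


def generate_roi_dataset(
    conditions: ConditionSet,
    spec: GroundTruthSpec,
    n_subjects: int = 15,
    n_voxels: int = 60,
    n_residual_timepoints: int = 150,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-subject (pattern, residual) pairs for one simulated ROI.

    Each subject's pattern is ``(code * strengths) @ P * gain_s`` plus
    Gaussian noise with covariance ``noise_sd**2 * spec.noise_covariance``;
    ``P`` is a fixed random voxel projection shared across subjects and
    ``gain_s`` a subject-specific scalar gain near 1.  Residual rows are
    i.i.d. draws from ``spec.noise_covariance`` (the estimate of noise
    structure handed to noise normalization).
    """
    if n_voxels < 2:
        raise ValueError("n_voxels must be at least 2")
    if n_residual_timepoints < 2:
        raise ValueError("n_residual_timepoints must be at least 2")
    if n_residual_timepoints <= n_voxels:
        warnings.warn(
            "fewer residual timepoints than voxels: covariance estimation "
            "will rely on shrinkage",
            stacklevel=2,
        )
    cov = spec.noise_covariance
    if cov is None:
        cov = ar1_covariance(n_voxels)
    cov = np.asarray(cov, float)
    if cov.shape != (n_voxels, n_voxels):
        raise ValueError("noise_covariance shape must match n_voxels")
    _check_positive_definite(cov)
    chol = cholesky(cov, lower=True)

    code = make_latent_code(conditions, spec.effective_code_seed)
    k = LATENT_DIMS_PER_CATEGORY
    weights = np.repeat(spec.strength_vector(), k)
    latent_dim = code.shape[1]
    proj_rng = np.random.default_rng([spec.seed, _STREAM_ROI_PROJ])
    # Scaled so a unit-strength category signal has voxel sd near 1: each
    # condition loads on k active latent dims of variance ~ (1 + within^2).
    proj_sd = 1.0 / np.sqrt(k * (1.0 + WITHIN_CATEGORY_SD**2))
    projection = proj_rng.standard_normal((latent_dim, n_voxels)) * proj_sd
    signal = (code * weights) @ projection

    out = []
    for s in range(n_subjects):
        rng = np.random.default_rng([spec.seed, _STREAM_SUBJECT, s])
        gain = max(1.0 + 0.1 * rng.standard_normal(), 0.2)
        noise = rng.standard_normal(signal.shape) @ chol.T * spec.noise_sd
        patterns = signal * gain + noise
        res_rng = np.random.default_rng([spec.seed, _STREAM_RESIDUAL, s])
        residuals = res_rng.standard_normal((n_residual_timepoints, n_voxels)) @ chol.T
        out.append((patterns, residuals))
    return out


def generate_activation_stacks(
    conditions: ConditionSet,
    spec: GroundTruthSpec,
    n_layers: int = 5,
    H: int = 13,
    W: int = 13,
    D: int = 24,
    noise_sd: float = 1.0,
):
    """Per-layer conditions x H x W x D activation tensors.

    Depth channels are assigned round-robin to the five category groups;
    channel ``d`` responds to a random mixture of its category's latent
    code dimensions, scaled by that category's signal strength and by
    the spatial gain profile evaluated at the channel's (x, y) cell.
    Independent Gaussian noise of sd ``noise_sd`` (unit by default) is
    added everywhere, so the per-cell signal-to-noise ratio follows the
    gain profile.

    Returns a list of :class:`toporsa.topography.ActivationStack`.
    """
    from .topography import ActivationStack  # local import avoids a cycle

    if conditions.n_conditions == 0:
        raise ValueError("empty condition set")
    if H < 1 or W < 1 or D < 2:
        raise ValueError("need H, W >= 1 and D >= 2")
    code = make_latent_code(conditions, spec.effective_code_seed)
    k = LATENT_DIMS_PER_CATEGORY
    n_cat = len(CATEGORIES)
    strengths = spec.strength_vector()
    gain = spatial_gain(spec.spatial_gain_profile, spec.gain_scale, H, W)

    stacks = []
    for layer in range(n_layers):
        rng = np.random.default_rng([spec.seed, _STREAM_LAYER, layer])
        groups = np.arange(D) % n_cat
        channel_w = rng.standard_normal((D, k)) / np.sqrt(k)
        # conditions x D channel signals before spatial modulation
        signal = np.empty((conditions.n_conditions, D))
        for d in range(D):
            g = groups[d]
            block = code[:, g * k : (g + 1) * k]
            signal[:, d] = strengths[g] * (block @ channel_w[d])
        values = signal[:, None, None, :] * gain[None, :, :, None]
        values = values + noise_sd * rng.standard_normal(values.shape)
        stacks.append(ActivationStack(values=values, layer_id=f"conv{layer + 1}"))
    return stacks


def null_spec(spec: GroundTruthSpec) -> GroundTruthSpec:
    """A copy of ``spec`` with all category signals set to zero (pure noise)."""
    return replace(
        spec, category_signal_strengths={c: 0.0 for c in CATEGORIES}
    )
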