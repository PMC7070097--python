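"""End-to-end pipeline: simulate -> whiten -> RDMs -> RSA -> maps -> inference.

One :class:`PipelineConfig` drives every stage; a master seed plus a
documented per-stage hash gives each stage its own reproducible random
stream, so re-running the whole pipeline (or one stage in isolation)
with the same config and seed reproduces every numeric output
bit-for-bit.  The run manifest records config hash, per-artifact
content checksums, package versions and warnings.

The default ("ci") profile is a reduced-scale study — 40 conditions,
8 subjects, 13 x 13 grids, 200 permutations — sized for routine
continuous testing; the "paper" profile restores the full study
conditions (156 conditions, 15 subjects, 1000 permutations).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import container
from .conditions import CATEGORIES, ConditionSet
from .inference import cluster_size_inference, layerwise_rsa_stats, sign_permutation_test
from .rdm import (
    compute_noise_ceiling,
    compute_rdm,
    estimate_noise_covariance,
    mds_embed,
    spearman_rdm_similarity,
    whiten_patterns,
    write_rdm_text,
)
from .synthetic import (
    GroundTruthSpec,
    generate_activation_stacks,
    generate_condition_set,
    generate_event_sequence,
    generate_roi_dataset,
)
from .topography import build_rdm_field, correlation_maps, upsample_map, vectorize_layer

#: Default synthetic ROI analogs of the four ventral-stream regions:
#: an early-visual region with no category preference, a face-dominated
#: fusiform analog, an animate/object-preferring IT analog and a
#: scene-dominated parahippocampal analog.
DEFAULT_ROIS: dict[str, dict[str, float]] = {
    "evc_analog": {c: 0.8 for c in CATEGORIES},
    "fusiform_analog": {
        "face": 2.0,
        "animal_body": 0.8,
        "person": 0.8,
        "object": 0.4,
        "scene": 0.4,
    },
    "it_analog": {
        "face": 0.8,
        "animal_body": 1.6,
        "person": 1.6,
        "object": 1.6,
        "scene": 0.4,
    },
    "phc_analog": {
        "face": 0.4,
        "animal_body": 0.4,
        "person": 0.4,
        "object": 0.8,
        "scene": 2.0,
    },
}


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    # study size
    n_conditions: int = 40
    category_counts: dict[str, int] | None = None
    n_subjects: int = 8
    n_voxels: int = 60
    n_residual_timepoints: int = 150
    # event design
    null_fraction: float = 0.25
    trial_duration: float = 0.5
    isi: float = 2.5
    # ground truth
    rois: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ROIS.items()}
    )
    gain_profile: str = "center"
    gain_scale: float = 0.25
    noise_sd: float = 1.0
    stack_noise_sd: float = 1.0
    # model layers
    n_layers: int = 5
    grid_h: int = 13
    grid_w: int = 13
    depth: int = 24
    # analysis
    shrinkage: str = "diag_shrink"
    n_permutations: int = 200
    cdt: float = 0.01
    alpha: float = 0.05
    connectivity: int = 8
    family_size: int | None = None
    upsample_h: int = 64
    upsample_w: int = 64
    upsample_method: str = "bilinear"
    mds_dims: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.cdt < 1 or not 0 < self.alpha < 1:
            raise ValueError("cdt and alpha must lie in (0, 1)")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_layers < 1:
            raise ValueError("need at least 1 layer")
        if not self.rois:
            raise ValueError("need at least one ROI")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def write_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def ci_profile(seed: int = 0) -> PipelineConfig:
    """Reduced-scale profile for fast, routine runs."""
    return PipelineConfig(seed=seed)


def paper_profile(seed: int = 0) -> PipelineConfig:
    """Full study conditions: 156 conditions, 15 subjects, 1000 permutations."""
    return PipelineConfig(
        n_conditions=156,
        n_subjects=15,
        n_voxels=100,
        n_residual_timepoints=300,
        n_permutations=1000,
        seed=seed,
    )


def get_profile(name: str, seed: int = 0) -> PipelineConfig:
    if name == "ci":
        return ci_profile(seed)
    if name == "paper":
        return paper_profile(seed)
    raise ValueError(f"unknown profile {name!r} (expected 'ci' or 'paper')")


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage sub-seed: blake2b hash of ``"<master>:<stage>"``, below 2^31."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


def _subject_rdm(patterns: np.ndarray, residuals: np.ndarray, shrinkage: str):
    cov = estimate_noise_covariance(residuals, shrinkage=shrinkage)
    return compute_rdm(whiten_patterns(patterns, cov))


def simulate(config: PipelineConfig, out_dir: Path) -> dict[str, str]:
    """Stage 1: conditions, events, ROI datasets and activation stacks."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}

    conditions = generate_condition_set(
        config.n_conditions, config.category_counts, seed=stage_seed(config.seed, "conditions")
    )
    conditions.write_tsv(out_dir / "conditions.tsv")
    events = generate_event_sequence(
        conditions,
        null_fraction=config.null_fraction,
        trial_duration=config.trial_duration,
        isi=config.isi,
        seed=stage_seed(config.seed, "events"),
    )
    events.write_csv(out_dir / "events.csv")

    roi_arrays: dict[str, np.ndarray] = {}
    code_seed = stage_seed(config.seed, "latent_code")
    for roi, strengths in config.rois.items():
        spec = GroundTruthSpec(
            category_signal_strengths=strengths,
            spatial_gain_profile=config.gain_profile,
            gain_scale=config.gain_scale,
            noise_sd=config.noise_sd,
            seed=stage_seed(config.seed, f"roi:{roi}"),
            code_seed=code_seed,
        )
        data = generate_roi_dataset(
            conditions,
            spec,
            n_subjects=config.n_subjects,
            n_voxels=config.n_voxels,
            n_residual_timepoints=config.n_residual_timepoints,
        )
        for s, (patterns, residuals) in enumerate(data):
            roi_arrays[f"{roi}/patterns/sub{s:02d}"] = patterns
            roi_arrays[f"{roi}/residuals/sub{s:02d}"] = residuals
    container.write_arrays(out_dir / "roi_data.h5", roi_arrays, {"stage": "simulate"})

    model_spec = GroundTruthSpec(
        spatial_gain_profile=config.gain_profile,
        gain_scale=config.gain_scale,
        seed=stage_seed(config.seed, "stacks"),
        code_seed=code_seed,
    )
    stacks = generate_activation_stacks(
        conditions,
        model_spec,
        n_layers=config.n_layers,
        H=config.grid_h,
        W=config.grid_w,
        D=config.depth,
        noise_sd=config.stack_noise_sd,
    )
    stack_arrays = {f"layer{k + 1}/stack": st.values for k, st in enumerate(stacks)}
    container.write_arrays(out_dir / "stacks.h5", stack_arrays, {"stage": "simulate"})

    config.write_yaml(out_dir / "config.yaml")
    checksums["conditions.tsv"] = container.text_checksum(out_dir / "conditions.tsv")
    checksums["events.csv"] = container.text_checksum(out_dir / "events.csv")
    checksums["roi_data.h5"] = container.content_checksum(roi_arrays)
    checksums["stacks.h5"] = container.content_checksum(stack_arrays)
    return checksums


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Artifacts: condition table, event table, ROI data and stacks
    (HDF5), subject and layer RDMs, layerwise RSA table with noise
    ceilings, per-(layer, ROI) correlation maps with cluster inference
    (mask, cluster table), upsampled topographical maps (PNG plus exact
    TSV dump), MDS coordinates, and ``manifest.json``.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    caught: list[str] = []
    checksums = simulate(config, out_dir)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        manifest = _analyze(config, out_dir, checksums)
        caught = [str(w.message) for w in wlist]

    manifest["warnings"] = caught
    manifest["runtime_seconds"] = round(time.time() - t0, 3)
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest


def _analyze(config: PipelineConfig, out_dir: Path, checksums: dict[str, str]) -> dict:
    conditions = ConditionSet.read_tsv(out_dir / "conditions.tsv")
    roi_data = container.read_arrays(out_dir / "roi_data.h5")
    stack_data = container.read_arrays(out_dir / "stacks.h5")
    roi_names = list(config.rois)
    layer_names = [f"layer{k + 1}" for k in range(config.n_layers)]

    # Subject ROI RDMs (noise-normalized betas) and group means.
    rdm_arrays: dict[str, np.ndarray] = {}
    subject_rdms: dict[str, list[np.ndarray]] = {}
    for roi in roi_names:
        rdms = []
        for s in range(config.n_subjects):
            rdm = _subject_rdm(
                roi_data[f"{roi}/patterns/sub{s:02d}"],
                roi_data[f"{roi}/residuals/sub{s:02d}"],
                config.shrinkage,
            )
            rdms.append(rdm)
            rdm_arrays[f"rois/{roi}/sub{s:02d}"] = rdm
        subject_rdms[roi] = rdms
        rdm_arrays[f"rois/{roi}/group_mean"] = np.mean(rdms, axis=0)
        write_rdm_text(rdm_arrays[f"rois/{roi}/group_mean"], out_dir / f"rdm_{roi}.tsv")

    # Layer RDMs from vectorized whole-layer activations.
    from .topography import ActivationStack

    stacks = [
        ActivationStack(values=stack_data[f"{name}/stack"], layer_id=name)
        for name in layer_names
    ]
    layer_rdms = {st.layer_id: compute_rdm(vectorize_layer(st)) for st in stacks}
    for name, rdm in layer_rdms.items():
        rdm_arrays[f"layers/{name}"] = rdm
    container.write_arrays(out_dir / "rdms.h5", rdm_arrays, {"stage": "rdm"})
    checksums["rdms.h5"] = container.content_checksum(rdm_arrays)

    # Layerwise RSA summary with noise ceilings.
    rhos = np.empty((config.n_subjects, config.n_layers, len(roi_names)))
    for li, lname in enumerate(layer_names):
        for ri, roi in enumerate(roi_names):
            for s in range(config.n_subjects):
                rhos[s, li, ri] = spearman_rdm_similarity(
                    subject_rdms[roi][s], layer_rdms[lname]
                )
    ceilings = {roi: compute_noise_ceiling(subject_rdms[roi]) for roi in roi_names}
    layer_stats = layerwise_rsa_stats(
        rhos,
        alpha=config.alpha,
        family_size=config.family_size,
        seed=stage_seed(config.seed, "layerwise"),
        noise_ceilings={k: (c.lower, c.upper) for k, c in ceilings.items()},
    )
    rows = []
    for li, lname in enumerate(layer_names):
        for ri, roi in enumerate(roi_names):
            rows.append(
                {
                    "layer": lname,
                    "roi": roi,
                    "mean_rho": layer_stats.mean[li, ri],
                    "sem": layer_stats.sem[li, ri],
                    "p_uncorrected": layer_stats.p_uncorrected[li, ri],
                    "p_corrected": layer_stats.p_corrected[li, ri],
                    "significant": bool(layer_stats.significant[li, ri]),
                    "ceiling_lower": ceilings[roi].lower,
                    "ceiling_upper": ceilings[roi].upper,
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "layerwise.csv", index=False, float_format="%.10g")
    checksums["layerwise.csv"] = container.text_checksum(out_dir / "layerwise.csv")

    # Topographical maps and cluster inference per (layer, ROI).
    map_arrays: dict[str, np.ndarray] = {}
    n_sig_clusters: dict[str, int] = {}
    for lname, stack in zip(layer_names, stacks):
        rdm_field = build_rdm_field(stack)
        for roi in roi_names:
            maps = correlation_maps(rdm_field, subject_rdms[roi])  # S x H x W
            test = sign_permutation_test(
                maps,
                n_permutations=config.n_permutations,
                tail="two",
                seed=stage_seed(config.seed, f"infer:{lname}:{roi}"),
            )
            clu = cluster_size_inference(
                test,
                cdt=config.cdt,
                alpha=config.alpha,
                connectivity=config.connectivity,
            )
            key = f"{lname}_{roi}"
            map_arrays[f"maps/{key}"] = maps
            map_arrays[f"stat/{key}"] = clu.stat_map
            map_arrays[f"p/{key}"] = clu.pointwise_p
            map_arrays[f"mask/{key}"] = clu.significance_mask.astype(np.uint8)
            clu.table().to_csv(out_dir / f"clusters_{key}.csv", index=False)
            checksums[f"clusters_{key}.csv"] = container.text_checksum(
                out_dir / f"clusters_{key}.csv"
            )
            n_sig_clusters[key] = int(
                sum(c.p_value <= config.alpha for c in clu.clusters)
            )
            topo = upsample_map(
                clu.stat_map,
                config.upsample_h,
                config.upsample_w,
                method=config.upsample_method,
            )
            np.savetxt(out_dir / f"topomap_{key}.tsv", topo, delimiter="\t", fmt="%.10g")
            checksums[f"topomap_{key}.tsv"] = container.text_checksum(
                out_dir / f"topomap_{key}.tsv"
            )
            _save_grayscale(topo, out_dir / f"topomap_{key}.png")
    container.write_arrays(
        out_dir / "maps.h5",
        map_arrays,
        {
            "stage": "infer",
            "n_permutations": config.n_permutations,
            "cdt": config.cdt,
            "alpha": config.alpha,
            "connectivity": config.connectivity,
            "seed": config.seed,
        },
    )
    checksums["maps.h5"] = container.content_checksum(map_arrays)

    # MDS embedding of each ROI's group-mean RDM.
    for roi in roi_names:
        coords = mds_embed(rdm_arrays[f"rois/{roi}/group_mean"], config.mds_dims)
        frame = pd.DataFrame(
            coords, columns=[f"dim{i + 1}" for i in range(coords.shape[1])]
        )
        frame.insert(0, "condition_id", np.arange(coords.shape[0]))
        frame.insert(1, "category", list(conditions.categories))
        frame.to_csv(out_dir / f"mds_{roi}.csv", index=False, float_format="%.10g")
        checksums[f"mds_{roi}.csv"] = container.text_checksum(out_dir / f"mds_{roi}.csv")

    import toporsa

    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "checksums": checksums,
        "n_significant_clusters": n_sig_clusters,
        "versions": {"toporsa": toporsa.__version__, "numpy": np.__version__},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def _save_grayscale(values: np.ndarray, path) -> None:
    """Render a map as a grayscale PNG (display only; NaN shown black)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v = np.asarray(values, float)
    finite = np.isfinite(v)
    lo = v[finite].min() if finite.any() else 0.0
    hi = v[finite].max() if finite.any() else 1.0
    scaled = np.zeros_like(v) if hi == lo else (np.nan_to_num(v, nan=lo) - lo) / (hi - lo)
    plt.imsave(path, scaled, cmap="gray", vmin=0.0, vmax=1.0)


def make_report(run_dir) -> Path:
    """Assemble ``report.md`` (plus figures) from a finished run directory.

    The document lists the layerwise RSA table with significance stars
    and noise ceilings, cluster counts per (layer, ROI) map, and points
    at the MDS and topographical-map artifacts; missing artifacts are
    listed but do not abort the report.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {run_dir}")
    with open(manifest_path) as f:
        manifest = json.load(f)

    missing: list[str] = []
    lines = [
        "# Pipeline report",
        "",
        f"- config hash: `{manifest['config_hash']}`",
        f"- seed: {manifest['seed']}",
        "",
    ]

    layerwise = run_dir / "layerwise.csv"
    if layerwise.exists():
        table = pd.read_csv(layerwise)
        lines += ["## Layerwise brain-model correlations", ""]
        lines.append("| layer | roi | mean rho | SEM | p (corrected) | | ceiling |")
        lines.append("|---|---|---|---|---|---|---|")
        for _, row in table.iterrows():
            star = "*" if row["significant"] else ""
            lines.append(
                f"| {row['layer']} | {row['roi']} | {row['mean_rho']:.4f} | "
                f"{row['sem']:.4f} | {row['p_corrected']:.4g} | {star} | "
                f"[{row['ceiling_lower']:.3f}, {row['ceiling_upper']:.3f}] |"
            )
        lines.append("")
        _report_bar_figure(table, run_dir / "report_layerwise.png")
    else:
        missing.append("layerwise.csv")

    lines += ["## Cluster inference", ""]
    n_sig = manifest.get("n_significant_clusters", {})
    if n_sig:
        lines.append("| map | significant clusters |")
        lines.append("|---|---|")
        for key in sorted(n_sig):
            lines.append(f"| {key} | {n_sig[key]} |")
        lines.append("")
    topos = sorted(run_dir.glob("topomap_*.png"))
    if topos:
        lines.append(
            "Topographical maps: " + ", ".join(f"`{p.name}`" for p in topos)
        )
        lines.append("")

    mds_files = sorted(run_dir.glob("mds_*.csv"))
    if mds_files:
        lines += ["## MDS embeddings", ""]
        for p in mds_files:
            _report_mds_figure(p, run_dir / f"report_{p.stem}.png")
            lines.append(f"- `{p.name}` (figure: `report_{p.stem}.png`)")
        lines.append("")
    else:
        missing.append("mds_*.csv")

    if missing:
        lines += ["## Missing artifacts", ""] + [f"- {m}" for m in missing] + [""]

    report = run_dir / "report.md"
    report.write_text("\n".join(lines))
    return report


def _report_bar_figure(table: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rois = list(dict.fromkeys(table["roi"]))
    fig, axes = plt.subplots(1, len(rois), figsize=(3.2 * len(rois), 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, roi in zip(axes, rois):
        sub = table[table["roi"] == roi]
        x = np.arange(len(sub))
        ax.bar(x, sub["mean_rho"], yerr=sub["sem"], color="steelblue", capsize=2)
        for xi, (_, row) in zip(x, sub.iterrows()):
            if row["significant"]:
                ax.text(xi, row["mean_rho"] + row["sem"] + 0.01, "*", ha="center")
        ax.axhspan(
            sub["ceiling_lower"].iloc[0], sub["ceiling_upper"].iloc[0],
            color="gray", alpha=0.3,
        )
        ax.set_title(roi)
        ax.set_xticks(x)
        ax.set_xticklabels(sub["layer"], rotation=45, fontsize=7)
    axes[0].set_ylabel("Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _report_mds_figure(csv_path, out_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = pd.read_csv(csv_path)
    fig, ax = plt.subplots(figsize=(4, 4))
    for cat, sub in frame.groupby("category"):
        ax.scatter(sub["dim1"], sub["dim2"], label=cat, s=14)
    ax.legend(fontsize=7)
    ax.set_xlabel("MDS dim 1")
    ax.set_ylabel("MDS dim 2")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
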