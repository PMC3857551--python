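"""End-to-end orchestration: simulate -> MA images -> scan -> fractionate.

The four-step processing stream: (1) smooth peak coordinates into a 4D
modeled-activation dataset, (2) spatial ICA at model order d, (3) project
metadata labels onto the components, (4) cluster the metadata matrix and
score the dendrogram by CC_c. The scan repeats steps 2-4 over a model-order
grid, selects preferred orders, and fractionation relates the two best
orders by spatial cross-correlation. Robustness checks (experiment-order
randomization, repeated 90% subsampling) are provided alongside.

One root seed deterministically spawns per-stage and per-replicate
substreams, so adding replicates never perturbs earlier stages.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster_select import ScanResult, ccc_of_metadata, scan_model_orders
from .fractionation import (
    assign_parents,
    flag_artifacts,
    network_hca,
    spatial_cross_correlation,
    summarize_fractionation,
)
from .ica_decomp import component_stats, decompose, to_zmaps
from .maimage import MAMatrix, VolumeGrid, stack_corpus
from .metaproject import experiment_weights, project_metadata
from .synthcorpus import Corpus, SynthConfig, build_corpus, save_corpus

__all__ = ["PipelineConfig", "run_pipeline", "subsample_robustness", "default_paper_grid"]


def default_paper_grid() -> list[int]:
    """The canonical scan grid for a database-scale corpus: 20..200 step 10."""
    return list(range(20, 201, 10))


def default_grid_for(e: int) -> list[int]:
    """Scan grid scaled to corpus size (the canonical grid presumes e in the
    thousands); small corpora get 2..min(e//4, 20)."""
    if e >= 2000:
        return [d for d in default_paper_grid() if d <= e]
    hi = max(3, min(e // 4, 20))
    return list(range(2, hi + 1))


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    grid_spacing: float = 4.0
    grid_mask: str = "ellipsoid"
    fwhm: float = 12.0
    combine: str = "max"
    z_threshold: float = 4.0
    d_grid: list | None = None  # default: scaled to corpus size
    linkage_method: str = "single"
    subsample_fraction: float = 0.9
    subsample_reps: int = 10
    artifact_entropy_threshold: float = 0.97
    outdir: str = "runs/coactnet"
    seed: int = 0
    write_nifti: bool = False

    def __post_init__(self):
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        return cls(synth=synth, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _stage_seed(root: int, stage: str, index: int = 0) -> int:
    # stable across processes (builtin hash() is salted per run)
    tag = int.from_bytes(stage.encode()[:4].ljust(4, b"\0"), "big")
    h = np.random.SeedSequence([root, tag, index])
    return int(h.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full stream and write all artifacts to ``config.outdir``.

    Returns a manifest dict (also written as manifest.json). Per-d failures
    are recorded; the run fails only if no model order completes.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def record(stage: str, t0: float, **info):
        log.append({"stage": stage, "seconds": round(time.time() - t0, 3), **info})

    t0 = time.time()
    grid = VolumeGrid.talairach(spacing=config.grid_spacing, mask=config.grid_mask)
    corpus = build_corpus(config.synth, grid)
    save_corpus(corpus, outdir / "corpus")
    record("simulate", t0, e=corpus.n_experiments, n_classes=corpus.n_classes,
           n_clipped_peaks=corpus.n_clipped_peaks)

    t0 = time.time()
    ma = stack_corpus(corpus, grid, fwhm=config.fwhm, combine=config.combine)
    if config.write_nifti:
        import nibabel as nib

        nib.save(ma.to_nifti(), str(outdir / "ma_4d.nii"))
        nib.save(grid.to_nifti_mask(), str(outdir / "mask.nii"))
    record("build_ma", t0, v=ma.n_voxels, e=ma.n_experiments)

    d_grid = config.d_grid or default_grid_for(corpus.n_experiments)
    t0 = time.time()
    scan = scan_model_orders(
        ma,
        corpus.label_matrix,
        d_grid,
        seed=_stage_seed(config.seed, "scan"),
        linkage_method=config.linkage_method,
        class_names=corpus.class_names,
    )
    pd.DataFrame({"d": scan.d_grid, "ccc": scan.ccc_values}).to_csv(
        outdir / "ccc_scan.csv", index=False
    )
    selection = {
        "selected_orders": scan.selected_orders,
        "argmax_d": scan.argmax_d,
        "mean_ccc": scan.mean_ccc,
        "sd_ccc": scan.sd_ccc,
        "diagnostics": {str(k): v for k, v in scan.diagnostics.items()},
    }
    (outdir / "selection.json").write_text(json.dumps(selection, indent=1))
    record("scan", t0, d_grid=list(scan.d_grid), argmax_d=scan.argmax_d)

    # fractionation between the two preferred model orders (argmax plus the
    # best remaining selected order; self-comparison when the grid is degenerate)
    t0 = time.time()
    ranked = [d for _, d in sorted(
        ((c, d) for c, d in zip(scan.ccc_values, scan.d_grid) if np.isfinite(c)),
        reverse=True,
    )]
    d_low = min(ranked[:2]) if len(ranked) >= 2 else ranked[0]
    d_high = max(ranked[:2]) if len(ranked) >= 2 else ranked[0]
    frac = run_fractionation(
        ma, corpus, d_low, d_high,
        seed=_stage_seed(config.seed, "fractionation"),
        z_threshold=config.z_threshold,
        entropy_threshold=config.artifact_entropy_threshold,
        outdir=outdir,
    )
    record("fractionate", t0, d_low=d_low, d_high=d_high)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": log,
        "selection": selection,
        "fractionation": {
            "d_low": d_low,
            "d_high": d_high,
            "artifacts_low": frac["artifacts_low"],
            "artifacts_high": frac["artifacts_high"],
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def run_fractionation(
    ma: MAMatrix,
    corpus: Corpus,
    d_low: int,
    d_high: int,
    seed: int,
    z_threshold: float = 4.0,
    entropy_threshold: float = 0.97,
    group_of_parent: dict | None = None,
    outdir: Path | None = None,
    center: bool = True,
) -> dict:
    """Decompose at two orders, cross-correlate z-maps, assign parents.

    When no parent grouping is supplied, each low-order parent forms its own
    group (so rates count sub-networks per individual parent network).
    """
    low = decompose(ma, d_low, seed=_stage_seed(seed, "low"), center=center)
    high = decompose(ma, d_high, seed=_stage_seed(seed, "high"), center=center)
    z_low = to_zmaps(low, threshold=z_threshold)
    z_high = to_zmaps(high, threshold=z_threshold)
    meta_low = project_metadata(
        corpus.label_matrix,
        experiment_weights(low.experiment_modes, low.mixing),
        class_names=corpus.class_names,
    )
    meta_high = project_metadata(
        corpus.label_matrix,
        experiment_weights(high.experiment_modes, high.mixing),
        class_names=corpus.class_names,
    )
    art_low = flag_artifacts(meta_low, entropy_threshold)
    art_high = flag_artifacts(meta_high, entropy_threshold)
    cc = spatial_cross_correlation(z_high, z_low)
    assignment = assign_parents(cc, artifact_high=art_high, artifact_low=art_low)
    if group_of_parent is None:
        group_of_parent = {j: f"parent_{j:02d}" for j in range(d_low) if j not in art_low}
    summary = summarize_fractionation(assignment, group_of_parent)
    result = {
        "cross_correlation": cc,
        "assignment": assignment,
        "summary": summary,
        "network_tree_low": network_hca(meta_low) if d_low >= 2 else None,
        "network_tree_high": network_hca(meta_high) if d_high >= 2 else None,
        "artifacts_low": art_low,
        "artifacts_high": art_high,
        "component_stats_low": component_stats(z_low),
        "component_stats_high": component_stats(z_high),
    }
    if outdir is not None:
        outdir = Path(outdir)
        cc.to_csv(outdir / "cross_correlation.csv")
        pd.DataFrame(
            {"high_component": range(len(assignment.parent)),
             "parent": assignment.parent,
             "correlation": assignment.correlation}
        ).to_csv(outdir / "parent_assignment.csv", index=False)
        summary.to_frame().to_csv(outdir / "fractionation_summary.csv")
        for name, tree in (("low", result["network_tree_low"]), ("high", result["network_tree_high"])):
            if tree is not None:
                pd.DataFrame(tree, columns=["left", "right", "height", "size"]).to_csv(
                    outdir / f"network_dendrogram_{name}.csv", index=False
                )
    return result


def subsample_robustness(
    corpus: Corpus,
    grid: VolumeGrid,
    d_grid,
    seed: int,
    fraction: float = 0.9,
    reps: int = 10,
    fwhm: float = 12.0,
    combine: str = "max",
    linkage_method: str = "single",
    ma: MAMatrix | None = None,
) -> dict:
    """CC_c scan on repeated random subsets of the corpus.

    Draws ``reps`` independent uniform subsets (without replacement) of
    size floor(fraction * e), scans each, and reports the per-replicate
    CC_c curves and their mean. Because MA columns are independent, the
    full MA matrix is stacked once and column-sliced per subset.
    """
    e = corpus.n_experiments
    size = int(np.floor(fraction * e))
    d_grid = sorted(int(d) for d in d_grid)
    if size < max(d_grid):
        raise ValueError(f"subset size {size} is below max(d_grid)={max(d_grid)}")
    if ma is None:
        ma = stack_corpus(corpus, grid, fwhm=fwhm, combine=combine)
    curves = np.empty((reps, len(d_grid)))
    subset_seeds = np.random.SeedSequence([seed, 777]).generate_state(reps) % (2**31)
    for r in range(reps):
        rng = np.random.default_rng(int(subset_seeds[r]))
        if fraction == 1.0:
            sub_values, sub_labels = ma.values, corpus.label_matrix
        else:
            idx = np.sort(rng.choice(e, size=size, replace=False))
            sub_values, sub_labels = ma.values[:, idx], corpus.label_matrix[:, idx]
        # the scan substream is shared across replicates so that a
        # fraction-1.0 replicate reproduces the full-corpus scan exactly
        scan = scan_model_orders(
            sub_values.T,
            sub_labels,
            d_grid,
            seed=seed,
            linkage_method=linkage_method,
            class_names=corpus.class_names,
        )
        curves[r] = scan.ccc_values
    mean_curve = np.nanmean(curves, axis=0)
    return {
        "d_grid": d_grid,
        "curves": curves,
        "mean_curve": mean_curve,
        "argmax_d": int(d_grid[int(np.nanargmax(mean_curve))]),
    }
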