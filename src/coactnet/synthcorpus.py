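"""Synthetic coordinate corpora with planted co-activation structure.

The generator emulates the statistical structure a coordinate-based
meta-analytic ICA assumes about a large curated database: experiments are
drawn from a small number of latent spatial networks, each network is a set
of Gaussian blobs in standard space, reported peaks scatter around blob
centers, and taxonomy labels (behavioral domains and task paradigms)
correlate with network identity with configurable fidelity.

Every quantity is a pure, reproducible function of (config, grid).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .maimage import VolumeGrid

__all__ = [
    "GroundTruthNetwork",
    "Experiment",
    "SynthConfig",
    "Corpus",
    "default_taxonomy",
    "make_ground_truth",
    "sample_experiment",
    "build_corpus",
    "save_corpus",
    "load_corpus",
]

# Standard sizes of the two taxonomy fields used for functional labeling:
# task paradigm classes and behavioral domains.
N_PARADIGM_CLASSES = 75
N_BEHAVIORAL_DOMAINS = 50


def default_taxonomy(
    n_paradigms: int = N_PARADIGM_CLASSES,
    n_domains: int = N_BEHAVIORAL_DOMAINS,
) -> list[str]:
    """Combined label space: paradigm classes followed by behavioral domains."""
    return [f"paradigm_{i:03d}" for i in range(n_paradigms)] + [
        f"domain_{i:03d}" for i in range(n_domains)
    ]


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A planted latent network: blob centers, spatial scale, and its labels."""

    network_id: int
    blob_centers: np.ndarray  # (n_blobs, 3) mm
    blob_sigma: float
    class_ids: frozenset

    def __post_init__(self):
        centers = np.atleast_2d(np.asarray(self.blob_centers, dtype=float))
        if centers.shape[0] < 1:
            raise ValueError("network needs at least one blob center")
        if self.blob_sigma <= 0:
            raise ValueError("blob_sigma must be positive")
        if not self.class_ids:
            raise ValueError("class_ids must be non-empty")
        object.__setattr__(self, "blob_centers", centers)
        object.__setattr__(self, "class_ids", frozenset(self.class_ids))

    @property
    def centroid(self) -> np.ndarray:
        return self.blob_centers.mean(axis=0)


@dataclass(frozen=True)
class Experiment:
    """One experiment: its reported peaks and its metadata labels."""

    experiment_id: str
    peaks: np.ndarray  # (n_peaks, 3) mm
    labels: frozenset

    def __post_init__(self):
        peaks = np.atleast_2d(np.asarray(self.peaks, dtype=float))
        if peaks.shape[0] < 1:
            raise ValueError("experiment needs at least one peak")
        if not np.all(np.isfinite(peaks)):
            raise ValueError("peaks must be finite")
        object.__setattr__(self, "peaks", peaks)
        object.__setattr__(self, "labels", frozenset(self.labels))


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults define the standard study conditions."""

    k_networks: int = 5
    e_experiments: int = 300
    peaks_per_experiment: tuple[int, int] = (5, 12)
    # one blob per network by default: the ICA model order then equals the
    # network count, keeping the planted order identifiable; multi-blob
    # networks are the substrate for fractionation experiments
    blobs_per_network: tuple[int, int] = (1, 1)
    peak_jitter_sd: float = 6.0
    # probability each blob of the drawn network is expressed by an
    # experiment (at least one blob always is). 1.0 = strict co-activation,
    # fully recoverable at d = k; < 1 gives sub-network expression
    # variability, the substrate for fractionation at higher model orders
    blob_coverage: float = 1.0
    # uniformly placed foci unrelated to any network: published experiments
    # report peaks outside their dominant co-activation pattern, and this
    # background is what gives z-statistic maps a non-degenerate null
    background_peaks_per_experiment: tuple[int, int] = (3, 8)
    label_fidelity: float = 0.95
    false_label_rate: float = 0.02
    classes_per_network: int = 4
    min_network_separation: float = 40.0
    blob_scatter_mm: float = 15.0
    mixture_prob: float = 0.0  # probability an experiment mixes two networks
    seed: int = 0

    def __post_init__(self):
        for name in ("peaks_per_experiment", "blobs_per_network", "background_peaks_per_experiment"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        for name in ("label_fidelity", "false_label_rate", "mixture_prob", "blob_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("peaks_per_experiment", "blobs_per_network"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range ({lo}, {hi}) is empty or invalid")
        bg_lo, bg_hi = self.background_peaks_per_experiment
        if bg_lo < 0 or bg_hi < bg_lo:
            raise ValueError("background_peaks_per_experiment range is invalid")
        if self.peak_jitter_sd < 0 or self.min_network_separation < 0:
            raise ValueError("jitter and separation must be non-negative")
        if self.k_networks < 0 or self.e_experiments < 1 or self.classes_per_network < 1:
            raise ValueError("counts must be positive")


@dataclass
class Corpus:
    """Experiments, their binary label matrix, and (optionally) ground truth."""

    experiments: list
    label_matrix: np.ndarray  # (n_classes, e) binary
    class_names: list
    ground_truth: list | None = None
    network_of_experiment: np.ndarray | None = None
    n_clipped_peaks: int = 0

    def __post_init__(self):
        self.label_matrix = np.asarray(self.label_matrix)
        n, e = self.label_matrix.shape
        if n != len(self.class_names):
            raise ValueError("label_matrix rows must match class_names")
        if e != len(self.experiments):
            raise ValueError("label_matrix columns must match experiments")

    @property
    def n_classes(self) -> int:
        return self.label_matrix.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.label_matrix.shape[1]

    def subset(self, indices) -> "Corpus":
        """Column subset of the corpus (experiments kept in the given order)."""
        indices = np.asarray(indices, dtype=int)
        net = self.network_of_experiment
        return Corpus(
            experiments=[self.experiments[i] for i in indices],
            label_matrix=self.label_matrix[:, indices],
            class_names=list(self.class_names),
            ground_truth=self.ground_truth,
            network_of_experiment=None if net is None else net[indices],
            n_clipped_peaks=self.n_clipped_peaks,
        )


def make_ground_truth(
    config: SynthConfig,
    grid: VolumeGrid,
    rng: np.random.Generator | None = None,
    max_attempts: int = 5000,
) -> list[GroundTruthNetwork]:
    """Plant ``k_networks`` latent networks in the grid mask.

    Network centroids are rejection-sampled from in-mask voxel centers
    subject to the pairwise ``min_network_separation`` constraint; blob
    centers scatter around the centroid (sd ``blob_scatter_mm``) and are
    snapped into the mask. Class identifiers are assigned in disjoint,
    contiguous blocks of ``classes_per_network``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.k_networks == 0:
        return []
    centers_pool = grid.mask_coords()
    centroids: list[np.ndarray] = []
    attempts = 0
    while len(centroids) < config.k_networks:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {config.k_networks} networks with separation "
                f">= {config.min_network_separation} mm in {max_attempts} attempts"
            )
        cand = centers_pool[rng.integers(len(centers_pool))]
        if all(np.linalg.norm(cand - c) >= config.min_network_separation for c in centroids):
            centroids.append(cand)

    networks = []
    for k, centroid in enumerate(centroids):
        n_blobs = int(rng.integers(config.blobs_per_network[0], config.blobs_per_network[1] + 1))
        offsets = rng.normal(0.0, config.blob_scatter_mm, size=(n_blobs, 3))
        blob_centers, _ = grid.clip_to_mask(centroid + offsets)
        # recenter so the blob centroid honors the separation constraint
        blob_centers = blob_centers - blob_centers.mean(axis=0) + centroid
        blob_centers, _ = grid.clip_to_mask(blob_centers)
        class_ids = frozenset(
            range(k * config.classes_per_network, (k + 1) * config.classes_per_network)
        )
        networks.append(
            GroundTruthNetwork(
                network_id=k,
                blob_centers=blob_centers,
                blob_sigma=max(config.peak_jitter_sd, 1e-6),
                class_ids=class_ids,
            )
        )
    return networks


def sample_experiment(
    network: GroundTruthNetwork,
    config: SynthConfig,
    rng: np.random.Generator,
    experiment_id: str = "exp",
    all_class_ids: frozenset | None = None,
    second_network: GroundTruthNetwork | None = None,
) -> Experiment:
    """Draw one experiment from a planted network.

    The peak count is uniform over ``peaks_per_experiment``; peaks are
    spread over the network's blob centers as evenly as possible (all the
    regions of a co-activation network activate together, so every blob is
    expressed whenever the peak count allows) and each peak is its blob
    center plus isotropic Gaussian jitter of sd ``peak_jitter_sd``. Each of
    the network's classes is attached with probability ``label_fidelity``;
    each foreign class with probability ``false_label_rate``. If
    ``second_network`` is given, peaks are drawn from the union of both
    networks' blob centers (mixture experiments).
    """
    lo, hi = config.peaks_per_experiment
    n_peaks = int(rng.integers(lo, hi + 1))
    centers = network.blob_centers
    true_classes = set(network.class_ids)
    if second_network is not None:
        centers = np.vstack([centers, second_network.blob_centers])
        true_classes |= set(second_network.class_ids)
    # even coverage of blobs, surplus peaks assigned at random
    n_blobs = len(centers)
    reps = np.tile(np.arange(n_blobs), n_peaks // n_blobs)
    extra = rng.permutation(n_blobs)[: n_peaks - len(reps)]
    if config.blob_coverage < 1.0 and len(centers) > 1:
        keep = np.flatnonzero(rng.random(len(centers)) < config.blob_coverage)
        if keep.size == 0:
            keep = np.array([rng.integers(len(centers))])
        centers = centers[keep]
        n_blobs = len(centers)
        reps = np.tile(np.arange(n_blobs), n_peaks // n_blobs)
        extra = rng.permutation(n_blobs)[: n_peaks - len(reps)]
    chosen = centers[np.concatenate([reps, extra]).astype(int)]
    peaks = chosen + rng.normal(0.0, config.peak_jitter_sd, size=(n_peaks, 3))

    labels = {c for c in sorted(true_classes) if rng.random() < config.label_fidelity}
    if all_class_ids is not None and config.false_label_rate > 0:
        for c in sorted(set(all_class_ids) - true_classes):
            if rng.random() < config.false_label_rate:
                labels.add(c)
    return Experiment(experiment_id=experiment_id, peaks=peaks, labels=frozenset(labels))


def build_corpus(config: SynthConfig, grid: VolumeGrid) -> Corpus:
    """Generate a full corpus: planted networks, experiments, label matrix.

    Experiments are assigned to networks round-robin (balanced design,
    per-network counts differ by at most one); peaks falling outside the
    mask after jitter are clipped to the nearest in-mask voxel center and
    counted in ``Corpus.n_clipped_peaks``.
    """
    rng = np.random.default_rng(config.seed)
    networks = make_ground_truth(config, grid, rng=rng)
    if not networks:
        raise ValueError("cannot build a corpus with zero networks")
    n_classes = config.k_networks * config.classes_per_network
    all_class_ids = frozenset(range(n_classes))
    taxonomy = default_taxonomy()
    if n_classes <= len(taxonomy):
        class_names = taxonomy[:n_classes]
    else:
        class_names = [f"class_{i:03d}" for i in range(n_classes)]

    experiments = []
    net_of_exp = np.empty(config.e_experiments, dtype=int)
    n_clipped = 0
    centers_pool = grid.mask_coords()
    for j in range(config.e_experiments):
        k = j % config.k_networks
        net_of_exp[j] = k
        second = None
        if config.mixture_prob > 0 and config.k_networks > 1 and rng.random() < config.mixture_prob:
            other = int(rng.integers(config.k_networks - 1))
            second = networks[other if other < k else other + 1]
        exp = sample_experiment(
            networks[k],
            config,
            rng,
            experiment_id=f"exp_{j:05d}",
            all_class_ids=all_class_ids,
            second_network=second,
        )
        peaks = exp.peaks
        bg_lo, bg_hi = config.background_peaks_per_experiment
        if bg_hi > 0:
            n_bg = int(rng.integers(bg_lo, bg_hi + 1))
            if n_bg > 0:
                bg = centers_pool[rng.integers(len(centers_pool), size=n_bg)]
                peaks = np.vstack([peaks, bg])
        peaks, clipped = grid.clip_to_mask(peaks)
        n_clipped += clipped
        experiments.append(Experiment(exp.experiment_id, peaks, exp.labels))

    label_matrix = np.zeros((n_classes, config.e_experiments), dtype=np.int8)
    for j, exp in enumerate(experiments):
        for c in exp.labels:
            label_matrix[c, j] = 1
    if not label_matrix.any():
        warnings.warn("corpus has an all-zero label matrix (fidelity too low?)")
    return Corpus(
        experiments=experiments,
        label_matrix=label_matrix,
        class_names=class_names,
        ground_truth=networks,
        network_of_experiment=net_of_exp,
        n_clipped_peaks=n_clipped,
    )


# ---------------------------------------------------------------------------
# CSV / JSON round trip

def save_corpus(corpus: Corpus, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for exp in corpus.experiments:
        for p in exp.peaks:
            rows.append((exp.experiment_id, p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=["experiment_id", "x", "y", "z"]).to_csv(
        outdir / "peaks.csv", index=False
    )
    labels = pd.DataFrame(
        corpus.label_matrix,
        index=corpus.class_names,
        columns=[e.experiment_id for e in corpus.experiments],
    )
    labels.to_csv(outdir / "labels.csv", index_label="class")
    if corpus.ground_truth is not None:
        gt = [
            {
                "network_id": n.network_id,
                "blob_centers": n.blob_centers.tolist(),
                "blob_sigma": n.blob_sigma,
                "class_ids": sorted(n.class_ids),
            }
            for n in corpus.ground_truth
        ]
        (outdir / "ground_truth.json").write_text(json.dumps(gt, indent=1))


def load_corpus(indir) -> Corpus:
    indir = Path(indir)
    peaks = pd.read_csv(indir / "peaks.csv")
    labels = pd.read_csv(indir / "labels.csv", index_col=0)
    class_names = list(labels.index)
    experiments = []
    for eid in labels.columns:
        sub = peaks[peaks["experiment_id"] == eid]
        lab = frozenset(int(i) for i, v in enumerate(labels[eid].to_numpy()) if v)
        experiments.append(Experiment(eid, sub[["x", "y", "z"]].to_numpy(), lab))
    ground_truth = None
    gt_path = indir / "ground_truth.json"
    if gt_path.exists():
        ground_truth = [
            GroundTruthNetwork(
                network_id=g["network_id"],
                blob_centers=np.asarray(g["blob_centers"]),
                blob_sigma=g["blob_sigma"],
                class_ids=frozenset(g["class_ids"]),
            )
            for g in json.loads(gt_path.read_text())
        ]
    return Corpus(
        experiments=experiments,
        label_matrix=labels.to_numpy(),
        class_names=class_names,
        ground_truth=ground_truth,
    )
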