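"""Tracking how low-order networks fractionate into high-order sub-networks.

Two decompositions (a low model order and a high one) are related by the
Pearson cross-correlation of their unthresholded z-maps over the analysis
mask. Each high-order component is assigned to the low-order "parent" with
which it correlates most strongly; artifact components (near-uniform
metadata profiles) are excluded. Counting assigned sub-networks per
functional group of parents gives per-group fractionation rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_select import correlation_distances, single_linkage
from .ica_decomp import ZMaps
from .metaproject import MetadataMatrix

__all__ = [
    "CrossCorrMatrix",
    "ParentAssignment",
    "FractionationSummary",
    "ARTIFACT",
    "spatial_cross_correlation",
    "assign_parents",
    "network_hca",
    "flag_artifacts",
    "summarize_fractionation",
]

ARTIFACT = -1  # parent marker for excluded components


@dataclass
class CrossCorrMatrix:
    values: np.ndarray  # (d_high, d_low), NaN where a map is constant
    high_ids: list
    low_ids: list

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.high_ids, columns=self.low_ids).to_csv(
            path, index_label="high_component"
        )


@dataclass
class ParentAssignment:
    parent: np.ndarray  # per high component: low id, or ARTIFACT
    correlation: np.ndarray  # NaN for artifacts

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.correlation = np.asarray(self.correlation, dtype=float)

    @property
    def n_assigned(self) -> int:
        return int((self.parent != ARTIFACT).sum())


@dataclass
class FractionationSummary:
    """Per functional group: parent count, sub-network count, and rate."""

    groups: list
    n_parents: dict
    n_subnetworks: dict
    rate: dict  # full precision; NaN marks a group with zero parents
    rate_2dp: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_parents": [self.n_parents[g] for g in self.groups],
                "n_subnetworks": [self.n_subnetworks[g] for g in self.groups],
                "rate": [self.rate[g] for g in self.groups],
                "rate_2dp": [self.rate_2dp[g] for g in self.groups],
            },
            index=pd.Index(self.groups, name="group"),
        )


def spatial_cross_correlation(zmaps_high: ZMaps, zmaps_low: ZMaps, threshold: float | None = None) -> CrossCorrMatrix:
    """Pearson correlation of every high-order map with every low-order map.

    Correlations are computed over in-mask voxels of the unthresholded
    z-maps (both map sets must come from the same grid/mask, i.e. share the
    voxel dimension). ``threshold`` optionally zeroes sub-threshold values
    first (sensitivity analysis). Constant maps yield NaN entries.
    """
    H = np.asarray(zmaps_high.zvalues, dtype=float)
    L = np.asarray(zmaps_low.zvalues, dtype=float)
    if H.shape[1] != L.shape[1]:
        raise ValueError(f"voxel dimensions differ: {H.shape[1]} vs {L.shape[1]}")
    if threshold is not None:
        H = np.where(H > threshold, H, 0.0)
        L = np.where(L > threshold, L, 0.0)
    const_h = H.std(axis=1) == 0
    const_l = L.std(axis=1) == 0
    if const_h.any() or const_l.any():
        warnings.warn("constant z-map(s): their correlations are undefined (NaN)")
    with np.errstate(invalid="ignore", divide="ignore"):
        Hc = H - H.mean(axis=1, keepdims=True)
        Lc = L - L.mean(axis=1, keepdims=True)
        num = Hc @ Lc.T
        den = np.outer(np.linalg.norm(Hc, axis=1), np.linalg.norm(Lc, axis=1))
        values = np.divide(num, den, out=np.full_like(num, np.nan), where=den > 0)
    values = np.clip(values, -1.0, 1.0)
    values[const_h, :] = np.nan
    values[:, const_l] = np.nan
    return CrossCorrMatrix(
        values=values,
        high_ids=list(range(H.shape[0])),
        low_ids=list(range(L.shape[0])),
    )


def assign_parents(
    cc: CrossCorrMatrix,
    artifact_high: list | None = None,
    artifact_low: list | None = None,
) -> ParentAssignment:
    """Assign each non-artifact high component to its best-correlated parent.

    The parent is the argmax over non-artifact low components; exact ties
    break toward the lower component id. Artifact high components receive
    the ARTIFACT marker.
    """
    artifact_high = set(artifact_high or [])
    artifact_low = set(artifact_low or [])
    d_high, d_low = cc.values.shape
    valid_low = [j for j in range(d_low) if j not in artifact_low]
    if not valid_low:
        raise ValueError("every low-order component is flagged as artifact")
    parent = np.full(d_high, ARTIFACT, dtype=int)
    corr = np.full(d_high, np.nan)
    for i in range(d_high):
        if i in artifact_high:
            continue
        row = cc.values[i, valid_low]
        j = int(np.nanargmax(row))  # first (lowest id) wins exact ties
        parent[i] = valid_low[j]
        corr[i] = row[j]
    return ParentAssignment(parent=parent, correlation=corr)


def network_hca(meta: MetadataMatrix, method: str = "single") -> np.ndarray:
    """Single-linkage tree over components (columns of P_d), 1-r distance.

    The transposed analysis: instead of clustering metadata classes, the d
    component metadata profiles are clustered to reveal groups of
    functionally similar networks.
    """
    if meta.d < 2:
        raise ValueError("need at least two components")
    dist = correlation_distances(meta.values.T)
    return single_linkage(dist, method=method)


def flag_artifacts(
    meta: MetadataMatrix,
    uniformity_threshold: float = 0.97,
    include: list | None = None,
    exclude: list | None = None,
) -> list:
    """Components with near-uniform metadata profiles.

    The normalized Shannon entropy of the absolute metadata weights of a
    component (1 = perfectly uniform over classes, 0 = one-hot) is compared
    with ``uniformity_threshold``; components above it are flagged.
    ``include``/``exclude`` force components in or out of the flagged set
    (manual overrides, since artifact status is ultimately a judgment call).
    """
    flagged = []
    n = len(meta.class_names)
    for i in range(meta.d):
        w = np.abs(meta.values[:, i])
        total = w.sum()
        if total == 0:
            entropy = 1.0  # an all-zero profile carries no class information
        else:
            p = w / total
            nz = p[p > 0]
            entropy = float(-(nz * np.log(nz)).sum() / np.log(n)) if n > 1 else 0.0
        if entropy > uniformity_threshold:
            flagged.append(i)
    flagged = set(flagged) | set(include or [])
    flagged -= set(exclude or [])
    return sorted(flagged)


def summarize_fractionation(assignment: ParentAssignment, group_of_parent: dict) -> FractionationSummary:
    """Per-group sub-network counts and fractionation rates.

    ``group_of_parent`` maps every low-order parent id to a group label.
    rate = n_subnetworks / n_parents, reported to 2 decimals alongside the
    full-precision value; a group with zero parents gets a NaN rate.
    """
    for p in assignment.parent:
        if p != ARTIFACT and p not in group_of_parent:
            raise KeyError(f"parent component {p} has no group label")
    groups = sorted(set(group_of_parent.values()), key=str)
    n_parents = {g: sum(1 for v in group_of_parent.values() if v == g) for g in groups}
    n_sub = {g: 0 for g in groups}
    for p in assignment.parent:
        if p != ARTIFACT:
            n_sub[group_of_parent[p]] += 1
    rate = {}
    rate_2dp = {}
    for g in groups:
        if n_parents[g] == 0:
            rate[g] = float("nan")
            rate_2dp[g] = float("nan")
        else:
            rate[g] = n_sub[g] / n_parents[g]
            rate_2dp[g] = round(rate[g], 2)
    return FractionationSummary(
        groups=groups, n_parents=n_parents, n_subnetworks=n_sub, rate=rate, rate_2dp=rate_2dp
    )
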