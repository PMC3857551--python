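"""Metadata clustering and cophenetic model-order selection.

For each ICA model order d the metadata matrix is hierarchically clustered
over its classes (single linkage, 1 - Pearson r distance) and the quality
of the dendrogram is summarized by the cophenetic correlation coefficient
CC_c: the Pearson correlation between the original pairwise distances and
the cophenetic distances (the merge height at which two leaves first join).
Scanning CC_c over a grid of model orders and keeping orders whose CC_c
exceeds mean + 2 sd (plus the global argmax) selects the decompositions
whose metadata structure the dendrogram represents most faithfully.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .ica_decomp import fit_ica, reduce_svd
from .maimage import MAMatrix
from .metaproject import MetadataMatrix, experiment_weights, project_metadata

__all__ = [
    "ScanResult",
    "class_distances",
    "correlation_distances",
    "single_linkage",
    "cophenetic_distances",
    "cophenetic_cc",
    "scan_model_orders",
]


@dataclass
class ScanResult:
    d_grid: list
    ccc_values: np.ndarray  # NaN where a stage failed
    mean_ccc: float
    sd_ccc: float
    selected_orders: list  # {d : CC_c(d) > mean + 2 sd}
    argmax_d: int
    degenerate_orders: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    seed: int = 0


def correlation_distances(rows: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson-r distances between the rows of a matrix.

    A zero-variance row has undefined correlations; its distances are set
    to 1 (maximally uninformative under the 1 - r metric) with a warning.
    """
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    if n < 2:
        raise ValueError("need at least two rows")
    sd = rows.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s); their 1-r distances set to 1"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(rows)
    dist = 1.0 - r
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    # clamp the tiny negative round-off that 1 - r can produce
    dist = np.clip(dist, 0.0, 2.0)
    return squareform(dist, checks=False)


def class_distances(meta: MetadataMatrix) -> np.ndarray:
    """Condensed 1 - r distances between metadata classes (rows of P_d)."""
    return correlation_distances(meta.values)


def single_linkage(dist: np.ndarray, method: str = "single") -> np.ndarray:
    """Agglomerative clustering; returns the standard (n-1) x 4 merge table."""
    dist = np.asarray(dist, dtype=float)
    n = int((1 + np.sqrt(1 + 8 * len(dist))) / 2)
    if n < 2 or n * (n - 1) // 2 != len(dist):
        raise ValueError("not a valid condensed distance vector for n >= 2 items")
    return linkage(dist, method=method)


def cophenetic_distances(tree: np.ndarray) -> np.ndarray:
    """Condensed cophenetic distances: first-merge height per leaf pair."""
    return cophenet(tree)


def cophenetic_cc(original: np.ndarray, cophenetic: np.ndarray) -> float:
    """CC_c: Pearson correlation of original vs cophenetic condensed distances."""
    x = np.asarray(original, dtype=float)
    y = np.asarray(cophenetic, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("distance vectors must have equal length >= 2")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant distance vector: CC_c undefined, returning NaN")
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def ccc_of_metadata(meta: MetadataMatrix, method: str = "single") -> float:
    """Convenience: CC_c of the class dendrogram of one metadata matrix."""
    dist = class_distances(meta)
    tree = single_linkage(dist, method=method)
    return cophenetic_cc(dist, cophenetic_distances(tree))


def _child_seed(seed: int, d: int) -> int:
    return int(np.random.SeedSequence([seed, d]).generate_state(1)[0] % (2**31))


def scan_model_orders(
    ma: MAMatrix | np.ndarray,
    label_matrix: np.ndarray,
    d_grid,
    seed: int,
    linkage_method: str = "single",
    class_names: list | None = None,
) -> ScanResult:
    """CC_c across a grid of ICA model orders; select preferred orders.

    For each d: SVD reduction -> ICA -> experiment weights -> metadata
    projection -> class clustering -> CC_c. A failure at one d is recorded
    in ``diagnostics`` and the scan continues; the scan fails only if no d
    completes. Selected orders are those with CC_c > mean + 2 sd of the
    completed grid; the global argmax is always reported, ties broken
    toward smaller d.

    Orders d <= 2 are degenerate for the 1 - r metric: the Pearson
    correlation between two metadata rows of length 2 is identically +-1,
    so every distance is 0 or 2, the dendrogram is exactly ultrametric and
    CC_c = 1 regardless of the data. Their CC_c is recorded but they are
    listed in ``degenerate_orders`` and excluded from the mean/sd, the
    selection and the argmax.
    """
    d_grid = sorted(int(d) for d in d_grid)
    if not d_grid:
        raise ValueError("d_grid must be non-empty")
    if isinstance(ma, MAMatrix):
        X = ma.values.T
    else:
        X = np.asarray(ma, dtype=float)
    e, v = X.shape
    if max(d_grid) > min(e, v):
        raise ValueError(f"max(d_grid)={max(d_grid)} exceeds min(e, v)={min(e, v)}")

    # one SVD serves every model order in the grid
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    from .ica_decomp import _fix_svd_signs

    U, Vt = _fix_svd_signs(U, Vt)
    rank = int(np.sum(s > s[0] * max(e, v) * np.finfo(float).eps))

    ccc = np.full(len(d_grid), np.nan)
    diagnostics: dict = {}
    for i, d in enumerate(d_grid):
        try:
            if d > rank:
                raise ValueError(f"d={d} exceeds the achievable rank {rank}")
            modes = U[:, :d] * s[:d]
            whitened = np.sqrt(v) * Vt[:d]
            decomp = fit_ica(
                whitened, d, _child_seed(seed, d),
                experiment_modes=modes, singular_values=s[:d],
            )
            weights = experiment_weights(decomp.experiment_modes, decomp.mixing)
            meta = project_metadata(label_matrix, weights, class_names=class_names)
            ccc[i] = ccc_of_metadata(meta, method=linkage_method)
        except Exception as exc:  # keep scanning the remaining orders
            diagnostics[d] = repr(exc)
    degenerate = [d for d in d_grid if d <= 2]
    ok = np.isfinite(ccc) & np.array([d not in degenerate for d in d_grid])
    if not ok.any():
        raise RuntimeError(f"no non-degenerate model order completed: {diagnostics}")
    mean_ccc = float(ccc[ok].mean())
    sd_ccc = float(ccc[ok].std(ddof=0))
    selected = [d for i, d in enumerate(d_grid) if ok[i] and ccc[i] > mean_ccc + 2 * sd_ccc]
    masked = np.where(ok, ccc, -np.inf)
    argmax_d = d_grid[int(np.argmax(masked))]  # ties resolve to smaller d
    return ScanResult(
        d_grid=d_grid,
        ccc_values=ccc,
        mean_ccc=mean_ccc,
        sd_ccc=sd_ccc,
        selected_orders=selected,
        argmax_d=argmax_d,
        degenerate_orders=degenerate,
        diagnostics=diagnostics,
        seed=seed,
    )
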