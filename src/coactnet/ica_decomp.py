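"""Spatial ICA of the modeled-activation matrix.

The experiments x voxels matrix is centered per voxel, reduced to its top-d
singular modes, and whitened; a fixed-point ICA (tanh contrast, symmetric
decorrelation) rotates the whitened spatial data into maximally
non-Gaussian spatial sources. Each source map is converted to z-statistic
units by fitting a Gaussian null to the background of its histogram with a
small mixture model, then thresholded downstream (default z > 4).

Conventions
-----------
Let X be the centered e x v data, X = U S Vt its SVD, and Z = sqrt(v) * Vt_d
the whitened spatial data (second-moment matrix Z Z'/v = I exactly). ICA
finds an orthogonal rotation W with sources = W Z. The stored mixing matrix
is M_d = W'/sqrt(v), so that experiment_modes (U_d S_d) @ M_d gives the
least-squares weight of each source in each experiment and
experiment_modes @ M_d @ sources reconstructs the rank-d approximation of X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .maimage import MAMatrix

__all__ = [
    "Decomposition",
    "ZMaps",
    "ComponentStats",
    "reduce_svd",
    "fit_ica",
    "to_zmaps",
    "component_stats",
]


@dataclass
class Decomposition:
    """Spatial ICA result at model order d."""

    d: int
    sources: np.ndarray  # (d, v) unit-variance spatial components
    mixing: np.ndarray  # (d, d)
    experiment_modes: np.ndarray  # (e, d) = U_d * S_d
    singular_values: np.ndarray  # (d,) non-increasing
    seed: int
    n_iter: int = 0


@dataclass
class ZMaps:
    """Per-component z-statistic maps and the null fits behind them."""

    zvalues: np.ndarray  # (d, v)
    threshold: float
    background_fit: list  # per-component dict: mean, sd, method, n_mixture


@dataclass
class ComponentStats:
    d: int
    mean_sig_voxels: float
    mean_sig_z: float  # NaN when no component has supra-threshold voxels
    per_component_sig_voxels: np.ndarray = field(default=None, repr=False)
    per_component_mean_z: np.ndarray = field(default=None, repr=False)


def _fix_svd_signs(U: np.ndarray, Vt: np.ndarray):
    """Deterministic sign convention on singular vectors.

    Each spatial mode is flipped so its largest-magnitude voxel loading is
    positive. The convention depends only on the spatial modes, so the
    whitened data — and everything downstream — is invariant to the order
    of the input experiments.
    """
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    return U * flip, Vt * flip[:, None]


def reduce_svd(ma: MAMatrix | np.ndarray, d: int, center: bool = True):
    """Center per voxel, take the top-d SVD modes, and whiten spatially.

    Parameters
    ----------
    ma : MAMatrix (voxels x experiments) or a plain (e x v) array already
        oriented experiments-by-voxels.
    d : number of singular modes to retain.
    center : remove each voxel's mean across experiments first (standard
        probabilistic-ICA preprocessing). With ``center=False`` the grand
        mean structure stays in the retained modes, which keeps planted
        single-network sources exactly representable at d = k.

    Returns
    -------
    experiment_modes : (e, d) array, U_d * S_d.
    singular_values : (d,) non-increasing.
    whitened : (d, v) spatial data with identity second-moment matrix.
    """
    if isinstance(ma, MAMatrix):
        X = ma.values.T.copy()
    else:
        X = np.array(ma, dtype=float)
    e, v = X.shape
    if not 1 <= d <= min(e, v):
        raise ValueError(f"d={d} must be in [1, min(e, v)={min(e, v)}]")
    if center:
        X -= X.mean(axis=0, keepdims=True)  # per-voxel centering across experiments
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, Vt = _fix_svd_signs(U, Vt)
    rank = int(np.sum(s > s[0] * max(e, v) * np.finfo(float).eps)) if s.size else 0
    if d > rank:
        raise ValueError(f"d={d} exceeds the matrix rank (achievable rank: {rank})")
    experiment_modes = U[:, :d] * s[:d]
    whitened = np.sqrt(v) * Vt[:d]
    return experiment_modes, s[:d].copy(), whitened


def fit_ica(
    whitened: np.ndarray,
    d: int,
    seed: int,
    experiment_modes: np.ndarray | None = None,
    singular_values: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> Decomposition:
    """Fixed-point ICA on whitened spatial data.

    Sources are decorrelated (symmetric updates), sign-fixed so every
    source has non-negative skewness, and ordered by explained variance
    (descending). Deterministic for a fixed seed.
    """
    whitened = np.asarray(whitened, dtype=float)
    if whitened.shape[0] != d:
        raise ValueError("whitened data must have d rows")
    v = whitened.shape[1]
    if d == 1:
        W = np.ones((1, 1))
        n_iter = 0
    else:
        rng = np.random.default_rng(seed)
        w_init = rng.standard_normal((d, d))
        ica = FastICA(
            algorithm="parallel",
            fun="logcosh",
            whiten=False,
            max_iter=max_iter,
            tol=tol,
            w_init=w_init,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=ConvergenceWarning)
            try:
                ica.fit(whitened.T)  # samples = voxels, features = d whitened dims
            except ConvergenceWarning as exc:
                raise RuntimeError(
                    f"ICA did not converge at d={d} within {max_iter} iterations: {exc}"
                ) from exc
        W = ica.components_
        n_iter = ica.n_iter_
    sources = W @ whitened
    mixing = W.T / np.sqrt(v)

    # sign convention: non-negative skewness per source
    flip = np.where(stats.skew(sources, axis=1) < 0, -1.0, 1.0)
    sources = sources * flip[:, None]
    mixing = mixing * flip[None, :]

    if experiment_modes is not None:
        weights = experiment_modes @ mixing
        order = np.argsort(-np.sum(weights**2, axis=0), kind="stable")
    else:
        order = np.arange(d)
    sources = sources[order]
    mixing = mixing[:, order]
    return Decomposition(
        d=d,
        sources=sources,
        mixing=mixing,
        experiment_modes=np.empty((0, d)) if experiment_modes is None else experiment_modes,
        singular_values=np.empty(0) if singular_values is None else np.asarray(singular_values),
        seed=seed,
        n_iter=n_iter,
    )


def decompose(
    ma: MAMatrix | np.ndarray, d: int, seed: int, center: bool = True, **ica_kwargs
) -> Decomposition:
    """reduce_svd + fit_ica in one call."""
    modes, svals, whitened = reduce_svd(ma, d, center=center)
    return fit_ica(
        whitened, d, seed, experiment_modes=modes, singular_values=svals, **ica_kwargs
    )


def _fit_gaussian_null(x: np.ndarray, seed: int = 0, max_fit_voxels: int = 20000):
    """Gaussian background of one source map via a small mixture model.

    Fits 1-, 2- and 3-component Gaussian mixtures (background plus up to
    two activation tails), selects by BIC, and takes the dominant-weight
    component as the null. Initialization and the fallback use the robust
    median/MAD location and scale.
    """
    med = np.median(x)
    mad_sd = stats.median_abs_deviation(x, scale="normal")
    if mad_sd <= 0:
        mad_sd = float(np.std(x))
    xfit = x
    if x.size > max_fit_voxels:  # deterministic thinning keeps the fit cheap
        step = x.size // max_fit_voxels + 1
        xfit = x[::step]
    Xf = xfit.reshape(-1, 1)
    best = None
    best_bic = np.inf
    inits = {
        1: np.array([[med]]),
        2: np.array([[med], [med + 4 * mad_sd]]),
        3: np.array([[med - 4 * mad_sd], [med], [med + 4 * mad_sd]]),
    }
    for k, means_init in inits.items():
        try:
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                means_init=means_init,
                random_state=seed,
                reg_covar=1e-8,
                max_iter=200,
            ).fit(Xf)
            bic = gm.bic(Xf)
        except Exception:
            continue
        if np.isfinite(bic) and bic < best_bic:
            best_bic = bic
            best = gm
    if best is None:
        return med, mad_sd, "median_mad", 0
    i = int(np.argmax(best.weights_))
    mean = float(best.means_[i, 0])
    sd = float(np.sqrt(best.covariances_[i, 0, 0]))
    if sd <= 0 or not np.isfinite(sd):
        return med, mad_sd, "median_mad", 0
    return mean, sd, "gaussian_mixture", int(best.n_components)


def to_zmaps(
    decomp: Decomposition,
    threshold: float = 4.0,
    method: str = "mixture",
) -> ZMaps:
    """Convert spatial sources to z-statistic maps.

    ``method='mixture'`` fits the Gaussian-background mixture per component;
    ``method='robust'`` standardizes by median/MAD directly. Thresholding is
    not applied here — the threshold is recorded and used by
    :func:`component_stats` and downstream comparisons.
    """
    if method not in ("mixture", "robust"):
        raise ValueError(f"unknown method {method!r}")
    z = np.empty_like(decomp.sources)
    fits = []
    for i, src in enumerate(decomp.sources):
        if not np.all(np.isfinite(src)):
            raise ValueError(f"component {i} contains non-finite values")
        if np.ptp(src) == 0:
            raise ValueError(f"component {i} is constant; cannot fit a null")
        if method == "mixture":
            mean, sd, how, k = _fit_gaussian_null(src, seed=decomp.seed)
        else:
            mean = float(np.median(src))
            sd = float(stats.median_abs_deviation(src, scale="normal"))
            if sd <= 0:
                sd = float(np.std(src))
            how, k = "median_mad", 0
        z[i] = (src - mean) / sd
        fits.append({"mean": mean, "sd": sd, "method": how, "n_mixture": k})
    return ZMaps(zvalues=z, threshold=threshold, background_fit=fits)


def component_stats(zmaps: ZMaps) -> ComponentStats:
    """Mean supra-threshold voxel count and mean supra-threshold z.

    Counts are strictly above the recorded threshold. Components with no
    supra-threshold voxel contribute 0 to the voxel-count mean and are
    excluded from the z mean; if every component is sub-threshold the z
    mean is NaN.
    """
    above = zmaps.zvalues > zmaps.threshold
    n_sig = above.sum(axis=1)
    mean_z = np.full(len(n_sig), np.nan)
    for i in np.flatnonzero(n_sig):
        mean_z[i] = zmaps.zvalues[i, above[i]].mean()
    active = n_sig > 0
    return ComponentStats(
        d=zmaps.zvalues.shape[0],
        mean_sig_voxels=float(n_sig.mean()),
        mean_sig_z=float(mean_z[active].mean()) if active.any() else float("nan"),
        per_component_sig_voxels=n_sig,
        per_component_mean_z=mean_z,
    )
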