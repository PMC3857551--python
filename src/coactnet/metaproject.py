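"""Projection of taxonomy labels onto ICA components.

The experiment-weight matrix M = V_d M_d gives the weight of each spatial
component in each experiment; left-multiplying by the binary class-by-
experiment indicator P yields the classes x components metadata matrix
P_d = P M, whose entry (c, i) sums component i's weights over all
experiments carrying class c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExperimentWeights", "MetadataMatrix", "experiment_weights", "project_metadata"]


@dataclass
class ExperimentWeights:
    weights: np.ndarray  # (e, d)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be 2-D (experiments x components)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


@dataclass
class MetadataMatrix:
    values: np.ndarray  # (n_classes, d)
    class_names: list
    d: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, d = self.values.shape
        if n != len(self.class_names):
            raise ValueError("row count must match class_names")
        if d != self.d:
            raise ValueError("column count must match d")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metadata values must be finite")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# d = {self.d}\n")
            for k, v in self.provenance.items():
                fh.write(f"# {k} = {v}\n")
            pd.DataFrame(
                self.values,
                index=self.class_names,
                columns=[f"component_{i:03d}" for i in range(self.d)],
            ).to_csv(fh, index_label="class")


def experiment_weights(experiment_modes: np.ndarray, mixing: np.ndarray) -> ExperimentWeights:
    """M = V_d M_d : weight of each component in each experiment."""
    experiment_modes = np.asarray(experiment_modes, dtype=float)
    mixing = np.asarray(mixing, dtype=float)
    if experiment_modes.ndim != 2 or mixing.ndim != 2:
        raise ValueError("inputs must be 2-D")
    if experiment_modes.shape[1] != mixing.shape[0] or mixing.shape[0] != mixing.shape[1]:
        raise ValueError(
            f"shape mismatch: modes {experiment_modes.shape} x mixing {mixing.shape}"
        )
    return ExperimentWeights(weights=experiment_modes @ mixing)


def project_metadata(
    label_matrix: np.ndarray,
    weights: ExperimentWeights,
    class_names: list | None = None,
    normalize_by_frequency: bool = False,
    provenance: dict | None = None,
) -> MetadataMatrix:
    """P_d = P M : metadata classes x components.

    The row for a class is the sum of the weight rows of the experiments
    carrying that class. ``normalize_by_frequency`` optionally divides each
    row by the class's experiment count (sensitivity analysis only; the
    default reported quantity is the raw projection). Fractional label
    weights are accepted and used as given.
    """
    P = np.asarray(label_matrix, dtype=float)
    M = weights.weights
    if P.ndim != 2 or P.shape[1] != M.shape[0]:
        raise ValueError(f"shape mismatch: labels {P.shape} x weights {M.shape}")
    values = P @ M
    if normalize_by_frequency:
        counts = P.sum(axis=1, keepdims=True)
        values = np.divide(values, counts, out=np.zeros_like(values), where=counts > 0)
    n = P.shape[0]
    if class_names is None:
        class_names = [f"class_{i:03d}" for i in range(n)]
    return MetadataMatrix(
        values=values,
        class_names=list(class_names),
        d=M.shape[1],
        provenance=provenance or {},
    )
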