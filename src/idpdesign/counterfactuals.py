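"""Post-hoc counterfactual analysis of a converged design run.

A counterfactual of a Pareto-optimal sequence is a sequence that is highly
similar in feature space (cosine similarity of the 30-dim feature vectors
above a threshold) yet measurably off the front (its Euclidean distance to
the nearest front point, in the z-scored B2-D plane over phase separators,
falls in a fixed band).  Averaging per-feature differences between a Pareto
sequence and its counterfactuals attributes optimality to specific features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_features import FEATURE_NAMES, cosine_similarity

__all__ = [
    "CounterfactualReport",
    "select_counterfactuals",
    "avg_feature_differences",
    "similarity_matrices",
]


@dataclass
class CounterfactualReport:
    pareto_id: str
    counterfactual_ids: list
    mean_differences: np.ndarray  # Pareto minus counterfactual, per feature
    se_differences: np.ndarray
    n: int

    def to_rows(self) -> list[dict]:
        return [
            {"feature": name, "mean_difference": float(m), "se": float(s),
             "n": self.n}
            for name, m, s in zip(FEATURE_NAMES, self.mean_differences,
                                  self.se_differences)
        ]


def _zscore_plane(b2: np.ndarray, d: np.ndarray) -> np.ndarray:
    pts = np.column_stack([b2, d]).astype(float)
    mu = pts.mean(axis=0)
    sd = pts.std(axis=0)
    sd[sd == 0] = 1.0
    return (pts - mu) / sd


def front_distances(b2: np.ndarray, d: np.ndarray,
                    front_mask: np.ndarray) -> np.ndarray:
    """Distance of every point to the nearest Pareto point, z-scored plane."""
    z = _zscore_plane(b2, d)
    front = z[front_mask]
    if len(front) == 0:
        raise ValueError("front mask selects no points")
    diff = z[:, None, :] - front[None, :, :]
    return np.min(np.linalg.norm(diff, axis=-1), axis=1)


def select_counterfactuals(pareto_index: int, features: np.ndarray,
                           b2: np.ndarray, d: np.ndarray,
                           front_mask: np.ndarray,
                           sim_threshold: float = 0.9,
                           dist_range: tuple[float, float] = (0.15, 0.3)
                           ) -> np.ndarray:
    """Indices of counterfactual candidates for one Pareto sequence.

    Inputs describe the phase-separating dataset: feature matrix, measured
    B2 and D arrays, and a boolean mask of the Pareto-front members.
    """
    if len(b2) == 0:
        raise ValueError("empty dataset")
    dist = front_distances(b2, d, front_mask)
    lo, hi = dist_range
    out = []
    for j in range(len(b2)):
        if j == pareto_index:
            continue
        if not (lo <= dist[j] <= hi):
            continue
        if cosine_similarity(features[pareto_index], features[j], "full") > sim_threshold:
            out.append(j)
    return np.array(out, dtype=int)


def avg_feature_differences(pareto_features: np.ndarray,
                            counterfactual_features: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error of x(Pareto) - x(counterfactual) per feature."""
    cf = np.atleast_2d(np.asarray(counterfactual_features, dtype=float))
    if len(cf) < 1:
        raise ValueError("need at least one counterfactual")
    diffs = np.asarray(pareto_features, dtype=float)[None, :] - cf
    mean = diffs.mean(axis=0)
    se = (diffs.std(axis=0, ddof=1) / np.sqrt(len(cf))
          if len(cf) > 1 else np.zeros_like(mean))
    return mean, se


def similarity_matrices(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise cosine-similarity matrices of the composition and descriptor
    feature components; both symmetric with unit diagonal."""
    f = np.atleast_2d(np.asarray(features, dtype=float))
    if len(f) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(f)
    comp = np.eye(n)
    desc = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            comp[i, j] = comp[j, i] = cosine_similarity(f[i], f[j], "composition")
            desc[i, j] = desc[j, i] = cosine_similarity(f[i], f[j], "descriptors")
    return comp, desc
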