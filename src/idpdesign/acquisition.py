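"""Pareto bookkeeping and acquisition mathematics for two-objective design.

Objectives are (-B2~, D~), both maximized: a sequence improves the archive if
it is simultaneously more attractive (more negative B2) and faster-diffusing.
The module provides nondominated extraction, the 2-D dominated hypervolume,
the exact expected hypervolume improvement (EHVI) for independent Gaussian
objective predictions, a similarity penalty that suppresses re-proposing
near-duplicate sequences, and the iteration-staged fitness:

* stage k = 0: minimize B2 only (fitness = -B2~ prediction);
* stages 0 < k < k_final: EHVI x classifier-label x similarity penalty;
* final stage: pure exploitation, -B2~ + D~.

The EHVI uses the standard strip decomposition over the front augmented with
sentinel endpoints.  Writing E1[c] = E[(Y1 - c)+] and E2[c] = E[(Y2 - c)+]
for the Gaussian partial expectations, with the front sorted by descending
first objective a_1 > ... > a_n (b_1 < ... < b_n) and reference point
(r1, r2):

    EHVI = sum_{k=0}^{n} (E1[a_{k+1}] - E1[a_k]) * E2[b_k]

with a_0 = +inf, a_{n+1} = r1, b_0 = r2.  Each term is the expected dominated
area contributed by the vertical strip between consecutive front abscissae.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .surrogates import SurrogatePrediction

__all__ = [
    "pareto_front",
    "hypervolume",
    "psi",
    "expected_excess",
    "ehvi",
    "ehvi_batch",
    "ParetoArchive",
    "similarity_penalty",
    "FitnessContext",
    "fitness",
]


def pareto_front(points: np.ndarray) -> np.ndarray:
    """Indices of the nondominated subset under maximize/maximize dominance.

    Ties on both coordinates keep the first-seen point.  Order of returned
    indices follows the input order.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("objective values must be finite")
    n = len(pts)
    # sort by f1 desc, then f2 desc, then input order (stable tie-break keeps
    # the first-seen of exact duplicates); sweep retaining strictly rising f2
    order = np.lexsort((np.arange(n), -pts[:, 1], -pts[:, 0]))
    keep = []
    best_f2 = -np.inf
    for i in order:
        if pts[i, 1] > best_f2:
            keep.append(i)
            best_f2 = pts[i, 1]
    return np.array(sorted(keep), dtype=int)


def hypervolume(points: np.ndarray, reference_point) -> float:
    """2-D dominated hypervolume (area) above the reference point.

    Dominated input points are ignored; points not dominating the reference
    point are excluded with a warning.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    ref = np.asarray(reference_point, dtype=float)
    if len(pts) == 0:
        return 0.0
    ok = (pts[:, 0] > ref[0]) & (pts[:, 1] > ref[1])
    if not np.all(ok):
        warnings.warn(f"excluded {int(np.sum(~ok))} point(s) not above the reference point")
    pts = pts[ok]
    if len(pts) == 0:
        return 0.0
    pts = pts[pareto_front(pts)]
    order = np.argsort(-pts[:, 0])  # descending f1 -> ascending f2 on a front
    pts = pts[order]
    hv = 0.0
    for i, (f1, f2) in enumerate(pts):
        nxt = pts[i + 1, 0] if i + 1 < len(pts) else ref[0]
        hv += (f1 - nxt) * (f2 - ref[1])
    return float(hv)


def psi(a: float, b: float, mu: float, sigma: float) -> float:
    """Gaussian partial expectation
    ``int_{-inf}^{b} (a - z) phi((z - mu)/sigma)/sigma dz``
    = ``(a - mu) Phi((b - mu)/sigma) + sigma phi((b - mu)/sigma)``.

    For sigma -> 0 the integral degenerates to a step: (a - mu) if mu < b.
    """
    if sigma > 0:
        t = (b - mu) / sigma
        return float((a - mu) * norm.cdf(t) + sigma * norm.pdf(t))
    return float((a - mu) * (mu <= b))


def expected_excess(mu, sigma, c):
    """E[(Y - c)+] for Y ~ N(mu, sigma^2); elementwise on arrays.

    Finite for c = +inf (returns 0); equals max(0, mu - c) when sigma = 0.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    c = np.asarray(c, dtype=float)
    mu, sigma, c = np.broadcast_arrays(mu, sigma, c)
    out = np.zeros(mu.shape)
    inf_c = np.isinf(c) & (c > 0)
    det = (sigma == 0) & ~inf_c
    out[det] = np.maximum(0.0, (mu - c)[det])
    sto = (~det) & (~inf_c)
    if np.any(sto):
        t = (c[sto] - mu[sto]) / sigma[sto]
        out[sto] = (mu[sto] - c[sto]) * norm.sf(t) + sigma[sto] * norm.pdf(t)
    return out if out.ndim else float(out)


def _front_arrays(front: np.ndarray, reference_point):
    pts = np.asarray(front, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("archive front must be nonempty")
    pts = pts[pareto_front(pts)]
    pts = pts[np.argsort(-pts[:, 0])]
    ref = np.asarray(reference_point, dtype=float)
    a = np.concatenate([[np.inf], pts[:, 0], [ref[0]]])  # a_0 .. a_{n+1}
    b = np.concatenate([[ref[1]], pts[:, 1]])            # b_0 .. b_n
    return a, b


def ehvi_batch(mu1, sd1, mu2, sd2, front, reference_point) -> np.ndarray:
    """Exact EHVI for a batch of candidates with independent Gaussian
    objective predictions (both objectives maximized)."""
    a, b = _front_arrays(front, reference_point)
    mu1 = np.atleast_1d(np.asarray(mu1, dtype=float))
    sd1 = np.atleast_1d(np.asarray(sd1, dtype=float))
    mu2 = np.atleast_1d(np.asarray(mu2, dtype=float))
    sd2 = np.atleast_1d(np.asarray(sd2, dtype=float))
    e1 = expected_excess(mu1[:, None], sd1[:, None], a[None, :])  # (m, n+2)
    e2 = expected_excess(mu2[:, None], sd2[:, None], b[None, :])  # (m, n+1)
    strips = e1[:, 1:] - e1[:, :-1]  # E1[a_{k+1}] - E1[a_k], k = 0..n
    vals = np.sum(strips * e2, axis=1)
    return np.maximum(vals, 0.0)


def ehvi(pred_b2: SurrogatePrediction, pred_d: SurrogatePrediction,
         front, reference_point) -> float:
    """Exact two-objective EHVI for a single candidate: objective 1 is the
    (standardized, negated) virial coefficient prediction, objective 2 the
    standardized diffusion prediction."""
    v = ehvi_batch(np.atleast_1d(pred_b2.mean), np.atleast_1d(pred_b2.sd),
                   np.atleast_1d(pred_d.mean), np.atleast_1d(pred_d.sd),
                   front, reference_point)
    return float(v[0])


@dataclass
class ParetoArchive:
    """Nondominated archive in a fixed 2-D maximize/maximize plane."""

    reference_point: tuple
    ids: list = field(default_factory=list)
    points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def add(self, new_ids: list, new_points: np.ndarray) -> list:
        """Insert points, re-extract the front; returns ids newly on the front."""
        new_points = np.asarray(new_points, dtype=float).reshape(-1, 2)
        all_ids = list(self.ids) + list(new_ids)
        all_pts = np.vstack([self.points, new_points]) if len(all_ids) else new_points
        keep = pareto_front(all_pts)
        before = set(self.ids)
        self.ids = [all_ids[i] for i in keep]
        self.points = all_pts[keep]
        return [i for i in self.ids if i not in before]

    def hypervolume(self) -> float:
        return hypervolume(self.points, self.reference_point)

    def to_json(self, iteration: int | None = None) -> str:
        return json.dumps({
            "iteration": iteration,
            "reference_point": list(map(float, self.reference_point)),
            "hypervolume": self.hypervolume(),
            "points": [
                {"id": i, "objectives": [float(p[0]), float(p[1])]}
                for i, p in zip(self.ids, self.points)
            ],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ParetoArchive":
        d = json.loads(text)
        arch = cls(reference_point=tuple(d["reference_point"]))
        if d["points"]:
            arch.add([p["id"] for p in d["points"]],
                     np.array([p["objectives"] for p in d["points"]]))
        return arch


def similarity_penalty(candidate: np.ndarray, history: list | np.ndarray) -> float:
    """Similarity penalty alpha in [0, 1]: the harmonic mean of the cosine
    dissimilarities (1 - cos)/2 between the candidate's feature vector and
    every previously simulated or proposed sequence.  High similarity to even
    one history entry drives alpha to zero; an empty history gives alpha = 1.
    """
    hist = np.asarray(history, dtype=float)
    if hist.size == 0:
        return 1.0
    hist = hist.reshape(len(hist), -1)
    x = np.asarray(candidate, dtype=float)
    cos = hist @ x / (np.linalg.norm(hist, axis=1) * np.linalg.norm(x))
    dis = 0.5 * (1.0 - cos)
    if np.any(dis <= 1e-12):  # identical (up to round-off) to a history entry
        return 0.0
    return float(len(dis) / np.sum(1.0 / dis))


def similarity_penalty_batch(candidates: np.ndarray, history) -> np.ndarray:
    """Vectorized :func:`similarity_penalty` over rows of `candidates`."""
    X = np.atleast_2d(np.asarray(candidates, dtype=float))
    hist = np.asarray(history, dtype=float)
    if hist.size == 0:
        return np.ones(len(X))
    hist = hist.reshape(len(hist), -1)
    cos = (X @ hist.T) / np.outer(np.linalg.norm(X, axis=1),
                                  np.linalg.norm(hist, axis=1))
    dis = 0.5 * (1.0 - cos)
    out = np.empty(len(X))
    degenerate = np.any(dis <= 1e-12, axis=1)
    out[degenerate] = 0.0
    ok = ~degenerate
    if np.any(ok):
        out[ok] = hist.shape[0] / np.sum(1.0 / dis[ok], axis=1)
    return out


@dataclass
class FitnessContext:
    """Everything the staged fitness needs at iteration k."""

    k: int
    k_final: int = 8
    gp_b2: object = None
    gp_d: object = None
    classifier: object = None
    front: np.ndarray | None = None        # standardized (-B2~, D~) front
    reference_point: tuple | None = None
    history: list = field(default_factory=list)  # feature vectors for alpha


def fitness(feature_rows: np.ndarray, ctx: FitnessContext) -> np.ndarray:
    """Staged fitness of Eq-schedule design, evaluated on a batch of
    feature-vector rows.  Note the B2 surrogate is trained on B2~, so the
    stage-0 and final-stage objectives negate its mean prediction."""
    X = np.atleast_2d(np.asarray(feature_rows, dtype=float))
    if ctx.gp_b2 is None:
        raise ValueError("fitness requires a fitted B2 surrogate")
    if ctx.k == 0:
        return -ctx.gp_b2.predict_mean(X)
    if ctx.k >= ctx.k_final:
        if ctx.gp_d is None:
            raise ValueError("final exploitation stage requires a fitted D surrogate")
        return -ctx.gp_b2.predict_mean(X) + ctx.gp_d.predict_mean(X)
    if ctx.gp_d is None or ctx.classifier is None or ctx.front is None:
        raise ValueError("EHVI stage requires D surrogate, classifier and archive front")
    pb = ctx.gp_b2.predict(X)
    pd_ = ctx.gp_d.predict(X)
    vals = ehvi_batch(-pb.mean, pb.sd, pd_.mean, pd_.sd,
                      ctx.front, ctx.reference_point)
    labels = ctx.classifier.label(X)
    alphas = similarity_penalty_batch(X, ctx.history)
    return vals * labels * alphas
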