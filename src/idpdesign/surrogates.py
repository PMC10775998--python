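"""Surrogate property models: Gaussian-process regressors for the
standardized virial coefficient (B2~) and diffusion coefficient (D~), and a
random-forest phase-separation classifier.

The GP is a compact squared-exponential regressor with unit prior amplitude
(targets are standardized before fitting), an isotropic length scale and an
observation-noise variance selected by maximizing the log marginal likelihood
over a small grid anchored at the median pairwise feature distance.  That
keeps refits cheap enough to run inside every active-learning iteration while
still providing calibrated predictive uncertainty: the predictive sd shrinks
toward ~sqrt(noise) at training points and reverts to the prior sd far away.

The diffusion model is trained only on phase-separating sequences (D is
undefined otherwise); the classifier gates D predictions in the acquisition
fitness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "StandardScale",
    "standardize",
    "SurrogatePrediction",
    "GPConfig",
    "GPRegressor",
    "fit_b2_gpr",
    "fit_d_gpr",
    "PhaseClassifier",
    "fit_phase_classifier",
    "save_bundle",
    "load_bundle",
]


@dataclass(frozen=True)
class StandardScale:
    """Mean/sd transform for standard-normalizing a property."""

    mean: float
    sd: float

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def standardize(values) -> tuple[np.ndarray, StandardScale]:
    """Zero-mean unit-sd transform fitted on the given values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.all(v == v.flat[0]):
        raise ValueError("standardize needs >= 2 distinct values")
    scale = StandardScale(mean=float(np.mean(v)), sd=float(np.std(v)))
    return scale.transform(v), scale


@dataclass(frozen=True)
class SurrogatePrediction:
    mean: np.ndarray
    sd: np.ndarray


@dataclass(frozen=True)
class GPConfig:
    """Hyperparameter search space (or fixed values) for the GP.

    `composition_weights` are candidate scalings applied to the 20
    composition features relative to the 10 sequence descriptors before
    computing kernel distances; the marginal likelihood chooses among them,
    a two-point stand-in for full automatic relevance determination that
    keeps refits cheap inside the active-learning loop.
    """

    length_scale: float | None = None  # fixed value; None -> grid search
    noise: float | None = None
    length_multipliers: tuple = (0.25, 0.5, 1.0, 2.0, 4.0)
    noise_grid: tuple = (1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2)
    composition_weights: tuple = (1.0,)
    n_composition_dims: int = 20


class GPRegressor:
    """Squared-exponential GP with unit prior variance and white noise."""

    def __init__(self, config: GPConfig | None = None):
        self.config = config or GPConfig()
        self.X_ = None
        self.alpha_ = None
        self._cho = None
        self.length_scale_ = None
        self.noise_ = None
        self.comp_weight_ = 1.0
        self.lml_ = None

    @staticmethod
    def _sqdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.maximum(
            np.sum(a**2, 1)[:, None] + np.sum(b**2, 1)[None, :] - 2.0 * a @ b.T, 0.0
        )

    def _kernel(self, a, b, ell):
        return np.exp(-0.5 * self._sqdist(a, b) / ell**2)

    def _lml(self, K, y):
        n = len(y)
        try:
            c, low = cho_factor(K, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf, None
        alpha = cho_solve((c, low), y)
        return (
            -0.5 * float(y @ alpha)
            - float(np.sum(np.log(np.diag(c))))
            - 0.5 * n * np.log(2.0 * np.pi),
            (c, low, alpha),
        )

    def _weighted(self, X: np.ndarray, w: float) -> np.ndarray:
        nc = self.config.n_composition_dims
        if w == 1.0 or X.shape[1] <= nc:
            return X
        out = X.copy()
        out[:, :nc] *= w
        return out

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GPRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n, d) with matching y")
        if len(X) < 2:
            raise ValueError("need at least 2 training rows")
        noises = ([self.config.noise] if self.config.noise is not None
                  else list(self.config.noise_grid))
        best = (-np.inf, None, None, 1.0, None)
        for w in self.config.composition_weights:
            xw = self._weighted(X, w)
            d2 = self._sqdist(xw, xw)
            med = np.sqrt(np.median(d2[d2 > 0])) if np.any(d2 > 0) else 1.0
            ells = ([self.config.length_scale] if self.config.length_scale
                    else [m * med for m in self.config.length_multipliers])
            for ell in ells:
                k0 = np.exp(-0.5 * d2 / ell**2)
                for nz in noises:
                    lml, sol = self._lml(k0 + nz * np.eye(len(X)), y)
                    if lml > best[0]:
                        best = (lml, ell, nz, w, sol)
        self.lml_, self.length_scale_, self.noise_, self.comp_weight_, sol = best
        if sol is None:
            raise RuntimeError("GP fit failed: no valid Cholesky factorization")
        c, low, alpha = sol
        self.X_ = self._weighted(X, self.comp_weight_)
        self.alpha_, self._cho = alpha, (c, low)
        return self

    def predict(self, X: np.ndarray) -> SurrogatePrediction:
        if self.X_ is None:
            raise RuntimeError("GPRegressor is not fitted")
        X = self._weighted(np.atleast_2d(np.asarray(X, dtype=float)),
                           self.comp_weight_)
        ks = self._kernel(X, self.X_, self.length_scale_)
        mean = ks @ self.alpha_
        v = cho_solve(self._cho, ks.T)
        var = 1.0 - np.sum(ks * v.T, axis=1)
        sd = np.sqrt(np.maximum(var, 0.0))
        return SurrogatePrediction(mean=mean, sd=sd)

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        """Posterior mean only (skips the predictive-variance solve)."""
        if self.X_ is None:
            raise RuntimeError("GPRegressor is not fitted")
        X = self._weighted(np.atleast_2d(np.asarray(X, dtype=float)),
                           self.comp_weight_)
        return self._kernel(X, self.X_, self.length_scale_) @ self.alpha_

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "length_scale": self.length_scale_,
            "noise": self.noise_,
            "comp_weight": self.comp_weight_,
            "lml": self.lml_,
        }

    def save(self, path: str | Path) -> None:
        np.savez(
            path, X=self.X_, alpha=self.alpha_,
            length_scale=self.length_scale_, noise=self.noise_,
            comp_weight=self.comp_weight_, lml=self.lml_,
        )

    @classmethod
    def load(cls, path: str | Path) -> "GPRegressor":
        d = np.load(path)
        gp = cls(GPConfig(length_scale=float(d["length_scale"]),
                          noise=float(d["noise"])))
        gp.X_ = d["X"]  # stored pre-weighted; queries reuse the same weight
        gp.alpha_ = d["alpha"]
        gp.length_scale_ = float(d["length_scale"])
        gp.noise_ = float(d["noise"])
        gp.comp_weight_ = float(d["comp_weight"])
        k = gp._kernel(gp.X_, gp.X_, gp.length_scale_) + gp.noise_ * np.eye(len(gp.X_))
        gp._cho = cho_factor(k, lower=True)
        return gp


def fit_b2_gpr(X: np.ndarray, y_std: np.ndarray,
               config: GPConfig | None = None, min_rows: int = 8) -> GPRegressor:
    """GP for the standardized second virial coefficient."""
    if len(X) < min_rows:
        raise ValueError(f"need at least {min_rows} rows to fit the B2 model")
    return GPRegressor(config).fit(X, y_std)


def fit_d_gpr(X: np.ndarray, y_std: np.ndarray,
              config: GPConfig | None = None, min_rows: int = 4) -> GPRegressor:
    """GP for the standardized diffusion coefficient (phase separators only)."""
    if len(X) < min_rows:
        raise ValueError(f"need at least {min_rows} rows to fit the D model")
    return GPRegressor(config).fit(X, y_std)


class PhaseClassifier:
    """Random-forest phase-separation classifier with a hard 0/1 label."""

    def __init__(self, n_trees: int = 500, seed: int = 0):
        self.model = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )

    def fit(self, X, labels) -> "PhaseClassifier":
        labels = np.asarray(labels, dtype=int)
        if set(np.unique(labels)) != {0, 1}:
            raise ValueError("need binary labels with both classes present")
        self.model.fit(np.asarray(X, dtype=float), labels)
        return self

    def label(self, X) -> np.ndarray:
        """Hard 0/1 label.  Aggregates the fitted trees directly (equivalent
        to RandomForestClassifier.predict, bypassing its per-tree dispatch
        overhead, which dominates in tight design loops)."""
        X32 = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float32)
        agg = None
        for est in self.model.estimators_:
            p = est.tree_.predict(X32)
            p = p.reshape(len(X32), -1)
            p = p / p.sum(axis=1, keepdims=True)
            agg = p if agg is None else agg + p
        return np.argmax(agg, axis=1).astype(int)

    def score_proba(self, X) -> np.ndarray:
        return self.model.predict_proba(np.atleast_2d(np.asarray(X, dtype=float)))[:, 1]


def fit_phase_classifier(X, labels, n_trees: int = 500, seed: int = 0) -> PhaseClassifier:
    return PhaseClassifier(n_trees=n_trees, seed=seed).fit(X, labels)


# ---------------------------------------------------------------------------
# Model bundle


def save_bundle(path: str | Path, gp_b2: GPRegressor | None,
                gp_d: GPRegressor | None, clf: PhaseClassifier | None,
                scales: dict, scaler_dict: dict, seed: int) -> None:
    """Persist surrogates plus the scaler / standardization metadata they
    were fitted with, so predictions are reproducible after reload."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": seed,
        "scaler": scaler_dict,
        "scales": {k: {"mean": v.mean, "sd": v.sd} for k, v in scales.items()},
        "gp_b2": gp_b2.to_dict() if gp_b2 else None,
        "gp_d": gp_d.to_dict() if gp_d else None,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    if gp_b2:
        gp_b2.save(path / "gp_b2.npz")
    if gp_d:
        gp_d.save(path / "gp_d.npz")
    if clf:
        joblib.dump(clf, path / "classifier.joblib")


def load_bundle(path: str | Path) -> dict:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    out = {
        "seed": meta["seed"],
        "scaler": meta["scaler"],
        "scales": {k: StandardScale(v["mean"], v["sd"])
                   for k, v in meta["scales"].items()},
        "gp_b2": None, "gp_d": None, "classifier": None,
    }
    if (path / "gp_b2.npz").exists():
        out["gp_b2"] = GPRegressor.load(path / "gp_b2.npz")
    if (path / "gp_d.npz").exists():
        out["gp_d"] = GPRegressor.load(path / "gp_d.npz")
    if (path / "classifier.joblib").exists():
        out["classifier"] = joblib.load(path / "classifier.joblib")
    return out
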