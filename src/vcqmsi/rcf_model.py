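"""Relative calibration factors and the feature -> RCF regression.

The equal-concentration mimetic model gives, per tissue type, the relative
drug response at identical spiked amount — the relative calibration factor
(RCF).  Under the grand-mean convention used here, RCF_t is the tissue's
mean drug intensity divided by the pooled mean over all spot pixels, so the
pixel-count-weighted mean of the table is exactly 1.

A single-hidden-layer tanh network regresses per-pixel RCF on the selected
endogenous features.  Training minimizes mean squared error with the
Levenberg–Marquardt algorithm (MINPACK via ``scipy.optimize.least_squares``,
analytic Jacobian), run in short stages with early stopping on the
validation partition.  Predictions are clipped to configurable bounds so the
downstream intensity division cannot blow up.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .msi_data import FeatureTable, LabelMap, SpectrumGrid, extract_ion_image

__all__ = [
    "RCFTable",
    "SplitAssignment",
    "TrainConfig",
    "RegressionModel",
    "compute_rcf_table",
    "split_pixels",
    "train_rcf_model",
    "predict_rcf",
    "rcf_image",
]

TRAIN, VALIDATION, TEST = 0, 1, 2


@dataclass
class RCFTable:
    rcf: dict[str, float]
    pixel_counts: dict[str, int]
    reference_convention: str = "pixel-weighted grand mean = 1"

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.rcf.values()):
            raise ValueError("all RCF values must be positive")

    def weighted_mean(self) -> float:
        w = np.array([self.pixel_counts[t] for t in self.rcf])
        v = np.array([self.rcf[t] for t in self.rcf])
        return float((w * v).sum() / w.sum())

    def per_pixel_targets(self, labels: LabelMap) -> np.ndarray:
        """Broadcast tissue RCFs to the labeled pixels (row-major order)."""
        out = []
        for r, c in np.argwhere(labels.labels > 0):
            out.append(self.rcf[labels.names[labels.labels[r, c]]])
        return np.array(out)


def compute_rcf_table(equal_model_grid: SpectrumGrid, truth_labels: LabelMap,
                      drug_mz: float, tol_ppm: float = 10.0) -> RCFTable:
    """Per-tissue relative drug response from the equal-concentration model."""
    img = extract_ion_image(equal_model_grid, drug_mz, tol_ppm=tol_ppm)
    tissue = truth_labels.labels > 0
    pooled = img.values[tissue]
    if pooled.size == 0:
        raise ValueError("no labeled spot pixels in equal-concentration model")
    grand = float(pooled.mean())
    rcf, counts = {}, {}
    for lab, name in sorted(truth_labels.names.items()):
        sel = img.values[truth_labels.labels == lab]
        if sel.size == 0 or sel.mean() == 0:
            raise ValueError(f"tissue {name!r} has zero mean drug intensity")
        rcf[name] = float(sel.mean() / grand)
        counts[name] = int(sel.size)
    return RCFTable(rcf=rcf, pixel_counts=counts)


@dataclass
class SplitAssignment:
    """Train/validation/test partition of pixel rows."""

    labels: np.ndarray  # int codes TRAIN/VALIDATION/TEST per row
    ratios: tuple[float, float, float]
    seed: int

    @property
    def train(self) -> np.ndarray:
        return self.labels == TRAIN

    @property
    def validation(self) -> np.ndarray:
        return self.labels == VALIDATION

    @property
    def test(self) -> np.ndarray:
        return self.labels == TEST


def split_pixels(n: int, ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
                 seed: int = 42) -> SplitAssignment:
    """Seeded uniform 70/15/15 split; floor counts, remainder train-first."""
    if n < 0:
        raise ValueError("n must be non-negative")
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios) or abs(sum(ratios) - 1) > 1e-9:
        raise ValueError(f"ratios must be 3 positive values summing to 1, got {ratios}")
    counts = [int(np.floor(n * r)) for r in ratios]
    remainder = n - sum(counts)
    for i in range(remainder):  # train-first, then validation, then test
        counts[i % 3] += 1
    perm = np.random.default_rng(seed).permutation(n)
    labels = np.empty(n, dtype=np.int8)
    labels[perm[:counts[0]]] = TRAIN
    labels[perm[counts[0]:counts[0] + counts[1]]] = VALIDATION
    labels[perm[counts[0] + counts[1]:]] = TEST
    return SplitAssignment(labels=labels, ratios=ratios, seed=seed)


@dataclass
class TrainConfig:
    hidden_units: int = 10
    max_iter: int = 1000        # total function-evaluation budget
    evals_per_check: int = 25   # LM evaluations between validation checks
    patience: int = 6           # validation checks without improvement
    clip: tuple[float, float] = (0.05, 20.0)
    seed: int = 42


@dataclass
class RegressionModel:
    """Single-hidden-layer tanh net with linear output, standardized inputs."""

    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    feature_mzs: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    clip: tuple[float, float] = (0.05, 20.0)
    config: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.W1.shape[0]

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {X.shape[1] if X.ndim == 2 else X.shape} != "
                f"model width {self.n_features}")
        Z = (X - self.x_mean) / self.x_std
        return np.tanh(Z @ self.W1 + self.b1) @ self.w2 + self.b2

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self.predict_raw(X), *self.clip)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2,
            "feature_mzs": self.feature_mzs.tolist(),
            "x_mean": self.x_mean.tolist(), "x_std": self.x_std.tolist(),
            "clip": list(self.clip), "config": self.config,
            "metrics": self.metrics,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegressionModel":
        d = json.loads(Path(path).read_text())
        return cls(W1=np.array(d["W1"]), b1=np.array(d["b1"]),
                   w2=np.array(d["w2"]), b2=float(d["b2"]),
                   feature_mzs=np.array(d["feature_mzs"]),
                   x_mean=np.array(d["x_mean"]), x_std=np.array(d["x_std"]),
                   clip=tuple(d["clip"]), config=d["config"], metrics=d["metrics"])


def _unpack(theta: np.ndarray, F: int, H: int):
    W1 = theta[:F * H].reshape(F, H)
    b1 = theta[F * H:F * H + H]
    w2 = theta[F * H + H:F * H + 2 * H]
    b2 = theta[-1]
    return W1, b1, w2, b2


def _residuals(theta: np.ndarray, Z: np.ndarray, y: np.ndarray, H: int) -> np.ndarray:
    W1, b1, w2, b2 = _unpack(theta, Z.shape[1], H)
    return np.tanh(Z @ W1 + b1) @ w2 + b2 - y


def _jacobian(theta: np.ndarray, Z: np.ndarray, y: np.ndarray, H: int) -> np.ndarray:
    n, F = Z.shape
    W1, b1, w2, _ = _unpack(theta, F, H)
    Hid = np.tanh(Z @ W1 + b1)          # n x H
    G = (1.0 - Hid * Hid) * w2          # n x H, d pred / d (pre-activation)
    J = np.empty((n, theta.size))
    J[:, :F * H] = (Z[:, :, None] * G[:, None, :]).reshape(n, F * H)
    J[:, F * H:F * H + H] = G
    J[:, F * H + H:F * H + 2 * H] = Hid
    J[:, -1] = 1.0
    return J


def _mse(theta, Z, y, H) -> float:
    r = _residuals(theta, Z, y, H)
    return float(np.mean(r * r))


def train_rcf_model(features: FeatureTable, rcf_targets: np.ndarray,
                    split: SplitAssignment,
                    config: TrainConfig | None = None) -> RegressionModel:
    """Fit the RCF regression with staged Levenberg–Marquardt training.

    Training runs in stages of ``evals_per_check`` LM evaluations; after each
    stage the validation MSE is evaluated and the best parameters kept.
    Training stops when the validation MSE has not improved for ``patience``
    consecutive checks, the optimizer converges, or the evaluation budget is
    exhausted.
    """
    config = config or TrainConfig()
    X = np.asarray(features.matrix, dtype=float)
    y = np.asarray(rcf_targets, dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("non-finite values in feature matrix")
    if X.shape[0] != y.size:
        raise ValueError("features and targets are not row-aligned")
    if np.any(y <= 0):
        raise ValueError("RCF targets must be positive")
    if not split.train.any():
        raise ValueError("train partition is empty")

    x_mean = X[split.train].mean(axis=0)
    x_std = X[split.train].std(axis=0)
    x_std = np.where(x_std == 0, 1.0, x_std)
    Z = (X - x_mean) / x_std
    F, H = X.shape[1], config.hidden_units

    y_tr = y[split.train]
    if np.ptp(y_tr) == 0:
        warnings.warn("constant RCF target; returning a constant model",
                      stacklevel=2)
        return RegressionModel(W1=np.zeros((F, H)), b1=np.zeros(H),
                               w2=np.zeros(H), b2=float(y_tr[0]),
                               feature_mzs=features.feature_mzs.copy(),
                               x_mean=x_mean, x_std=x_std, clip=config.clip,
                               config=vars(config).copy(),
                               metrics={"constant_target": True})

    rng = np.random.default_rng(config.seed)
    theta = np.concatenate([
        rng.normal(0.0, 1.0 / np.sqrt(F), F * H),
        np.zeros(H),
        rng.normal(0.0, 1.0 / np.sqrt(H), H),
        [float(y_tr.mean())],
    ])

    Z_tr = Z[split.train]
    Z_val = Z[split.validation]
    y_val = y[split.validation]
    has_val = y_val.size > 0
    method = "lm" if Z_tr.shape[0] >= theta.size else "trf"

    best_theta = theta.copy()
    best_val = _mse(theta, Z_val, y_val, H) if has_val else np.inf
    bad_checks = 0
    evals_used = 0
    n_checks = max(1, config.max_iter // config.evals_per_check)
    for _ in range(n_checks):
        res = least_squares(_residuals, theta, jac=_jacobian,
                            args=(Z_tr, y_tr, H), method=method,
                            max_nfev=config.evals_per_check)
        theta = res.x
        evals_used += res.nfev
        if has_val:
            val = _mse(theta, Z_val, y_val, H)
            if val < best_val - 1e-12:
                best_val, best_theta, bad_checks = val, theta.copy(), 0
            else:
                bad_checks += 1
                if bad_checks >= config.patience:
                    break
        else:
            best_theta = theta.copy()
        if res.status != 0 and res.nfev < config.evals_per_check:
            break  # optimizer converged before exhausting the stage budget
    theta = best_theta if has_val else theta

    W1, b1, w2, b2 = _unpack(theta, F, H)
    model = RegressionModel(W1=W1, b1=b1, w2=w2, b2=float(b2),
                            feature_mzs=features.feature_mzs.copy(),
                            x_mean=x_mean, x_std=x_std, clip=config.clip,
                            config=vars(config).copy())

    def _r2(mask: np.ndarray) -> float:
        if not mask.any() or np.ptp(y[mask]) == 0:
            return float("nan")
        pred = model.predict_raw(X[mask])
        ss_res = float(np.sum((pred - y[mask]) ** 2))
        ss_tot = float(np.sum((y[mask] - y[mask].mean()) ** 2))
        return 1.0 - ss_res / ss_tot

    model.metrics = {
        "train_mse": _mse(theta, Z_tr, y_tr, H),
        "validation_mse": _mse(theta, Z_val, y_val, H) if has_val else float("nan"),
        "test_mse": _mse(theta, Z[split.test], y[split.test], H)
        if split.test.any() else float("nan"),
        "train_r2": _r2(split.train),
        "validation_r2": _r2(split.validation),
        "test_r2": _r2(split.test),
        "function_evals": int(evals_used),
        "optimizer": f"levenberg-marquardt ({method})",
    }
    return model


def predict_rcf(model: RegressionModel, features) -> np.ndarray:
    """Clipped per-pixel RCF predictions for a FeatureTable (or raw matrix)."""
    X = features.matrix if isinstance(features, FeatureTable) else np.asarray(features)
    return model.predict(X)


def rcf_image(shape: tuple[int, int], features: FeatureTable,
              predictions: np.ndarray) -> np.ndarray:
    """Paint per-pixel RCF predictions onto the grid; background pixels 0."""
    out = np.zeros(shape)
    out[features.pixel_index[:, 0], features.pixel_index[:, 1]] = predictions
    return out
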