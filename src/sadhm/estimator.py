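"""Zernike-coefficient regression from diffraction triplets.

The regressor maps a 3-channel diffraction image (Fourier / focal / defocus
intensity) to the ten Zernike coefficients of the illumination aberration.
It follows the scikit-learn estimator protocol (``fit``/``predict``/
``get_params``) and trains an in-package residual CNN (:mod:`sadhm.nn`) with
Adam on a per-coefficient-scaled mean-squared error:

    loss = mean_n mean_k ((pred_k - true_k) / divisor_k)^2

The divisors (by default the per-coefficient max |label| of the training
set, i.e. the sampling half-ranges up to sampling noise) stop the carrier
terms c1, c2 — hundreds of radians — from dominating the unscaled loss by a
factor of several hundred.

Because every channel is min-max normalised intensity, the input carries no
trace of the piston term c0: a global phase offset leaves all three
intensities unchanged.  c0 is therefore unlearnable by construction and its
validation error stays at the level of a constant-zero predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field as _dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .dataset_gen import load_dataset
from .zernike import N_TERMS, ZernikeCoefficients


@dataclass
class TrainingHistory:
    """Per-epoch losses (scaled units); entry 0 of the validation trace is the
    pre-training (epoch-0) state."""

    train_loss: list = _dc_field(default_factory=list)
    val_loss: list = _dc_field(default_factory=list)
    val_mse_per_coeff: list = _dc_field(default_factory=list)  # rows: epochs+1 x 10

    def to_frame(self) -> pd.DataFrame:
        rows = len(self.val_mse_per_coeff)
        df = pd.DataFrame(np.asarray(self.val_mse_per_coeff),
                          columns=[f"val_mse_c{n}" for n in range(N_TERMS)])
        df.insert(0, "epoch", range(rows))
        df.insert(1, "train_loss", [np.nan] + list(self.train_loss))
        df.insert(2, "val_loss", self.val_loss)
        return df


@dataclass(frozen=True)
class EstimatorConfig:
    """Training configuration (defaults follow the full-scale study)."""

    architecture: str = "resnet-small"
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    lr_decay_milestones: tuple = (0.6, 0.85)  # fractions of total epochs
    lr_decay_factor: float = 0.3
    loss: str = "mse"
    input_size: int = 56
    head: str = "gap"
    target_divisors: tuple | None = None
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "mse":
            raise ValueError("only the mse loss is supported")
        if self.target_divisors is not None and np.any(np.asarray(self.target_divisors) <= 0):
            raise ValueError("divisors must be positive")


class ZernikeRegressor(BaseEstimator, RegressorMixin):
    """Residual-CNN regressor for the ten Zernike coefficients.

    Parameters
    ----------
    architecture : {"resnet-small", "resnet50"}
        ``resnet-small`` (three residual stages, default) trains on one CPU;
        ``resnet50`` is the bottleneck [3,4,6,3] topology for full-scale runs.
    epochs, batch_size, learning_rate, lr_decay_milestones, lr_decay_factor
        Adam schedule; the rate is multiplied by ``lr_decay_factor`` at the
        given fractions of the epoch budget.
    input_size : int
        Images are average-pooled to this side length before the network
        (224 inputs are pooled 4x to 56 by default).
    target_divisors : array-like of 10 or None
        Per-coefficient scaling; ``None`` uses max |y| per column.
    validation_fraction : float
        Held-out fraction used for the per-epoch validation trace.
    random_state : int
        Seeds initialisation and batch shuffling; runs are deterministic on
        a single-threaded CPU.

    Attributes
    ----------
    network_ : trained :class:`sadhm.nn.Sequential`
    divisors_ : ndarray (10,)
    history_ : :class:`TrainingHistory`
    """

    def __init__(self, architecture: str = "resnet-small", epochs: int = 30,
                 batch_size: int = 32, learning_rate: float = 1e-3,
                 lr_decay_milestones: tuple = (0.6, 0.85),
                 lr_decay_factor: float = 0.3, input_size: int = 56,
                 head: str = "gap", target_divisors=None,
                 validation_fraction: float = 0.1,
                 random_state: int = 0, verbose: bool = False):
        self.architecture = architecture
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_decay_milestones = lr_decay_milestones
        self.lr_decay_factor = lr_decay_factor
        self.input_size = input_size
        self.head = head
        self.target_divisors = target_divisors
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # --- helpers ----------------------------------------------------------
    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must be (n, H, W, 3) diffraction triplets")
        n, H, W, _ = X.shape
        s = self.input_size
        if H != s:
            if H % s:
                raise ValueError(f"image side {H} is not a multiple of input_size {s}")
            b = H // s
            X = X.reshape(n, s, b, s, b, 3).mean(axis=(2, 4))
        return np.ascontiguousarray(X.transpose(0, 3, 1, 2))

    def _build(self, rng: np.random.Generator) -> nn.Sequential:
        if self.architecture == "resnet-small":
            return nn.build_resnet_small(rng, out_dim=N_TERMS,
                                         input_size=self.input_size,
                                         head=self.head)
        if self.architecture == "resnet50":
            return nn.build_resnet50(rng, out_dim=N_TERMS)
        raise ValueError(f"unknown architecture {self.architecture!r}")

    def _forward_batched(self, X: np.ndarray, batch: int = 64) -> np.ndarray:
        out = [self.network_.forward(X[i:i + batch], train=False)
               for i in range(0, len(X), batch)]
        return np.concatenate(out, axis=0)

    # --- sklearn API ------------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y, dtype=np.float64)
        if y.ndim != 2 or y.shape[1] != N_TERMS:
            raise ValueError(f"y must be (n, {N_TERMS})")
        X = self._prepare(X)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(X) == 0:
            raise ValueError("empty dataset")

        rng = np.random.default_rng(self.random_state)
        if self.target_divisors is not None:
            div = np.asarray(self.target_divisors, dtype=np.float64)
        else:
            div = np.maximum(np.abs(y).max(axis=0), 1e-6)
        ys = (y / div).astype(np.float32)

        # deterministic shuffled split
        order = rng.permutation(len(X))
        n_val = max(1, int(round(self.validation_fraction * len(X)))) \
            if self.validation_fraction > 0 else 0
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(train_idx) == 0:
            raise ValueError("no training samples left after validation split")
        Xtr, ytr = X[train_idx], ys[train_idx]
        Xval, yval = X[val_idx], ys[val_idx]

        self.network_ = self._build(rng)
        self.divisors_ = div
        self.train_indices_, self.val_indices_ = train_idx, val_idx
        opt = nn.Adam(self.network_.params(), lr=self.learning_rate)
        milestones = {int(round(m * self.epochs)) for m in self.lr_decay_milestones}
        history = TrainingHistory()

        def val_stats():
            if n_val == 0:
                return np.nan, np.full(N_TERMS, np.nan)
            pred = self._forward_batched(Xval)
            per = ((pred - yval) ** 2).mean(axis=0)
            return float(per.mean()), per

        loss0, per0 = val_stats()
        history.val_loss.append(loss0)
        history.val_mse_per_coeff.append(per0)

        B = self.batch_size
        for epoch in range(self.epochs):
            if epoch in milestones:
                opt.lr *= self.lr_decay_factor
            perm = rng.permutation(len(Xtr))
            losses = []
            for start in range(0, len(Xtr), B):
                idx = perm[start:start + B]
                xb, yb = Xtr[idx], ytr[idx]
                opt.zero_grad()
                pred = self.network_.forward(xb, train=True)
                err = pred - yb
                losses.append(float((err**2).mean()))
                self.network_.backward((2.0 / err.size) * err.astype(np.float32))
                opt.step()
            vloss, vper = val_stats()
            history.train_loss.append(float(np.mean(losses)))
            history.val_loss.append(vloss)
            history.val_mse_per_coeff.append(vper)
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs}  "
                      f"train {history.train_loss[-1]:.4f}  val {vloss:.4f}")
        self.history_ = history
        self.n_features_in_ = X.shape[1] * X.shape[2] * X.shape[3]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = self._prepare(X)
        pred = self._forward_batched(X).astype(np.float64)
        return pred * self.divisors_

    def predict_coefficients(self, triplet) -> ZernikeCoefficients:
        """Predict for a single :class:`DiffractionTriplet` (or raw image)."""
        image = getattr(triplet, "image", triplet)
        return ZernikeCoefficients(self.predict(image[None])[0])

    # --- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write a self-contained model artifact (descriptor + weights)."""
        check_is_fitted(self, "network_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        desc = {"params": self.get_params(), "divisors": self.divisors_.tolist()}
        (directory / "model.json").write_text(json.dumps(desc, indent=2, default=list))
        np.savez(directory / "weights.npz", **nn.state_dict(self.network_))
        self.history_.to_frame().to_csv(directory / "history.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "ZernikeRegressor":
        directory = Path(directory)
        desc = json.loads((directory / "model.json").read_text())
        params = desc["params"]
        for key in ("lr_decay_milestones", "target_divisors"):
            if isinstance(params.get(key), list):
                params[key] = tuple(params[key])
        est = cls(**params)
        est.divisors_ = np.asarray(desc["divisors"])
        est.network_ = est._build(np.random.default_rng(0))
        with np.load(directory / "weights.npz") as state:
            nn.load_state_dict(est.network_, dict(state))
        est.history_ = TrainingHistory()
        return est


# ---------------------------------------------------------------------------
# manifest-level wrappers
# ---------------------------------------------------------------------------


def train(dataset_manifest: str | Path, config: EstimatorConfig,
          split: float = 0.8, out_dir: str | Path | None = None,
          verbose: bool = False) -> tuple[ZernikeRegressor, TrainingHistory]:
    """Train on an on-disk dataset; optionally write the model artifact."""
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    X, y, _, _ = load_dataset(dataset_manifest)
    if len(X) == 0:
        raise ValueError("empty dataset")
    est = ZernikeRegressor(
        architecture=config.architecture, epochs=config.epochs,
        batch_size=config.batch_size, learning_rate=config.learning_rate,
        lr_decay_milestones=tuple(config.lr_decay_milestones),
        lr_decay_factor=config.lr_decay_factor, input_size=config.input_size,
        head=config.head, target_divisors=config.target_divisors,
        validation_fraction=1.0 - split, random_state=config.seed,
        verbose=verbose,
    )
    est.fit(X, y)
    if out_dir is not None:
        est.save(out_dir)
        (Path(out_dir) / "config.json").write_text(json.dumps(asdict(config), indent=2))
    return est, est.history_


def evaluate(model: ZernikeRegressor | str | Path,
             test_manifest: str | Path,
             out_csv: str | Path | None = None) -> pd.DataFrame:
    """Per-coefficient error table on a labelled test set.

    Columns: sample_id, n, true, predicted, abs_err, rel_err (relative to the
    true value; NaN where the true value is 0).
    """
    if not isinstance(model, ZernikeRegressor):
        model = ZernikeRegressor.load(model)
    X, y, _, _ = load_dataset(test_manifest)
    pred = model.predict(X)
    rows = []
    for i in range(len(y)):
        for n in range(N_TERMS):
            t, p = y[i, n], pred[i, n]
            rows.append({
                "sample_id": i, "n": n, "true": t, "predicted": p,
                "abs_err": abs(p - t),
                "rel_err": abs(p - t) / abs(t) if t != 0 else np.nan,
            })
    table = pd.DataFrame(rows)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
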