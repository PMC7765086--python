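"""Regression models for polymer Tg prediction.

The central object is :class:`TgModel`, built from a dataset (or a
pre-encoded design matrix) in the style of statsmodels: construct, call
:meth:`TgModel.fit`, and receive a :class:`TgResults` carrying the
fitted estimator, the input scaler, diagnostics and a ``summary()``
table. Three estimator kinds share one contract:

``dnn``
    The deep feed-forward network (ReLU, dropout, Adam, cosine-annealed
    learning rate) — the primary model.
``svm``
    Radial-kernel support-vector regression (baseline).
``lasso``
    L1-penalised linear regression, penalty chosen by inner
    cross-validation unless given (baseline).

All kinds z-score the three numeric slots (composition, MW, PDI) using
statistics of the training rows only; fingerprint bits pass through
unchanged. The target is standardised internally and predictions are
returned on the original scale. MW spans two orders of magnitude in
typical compilations and would otherwise dominate gradients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .data import PolymerDataset
from .featurize import NUMERIC_SLOTS, PolymerSample, encode_many
from .nn import MLPRegressorNet

ALL_SLOTS: Tuple[str, ...] = NUMERIC_SLOTS


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are the optimum found by the Bayesian hyperparameter
    search: 128-bit fingerprints, 7 hidden layers of 512 neurons,
    dropout 0.2, 500 epochs of Adam (minibatch 32) under a
    cosine-annealed learning rate starting at 2e-3 — the rate at which
    the fixed epoch budget reaches training-set convergence.
    """

    n_bits: int = 128
    radius: int = 2
    fp_family: str = "morgan"
    hidden_layers: int = 7
    width: int = 512
    dropout_rate: float = 0.2
    epochs: int = 500
    optimizer: str = "adam"
    lr_schedule: str = "cosine"
    initial_lr: float = 2e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.width < 1 or self.hidden_layers < 1:
            raise ValueError("width and hidden_layers must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, seed=seed)

    @property
    def input_dim(self) -> int:
        return 2 * self.n_bits + len(ALL_SLOTS)


@dataclass
class FittedScaler:
    """Per-slot z-score parameters learned from training rows.

    A zero-variance slot gets scale 1 (with a warning) so constant
    columns pass through centred but unstretched.
    """

    slots: Tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray

    def transform_numeric(self, numeric: np.ndarray) -> np.ndarray:
        return (numeric - self.center) / self.scale

    def to_dict(self) -> dict:
        return {
            "slots": list(self.slots),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedScaler":
        return cls(
            slots=tuple(d["slots"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
        )


def fit_scaler(numeric: np.ndarray, slots: Sequence[str] = ALL_SLOTS) -> FittedScaler:
    """Fit z-score parameters for the numeric slots (training rows only)."""
    numeric = np.atleast_2d(np.asarray(numeric, dtype=float))
    if numeric.shape[0] == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    if numeric.shape[1] != len(slots):
        raise ValueError(f"expected {len(slots)} numeric columns, got {numeric.shape[1]}")
    center = numeric.mean(axis=0)
    scale = numeric.std(axis=0)
    for j, s in enumerate(scale):
        if s == 0.0:
            warnings.warn(
                f"numeric slot {slots[j]!r} has zero variance; scale set to 1",
                stacklevel=2,
            )
            scale[j] = 1.0
    return FittedScaler(slots=tuple(slots), center=center, scale=scale)


def _mask_columns(n_bits: int, feature_mask: Sequence[str]) -> np.ndarray:
    """Column indices of the full 2N+3 layout kept under a feature mask."""
    cols = list(range(2 * n_bits))
    for j, slot in enumerate(ALL_SLOTS):
        if slot in feature_mask:
            cols.append(2 * n_bits + j)
    return np.array(cols, dtype=int)


class TgModel:
    """A Tg regression model bound to data, in the statsmodels mould.

    Parameters
    ----------
    endog : array
        Measured Tg values.
    exog : array, shape (n, 2*n_bits + 3)
        Feature vectors in the full ``[fp_A | fp_B | frac_a | mw | pdi]``
        layout (use :meth:`from_dataset` to build both from records).
    config : ModelConfig
    kind : {"dnn", "svm", "lasso"}
    feature_mask : sequence of slot names
        Active numeric slots; dropping a slot removes its input node
        entirely (used by the ablation experiments).
    params : dict, optional
        Estimator-specific hyperparameters (e.g. ``{"C": 10.0}`` for
        svm, ``{"alpha": 0.01}`` for lasso).
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        config: Optional[ModelConfig] = None,
        kind: str = "dnn",
        feature_mask: Sequence[str] = ALL_SLOTS,
        params: Optional[dict] = None,
    ) -> None:
        if kind not in ("dnn", "svm", "lasso"):
            raise ValueError(f"unknown model kind {kind!r}")
        bad = [s for s in feature_mask if s not in ALL_SLOTS]
        if bad:
            raise ValueError(f"unknown feature slot(s) {bad}; choose from {ALL_SLOTS}")
        self.config = config or ModelConfig()
        self.kind = kind
        self.feature_mask = tuple(s for s in ALL_SLOTS if s in feature_mask)
        self.params = dict(params or {})
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError(
                f"exog {self.exog.shape} and endog {self.endog.shape} are inconsistent"
            )
        if self.exog.shape[1] != self.config.input_dim:
            raise ValueError(
                f"exog has {self.exog.shape[1]} columns; expected "
                f"{self.config.input_dim} (= 2*{self.config.n_bits}+3)"
            )
        if not (np.isfinite(self.exog).all() and np.isfinite(self.endog).all()):
            raise ValueError("non-finite values in model data")

    @classmethod
    def from_dataset(
        cls,
        ds: PolymerDataset,
        config: Optional[ModelConfig] = None,
        kind: str = "dnn",
        feature_mask: Sequence[str] = ALL_SLOTS,
        params: Optional[dict] = None,
    ) -> "TgModel":
        config = config or ModelConfig()
        y = ds.tg
        if np.isnan(y).any():
            raise ValueError("all samples must carry a measured tg to fit a model")
        X = encode_many(ds.samples, config.n_bits, config.radius, config.fp_family)
        return cls(y, X, config=config, kind=kind, feature_mask=feature_mask, params=params)

    # ------------------------------------------------------------------ fit

    def fit(self, seed: Optional[int] = None) -> "TgResults":
        """Train the estimator; fully deterministic given the seed."""
        cfg = self.config if seed is None else self.config.with_seed(seed)
        n_bits = cfg.n_bits
        cols = _mask_columns(n_bits, self.feature_mask)
        X = self.exog[:, cols]
        y = self.endog
        n_numeric = len(self.feature_mask)
        if n_numeric:
            scaler = fit_scaler(X[:, -n_numeric:] if n_numeric else X[:, :0],
                                self.feature_mask)
            Xs = X.copy()
            Xs[:, -n_numeric:] = scaler.transform_numeric(X[:, -n_numeric:])
        else:
            scaler = FittedScaler(slots=(), center=np.zeros(0), scale=np.ones(0))
            Xs = X
        y_center = float(np.mean(y))
        y_scale = float(np.std(y)) or 1.0
        ys = (y - y_center) / y_scale

        if self.kind == "dnn":
            est = MLPRegressorNet(
                input_dim=Xs.shape[1],
                hidden_layers=cfg.hidden_layers,
                width=cfg.width,
                dropout_rate=cfg.dropout_rate,
                seed=cfg.seed,
            ).fit(
                Xs,
                ys,
                epochs=cfg.epochs,
                initial_lr=cfg.initial_lr,
                batch_size=cfg.batch_size,
                lr_schedule=cfg.lr_schedule,
            )
        elif self.kind == "svm":
            from sklearn.svm import SVR

            p = {"kernel": "rbf", "C": 10.0, "gamma": "scale", "epsilon": 0.1}
            p.update(self.params)
            est = SVR(**p).fit(Xs, ys)
        else:  # lasso
            est = self._fit_lasso(Xs, ys, cfg.seed)
        return TgResults(
            model=self,
            config=cfg,
            scaler=scaler,
            estimator=est,
            y_center=y_center,
            y_scale=y_scale,
        )

    def _fit_lasso(self, Xs: np.ndarray, ys: np.ndarray, seed: int):
        from sklearn.dummy import DummyRegressor
        from sklearn.linear_model import Lasso, LassoCV, LinearRegression

        alpha = self.params.get("alpha")
        if alpha is None:
            return LassoCV(cv=min(5, len(ys)), random_state=seed, max_iter=50_000).fit(
                Xs, ys
            )
        if np.isinf(alpha):
            return DummyRegressor(strategy="mean").fit(Xs, ys)
        if alpha == 0.0:
            return LinearRegression().fit(Xs, ys)
        return Lasso(alpha=alpha, max_iter=50_000).fit(Xs, ys)


@dataclass
class TgResults:
    """Fit results: estimator, scaler, and prediction/diagnostic methods."""

    model: TgModel
    config: ModelConfig
    scaler: FittedScaler
    estimator: object
    y_center: float
    y_scale: float

    # -------------------------------------------------------------- predict

    def predict(self, exog: np.ndarray) -> np.ndarray:
        """Predict Tg for rows in the full 2N+3 layout.

        Inference has no stochastic path (dropout disabled), so repeated
        calls on the same input give identical outputs.
        """
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        expected = self.config.input_dim
        if exog.shape[1] != expected:
            raise ValueError(
                f"feature width mismatch: expected {expected}, got {exog.shape[1]}"
            )
        cols = _mask_columns(self.config.n_bits, self.model.feature_mask)
        X = exog[:, cols]
        n_numeric = len(self.model.feature_mask)
        if n_numeric:
            X = X.copy()
            X[:, -n_numeric:] = self.scaler.transform_numeric(X[:, -n_numeric:])
        raw = np.asarray(self.estimator.predict(X), dtype=float).ravel()
        return raw * self.y_scale + self.y_center

    def predict_samples(self, samples: Sequence[PolymerSample]) -> np.ndarray:
        cfg = self.config
        X = encode_many(samples, cfg.n_bits, cfg.radius, cfg.fp_family)
        return self.predict(X)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    # ----------------------------------------------------------- parameters

    @property
    def params(self) -> np.ndarray:
        """Linear coefficients on the original feature scale (linear kinds).

        Index order follows the masked layout ``[bits..., active slots]``;
        the final entry is the intercept.
        """
        coef = getattr(self.estimator, "coef_", None)
        if coef is None:
            raise AttributeError(f"{self.model.kind!r} estimator has no linear params")
        coef = np.asarray(coef, dtype=float).ravel()
        intercept = float(np.atleast_1d(self.estimator.intercept_)[0])
        n_numeric = len(self.model.feature_mask)
        scale = np.ones_like(coef)
        center = np.zeros_like(coef)
        if n_numeric:
            scale[-n_numeric:] = self.scaler.scale
            center[-n_numeric:] = self.scaler.center
        coef_orig = coef * self.y_scale / scale
        intercept_orig = (
            intercept * self.y_scale + self.y_center - float(np.sum(coef_orig * center))
        )
        return np.append(coef_orig, intercept_orig)

    @property
    def n_parameters(self) -> int:
        est = self.estimator
        if hasattr(est, "n_parameters"):
            return est.n_parameters
        coef = getattr(est, "coef_", None)
        if coef is not None:
            return int(np.asarray(coef).size) + 1
        return -1

    # -------------------------------------------------------------- summary

    def summary(self) -> str:
        from . import evaluation as ev

        y, yh = self.model.endog, self.fittedvalues
        lines = [
            "Tg regression results",
            "=" * 52,
            f"kind:            {self.model.kind}",
            f"n obs:           {len(y)}",
            f"input dim:       {2 * self.config.n_bits + len(self.model.feature_mask)}"
            f"  (2x{self.config.n_bits} bits + {len(self.model.feature_mask)} numeric)",
            f"feature mask:    {', '.join(self.model.feature_mask) or '(bits only)'}",
        ]
        if self.model.kind == "dnn":
            lines += [
                f"architecture:    {self.config.hidden_layers} x {self.config.width}"
                f", dropout {self.config.dropout_rate}",
                f"training:        {self.config.epochs} epochs, adam, "
                f"{self.config.lr_schedule} lr from {self.config.initial_lr}",
                f"parameters:      {self.n_parameters}",
            ]
        try:
            lines += [
                "-" * 52,
                f"train R2:        {ev.r2(y, yh):.4f}",
                f"train MAE:       {ev.mae(y, yh):.4f}",
                f"train RMSE:      {ev.rmse(y, yh):.4f}",
            ]
        except ValueError:
            pass
        lines.append("=" * 52)
        return "\n".join(lines)

    # ---------------------------------------------------------- persistence

    def save(self, path_prefix: Union[str, Path]) -> None:
        """Write a self-describing checkpoint: weights + JSON sidecar."""
        prefix = Path(path_prefix)
        sidecar = {
            "kind": self.model.kind,
            "config": asdict(self.config),
            "feature_mask": list(self.model.feature_mask),
            "scaler": self.scaler.to_dict(),
            "y_center": self.y_center,
            "y_scale": self.y_scale,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        if self.model.kind == "dnn":
            np.savez(prefix.with_suffix(".npz"), **self.estimator.state_dict())
        else:
            import joblib

            joblib.dump(self.estimator, prefix.with_suffix(".joblib"))

    @classmethod
    def load(cls, path_prefix: Union[str, Path]) -> "TgResults":
        prefix = Path(path_prefix)
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        config = ModelConfig(**sidecar["config"])
        mask = tuple(sidecar["feature_mask"])
        scaler = FittedScaler.from_dict(sidecar["scaler"])
        # rebind to an empty shell model (no training data retained)
        shell = TgModel.__new__(TgModel)
        shell.config = config
        shell.kind = sidecar["kind"]
        shell.feature_mask = mask
        shell.params = {}
        shell.endog = np.zeros(0)
        shell.exog = np.zeros((0, config.input_dim))
        if sidecar["kind"] == "dnn":
            est = MLPRegressorNet(
                input_dim=2 * config.n_bits + len(mask),
                hidden_layers=config.hidden_layers,
                width=config.width,
                dropout_rate=config.dropout_rate,
                seed=config.seed,
            )
            with np.load(prefix.with_suffix(".npz")) as state:
                est.load_state_dict(dict(state))
        else:
            import joblib

            est = joblib.load(prefix.with_suffix(".joblib"))
        return cls(
            model=shell,
            config=config,
            scaler=scaler,
            estimator=est,
            y_center=sidecar["y_center"],
            y_scale=sidecar["y_scale"],
        )


# ---------------------------------------------------------------- wrappers


def train_dnn(X: np.ndarray, y: np.ndarray, config: Optional[ModelConfig] = None,
              feature_mask: Sequence[str] = ALL_SLOTS) -> TgResults:
    """Train the deep network on a full-layout design matrix."""
    return TgModel(y, X, config=config, kind="dnn", feature_mask=feature_mask).fit()


def train_svm(X: np.ndarray, y: np.ndarray, params: Optional[dict] = None,
              config: Optional[ModelConfig] = None) -> TgResults:
    """Train the support-vector baseline (same scaling contract)."""
    return TgModel(y, X, config=config, kind="svm", params=params).fit()


def train_lasso(X: np.ndarray, y: np.ndarray, params: Optional[dict] = None,
                config: Optional[ModelConfig] = None) -> TgResults:
    """Train the sparse-linear baseline (same scaling contract)."""
    return TgModel(y, X, config=config, kind="lasso", params=params).fit()
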