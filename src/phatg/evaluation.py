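"""Cross-validation harness, metrics, symmetry diagnostics, grouped
feature importance, and the missing-data experiments.

The harness follows one protocol throughout: k nearly equal random
folds, each held out once; the input scaler is fit inside each training
fold; fold metrics (R2, MAE, RMSE) are averaged arithmetically into the
reported score. Symmetry-augmented datasets use pair-aware folds by
default so a record and its mirror image never straddle a train/test
boundary (mirrored duplicates carry the same Tg and would leak labels).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .data import FoldAssignment, PolymerDataset, make_folds
from .featurize import NUMERIC_SLOTS, encode_many, mirror
from .model import ALL_SLOTS, ModelConfig, TgModel, TgResults

__all__ = [
    "r2", "mae", "rmse", "ConstantTargetError",
    "EvalReport", "cross_validate", "symmetry_gap",
    "ImportanceReport", "importance", "bit_level_importance",
    "ablation_experiment", "imputation_experiment", "imputation_cv",
]


class ConstantTargetError(ValueError):
    """R2 is undefined when the observed targets are all equal."""


def _check_pair(y: np.ndarray, y_hat: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size == 0 or y.size != y_hat.size:
        raise ValueError(f"need equal non-zero lengths, got {y.size} and {y_hat.size}")
    return y, y_hat


def r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot (may be < 0)."""
    y, y_hat = _check_pair(y, y_hat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ConstantTargetError("R2 undefined: observed targets are constant")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def mae(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute error, in the Tg unit."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.mean(np.abs(y - y_hat)))


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean square error, in the Tg unit (always >= MAE)."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


@dataclass
class EvalReport:
    """Per-fold and averaged metrics plus per-sample predictions.

    The averaged metric is the arithmetic mean of the fold metrics
    (the protocol's reporting convention), not the pooled metric.
    """

    fold_metrics: List[Dict[str, float]]
    averages: Dict[str, float]
    per_sample: pd.DataFrame
    metadata: Dict[str, object] = field(default_factory=dict)
    fold_results: Optional[List[TgResults]] = field(default=None, repr=False)
    folds: Optional[FoldAssignment] = field(default=None, repr=False)

    @classmethod
    def from_folds(
        cls,
        fold_metrics: List[Dict[str, float]],
        per_sample: pd.DataFrame,
        metadata: Optional[dict] = None,
        fold_results: Optional[List[TgResults]] = None,
        folds: Optional[FoldAssignment] = None,
    ) -> "EvalReport":
        averages = {
            m: float(np.mean([fm[m] for fm in fold_metrics]))
            for m in ("r2", "mae", "rmse")
        }
        return cls(
            fold_metrics=fold_metrics,
            averages=averages,
            per_sample=per_sample,
            metadata=metadata or {},
            fold_results=fold_results,
            folds=folds,
        )

    def summary(self) -> str:
        header = f"{'subgroup':>10} {'R2':>8} {'MAE':>8} {'RMSE':>8}"
        rows = [header, "-" * len(header)]
        for fm in self.fold_metrics:
            rows.append(
                f"{int(fm['fold']) + 1:>10d} {fm['r2']:>8.3f} "
                f"{fm['mae']:>8.3f} {fm['rmse']:>8.3f}"
            )
        a = self.averages
        rows.append(f"{'average':>10} {a['r2']:>8.3f} {a['mae']:>8.3f} {a['rmse']:>8.3f}")
        if self.metadata:
            rows.append(f"  [{', '.join(f'{k}={v}' for k, v in self.metadata.items())}]")
        return "\n".join(rows)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "fold_metrics": self.fold_metrics,
                "averages": self.averages,
                "metadata": {k: str(v) for k, v in self.metadata.items()},
            },
            indent=indent,
        )

    def predictions_to_csv(self, path) -> None:
        self.per_sample.to_csv(path, index=False)

    def plot_predictions(self, ax=None):
        """Scatter of predicted vs. measured Tg, coloured by fold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(
            self.per_sample["y"], self.per_sample["y_hat"],
            c=self.per_sample["fold"], cmap="viridis", s=18, alpha=0.8,
        )
        lims = [self.per_sample["y"].min(), self.per_sample["y"].max()]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel("measured Tg")
        ax.set_ylabel("predicted Tg")
        return ax


ModelKind = Union[str, Callable[..., np.ndarray]]


def cross_validate(
    ds: PolymerDataset,
    config: Optional[ModelConfig] = None,
    folds: Optional[FoldAssignment] = None,
    model_kind: ModelKind = "dnn",
    k: int = 5,
    seed: int = 0,
    pair_aware: Optional[bool] = None,
    feature_mask: Sequence[str] = ALL_SLOTS,
    params: Optional[dict] = None,
    keep_models: bool = False,
    exog: Optional[np.ndarray] = None,
) -> EvalReport:
    """k-fold cross-validation of a model kind over a dataset.

    ``model_kind`` is ``"dnn"``, ``"svm"``, ``"lasso"``, or a callable
    ``f(X_train, y_train, X_test, train_idx, test_idx) -> y_hat`` (used
    for oracle/reference predictors in tests). Encoding is computed once;
    scaling happens inside each training fold. ``pair_aware`` defaults to
    True exactly when the dataset carries mirror pairing.
    """
    config = config or ModelConfig()
    if pair_aware is None:
        pair_aware = ds.mirror_pairing is not None
    if folds is None:
        folds = make_folds(ds, k=k, seed=seed, pair_aware=pair_aware)
    if len(folds.fold_of) != len(ds):
        raise ValueError("fold assignment does not match dataset size")
    y = ds.tg
    if np.isnan(y).any():
        raise ValueError("all samples need a measured tg for cross-validation")
    if exog is None:
        exog = encode_many(ds.samples, config.n_bits, config.radius, config.fp_family)

    fold_metrics: List[Dict[str, float]] = []
    fold_results: List[Optional[TgResults]] = []
    y_hat_all = np.full(len(ds), np.nan)
    for f in range(folds.k):
        train_idx, test_idx = folds.train_test_indices(f)
        if len(test_idx) < 2:
            raise ValueError(f"fold {f} has fewer than 2 test samples")
        if callable(model_kind):
            y_hat = np.asarray(
                model_kind(exog[train_idx], y[train_idx], exog[test_idx],
                           train_idx, test_idx),
                dtype=float,
            ).ravel()
            res = None
        else:
            tm = TgModel(
                y[train_idx], exog[train_idx],
                config=config, kind=model_kind,
                feature_mask=feature_mask, params=params,
            )
            res = tm.fit(seed=config.seed + f)
            y_hat = res.predict(exog[test_idx])
        y_hat_all[test_idx] = y_hat
        fold_metrics.append(
            {
                "fold": float(f),
                "r2": r2(y[test_idx], y_hat),
                "mae": mae(y[test_idx], y_hat),
                "rmse": rmse(y[test_idx], y_hat),
                "n_test": float(len(test_idx)),
            }
        )
        fold_results.append(res)
    per_sample = pd.DataFrame(
        {"y": y, "y_hat": y_hat_all, "fold": folds.fold_of}
    )
    metadata = {
        "model_kind": model_kind if isinstance(model_kind, str) else "callable",
        "k": folds.k,
        "seed": seed,
        "pair_aware": pair_aware,
        "feature_mask": ",".join(feature_mask),
        "n": len(ds),
    }
    return EvalReport.from_folds(
        fold_metrics, per_sample, metadata,
        fold_results=fold_results if keep_models else None,
        folds=folds,
    )


def symmetry_gap(results: TgResults, ds: PolymerDataset) -> float:
    """Mean |prediction(s) - prediction(mirror(s))| over a dataset.

    Zero for a model that is perfectly insensitive to the arbitrary
    A/B monomer labelling; materially positive for a model trained
    without the symmetry augmentation.
    """
    preds = results.predict_samples(ds.samples)
    preds_m = results.predict_samples([mirror(s) for s in ds.samples])
    return float(np.mean(np.abs(preds - preds_m)))


# ------------------------------------------------------------- importance


@dataclass
class ImportanceReport:
    """Mean |Shapley attribution| per input variable group."""

    scores: Dict[str, float]
    metadata: Dict[str, object] = field(default_factory=dict)

    def ranking(self) -> List[str]:
        return sorted(self.scores, key=self.scores.get, reverse=True)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({"scores": self.scores}, indent=indent)

    def plot_bar(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        names = list(self.scores)
        ax.bar(names, [self.scores[n] for n in names])
        ax.set_ylabel("mean |attribution|")
        ax.tick_params(axis="x", rotation=30)
        return ax


def _group_columns(n_bits: int, feature_mask: Sequence[str]) -> Dict[str, np.ndarray]:
    groups = {
        "monomer_a": np.arange(0, n_bits),
        "monomer_b": np.arange(n_bits, 2 * n_bits),
    }
    for j, slot in enumerate(NUMERIC_SLOTS):
        if slot in feature_mask:
            groups[slot] = np.array([2 * n_bits + j])
    return groups


def importance(
    results: TgResults,
    ds: PolymerDataset,
    n_samples: int = 50,
    seed: int = 0,
    n_background: int = 10,
    background: Optional[PolymerDataset] = None,
) -> ImportanceReport:
    """Exact grouped Shapley attribution of the model's predictions.

    Each input variable is one Shapley player: the monomer-A fingerprint
    block, the monomer-B block, and each active numeric slot. With at
    most five players all 2^5 coalitions are enumerated, so the Shapley
    values are exact up to the background average: a feature absent from
    a coalition is replaced by the value from a background record drawn
    from the (training) dataset. The reported score per group is the
    mean |Shapley value| over the evaluated samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cfg = results.config
    rng = np.random.default_rng(seed)
    X = encode_many(ds.samples, cfg.n_bits, cfg.radius, cfg.fp_family)
    bg_ds = background if background is not None else ds
    Xbg = (
        X
        if background is None
        else encode_many(bg_ds.samples, cfg.n_bits, cfg.radius, cfg.fp_family)
    )
    eval_idx = rng.choice(len(X), size=min(n_samples, len(X)), replace=False)
    bg_idx = rng.choice(len(Xbg), size=min(n_background, len(Xbg)), replace=False)

    groups = _group_columns(cfg.n_bits, results.model.feature_mask)
    names = list(groups)
    G = len(names)
    coalitions = list(itertools.product((0, 1), repeat=G))
    coal_index = {c: i for i, c in enumerate(coalitions)}

    # one big batch: for every (eval sample, background, coalition) build the
    # hybrid row and predict in a single call
    n_e, n_b, n_c = len(eval_idx), len(bg_idx), len(coalitions)
    hybrid = np.empty((n_e * n_b * n_c, X.shape[1]), dtype=float)
    row = 0
    for ei in eval_idx:
        for bi in bg_idx:
            base = Xbg[bi]
            for c in coalitions:
                v = base.copy()
                for g, present in enumerate(c):
                    if present:
                        cols = groups[names[g]]
                        v[cols] = X[ei, cols]
                hybrid[row] = v
                row += 1
    preds = results.predict(hybrid).reshape(n_e, n_b, n_c)

    fact = math.factorial
    phi = np.zeros((n_e, G))
    for g in range(G):
        for c in coalitions:
            if c[g] == 1:
                continue
            s = sum(c)
            weight = fact(s) * fact(G - s - 1) / fact(G)
            c_with = tuple(1 if i == g else c[i] for i in range(G))
            delta = preds[:, :, coal_index[c_with]] - preds[:, :, coal_index[c]]
            phi[:, g] += weight * delta.mean(axis=1)
    scores = {names[g]: float(np.mean(np.abs(phi[:, g]))) for g in range(G)}
    return ImportanceReport(
        scores=scores,
        metadata={"n_samples": n_e, "n_background": n_b, "seed": seed, "exact": True},
    )


def bit_level_importance(
    results: TgResults,
    ds: PolymerDataset,
    n_samples: int = 20,
    seed: int = 0,
    n_permutations: int = 10,
) -> ImportanceReport:
    """Alternative aggregation: sum of |bit-level sampled Shapley values|.

    Every input column is a player; Shapley values are estimated by
    permutation sampling against a background of column means, and
    |values| are summed within each variable group. Coarser than
    :func:`importance` but useful as a cross-check of the grouping.
    """
    cfg = results.config
    rng = np.random.default_rng(seed)
    X = encode_many(ds.samples, cfg.n_bits, cfg.radius, cfg.fp_family)
    eval_idx = rng.choice(len(X), size=min(n_samples, len(X)), replace=False)
    base = X.mean(axis=0)
    d = X.shape[1]
    phi = np.zeros((len(eval_idx), d))
    for _ in range(n_permutations):
        order = rng.permutation(d)
        cur = np.tile(base, (len(eval_idx), 1))
        prev = results.predict(cur)
        for col in order:
            cur[:, col] = X[eval_idx, col]
            nxt = results.predict(cur)
            phi[:, col] += nxt - prev
            prev = nxt
    phi /= n_permutations
    groups = _group_columns(cfg.n_bits, results.model.feature_mask)
    scores = {
        name: float(np.mean(np.sum(np.abs(phi[:, cols]), axis=1)))
        for name, cols in groups.items()
    }
    return ImportanceReport(
        scores=scores,
        metadata={"n_samples": len(eval_idx), "n_permutations": n_permutations,
                  "seed": seed, "exact": False},
    )


# ----------------------------------------------------- ablation / imputation

_DROP_ALIASES = {
    "frac_a": ("frac_a",),
    "mw": ("mw",),
    "pdi": ("pdi",),
    "mw+pdi": ("mw", "pdi"),
}


def _normalize_drop(drop: Union[str, Sequence[str]]) -> Tuple[str, ...]:
    if isinstance(drop, str):
        if drop not in _DROP_ALIASES:
            raise ValueError(f"unknown drop spec {drop!r}; one of {list(_DROP_ALIASES)}")
        return _DROP_ALIASES[drop]
    dropped = tuple(drop)
    bad = [s for s in dropped if s not in NUMERIC_SLOTS]
    if bad:
        raise ValueError(
            f"cannot drop {bad}: only the numeric slots {NUMERIC_SLOTS} can be "
            "removed (fingerprint blocks are not removable)"
        )
    return dropped


def ablation_experiment(
    ds: PolymerDataset,
    config: Optional[ModelConfig] = None,
    drop: Union[str, Sequence[str]] = (),
    k: int = 5,
    seed: int = 0,
    model_kind: str = "dnn",
    pair_aware: Optional[bool] = None,
) -> EvalReport:
    """Retrain under the standard CV protocol with input nodes removed.

    ``drop`` names the numeric slots whose input neurons are removed
    (e.g. ``"frac_a"`` or ``"mw+pdi"``); fingerprint blocks cannot be
    dropped. ``drop=()`` reproduces the full-input protocol exactly.
    """
    dropped = _normalize_drop(drop)
    mask = tuple(s for s in ALL_SLOTS if s not in dropped)
    report = cross_validate(
        ds, config=config, k=k, seed=seed,
        model_kind=model_kind, feature_mask=mask, pair_aware=pair_aware,
    )
    report.metadata["dropped"] = ",".join(dropped) or "(none)"
    return report


def impute_columns(
    X: np.ndarray, n_bits: int, slots: Sequence[str], values: Dict[str, float]
) -> np.ndarray:
    """Return a copy of the design matrix with the chosen numeric slots
    replaced by fixed values (on the original, unscaled feature scale)."""
    out = np.array(X, dtype=float, copy=True)
    for slot in slots:
        j = NUMERIC_SLOTS.index(slot)
        out[:, 2 * n_bits + j] = values[slot]
    return out


def _train_statistic(exog: np.ndarray, n_bits: int, slot: str, statistic: str) -> float:
    j = NUMERIC_SLOTS.index(slot)
    col = exog[:, 2 * n_bits + j]
    if col.size == 0:
        raise ValueError("cannot compute an imputation statistic on an empty training set")
    return {"mean": float(np.mean(col)),
            "min": float(np.min(col)),
            "max": float(np.max(col))}[statistic]


def imputation_experiment(
    results: TgResults,
    ds: PolymerDataset,
    features: Union[str, Sequence[str]],
    statistic: str = "mean",
) -> Dict[str, float]:
    """Evaluate an untouched trained model when a feature is 'missing'.

    The chosen slots of every evaluation record are replaced with the
    given statistic (mean / min / max) of the *training* rows the model
    was fitted on; the model is not retrained. Returns the metric triple
    on the imputed inputs.
    """
    if statistic not in ("mean", "min", "max"):
        raise ValueError(f"statistic must be mean/min/max, got {statistic!r}")
    slots = _normalize_drop(features)
    cfg = results.config
    train_exog = results.model.exog
    if train_exog.shape[0] == 0:
        raise ValueError("model carries no training rows to compute statistics from")
    values = {s: _train_statistic(train_exog, cfg.n_bits, s, statistic) for s in slots}
    X = encode_many(ds.samples, cfg.n_bits, cfg.radius, cfg.fp_family)
    Xi = impute_columns(X, cfg.n_bits, slots, values)
    y = ds.tg
    y_hat = results.predict(Xi)
    return {"r2": r2(y, y_hat), "mae": mae(y, y_hat), "rmse": rmse(y, y_hat)}


def imputation_cv(
    cv_report: EvalReport,
    ds: PolymerDataset,
    config: ModelConfig,
    features: Union[str, Sequence[str]],
    statistic: str = "mean",
) -> EvalReport:
    """Missing-data evaluation under the CV protocol, without retraining.

    Takes a cross-validation report run with ``keep_models=True``; for
    each fold, the imputation statistic is computed from that fold's
    training rows only, the held-out rows get their slots replaced, and
    the fold's already-trained model is re-evaluated.
    """
    if cv_report.fold_results is None or cv_report.folds is None:
        raise ValueError("cv_report must come from cross_validate(keep_models=True)")
    if statistic not in ("mean", "min", "max"):
        raise ValueError(f"statistic must be mean/min/max, got {statistic!r}")
    slots = _normalize_drop(features)
    X = encode_many(ds.samples, config.n_bits, config.radius, config.fp_family)
    y = ds.tg
    folds = cv_report.folds
    fold_metrics: List[Dict[str, float]] = []
    y_hat_all = np.full(len(ds), np.nan)
    for f in range(folds.k):
        train_idx, test_idx = folds.train_test_indices(f)
        values = {
            s: _train_statistic(X[train_idx], config.n_bits, s, statistic)
            for s in slots
        }
        Xi = impute_columns(X[test_idx], config.n_bits, slots, values)
        res = cv_report.fold_results[f]
        y_hat = res.predict(Xi)
        y_hat_all[test_idx] = y_hat
        fold_metrics.append(
            {
                "fold": float(f),
                "r2": r2(y[test_idx], y_hat),
                "mae": mae(y[test_idx], y_hat),
                "rmse": rmse(y[test_idx], y_hat),
                "n_test": float(len(test_idx)),
            }
        )
    per_sample = pd.DataFrame({"y": y, "y_hat": y_hat_all, "fold": folds.fold_of})
    metadata = {"imputed": ",".join(slots), "statistic": statistic}
    return EvalReport.from_folds(fold_metrics, per_sample, metadata)
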