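"""Bayesian optimization of fingerprint length and network shape.

A Gaussian-process surrogate (Matern-5/2 over the normalised
hyperparameter coordinates) models the objective — mean k-fold
cross-validated RMSE — and an expected-improvement acquisition picks
each next trial from a random candidate pool. The first third of the
budget is random exploration to seed the surrogate. Failed trials
(non-finite objective) are logged and excluded from the surrogate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .data import PolymerDataset
from .evaluation import cross_validate
from .model import ModelConfig


@dataclass(frozen=True)
class SearchSpace:
    """Hyperparameter ranges for the network-shape search."""

    n_bits: Tuple[int, ...] = (32, 64, 128, 256)
    hidden_layers: Tuple[int, int] = (1, 10)
    width: Tuple[int, ...] = (64, 128, 256, 512, 1024)
    dropout_rate: Tuple[float, float] = (0.0, 0.5)

    def __post_init__(self) -> None:
        for nb in self.n_bits:
            if nb < 8 or nb & (nb - 1):
                raise ValueError(f"n_bits candidates must be powers of two >= 8: {nb}")
        lo, hi = self.hidden_layers
        if lo < 1 or hi < lo:
            raise ValueError("hidden_layers range must satisfy 1 <= lo <= hi")
        dlo, dhi = self.dropout_rate
        if not (0.0 <= dlo <= dhi < 1.0):
            raise ValueError("dropout_rate range must lie in [0, 1)")

    def sample(self, rng: np.random.Generator) -> dict:
        return {
            "n_bits": int(rng.choice(self.n_bits)),
            "hidden_layers": int(rng.integers(self.hidden_layers[0],
                                              self.hidden_layers[1] + 1)),
            "width": int(rng.choice(self.width)),
            "dropout_rate": float(rng.uniform(*self.dropout_rate)),
        }

    def contains(self, point: dict) -> bool:
        return (
            point["n_bits"] in self.n_bits
            and self.hidden_layers[0] <= point["hidden_layers"] <= self.hidden_layers[1]
            and point["width"] in self.width
            and self.dropout_rate[0] <= point["dropout_rate"] <= self.dropout_rate[1]
        )

    def n_distinct(self) -> int:
        lo, hi = self.hidden_layers
        discrete = len(set(self.n_bits)) * (hi - lo + 1) * len(set(self.width))
        return discrete if self.dropout_rate[0] == self.dropout_rate[1] else -1

    def to_unit(self, point: dict) -> np.ndarray:
        """Map a point to [0,1]^4 coordinates for the GP surrogate."""
        def cat(value, choices):
            choices = sorted(set(choices))
            if len(choices) == 1:
                return 0.0
            return choices.index(value) / (len(choices) - 1)

        lo, hi = self.hidden_layers
        dlo, dhi = self.dropout_rate
        return np.array(
            [
                cat(point["n_bits"], self.n_bits),
                0.0 if hi == lo else (point["hidden_layers"] - lo) / (hi - lo),
                cat(point["width"], self.width),
                0.0 if dhi == dlo else (point["dropout_rate"] - dlo) / (dhi - dlo),
            ]
        )


@dataclass
class TrialRecord:
    """One evaluated hyperparameter point."""

    trial: int
    point: dict
    objective: float  # mean CV RMSE; NaN marks a failed trial
    fold_metrics: List[dict] = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["objective"] = None if np.isnan(self.objective) else self.objective
        return json.dumps(d)


def write_trial_log(trials: Sequence[TrialRecord], path) -> None:
    """One trial per line (JSON lines)."""
    Path(path).write_text("\n".join(t.to_json() for t in trials) + "\n")


def _evaluate_point(
    ds: PolymerDataset,
    point: dict,
    base_config: ModelConfig,
    k: int,
    seed: int,
) -> TrialRecord:
    config = replace(base_config, **point, seed=seed)
    try:
        report = cross_validate(ds, config=config, k=k, seed=seed)
        obj = report.averages["rmse"]
        folds = report.fold_metrics
        if not np.isfinite(obj):
            obj, folds = float("nan"), []
    except (ValueError, FloatingPointError):
        obj, folds = float("nan"), []
    return TrialRecord(trial=-1, point=point, objective=float(obj),
                       fold_metrics=folds, seed=seed)


def optimize(
    ds: PolymerDataset,
    space: Optional[SearchSpace] = None,
    n_trials: int = 25,
    seed: int = 0,
    base_config: Optional[ModelConfig] = None,
    k: int = 5,
    n_candidates: int = 128,
) -> Tuple[ModelConfig, List[TrialRecord]]:
    """Search the space for the config minimising mean CV RMSE.

    Returns the best :class:`ModelConfig` (base config with the winning
    point substituted) and the full trial log, which is sufficient to
    replay the best configuration exactly. Duplicate points are not
    re-evaluated; a space collapsed to a single point returns after one
    evaluation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    space = space or SearchSpace()
    base_config = base_config or ModelConfig()
    rng = np.random.default_rng(seed)
    trials: List[TrialRecord] = []
    seen = set()

    def key(p: dict) -> tuple:
        return (p["n_bits"], p["hidden_layers"], p["width"], round(p["dropout_rate"], 12))

    def run(point: dict) -> None:
        rec = _evaluate_point(ds, point, base_config, k, seed + len(trials))
        rec.trial = len(trials)
        trials.append(rec)
        seen.add(key(point))

    n_init = max(2, n_trials // 3) if n_trials >= 2 else 1
    max_distinct = space.n_distinct()
    for _ in range(min(n_init, n_trials)):
        point = space.sample(rng)
        for _retry in range(50):
            if key(point) not in seen:
                break
            point = space.sample(rng)
        if key(point) in seen and 0 < max_distinct <= len(seen):
            break  # space exhausted
        if key(point) not in seen:
            run(point)

    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

    while len(trials) < n_trials:
        ok = [t for t in trials if np.isfinite(t.objective)]
        if 0 < max_distinct <= len(seen):
            break  # every distinct point evaluated
        candidates = [space.sample(rng) for _ in range(n_candidates)]
        candidates = [c for c in candidates if key(c) not in seen]
        if not candidates:
            break
        if len(ok) >= 2:
            Xo = np.array([space.to_unit(t.point) for t in ok])
            yo = np.array([t.objective for t in ok])
            y_mu, y_sd = yo.mean(), yo.std() or 1.0
            # fixed kernel scales: with a handful of trials, marginal-
            # likelihood fitting of the kernel is noisier than it is worth
            gp = GaussianProcessRegressor(
                kernel=ConstantKernel(1.0) * Matern(length_scale=0.3, nu=2.5)
                + WhiteKernel(noise_level=1e-4),
                optimizer=None,
                normalize_y=False,
                random_state=seed,
            ).fit(Xo, (yo - y_mu) / y_sd)
            Xc = np.array([space.to_unit(c) for c in candidates])
            mu, sd = gp.predict(Xc, return_std=True)
            best = ((yo.min() - y_mu) / y_sd)
            sd = np.maximum(sd, 1e-9)
            z = (best - mu) / sd
            ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
            point = candidates[int(np.argmax(ei))]
        else:
            point = candidates[0]
        run(point)

    ok = [t for t in trials if np.isfinite(t.objective)]
    if not ok:
        raise RuntimeError("all trials failed; no finite objective observed")
    best = min(ok, key=lambda t: t.objective)
    return replace(base_config, **best.point), trials


def random_search(
    ds: PolymerDataset,
    space: Optional[SearchSpace] = None,
    n_trials: int = 25,
    seed: int = 0,
    base_config: Optional[ModelConfig] = None,
    k: int = 5,
) -> List[TrialRecord]:
    """Uniform random search at the same budget; the reference the
    surrogate-guided search is judged against."""
    space = space or SearchSpace()
    base_config = base_config or ModelConfig()
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_trials):
        rec = _evaluate_point(ds, space.sample(rng), base_config, k, seed + i)
        rec.trial = i
        trials.append(rec)
    return trials
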