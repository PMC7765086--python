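"""Seeded generator of PHA-like copolymer datasets with known ground truth.

The generator emulates the structure of experimental PHA Tg compilations:
a mix of homopolymers and two-monomer copolymers built from
hydroxyalkanoate chemistry, with composition skewed toward 100%,
right-skewed molecular weight (lognormal), PDI >= 1 (shifted gamma), and
a glass transition temperature driven almost entirely by monomer
chemistry and composition, with a weak Flory-Fox molecular-weight term
and no true PDI effect.

Ground truth uses the Fox mixing rule

    1 / Tg = w_A / Tg_A + (1 - w_A) / Tg_B

which is symmetric under (A, w) <-> (B, 1 - w) — exactly the label-swap
invariance the symmetry-augmentation experiments probe. The Gordon-Taylor
rule (with a tunable asymmetry constant kappa) is available as an
alternative. Compositions are used as weight fractions directly
(``frac_a / 100``); the mole/weight-fraction distinction is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

from .data import PolymerDataset
from .featurize import MonomerSpec, PolymerSample

# 3-/4-/5-hydroxyalkanoate free acids: HO2C-(linker)-CH(OH)-side
# (terminal CH2OH when the side chain is H). Side chains cover H, short
# n-alkyl, branched and unsaturated chains, and phenyl-terminated chains,
# mimicking reported PHA monomer chemistry (3HB, 3HV, ... 3H5PhP). Long
# unbranched homologues are deliberately absent: beyond ~pentyl they share
# every radius-2 atom environment and would collide in binary fingerprint
# space.
_LINKERS = ["C", "CC", "CCC"]
_SIDE_CHAINS = [
    "", "C", "CC", "CCC", "CCCC",
    "C(C)C", "CC(C)C", "C=C", "CC=C",
    "Cc1ccccc1", "CCc1ccccc1", "CCCc1ccccc1",
]


def monomer_template_capacity() -> int:
    return len(_LINKERS) * len(_SIDE_CHAINS)


def generate_monomers(n: int, seed: int = 0) -> List[MonomerSpec]:
    """Deterministically pick *n* distinct hydroxyalkanoate monomers.

    The template library enumerates backbone length x side chain; the
    seed shuffles which members are drawn (the first few templates are
    the common short-chain monomers, so small *n* at any seed still
    yields chemically plausible sets).
    """
    if n < 2:
        raise ValueError(f"need at least 2 monomers, got {n}")
    templates = []
    for linker in _LINKERS:
        for side in _SIDE_CHAINS:
            if side == "":
                templates.append(f"OC(=O){linker}CO")
            else:
                templates.append(f"OC(=O){linker}C(O){side}")
    if n > len(templates):
        raise ValueError(
            f"n={n} exceeds template capacity {len(templates)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(templates))[:n]
    return [MonomerSpec(smiles=templates[i], label=f"syn{i}") for i in sorted(order)]


def fox_tg(tg_a: float, tg_b: float, w_a: float) -> float:
    """Fox-rule glass transition of a two-component mixture (kelvin).

    ``1/Tg = w_a/tg_a + (1 - w_a)/tg_b``; requires absolute (positive)
    temperatures and ``w_a`` in [0, 1].
    """
    if tg_a <= 0 or tg_b <= 0:
        raise ValueError(
            f"Fox rule requires absolute-scale temperatures > 0, got {tg_a}, {tg_b}"
        )
    if not 0.0 <= w_a <= 1.0:
        raise ValueError(f"w_a must be in [0, 1], got {w_a}")
    return 1.0 / (w_a / tg_a + (1.0 - w_a) / tg_b)


def gordon_taylor_tg(tg_a: float, tg_b: float, w_a: float, kappa: float = 1.0) -> float:
    """Gordon-Taylor mixing rule; kappa=1 reduces to the linear rule."""
    if tg_a <= 0 or tg_b <= 0:
        raise ValueError("Gordon-Taylor requires absolute-scale temperatures > 0")
    if not 0.0 <= w_a <= 1.0:
        raise ValueError(f"w_a must be in [0, 1], got {w_a}")
    return (w_a * tg_a + kappa * (1 - w_a) * tg_b) / (w_a + kappa * (1 - w_a))


@dataclass(frozen=True)
class SyntheticConfig:
    """Distributions and ground-truth mixing rule for the generator.

    Defaults are tuned to the shape of published PHA Tg compilations:
    133 records, ~35% homopolymers, copolymer composition uniform on
    [5, 95] (overall mean ~67, median ~74 with the homopolymers at 100),
    lognormal MW with median ~505 and mean ~1160 kg/mol, PDI = 1 + gamma
    with mean ~2.6 and SD ~1.1, monomer Tg values uniform on 230-300 K,
    observation noise 2 K, and a weak Flory-Fox term Tg -= K/MW with
    K = 500 K kg/mol (~1 K at the median MW).
    """

    n_samples: int = 133
    n_monomers: int = 12
    frac_homopolymers: float = 0.35
    noise_sd: float = 2.0
    mw_log_mean: float = math.log(505.0)
    mw_log_sd: float = 1.2896
    mw_min: float = 47.0  # observed minimum of the emulated compilation
    pdi_shape: float = 2.116
    pdi_scale: float = 0.756
    flory_fox_k: float = 500.0
    tg_range: Tuple[float, float] = (230.0, 300.0)
    frac_range: Tuple[float, float] = (5.0, 95.0)
    mixing_rule: str = "fox"  # or "gordon-taylor"
    gt_kappa: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.frac_homopolymers <= 1.0:
            raise ValueError("frac_homopolymers must be in [0, 1]")
        if self.mixing_rule not in ("fox", "gordon-taylor"):
            raise ValueError(f"unknown mixing rule {self.mixing_rule!r}")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """True generating quantities for a synthetic dataset.

    ``monomer_tg`` maps canonical SMILES to the true homopolymer Tg;
    ``tg_mix`` is the noiseless mixing-rule value, ``tg_noiseless``
    additionally includes the Flory-Fox MW term, and ``tg_observed``
    adds the measurement noise (equals the dataset's tg column).
    """

    monomer_tg: Dict[str, float]
    tg_mix: np.ndarray
    tg_noiseless: np.ndarray
    tg_observed: np.ndarray
    config: SyntheticConfig = field(repr=False, default=None)


def _mix(cfg: SyntheticConfig, tg_a: float, tg_b: float, w_a: float) -> float:
    if cfg.mixing_rule == "fox":
        return fox_tg(tg_a, tg_b, w_a)
    return gordon_taylor_tg(tg_a, tg_b, w_a, cfg.gt_kappa)


def generate_dataset(cfg: SyntheticConfig) -> Tuple[PolymerDataset, GroundTruth]:
    """Draw a fully seeded PHA-like dataset plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    monomers = generate_monomers(cfg.n_monomers, cfg.seed)
    lo, hi = cfg.tg_range
    monomer_tg = {
        m.canonical_smiles: float(rng.uniform(lo, hi)) for m in monomers
    }
    samples: List[PolymerSample] = []
    mix_vals, noiseless_vals, observed_vals = [], [], []
    for _ in range(cfg.n_samples):
        # truncate at the compilation's observed minimum: below ~47 kg/mol
        # the -K/MW term would be oligomer physics the emulation never sees
        mw = max(float(rng.lognormal(cfg.mw_log_mean, cfg.mw_log_sd)), cfg.mw_min)
        pdi = 1.0 + float(rng.gamma(cfg.pdi_shape, cfg.pdi_scale))
        if rng.random() < cfg.frac_homopolymers:
            a = monomers[rng.integers(len(monomers))]
            b = None
            frac_a = 100.0
            tg_mix = monomer_tg[a.canonical_smiles]
        else:
            ia, ib = rng.choice(len(monomers), size=2, replace=False)
            a, b = monomers[int(ia)], monomers[int(ib)]
            frac_a = float(rng.uniform(*cfg.frac_range))
            tg_mix = _mix(
                cfg,
                monomer_tg[a.canonical_smiles],
                monomer_tg[b.canonical_smiles],
                frac_a / 100.0,
            )
        tg_noiseless = tg_mix - cfg.flory_fox_k / mw
        tg_obs = tg_noiseless + float(rng.normal(0.0, cfg.noise_sd))
        samples.append(
            PolymerSample(
                monomer_a=a, monomer_b=b, frac_a=frac_a, mw=mw, pdi=pdi, tg=tg_obs
            )
        )
        mix_vals.append(tg_mix)
        noiseless_vals.append(tg_noiseless)
        observed_vals.append(tg_obs)
    ds = PolymerDataset(
        samples=samples, provenance=f"synthetic(seed={cfg.seed}, n={cfg.n_samples})"
    )
    gt = GroundTruth(
        monomer_tg=monomer_tg,
        tg_mix=np.array(mix_vals),
        tg_noiseless=np.array(noiseless_vals),
        tg_observed=np.array(observed_vals),
        config=cfg,
    )
    return ds, gt


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Write the per-sample ground truth plus monomer table as CSV."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "sample_id": np.arange(len(gt.tg_observed)),
            "tg_mix": gt.tg_mix,
            "tg_noiseless": gt.tg_noiseless,
            "tg_observed": gt.tg_observed,
        }
    )
    df.to_csv(path, index=False)
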