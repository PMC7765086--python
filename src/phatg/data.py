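"""Dataset container, CSV I/O, descriptive statistics, cross-validation
folds, and symmetry augmentation.

The on-disk format is a UTF-8 CSV with header columns
``monomer_a_smiles, monomer_b_smiles, frac_a_pct, mw_kg_mol, pdi, tg``.
An empty ``monomer_b_smiles`` denotes a homopolymer of A (``frac_a_pct``
must be 100); an empty ``monomer_a_smiles`` denotes a mirrored
homopolymer record (``frac_a_pct`` must be 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .featurize import MonomerSpec, PolymerSample, SmilesParseError, mirror

CSV_COLUMNS = ["monomer_a_smiles", "monomer_b_smiles", "frac_a_pct", "mw_kg_mol", "pdi", "tg"]

#: variables summarised by :func:`describe`
DESCRIBED_VARIABLES = ("frac_a", "mw", "pdi")


class DatasetValidationError(ValueError):
    """A dataset row or column violates the schema; names row and column."""


@dataclass
class PolymerDataset:
    """An ordered collection of :class:`PolymerSample` records.

    ``mirror_pairing`` maps a sample index to the index of its mirror
    partner when the dataset was built by :func:`augment_symmetric`;
    pair-aware fold assignment uses it to keep a record and its mirror
    on the same side of every train/test split.
    """

    samples: List[PolymerSample]
    provenance: str = ""
    mirror_pairing: Optional[Dict[int, int]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.samples) == 0:
            raise ValueError("dataset must contain at least one sample")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[PolymerSample]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> PolymerSample:
        return self.samples[i]

    def subset(self, indices: Sequence[int], provenance: str = "") -> "PolymerDataset":
        return PolymerDataset(
            samples=[self.samples[i] for i in indices],
            provenance=provenance or f"{self.provenance} [subset of {len(self)}]",
        )

    @property
    def tg(self) -> np.ndarray:
        """Measured Tg values as a float array (NaN where missing)."""
        return np.array(
            [s.tg if s.tg is not None else np.nan for s in self.samples], dtype=float
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append(
                {
                    "monomer_a_smiles": s.monomer_a.smiles if s.monomer_a else "",
                    "monomer_b_smiles": s.monomer_b.smiles if s.monomer_b else "",
                    "frac_a_pct": s.frac_a,
                    "mw_kg_mol": s.mw,
                    "pdi": s.pdi,
                    "tg": s.tg if s.tg is not None else np.nan,
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _parse_row(i: int, row: pd.Series) -> PolymerSample:
    def num(col: str, optional: bool = False) -> Optional[float]:
        raw = row[col]
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
            if optional:
                return None
            raise DatasetValidationError(f"row {i}: missing value in column {col!r}")
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise DatasetValidationError(
                f"row {i}: non-numeric value {raw!r} in column {col!r}"
            ) from None

    def monomer(col: str) -> Optional[MonomerSpec]:
        raw = row[col]
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
            return None
        try:
            return MonomerSpec(smiles=str(raw).strip())
        except SmilesParseError as exc:
            raise DatasetValidationError(f"row {i}, column {col!r}: {exc}") from exc

    mon_a = monomer("monomer_a_smiles")
    mon_b = monomer("monomer_b_smiles")
    frac_a = num("frac_a_pct")
    mw = num("mw_kg_mol")
    pdi = num("pdi")
    tg = num("tg", optional=True)
    try:
        return PolymerSample(
            monomer_a=mon_a, monomer_b=mon_b, frac_a=frac_a, mw=mw, pdi=pdi, tg=tg
        )
    except ValueError as exc:
        raise DatasetValidationError(f"row {i}: {exc}") from exc


def read_dataset(path: Union[str, Path]) -> PolymerDataset:
    """Read and validate a polymer dataset CSV.

    Raises :class:`DatasetValidationError` naming the offending row and
    column for any schema violation (missing column, non-numeric field,
    composition outside [0, 100], PDI < 1, homopolymer with frac != 100).
    """
    df = pd.read_csv(
        path,
        dtype={"monomer_a_smiles": str, "monomer_b_smiles": str},
        float_precision="round_trip",
    )
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"missing column(s): {', '.join(missing)}")
    samples = [_parse_row(i, row) for i, row in df.iterrows()]
    return PolymerDataset(samples=samples, provenance=str(path))


def write_dataset(ds: PolymerDataset, path: Union[str, Path]) -> None:
    """Write the dataset CSV (round-trips exactly through read_dataset)."""
    # 17 significant digits round-trips any float64 exactly
    ds.to_dataframe().to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class DescriptiveStats:
    """Mean / sample SD / max / min / median for each numeric input."""

    stats: Dict[str, Dict[str, float]]

    def __getitem__(self, variable: str) -> Dict[str, float]:
        return self.stats[variable]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.stats, indent=indent)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.stats).T[["mean", "sd", "max", "min", "median"]]


def describe(ds: PolymerDataset) -> DescriptiveStats:
    """Descriptive statistics of the numeric inputs (frac_a, mw, pdi).

    SD is the sample standard deviation (ddof=1; 0.0 for a single row);
    the median of an even count is the mean of the two central order
    statistics.
    """
    cols = {
        "frac_a": np.array([s.frac_a for s in ds.samples], dtype=float),
        "mw": np.array([s.mw for s in ds.samples], dtype=float),
        "pdi": np.array([s.pdi for s in ds.samples], dtype=float),
    }
    out: Dict[str, Dict[str, float]] = {}
    for name, x in cols.items():
        out[name] = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "max": float(np.max(x)),
            "min": float(np.min(x)),
            "median": float(np.median(x)),
        }
    return DescriptiveStats(stats=out)


@dataclass(frozen=True)
class FoldAssignment:
    """A k-fold partition of sample indices.

    ``fold_of[i]`` is the fold id of sample ``i``. When built pair-aware
    over an augmented dataset, a sample and its mirror partner always
    share a fold, so mirrored duplicates of a test record never appear
    in its training set.
    """

    k: int
    fold_of: np.ndarray
    pairing: Optional[Dict[int, int]] = None

    def train_test_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.fold_of == fold)
        train = np.flatnonzero(self.fold_of != fold)
        return train, test

    def fold_sizes(self) -> List[int]:
        return [int(np.sum(self.fold_of == f)) for f in range(self.k)]


def make_folds(
    ds: PolymerDataset,
    k: int = 5,
    seed: int = 0,
    pair_aware: bool = False,
) -> FoldAssignment:
    """Randomly partition the dataset into k nearly equal-sized folds.

    Without pairing constraints fold sizes differ by at most one. With
    ``pair_aware=True`` (requires ``ds.mirror_pairing``) each
    mirror pair is assigned as a unit, so both members land in the same
    fold; fold sizes then differ by at most one pair.
    """
    n = len(ds)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    rng = np.random.default_rng(seed)
    fold_of = np.full(n, -1, dtype=int)
    if not pair_aware:
        perm = rng.permutation(n)
        fold_of[perm] = np.arange(n) % k
        return FoldAssignment(k=k, fold_of=fold_of)
    pairing = ds.mirror_pairing
    if pairing is None:
        raise ValueError("pair_aware folding requires a dataset with mirror_pairing")
    units: List[List[int]] = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        j = pairing.get(i)
        if j is not None and j != i and j not in seen:
            units.append([i, j])
            seen.update((i, j))
        else:
            units.append([i])
            seen.add(i)
    order = rng.permutation(len(units))
    sizes = np.zeros(k, dtype=int)
    for u in order:
        f = int(np.argmin(sizes))  # greedy: keep folds balanced
        for idx in units[u]:
            fold_of[idx] = f
        sizes[f] += len(units[u])
    return FoldAssignment(k=k, fold_of=fold_of, pairing=pairing)


def augment_symmetric(ds: PolymerDataset) -> PolymerDataset:
    """Append the mirror image of every record (monomer labels swapped,
    composition complemented); MW, PDI and Tg are carried over unchanged.

    The output has twice the input size: original samples first, then
    their mirrors in the same order, with ``mirror_pairing`` recording
    the i <-> n+i correspondence for pair-aware folding.
    """
    n = len(ds)
    mirrored = [mirror(s) for s in ds.samples]
    pairing = {i: n + i for i in range(n)}
    pairing.update({n + i: i for i in range(n)})
    return PolymerDataset(
        samples=list(ds.samples) + mirrored,
        provenance=f"{ds.provenance} + symmetry set",
        mirror_pairing=pairing,
    )
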