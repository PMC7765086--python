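"""Monomer featurization: SMILES canonicalization, circular fingerprints,
and assembly of copolymer feature vectors.

A polymer record is encoded as a fixed-width numeric vector

    [ fp_A (N bits) | fp_B (N bits) | frac_a | mw | pdi ]

of length ``2 N + 3``, where ``N`` is the fingerprint length. For a
homopolymer the B block is all zeros and ``frac_a`` is 100. The monomer
order (A vs. B) is physically arbitrary; :func:`mirror` produces the
label-swapped record with ``frac_a`` complemented to ``100 - frac_a``,
which is the symmetry the augmentation strategy exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")  # parse failures are raised as SmilesParseError

#: numeric slots appended after the two fingerprint blocks, in layout order
NUMERIC_SLOTS = ("frac_a", "mw", "pdi")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


def canonicalize_smiles(smiles: str) -> str:
    """Return the canonical SMILES for *smiles*.

    Canonicalization is idempotent: applying it to its own output is a
    no-op. Raises :class:`SmilesParseError` naming the offending string
    if it does not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class MonomerSpec:
    """A monomer identified by its SMILES string.

    Monomers are represented as the free-acid monomer molecule (e.g.
    3-hydroxybutanoic acid), not the in-chain ester repeat unit.
    Equality and hashing use the canonical form, so two spellings of the
    same molecule compare equal.
    """

    smiles: str
    canonical_smiles: str = field(init=False)
    label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "canonical_smiles", canonicalize_smiles(self.smiles))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MonomerSpec):
            return NotImplemented
        return self.canonical_smiles == other.canonical_smiles

    def __hash__(self) -> int:
        return hash(self.canonical_smiles)


@dataclass(frozen=True)
class Fingerprint:
    """A binary substructure fingerprint of fixed length ``n_bits``."""

    bits: np.ndarray
    n_bits: int

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.shape != (self.n_bits,):
            raise ValueError(f"fingerprint length {bits.shape} != n_bits {self.n_bits}")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")
        object.__setattr__(self, "bits", bits)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


def fingerprint(
    monomer: MonomerSpec,
    n_bits: int = 128,
    radius: int = 2,
    family: str = "morgan",
) -> Fingerprint:
    """Compute the binary fingerprint of a monomer.

    Parameters
    ----------
    monomer : MonomerSpec
    n_bits : int
        Folded length; must be a power of two >= 8.
    radius : int
        Circular-environment radius (Morgan family only).
    family : {"morgan", "rdkit"}
        Hashed circular (Morgan) fingerprints are the default; the RDKit
        topological path fingerprint is available as an alternative.

    The result is a pure function of (canonical SMILES, n_bits, radius,
    family): the same monomer always maps to the same bit vector.
    """
    if n_bits < 8 or (n_bits & (n_bits - 1)) != 0:
        raise ValueError(f"n_bits must be a power of two >= 8, got {n_bits}")
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    mol = Chem.MolFromSmiles(monomer.canonical_smiles)
    if family == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    elif family == "rdkit":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    else:
        raise ValueError(f"unknown fingerprint family: {family!r}")
    bv = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=bits, n_bits=n_bits)


@dataclass(frozen=True)
class PolymerSample:
    """One polymer record: up to two monomers, composition, MW, PDI, Tg.

    ``frac_a`` is the fractional composition of monomer A in percent on
    [0, 100]; ``mw`` is the molecular weight in kg mol^-1; ``pdi`` the
    polydispersity index (>= 1). ``tg`` is the measured glass transition
    temperature (optional; unit follows the dataset, differences are
    unit-agnostic between K and degC).

    A homopolymer of A has ``monomer_b is None`` and ``frac_a == 100``.
    The mirror image of such a record has ``monomer_a is None`` and
    ``frac_a == 0`` (the A block encodes to zeros).
    """

    monomer_a: Optional[MonomerSpec]
    monomer_b: Optional[MonomerSpec]
    frac_a: float
    mw: float
    pdi: float
    tg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.monomer_a is None and self.monomer_b is None:
            raise ValueError("sample must have at least one monomer")
        if not (0.0 <= self.frac_a <= 100.0):
            raise ValueError(f"frac_a must be in [0, 100], got {self.frac_a}")
        if self.monomer_b is None and self.frac_a != 100.0:
            raise ValueError(
                f"homopolymer of A must have frac_a == 100, got {self.frac_a}"
            )
        if self.monomer_a is None and self.frac_a != 0.0:
            raise ValueError(
                f"record with empty A block must have frac_a == 0, got {self.frac_a}"
            )
        if not (self.mw > 0 and math.isfinite(self.mw)):
            raise ValueError(f"mw must be positive and finite, got {self.mw}")
        if not (self.pdi >= 1 and math.isfinite(self.pdi)):
            raise ValueError(f"pdi must be >= 1, got {self.pdi}")

    @property
    def is_homopolymer(self) -> bool:
        return self.monomer_a is None or self.monomer_b is None


def mirror(sample: PolymerSample) -> PolymerSample:
    """Swap the monomer A/B labels and complement the composition.

    The returned record describes the same physical polymer: monomers
    exchanged, ``frac_a`` replaced by ``100 - frac_a``, with MW, PDI and
    Tg unchanged. ``mirror`` is an involution: ``mirror(mirror(s)) == s``.
    """
    return PolymerSample(
        monomer_a=sample.monomer_b,
        monomer_b=sample.monomer_a,
        frac_a=100.0 - sample.frac_a,
        mw=sample.mw,
        pdi=sample.pdi,
        tg=sample.tg,
    )


def encode(
    sample: PolymerSample,
    n_bits: int = 128,
    radius: int = 2,
    family: str = "morgan",
) -> np.ndarray:
    """Encode a polymer record as the ``2 N + 3`` feature vector.

    Layout: ``[fp_A | fp_B | frac_a | mw | pdi]``. A missing monomer
    block is all zeros. Bits are stored unscaled {0, 1}; scaling of the
    three numeric slots is the model's concern.
    """
    vec = np.zeros(2 * n_bits + 3, dtype=np.float64)
    if sample.monomer_a is not None:
        vec[:n_bits] = fingerprint(sample.monomer_a, n_bits, radius, family).bits
    if sample.monomer_b is not None:
        vec[n_bits : 2 * n_bits] = fingerprint(
            sample.monomer_b, n_bits, radius, family
        ).bits
    vec[2 * n_bits] = sample.frac_a
    vec[2 * n_bits + 1] = sample.mw
    vec[2 * n_bits + 2] = sample.pdi
    return vec


def encode_many(
    samples: Sequence[PolymerSample],
    n_bits: int = 128,
    radius: int = 2,
    family: str = "morgan",
) -> np.ndarray:
    """Encode a sequence of records into an ``(n, 2N+3)`` design matrix."""
    if len(samples) == 0:
        return np.zeros((0, 2 * n_bits + 3))
    return np.vstack([encode(s, n_bits, radius, family) for s in samples])
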