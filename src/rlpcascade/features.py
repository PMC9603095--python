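"""The six fixed-dimension frequency encodings of protein sequences.

Feature types and their dimensionalities:

=====================  ====  =============================================
AAComposition            20  residue frequencies, full length
AAComposition_N_C        40  residue frequencies per N-/C-terminal half
Dipeptide               400  overlapping 2-mer frequencies
Tripeptide             8000  overlapping 3-mer frequencies
CPAASC                    9  side-chain chemical-property group frequencies
CPAASC_N_C               18  property-group frequencies per half
=====================  ====  =============================================

``X`` (unknown residue) never enters a numerator or a denominator: full-
length compositions are taken over canonical residues only and k-mers
containing ``X`` are skipped.  Property groups may overlap, so CPAASC
vectors need not sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from math import ceil
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import CANONICAL_ALPHABET, SequenceRecord

FEATURE_TYPES = (
    "AAComposition",
    "AAComposition_N_C",
    "Dipeptide",
    "Tripeptide",
    "CPAASC",
    "CPAASC_N_C",
)

FEATURE_DIMENSIONS = {
    "AAComposition": 20,
    "AAComposition_N_C": 40,
    "Dipeptide": 400,
    "Tripeptide": 8000,
    "CPAASC": 9,
    "CPAASC_N_C": 18,
}


class FeatureError(ValueError):
    """Sequence does not satisfy a feature type's precondition."""


@dataclass(frozen=True)
class PropertyGroupTable:
    """Ordered side-chain chemical-property groups (9 groups; may overlap)."""

    groups: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        if len(self.groups) != 9:
            raise ValueError("property table must define exactly 9 groups")
        for name, residues in self.groups:
            bad = residues - set(CANONICAL_ALPHABET)
            if bad:
                raise ValueError(f"group {name!r} has non-canonical residues {bad}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.groups]


def _table(*pairs: tuple[str, str]) -> PropertyGroupTable:
    return PropertyGroupTable(
        tuple((name, frozenset(res)) for name, res in pairs)
    )


#: Default property grouping: standard biochemical classes of the side
#: chains (charge, polarity, aromaticity, aliphaticity, hydrophobicity,
#: volume, mass) plus the conformationally special residues.  Configurable.
DEFAULT_PROPERTY_TABLE = _table(
    ("positively_charged", "RKH"),
    ("negatively_charged", "DE"),
    ("polar_uncharged", "STNQ"),
    ("aromatic", "FWY"),
    ("nonpolar_aliphatic", "GAVLIMP"),
    ("hydrophobic", "ACFILMVW"),
    ("large_volume", "FIKLMRWY"),
    ("large_mass", "FHKRWY"),
    ("special", "CGP"),
)

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_ALPHABET)}
_KMER_INDEX = {
    k: {
        "".join(t): i
        for i, t in enumerate(product(CANONICAL_ALPHABET, repeat=k))
    }
    for k in (2, 3)
}


def _canonical(residues: str) -> str:
    return residues.replace("X", "")


def aa_composition(residues: str) -> np.ndarray:
    """Frequency of each canonical residue, in ACDE...WY order (sums to 1)."""
    canon = _canonical(residues)
    if not canon:
        raise FeatureError("no canonical residues")
    counts = np.zeros(20)
    for r in canon:
        counts[_AA_INDEX[r]] += 1
    return counts / len(canon)


def split_nc(residues: str) -> tuple[str, str]:
    """Split into N- and C-terminal halves; odd lengths favour the N-half."""
    if len(residues) < 2:
        raise FeatureError("sequence too short to split into halves")
    mid = ceil(len(residues) / 2)
    return residues[:mid], residues[mid:]


def aa_composition_nc(residues: str) -> np.ndarray:
    n_half, c_half = split_nc(residues)
    return np.concatenate([aa_composition(n_half), aa_composition(c_half)])


def kmer_composition(residues: str, k: int) -> np.ndarray:
    """Overlapping k-mer frequencies (k=2 or 3) over the canonical alphabet.

    Windows slide with stride 1 over the raw sequence; windows containing
    ``X`` are skipped and the denominator counts valid windows only.
    """
    if k not in (2, 3):
        raise FeatureError(f"k must be 2 or 3, got {k}")
    index = _KMER_INDEX[k]
    counts = np.zeros(20**k)
    valid = 0
    for i in range(len(residues) - k + 1):
        kmer = residues[i : i + k]
        idx = index.get(kmer)
        if idx is not None:
            counts[idx] += 1
            valid += 1
    if valid == 0:
        raise FeatureError(f"no valid {k}-mer windows")
    return counts / valid


def cpaasc(
    residues: str, table: PropertyGroupTable = DEFAULT_PROPERTY_TABLE
) -> np.ndarray:
    """Per-group residue frequency over the canonical sequence length."""
    canon = _canonical(residues)
    if not canon:
        raise FeatureError("no canonical residues")
    out = np.empty(9)
    for j, (_, members) in enumerate(table.groups):
        out[j] = sum(1 for r in canon if r in members) / len(canon)
    return out


def cpaasc_nc(
    residues: str, table: PropertyGroupTable = DEFAULT_PROPERTY_TABLE
) -> np.ndarray:
    n_half, c_half = split_nc(residues)
    return np.concatenate([cpaasc(n_half, table), cpaasc(c_half, table)])


def compute_features(
    residues: str,
    feature_type: str,
    table: PropertyGroupTable = DEFAULT_PROPERTY_TABLE,
) -> np.ndarray:
    if feature_type == "AAComposition":
        return aa_composition(residues)
    if feature_type == "AAComposition_N_C":
        return aa_composition_nc(residues)
    if feature_type == "Dipeptide":
        return kmer_composition(residues, 2)
    if feature_type == "Tripeptide":
        return kmer_composition(residues, 3)
    if feature_type == "CPAASC":
        return cpaasc(residues, table)
    if feature_type == "CPAASC_N_C":
        return cpaasc_nc(residues, table)
    raise FeatureError(f"unknown feature type {feature_type!r}")


def feature_names(
    feature_type: str, table: PropertyGroupTable = DEFAULT_PROPERTY_TABLE
) -> list[str]:
    if feature_type == "AAComposition":
        return [f"AA:{a}" for a in CANONICAL_ALPHABET]
    if feature_type == "AAComposition_N_C":
        return [f"N_AA:{a}" for a in CANONICAL_ALPHABET] + [
            f"C_AA:{a}" for a in CANONICAL_ALPHABET
        ]
    if feature_type == "Dipeptide":
        return [f"DI:{m}" for m in _KMER_INDEX[2]]
    if feature_type == "Tripeptide":
        return [f"TRI:{m}" for m in _KMER_INDEX[3]]
    if feature_type == "CPAASC":
        return [f"CP:{n}" for n in table.names]
    if feature_type == "CPAASC_N_C":
        return [f"N_CP:{n}" for n in table.names] + [
            f"C_CP:{n}" for n in table.names
        ]
    raise FeatureError(f"unknown feature type {feature_type!r}")


def featurize(
    records: Iterable[SequenceRecord] | Sequence[SequenceRecord],
    feature_type: str,
    table: PropertyGroupTable = DEFAULT_PROPERTY_TABLE,
) -> pd.DataFrame:
    """Feature table: one row per record (in input order), fixed columns.

    A record failing the feature type's precondition raises a
    :class:`FeatureError` naming it.
    """
    columns = feature_names(feature_type, table)
    rows, index = [], []
    for rec in records:
        try:
            rows.append(compute_features(rec.residues, feature_type, table))
        except FeatureError as exc:
            raise FeatureError(f"record {rec.id!r}: {exc}") from exc
        index.append(rec.id)
    if not rows:
        return pd.DataFrame(np.empty((0, len(columns))), columns=columns)
    return pd.DataFrame(np.vstack(rows), index=index, columns=columns)
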