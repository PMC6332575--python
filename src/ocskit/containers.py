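"""Shared in-memory containers for kinship-type matrices and breed composition.

A *kinship* f(i, j) is the probability that two alleles, one sampled from each
of individuals i and j, are identical by descent (pedigree-based) or lie in
identical shared haplotype segments (segment-based).  Self-kinship is defined
with replacement, so f(i, i) = (1 + F_i) / 2 where F_i is the inbreeding
coefficient of i.

Native kinship is a conditional probability and is carried as a pair of
matrices: a joint numerator (IBD-and-native, or in-identical-segments-and-
native) and a both-native denominator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["KinshipMatrix", "NativeKinshipComponents", "BreedComposition"]


@dataclass
class KinshipMatrix:
    """Symmetric matrix of pairwise kinship-type probabilities with an id index.

    Parameters
    ----------
    ids
        Ordered individual identifiers labelling rows and columns.
    values
        Square symmetric array of probabilities in [0, 1].
    role
        Free-text role tag, e.g. ``"fPED"``, ``"fSEG"``, ``"fN"``.
    """

    ids: list[str]
    values: np.ndarray
    role: str = "kinship"

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kinship matrix shape {self.values.shape} does not match "
                f"{n} ids"
            )
        self._index = {ind: k for k, ind in enumerate(self.ids)}

    # -- element access -----------------------------------------------------
    def loc(self, i: str, j: str) -> float:
        """Kinship between individuals ``i`` and ``j``."""
        return float(self.values[self._index[str(i)], self._index[str(j)]])

    def submatrix(self, ids: list[str]) -> "KinshipMatrix":
        """Restriction to ``ids`` (in the given order)."""
        missing = [i for i in map(str, ids) if i not in self._index]
        if missing:
            raise KeyError(f"ids not in kinship matrix: {missing[:5]}")
        idx = [self._index[str(i)] for i in ids]
        return KinshipMatrix(list(map(str, ids)), self.values[np.ix_(idx, idx)], self.role)

    @property
    def additive(self) -> np.ndarray:
        """Additive (numerator) relationship matrix A = 2 f."""
        return 2.0 * self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    # -- plain-text round trip ---------------------------------------------
    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="Indiv")

    @classmethod
    def read(cls, path, role: str = "kinship") -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(list(df.index), df.to_numpy(dtype=float), role)


@dataclass
class NativeKinshipComponents:
    """Numerator/denominator pair defining a conditional (native) kinship.

    ``ratio()`` gives f(i,j | both alleles native) = numerator / denominator,
    undefined (NaN) wherever the both-native probability is zero.
    """

    numerator: KinshipMatrix
    denominator: KinshipMatrix

    def __post_init__(self) -> None:
        if self.numerator.ids != self.denominator.ids:
            raise ValueError("numerator and denominator id order differ")
        if np.any(self.numerator.values > self.denominator.values + 1e-9):
            raise ValueError("numerator exceeds denominator: not a valid "
                             "conditional kinship")

    @property
    def ids(self) -> list[str]:
        return self.numerator.ids

    def ratio(self) -> pd.DataFrame:
        num = self.numerator.values
        den = self.denominator.values
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        return pd.DataFrame(r, index=self.ids, columns=self.ids)

    def submatrix(self, ids: list[str]) -> "NativeKinshipComponents":
        return NativeKinshipComponents(
            self.numerator.submatrix(ids), self.denominator.submatrix(ids)
        )


@dataclass
class BreedComposition:
    """Per-individual genome composition by origin class.

    ``table`` has one row per individual and one column per origin class:
    ``native``, ``unknown``, and one column per foreign breed.  Rows sum to 1.
    """

    table: pd.DataFrame
    this_breed: str = ""
    _tol: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        sums = self.table.sum(axis=1).to_numpy()
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = self.table.index[np.abs(sums - 1.0) > 1e-6][:5].tolist()
            raise ValueError(f"composition rows do not sum to 1: {bad}")
        if (self.table.to_numpy() < -1e-12).any():
            raise ValueError("negative composition entries")

    @property
    def native(self) -> pd.Series:
        """Native contribution N(i) per individual."""
        return self.table["native"]

    @property
    def classes(self) -> list[str]:
        return list(self.table.columns)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="Indiv")
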