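"""Codominant genotype-matrix container.

The central data object of the package: a rectangular table of biallelic
array calls (``AA``/``AB``/``BB``/``NC``) for individuals, each individual
assigned to an accession (a seedbank entry from one collection site).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

CALLS = ("AA", "AB", "BB", "NC")
MISSING = "NC"

#: integer codes used internally: number of A alleles, -1 for missing
_CALL_CODE = {"AA": 2, "AB": 1, "BB": 0, "NC": -1}
_CODE_CALL = {v: k for k, v in _CALL_CODE.items()}


@dataclass
class GenotypeMatrix:
    """Individuals x markers codominant calls with accession assignment.

    Parameters
    ----------
    calls
        DataFrame indexed by sample id with one column per marker; values
        must be in ``{"AA", "AB", "BB", "NC"}``.
    accessions
        Series mapping every sample id to its accession id.
    """

    calls: pd.DataFrame
    accessions: pd.Series

    def __post_init__(self) -> None:
        if not self.calls.index.is_unique:
            raise FormatError("duplicate sample ids in genotype matrix")
        if not self.calls.columns.is_unique:
            raise FormatError("duplicate marker ids in genotype matrix")
        missing = self.calls.index.difference(self.accessions.index)
        if len(missing):
            raise FormatError(
                f"samples without accession assignment: {list(missing[:5])}"
            )
        self.accessions = self.accessions.reindex(self.calls.index)
        bad = ~np.isin(self.calls.to_numpy(), CALLS)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                "unknown call token "
                f"{self.calls.iat[i, j]!r} at sample {self.calls.index[i]!r}, "
                f"marker {self.calls.columns[j]!r}"
            )

    # -- basic views ---------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def codes(self) -> np.ndarray:
        """Integer view: A-allele dosage (0/1/2), -1 for missing."""
        arr = self.calls.to_numpy()
        out = np.full(arr.shape, -1, dtype=np.int8)
        out[arr == "AA"] = 2
        out[arr == "AB"] = 1
        out[arr == "BB"] = 0
        return out

    def missing_fraction(self) -> pd.Series:
        """Per-marker fraction of NC calls."""
        return (self.calls == MISSING).mean(axis=0)

    # -- subsetting ----------------------------------------------------
    def subset_markers(self, keep: Sequence[str] | Iterable[str]) -> "GenotypeMatrix":
        keep = [m for m in keep]
        return GenotypeMatrix(self.calls.loc[:, keep], self.accessions.copy())

    def subset_samples(self, keep: Sequence[str] | Iterable[str]) -> "GenotypeMatrix":
        keep = [s for s in keep]
        return GenotypeMatrix(self.calls.loc[keep], self.accessions.loc[keep])

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.calls.copy()
        out.insert(0, "accession_id", self.accessions)
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
        if "accession_id" not in df.columns:
            raise FormatError("genotype TSV lacks required column 'accession_id'")
        acc = df.pop("accession_id")
        return cls(df, acc)


def from_codes(
    codes: np.ndarray,
    sample_ids: Sequence[str],
    marker_ids: Sequence[str],
    accessions: Sequence[str],
) -> GenotypeMatrix:
    """Build a matrix from integer dosage codes (2=AA, 1=AB, 0=BB, -1=NC)."""
    tokens = np.array(["BB", "AB", "AA"], dtype=object)
    calls = np.where(codes >= 0, tokens[np.clip(codes, 0, 2)], MISSING)
    frame = pd.DataFrame(calls, index=list(sample_ids), columns=list(marker_ids))
    return GenotypeMatrix(frame, pd.Series(list(accessions), index=list(sample_ids)))
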