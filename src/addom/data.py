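"""Core data containers shared across the pipeline.

All containers are thin wrappers around numpy arrays / pandas frames so that
every module can exchange data without file round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "Pedigree",
    "RelationshipMatrix",
    "PedigreeError",
]

#: value used for an unknown parent in pedigree tables
UNKNOWN_PARENT = ""


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, missing records)."""


@dataclass
class GenotypeMatrix:
    """Animals x variants dosage matrix with variant metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` float array with values in ``{0, 1, 2}``
        and ``NaN`` for missing calls.
    variants
        Frame with columns ``chrom`` (str), ``pos`` (1-based int), ``ref``,
        ``alt`` and optionally ``id`` / ``af``.
    samples
        Sample identifiers, one per dosage row.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("sample count does not match dosage rows")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant count does not match dosage columns")
        self.variants = self.variants.reset_index(drop=True)
        if "id" not in self.variants.columns:
            self.variants = self.variants.assign(
                id=[
                    f"{c}:{p}"
                    for c, p in zip(self.variants["chrom"], self.variants["pos"])
                ]
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (alt) allele from non-missing calls."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return p

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries mean-imputed (2p per variant)."""
        x = self.dosages.copy()
        miss = np.isnan(x)
        if miss.any():
            fill = np.broadcast_to(2.0 * self.allele_freq(), x.shape)
            x[miss] = fill[miss]
        return x

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
        )

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            rows = [lookup[s] for s in ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"sample not in genotype matrix: {exc}") from exc
        return GenotypeMatrix(
            dosages=self.dosages[rows, :],
            variants=self.variants.copy(),
            samples=list(ids),
        )


@dataclass
class Pedigree:
    """Animal / sire / dam records; unknown parents are empty strings."""

    records: pd.DataFrame

    REQUIRED = ("animal", "sire", "dam")

    def __post_init__(self) -> None:
        df = self.records.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise PedigreeError(f"pedigree lacks required column {col!r}")
            df[col] = df[col].fillna(UNKNOWN_PARENT).astype(str)
        if df["animal"].duplicated().any():
            dup = df.loc[df["animal"].duplicated(), "animal"].iloc[0]
            raise PedigreeError(f"duplicate animal record: {dup}")
        self.records = df.reset_index(drop=True)

    @property
    def animals(self) -> list[str]:
        return list(self.records["animal"])

    def parents(self, animal: str) -> tuple[str, str]:
        row = self.records.loc[self.records["animal"] == animal]
        if row.empty:
            return UNKNOWN_PARENT, UNKNOWN_PARENT
        return str(row["sire"].iloc[0]), str(row["dam"].iloc[0])

    def founders(self) -> list[str]:
        m = (self.records["sire"] == UNKNOWN_PARENT) & (
            self.records["dam"] == UNKNOWN_PARENT
        )
        return list(self.records.loc[m, "animal"])

    def topological_order(self) -> list[str]:
        """Animals sorted parents-before-offspring; raises on cycles."""
        known = dict(
            zip(self.records["animal"], zip(self.records["sire"], self.records["dam"]))
        )
        order: list[str] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for root in self.records["animal"]:
            if state.get(root) == 1:
                continue
            stack = [(root, False)]
            while stack:
                animal, processed = stack.pop()
                if processed:
                    state[animal] = 1
                    order.append(animal)
                    continue
                if state.get(animal) == 1:
                    continue
                if state.get(animal) == 0:
                    raise PedigreeError(
                        f"pedigree cycle detected involving animal {animal!r}"
                    )
                state[animal] = 0
                stack.append((animal, True))
                for parent in known.get(animal, (UNKNOWN_PARENT, UNKNOWN_PARENT)):
                    if parent != UNKNOWN_PARENT and state.get(parent) != 1:
                        if parent not in known:
                            continue  # phantom parent treated as founder
                        stack.append((parent, False))
        return order


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix keyed by animal IDs."""

    values: np.ndarray
    ids: list[str]
    kind: str = "G_additive"

    KINDS = ("G_additive", "D_dominance", "A_pedigree", "D_pedigree")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square")
        if len(self.ids) != n:
            raise ValueError("ID list does not match matrix order")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def align(self, ids: Sequence[str]) -> "RelationshipMatrix":
        """Reorder / subset the matrix to the given ID sequence."""
        lookup = {s: i for i, s in enumerate(self.ids)}
        rows = np.array([lookup[s] for s in ids])
        return RelationshipMatrix(
            values=self.values[np.ix_(rows, rows)], ids=list(ids), kind=self.kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)
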