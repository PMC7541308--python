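"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`AbundanceMatrix`: a proteins x samples matrix of
log2 reporter-ion abundances together with per-sample metadata and a boolean
mask marking which cells were actually quantified.  Missing cells are carried
in the mask, never as sentinel numbers, so arithmetic on ``values`` is only
meaningful where ``mask`` is True.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "KO")
AGE_GROUPS = ("young", "old")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for a single TMT channel / biological sample."""

    sample_id: str
    genotype: str
    age_group: str
    batch: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}")

    @property
    def group(self) -> str:
        """Four-level design cell, e.g. ``WT-young``."""
        return f"{self.genotype}-{self.age_group}"


@dataclass
class AbundanceMatrix:
    """Log2 protein abundances with sample metadata and a quantification mask.

    Parameters
    ----------
    proteins
        Ordered protein identifiers (opaque strings; unique).
    samples
        Ordered :class:`SampleMeta`, one per column.
    values
        ``(n_proteins, n_samples)`` float array of log2 abundances.  Entries
        where ``mask`` is False are undefined (stored as NaN).
    mask
        Boolean array of the same shape; True where the cell was quantified.
    """

    proteins: list[str]
    samples: list[SampleMeta]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n_p, n_s = len(self.proteins), len(self.samples)
        if self.values.shape != (n_p, n_s):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{n_p} proteins x {n_s} samples"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape differs from values shape")
        if len(set(self.proteins)) != n_p:
            dupes = pd.Index(self.proteins)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate protein ids: {dupes}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != n_s:
            raise ValueError("duplicate sample ids in sample sheet")
        # undefined cells are stored as NaN so accidental use is loud
        self.values = np.where(self.mask, self.values, np.nan)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def batches(self) -> list[str]:
        """Distinct batch names in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.batch, None)
        return list(seen)

    def batch_columns(self, batch: str) -> np.ndarray:
        """Column indices belonging to one TMT batch."""
        idx = np.array([i for i, s in enumerate(self.samples) if s.batch == batch], dtype=int)
        if idx.size == 0:
            raise KeyError(f"unknown batch {batch!r}")
        return idx

    def missing_fraction(self) -> np.ndarray:
        """Per-protein fraction of unquantified cells."""
        return 1.0 - self.mask.mean(axis=1)

    def complete_index(self) -> np.ndarray:
        """Row indices of proteins quantified in every sample."""
        return np.flatnonzero(self.mask.all(axis=1))

    def half_missing_index(self) -> np.ndarray:
        """Rows quantified in exactly one batch of a two-equal-batch design."""
        batches = self.batches
        if len(batches) != 2:
            return np.zeros(0, dtype=int)
        cols = [self.batch_columns(b) for b in batches]
        if cols[0].size != cols[1].size:
            return np.zeros(0, dtype=int)
        full = [self.mask[:, c].all(axis=1) for c in cols]
        none = [~self.mask[:, c].any(axis=1) for c in cols]
        half = (full[0] & none[1]) | (full[1] & none[0])
        return np.flatnonzero(half)

    def subset(self, rows: np.ndarray | list[int]) -> "AbundanceMatrix":
        rows = np.asarray(rows, dtype=int)
        return AbundanceMatrix(
            proteins=[self.proteins[i] for i in rows],
            samples=list(self.samples),
            values=self.values[rows].copy(),
            mask=self.mask[rows].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.proteins, columns=self.sample_ids)

    def sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "genotype": [s.genotype for s in self.samples],
                "age_group": [s.age_group for s in self.samples],
                "batch": [s.batch for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def trait_vector(self, trait: str) -> np.ndarray:
        """Binary 0/1 encoding of a sample trait (``genotype`` -> KO=1, ``age`` -> old=1)."""
        if trait == "genotype":
            return np.array([1.0 if s.genotype == "KO" else 0.0 for s in self.samples])
        if trait in ("age", "age_group"):
            return np.array([1.0 if s.age_group == "old" else 0.0 for s in self.samples])
        raise KeyError(f"unknown trait {trait!r}")


@dataclass
class GeneSetCollection:
    """Named gene/protein sets (cell-type markers or ontology terms).

    ``sets`` preserves insertion order; members within a set are unique with
    original order kept.  ``universe`` optionally restricts the background.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                # deduplicate, preserving order
                self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def restricted(self, universe: list[str]) -> "GeneSetCollection":
        """Intersect every set with an explicit universe (dropped ids are lost)."""
        uni = set(universe)
        return GeneSetCollection(
            sets={n: [m for m in mem if m in uni] for n, mem in self.sets.items()},
            universe=list(universe),
        )
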