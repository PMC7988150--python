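"""In-memory containers for expression matrices and gene sets.

Expression values are FPKM-like: non-negative, finite floats. Gene and
sample identifiers are opaque strings; no genome coordinates are handled
anywhere in the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "TimeCourseMatrix",
    "GroupedMatrix",
    "GeneSet",
]


class ValidationError(ValueError):
    """A matrix or gene set violates its structural contract."""


def _check_values(df: pd.DataFrame) -> None:
    vals = df.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValidationError("expression values must be finite")
    if (vals < 0).any():
        raise ValidationError("expression values must be non-negative")


def _check_gene_index(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene IDs: {dups[:5]}")


@dataclass(frozen=True)
class TimeCourseMatrix:
    """Genes x time points (hours), a single replicate per time point.

    ``data`` is indexed by gene ID with one float column per hour,
    strictly increasing. This is the observable of the simulated
    postmortem interval: one tissue block sampled repeatedly over 0-24 h.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_gene_index(df)
        try:
            hours = [float(c) for c in df.columns]
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"time-point columns must be numeric hours: {exc}")
        if len(set(hours)) != len(hours):
            raise ValidationError("duplicate time points")
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValidationError("time points must be strictly increasing")
        _check_values(df)
        df = df.astype(float)
        df.columns = hours
        object.__setattr__(self, "data", df)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def timepoints_h(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    def subset(self, genes: Sequence[str]) -> "TimeCourseMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return TimeCourseMatrix(self.data.loc[list(genes)])


@dataclass(frozen=True)
class GroupedMatrix:
    """Genes x replicated samples with a two-level group factor.

    ``levels`` orders the two factor levels (A, B); fold changes computed
    downstream are A over B (e.g. fresh over postmortem).
    """

    data: pd.DataFrame
    group_of: Mapping[str, str]
    levels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        df = self.data
        _check_gene_index(df)
        samples = [str(c) for c in df.columns]
        if len(set(samples)) != len(samples):
            raise ValidationError("duplicate sample IDs")
        group_of = dict(self.group_of)
        missing = [s for s in samples if s not in group_of]
        if missing:
            raise ValidationError(f"samples without group assignment: {missing[:5]}")
        group_of = {s: str(group_of[s]) for s in samples}
        found = sorted(set(group_of.values()))
        if len(found) != 2:
            raise ValidationError(f"need exactly 2 groups, found {found}")
        levels = self.levels if self.levels is not None else (found[0], found[1])
        if sorted(levels) != found:
            raise ValidationError(f"levels {levels} do not match groups {found}")
        for lev in levels:
            if not any(g == lev for g in group_of.values()):
                raise ValidationError(f"group {lev!r} is empty")
        _check_values(df)
        df = df.astype(float)
        df.columns = samples
        object.__setattr__(self, "data", df)
        object.__setattr__(self, "group_of", group_of)
        object.__setattr__(self, "levels", (str(levels[0]), str(levels[1])))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def samples_in(self, level: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == level]

    def group_values(self, level: str) -> np.ndarray:
        """Genes x replicates array for one factor level."""
        return self.data[self.samples_in(level)].to_numpy(dtype=float)


@dataclass(frozen=True)
class GeneSet:
    """A named, unordered collection of unique gene IDs."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(str(g) for g in self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    def intersection(self, other: "GeneSet | frozenset[str] | set[str]") -> frozenset[str]:
        members = other.members if isinstance(other, GeneSet) else frozenset(other)
        return self.members & members
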