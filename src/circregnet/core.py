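"""Shared containers for the stage-course experiment.

The study design is a five-stage differentiation time course (0, 12, 48, 72
and 120 h after adipogenic induction, labelled A0..A120) with three
replicate libraries per stage.  Every expression layer (circRNA back-splice
junction counts, miRNA counts, mRNA fragment counts and their normalized
forms) is carried as an :class:`ExpressionMatrix`: a features x samples table
with an explicit abundance unit and the sample design attached, so that unit
mix-ups between pipeline stages are detectable instead of silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical ordered stage labels of the differentiation course.
STAGES: tuple[str, ...] = ("A0", "A12", "A48", "A72", "A120")

#: Abundance units an ExpressionMatrix may carry.
UNITS: tuple[str, ...] = ("raw_count", "SRPBM", "TPM", "FPKM")


class FormatError(ValueError):
    """Malformed on-disk input (raised instead of silently coercing)."""


class UnitError(ValueError):
    """An operation received a matrix in the wrong abundance unit."""


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing library: its stage and replicate number."""

    sample_id: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}"
            )
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


def validate_design(design: Sequence[SampleDesign]) -> None:
    """Check (stage, replicate) uniqueness and sample-id uniqueness."""
    pairs = [(d.stage, d.replicate) for d in design]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (stage, replicate) pair in design")
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in design")


def stage_of(design: Sequence[SampleDesign]) -> pd.Series:
    """Sample-id -> stage mapping as a Series in design order."""
    return pd.Series(
        {d.sample_id: d.stage for d in design},
        index=[d.sample_id for d in design],
    )


@dataclass
class ExpressionMatrix:
    """Features x samples abundance table with unit and design metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative abundances, features as rows, samples as columns.
    unit : str
        One of ``raw_count``, ``SRPBM``, ``TPM``, ``FPKM``.
    design : list of SampleDesign
        One entry per sample column, in column order.
    """

    values: pd.DataFrame
    unit: str
    design: list[SampleDesign] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise UnitError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if arr.size and np.nanmin(arr) < 0:
            raise ValueError("expression values must be non-negative")
        if self.design:
            validate_design(self.design)
            ids = [d.sample_id for d in self.design]
            if list(self.values.columns) != ids:
                raise ValueError(
                    "sample columns do not match the design: "
                    f"{list(self.values.columns)} vs {ids}"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def require_unit(self, *units: str) -> None:
        if self.unit not in units:
            raise UnitError(f"expected unit in {units}, got {self.unit!r}")

    def log2p1(self) -> pd.DataFrame:
        """log2(x + 1) transform used throughout the correlation stages."""
        return np.log2(self.values + 1.0)

    def stage_means(self) -> pd.DataFrame:
        """Average replicates per stage -> features x stages (design order)."""
        if not self.design:
            raise ValueError("stage averaging requires an attached design")
        stages = [s for s in STAGES if any(d.stage == s for d in self.design)]
        cols = {}
        for s in stages:
            ids = [d.sample_id for d in self.design if d.stage == s]
            cols[s] = self.values[ids].mean(axis=1)
        return pd.DataFrame(cols)

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [f for f in feature_ids if f in self.values.index]
        return ExpressionMatrix(self.values.loc[keep], self.unit, list(self.design))
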