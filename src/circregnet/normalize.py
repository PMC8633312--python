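"""The three abundance normalizations used by the expression layers.

circRNA back-splice junction counts are normalized to SRPBM (spliced reads
per billion mapped reads): ``count * 1e9 / mapped_reads``, where the
denominator is the sample's total mapped-read count.  mRNA fragment counts
become FPKM (``count * 1e9 / (total_fragments * length_nt)``) and miRNA read
counts become TPM (length-corrected rates rescaled so each sample sums to
one million).  These are within-sample scalings only; no between-sample size
factors are applied, matching how each of these layers is conventionally quantified.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix


def _mapped_as_array(matrix: ExpressionMatrix, mapped: Sequence[float] | Mapping[str, float]) -> np.ndarray:
    if isinstance(mapped, Mapping):
        missing = [s for s in matrix.sample_ids if s not in mapped]
        if missing:
            raise ValueError(f"no mapped-read total for samples {missing}")
        arr = np.asarray([mapped[s] for s in matrix.sample_ids], dtype=float)
    else:
        arr = np.asarray(list(mapped), dtype=float)
        if arr.size != len(matrix.sample_ids):
            raise ValueError(
                f"expected {len(matrix.sample_ids)} mapped-read totals, got {arr.size}"
            )
    if np.any(arr <= 0):
        raise ValueError("mapped-read totals must be positive")
    return arr


def _lengths_as_array(matrix: ExpressionMatrix, lengths: Sequence[float] | Mapping[str, float]) -> np.ndarray:
    if isinstance(lengths, Mapping):
        missing = [f for f in matrix.feature_ids if f not in lengths]
        if missing:
            raise ValueError(f"no length for features {missing[:5]}")
        arr = np.asarray([lengths[f] for f in matrix.feature_ids], dtype=float)
    else:
        arr = np.asarray(list(lengths), dtype=float)
        if arr.size != len(matrix.feature_ids):
            raise ValueError(
                f"expected {len(matrix.feature_ids)} lengths, got {arr.size}"
            )
    if np.any(arr <= 0):
        raise ValueError("feature lengths must be positive")
    return arr


def srpbm(
    junction_counts: ExpressionMatrix,
    mapped_reads: Sequence[float] | Mapping[str, float],
) -> ExpressionMatrix:
    """BSJ counts -> spliced reads per billion mapped reads."""
    junction_counts.require_unit("raw_count")
    denom = _mapped_as_array(junction_counts, mapped_reads)
    out = junction_counts.values * (1e9 / denom)
    return ExpressionMatrix(out, unit="SRPBM", design=list(junction_counts.design))


def fpkm(
    fragment_counts: ExpressionMatrix,
    feature_lengths_nt: Sequence[float] | Mapping[str, float],
) -> ExpressionMatrix:
    """Fragment counts -> fragments per kilobase per million mapped fragments.

    The per-sample fragment total is the column sum of the count table.
    """
    fragment_counts.require_unit("raw_count")
    lengths = _lengths_as_array(fragment_counts, feature_lengths_nt)
    totals = fragment_counts.values.sum(axis=0).to_numpy(dtype=float)
    if np.any(totals <= 0):
        bad = [s for s, t in zip(fragment_counts.sample_ids, totals) if t <= 0]
        raise ValueError(f"all-zero sample(s) {bad}: FPKM undefined")
    out = fragment_counts.values * 1e9
    out = out.div(totals, axis=1).div(lengths, axis=0)
    return ExpressionMatrix(out, unit="FPKM", design=list(fragment_counts.design))


def tpm(
    read_counts: ExpressionMatrix,
    feature_lengths_nt: Sequence[float] | Mapping[str, float],
) -> ExpressionMatrix:
    """Read counts -> transcripts per million (columns sum to 1e6)."""
    read_counts.require_unit("raw_count")
    lengths = _lengths_as_array(read_counts, feature_lengths_nt)
    rates = read_counts.values.div(lengths, axis=0)
    denom = rates.sum(axis=0).to_numpy(dtype=float)
    if np.any(denom <= 0):
        bad = [s for s, t in zip(read_counts.sample_ids, denom) if t <= 0]
        raise ValueError(f"all-zero sample(s) {bad}: TPM undefined")
    out = rates.mul(1e6 / denom, axis=1)
    return ExpressionMatrix(out, unit="TPM", design=list(read_counts.design))
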