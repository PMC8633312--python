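"""Correlation of circRNAs with their parental genes.

Each circRNA is correlated (Pearson, across all samples, on log2(x + 1)
normalized abundances) with the gene it was back-spliced from.  Pairs with
p < 0.05 are "effective"; effective pairs are classified by correlation
sign (strong negative r < -0.5, strong positive r > 0.5, weak otherwise)
and stratified by circRNA class.  The biological expectation this feeds is
that exonic circles compete with linear splicing of their host (negative
coupling) while intronic circles can promote host transcription (positive
coupling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix
from .annotate import CircRNARecord


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t transform
    (t = r * sqrt((n - 2) / (1 - r^2)), df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def spearman_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Rank-correlation alternative (option flag in the CLI)."""
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class ParentalPair:
    circ_id: str
    gene_id: str
    circ_class: str
    r: float
    p: float

    @property
    def effective(self) -> bool:
        return self.p < 0.05

    @property
    def sign_class(self) -> str:
        if self.r < -0.5:
            return "strong_negative"
        if self.r > 0.5:
            return "strong_positive"
        return "weak"


def classify_pairs(
    pairs: Sequence[tuple[str, str]],
    circ_matrix: ExpressionMatrix,
    gene_matrix: ExpressionMatrix,
    records: Sequence[CircRNARecord] | None = None,
    method: str = "pearson",
) -> tuple[list[ParentalPair], pd.DataFrame, list[tuple[str, str]]]:
    """Correlate circRNA/parental-gene pairs and summarize per class.

    Returns (pairs, class-stratified summary, skipped pairs).  Pairs whose
    members are absent from a matrix are reported as skipped, never
    silently dropped.
    """
    if [d.sample_id for d in circ_matrix.design] != [
        d.sample_id for d in gene_matrix.design
    ]:
        raise ValueError("circ and gene matrices must share the sample design")
    corr = pearson_with_p if method == "pearson" else spearman_with_p
    class_of = {r.circ_id: r.circ_class for r in records or []}

    lc = circ_matrix.log2p1()
    lg = gene_matrix.log2p1()
    out: list[ParentalPair] = []
    skipped: list[tuple[str, str]] = []
    for circ_id, gene_id in pairs:
        if circ_id not in lc.index or gene_id not in lg.index:
            skipped.append((circ_id, gene_id))
            continue
        x = lc.loc[circ_id].to_numpy()
        y = lg.loc[gene_id].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            skipped.append((circ_id, gene_id))
            continue
        r, p = corr(x, y)
        out.append(
            ParentalPair(circ_id, gene_id, class_of.get(circ_id, "unknown"), r, p)
        )

    rows = []
    frame = pd.DataFrame(
        [
            {"circ_id": q.circ_id, "gene_id": q.gene_id, "circ_class": q.circ_class,
             "r": q.r, "p": q.p, "effective": q.effective,
             "sign_class": q.sign_class}
            for q in out
        ]
    )
    if len(frame):
        for cls, sub in frame.groupby("circ_class"):
            eff = sub[sub["effective"]]
            rows.append(
                {"circ_class": cls, "n_pairs": len(sub), "n_effective": len(eff),
                 "n_strong_negative": int((eff["sign_class"] == "strong_negative").sum()),
                 "n_strong_positive": int((eff["sign_class"] == "strong_positive").sum()),
                 "n_weak": int((eff["sign_class"] == "weak").sum()),
                 "median_r_effective": float(eff["r"].median()) if len(eff) else np.nan}
            )
    summary = pd.DataFrame(
        rows, columns=["circ_class", "n_pairs", "n_effective", "n_strong_negative",
                       "n_strong_positive", "n_weak", "median_r_effective"]
    )
    return out, summary, skipped
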