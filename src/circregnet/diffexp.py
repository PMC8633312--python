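"""Stage-adjacent pairwise differential expression.

Each layer is tested between consecutive differentiation stages
(A0 vs A12, A12 vs A48, A48 vs A72, A72 vs A120) with Welch's
unequal-variance t test on log2(x + c) of the normalized abundances
(pseudocount c = 1 by default), and Benjamini–Hochberg adjustment within
each contrast.  Calling thresholds follow the per-layer conventions of the
study design: circRNA and miRNA are called at fold change >= 1.5 and
p < 0.05; mRNA at |log2FC| >= 1 and FDR < 0.01.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import STAGES, ExpressionMatrix

#: layer -> (|log2fc| threshold, p threshold, use FDR instead of raw p)
LAYER_THRESHOLDS: dict[str, tuple[float, float, bool]] = {
    "circRNA": (np.log2(1.5), 0.05, False),
    "miRNA": (np.log2(1.5), 0.05, False),
    "gene": (1.0, 0.01, True),
}


def adjacent_contrasts(design) -> list[tuple[str, str]]:
    """Stage-adjacent contrast pairs present in a design."""
    present = [s for s in STAGES if any(d.stage == s for d in design)]
    return list(zip(present, present[1:]))


def de_test(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
    contrast: str | None = None,
) -> pd.DataFrame:
    """Per-feature log2 fold change (B over A) and Welch-t p value.

    Zero-variance features (constant within both groups) are assigned
    p = 1 so that degenerate features are never called significant; their
    log2fc still follows the pseudocounted mean formula.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if min(len(group_a), len(group_b)) < 2:
        raise ValueError("each group needs >= 2 samples")
    for s in group_a + group_b:
        if s not in matrix.values.columns:
            raise ValueError(f"sample {s!r} not in matrix")

    a = matrix.values[group_a].to_numpy(dtype=float)
    b = matrix.values[group_b].to_numpy(dtype=float)
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    degenerate = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    p = np.where(degenerate, 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)

    out = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "contrast": contrast or "A_vs_B",
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2fc": log2fc,
            "p": p,
        }
    )
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    table: pd.DataFrame,
    layer: str,
    lfc_min: float | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Attach FDR and up/down/ns calls using the layer's thresholds.

    ``lfc_min`` / ``alpha`` override the layer defaults when given.
    """
    if layer not in LAYER_THRESHOLDS:
        raise ValueError(f"unknown layer {layer!r}; expected {list(LAYER_THRESHOLDS)}")
    d_lfc, d_alpha, use_fdr = LAYER_THRESHOLDS[layer]
    lfc_min = d_lfc if lfc_min is None else lfc_min
    alpha = d_alpha if alpha is None else alpha
    out = table.copy()
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    crit = out["fdr"] if use_fdr else out["p"]
    signif = (crit < alpha) & (out["log2fc"].abs() >= lfc_min)
    out["call"] = np.where(
        signif & (out["log2fc"] > 0), "up", np.where(signif, "down", "ns")
    )
    return out


def de_all_contrasts(
    matrix: ExpressionMatrix,
    layer: str,
    pseudocount: float = 1.0,
    lfc_min: float | None = None,
    alpha: float | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Run all stage-adjacent contrasts; return the stacked table and the
    union of differentially expressed feature ids."""
    tables = []
    for sa, sb in adjacent_contrasts(matrix.design):
        ga = [d.sample_id for d in matrix.design if d.stage == sa]
        gb = [d.sample_id for d in matrix.design if d.stage == sb]
        t = de_test(matrix, ga, gb, pseudocount=pseudocount,
                    contrast=f"{sa}_vs_{sb}")
        tables.append(call_de(t, layer, lfc_min=lfc_min, alpha=alpha))
    table = pd.concat(tables, ignore_index=True)
    de_ids = set(table.loc[table["call"] != "ns", "feature_id"])
    return table, de_ids
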