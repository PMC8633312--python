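"""Signed weighted co-expression network construction from scratch.

The workflow mirrors the standard weighted co-expression recipe: a signed
adjacency ``a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta`` (so anti-correlated
features get near-zero weight), a topological overlap matrix

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

average-linkage hierarchical clustering on ``1 - TOM``, a static tree cut,
a minimum module size, and module merging by eigengene correlation.  The
soft power beta is scanned over 1..30 against an approximate scale-free
topology criterion (signed R^2 of the log-log degree distribution), with a
documented fallback of 12, the conventional operating point for signed
networks at this scale, when no power reaches the target fit.

Module eigengenes are first principal components of the standardized module
expression, sign-oriented to correlate positively with the module mean.
Module–trait statistics use one-hot stage indicators; features with
|GS| > 0.8 (feature–stage correlation) and |MM| > 0.8 (feature–eigengene
correlation) in a stage-significant module are flagged as hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .core import STAGES, ExpressionMatrix, SampleDesign

UNASSIGNED = "grey"


# ---------------------------------------------------------------------------
# low-level pieces (exposed for testing against direct-formula oracles)
# ---------------------------------------------------------------------------

def signed_adjacency(corr: np.ndarray, beta: int) -> np.ndarray:
    """((1 + r) / 2) ** beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = ((1.0 + corr) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM from a symmetric adjacency with unit diagonal."""
    a = adjacency
    k = a.sum(axis=0) - 1.0                      # connectivity excludes self
    s = a @ a                                    # includes the two self terms
    shared = s - 2.0 * a                         # sum_{u != i,j} a_iu a_uj
    min_k = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (min_k + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log10 p(k) vs log10 k regression, and the slope."""
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-9, n_bins + 1)
    idx = np.digitize(logk, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(logk[mask].mean())
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2), float(slope)


def pick_soft_threshold(
    values: pd.DataFrame,
    powers: Sequence[int] = tuple(range(1, 31)),
    r2_target: float = 0.8,
    fallback: int = 12,
) -> tuple[int, pd.DataFrame]:
    """Scan powers for approximate scale-free topology.

    Returns the smallest power whose signed fit reaches ``r2_target``; if
    none does, the documented operating-point fallback is returned with a
    warning.  The fit table has one row per scanned power.
    """
    x = _drop_constant(values)
    corr = np.corrcoef(x.to_numpy())
    rows = []
    beta = None
    for p in powers:
        a = signed_adjacency(corr, p)
        k = a.sum(axis=0) - 1.0
        fit, slope = scale_free_fit(k)
        rows.append({"power": p, "fit": fit, "slope": slope,
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
        if beta is None and fit >= r2_target:
            beta = p
    table = pd.DataFrame(rows)
    if beta is None:
        warnings.warn(
            f"no power in {list(powers)[0]}..{list(powers)[-1]} reached "
            f"scale-free fit {r2_target}; falling back to beta={fallback}"
        )
        beta = fallback
    return beta, table


def _drop_constant(values: pd.DataFrame) -> pd.DataFrame:
    sd = values.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant feature(s)")
    return values.loc[~const]


def _module_eigengene(x_std: np.ndarray) -> tuple[np.ndarray, float]:
    """First right singular vector of standardized module expression.

    Sign-oriented to correlate positively with the module mean profile.
    Returns (eigengene over samples, fraction of variance explained).
    """
    u, s, vt = np.linalg.svd(x_std, full_matrices=False)
    eig = vt[0]
    mean_profile = x_std.mean(axis=0)
    if np.corrcoef(eig, mean_profile)[0, 1] < 0:
        eig = -eig
    var_explained = float(s[0] ** 2 / (s**2).sum()) if s.size else 0.0
    return eig, var_explained


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def corr_with_pvalues(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of each x-row against each y-row, with two-sided
    p values from the t transform (df = n - 2)."""
    n = x.shape[1]
    xs = _standardize_rows(x)
    ys = _standardize_rows(y)
    r = np.clip(xs @ ys.T / n, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return r, p


@dataclass
class ModuleStats:
    """Module–trait correlations and per-feature GS/MM tables."""

    module_trait_r: pd.DataFrame      # modules x stages
    module_trait_p: pd.DataFrame
    gs: pd.DataFrame                  # features x stages
    mm: pd.DataFrame                  # features x modules
    hubs: pd.DataFrame                # feature, module, stage, gs, mm


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class CoexpressionNetwork(BaseEstimator):
    """Signed co-expression network with module detection.

    Parameters
    ----------
    power : "auto" or int, default "auto"
        Soft-threshold power; "auto" scans 1..30 for scale-free fit.
    r2_target : float, default 0.8
        Scale-free fit required when power="auto".
    min_module_size : int, default 30
        Smaller clusters go to the unassigned ("grey") label.
    merge_cut_height : float, default 0.25
        Modules whose eigengene dissimilarity 1 - r falls below this are
        merged.
    cut_height : float, default 0.92
        Static tree-cut height on the 1 - TOM dendrogram.  Co-regulated
        families complete their subtrees well below this, while mutually
        unrelated features merge close to 1; cutting between the two
        regimes sends noise features to the unassigned label.
    log_transform : bool, default True
        Apply log2(x + 1) when fitting an ExpressionMatrix.

    Attributes (after fit)
    ----------------------
    beta_, fit_table_, adjacency_, tom_, module_labels_, eigengenes_,
    eigengene_variance_, feature_ids_
    """

    def __init__(self, power: int | str = "auto", r2_target: float = 0.8,
                 min_module_size: int = 30, merge_cut_height: float = 0.25,
                 cut_height: float = 0.92, log_transform: bool = True):
        self.power = power
        self.r2_target = r2_target
        self.min_module_size = min_module_size
        self.merge_cut_height = merge_cut_height
        self.cut_height = cut_height
        self.log_transform = log_transform

    # ------------------------------------------------------------------
    def fit(self, X: ExpressionMatrix | pd.DataFrame, y=None):
        if isinstance(X, ExpressionMatrix):
            values = X.log2p1() if self.log_transform else X.values.copy()
            self.design_ = list(X.design)
        else:
            values = pd.DataFrame(X, dtype=float)
            self.design_ = []
        values = _drop_constant(values)
        if values.shape[1] < 3:
            raise ValueError("need >= 3 samples to correlate features")
        self.X_ = values
        self.feature_ids_ = list(values.index)

        corr = np.corrcoef(values.to_numpy())
        if self.power == "auto":
            self.beta_, self.fit_table_ = pick_soft_threshold(
                values, r2_target=self.r2_target
            )
        else:
            self.beta_ = int(self.power)
            self.fit_table_ = None
        self.adjacency_ = signed_adjacency(corr, self.beta_)
        self.tom_ = topological_overlap(self.adjacency_)
        self._detect_modules()
        return self

    # ------------------------------------------------------------------
    def _detect_modules(self) -> None:
        n = len(self.feature_ids_)
        if n < self.min_module_size:
            warnings.warn("fewer features than min_module_size: all unassigned")
            self.module_labels_ = pd.Series(UNASSIGNED, index=self.feature_ids_)
            self.eigengenes_ = pd.DataFrame(index=self._sample_index())
            self.eigengene_variance_ = {}
            return

        diss = 1.0 - self.tom_
        np.fill_diagonal(diss, 0.0)
        z = linkage(squareform(diss, checks=False), method="average")
        raw = fcluster(z, t=self.cut_height, criterion="distance")

        members: dict[int, list[int]] = {}
        for i, c in enumerate(raw):
            members.setdefault(int(c), []).append(i)
        modules = [idx for idx in members.values() if len(idx) >= self.min_module_size]
        modules = self._merge_modules(modules)

        modules.sort(key=len, reverse=True)
        labels = pd.Series(UNASSIGNED, index=self.feature_ids_, dtype=object)
        eig_cols, var_expl = {}, {}
        x = self.X_.to_numpy()
        for rank, idx in enumerate(modules, start=1):
            name = f"M{rank}"
            labels.iloc[idx] = name
            eig, ve = _module_eigengene(_standardize_rows(x[idx]))
            eig_cols[name] = eig
            var_expl[name] = ve
        self.module_labels_ = labels
        self.eigengenes_ = pd.DataFrame(eig_cols, index=self._sample_index())
        self.eigengene_variance_ = var_expl

    def _merge_modules(self, modules: list[list[int]]) -> list[list[int]]:
        """Iteratively merge module pairs with eigengene dissimilarity
        1 - r below merge_cut_height."""
        x = self.X_.to_numpy()
        while len(modules) > 1:
            eigs = np.vstack(
                [_module_eigengene(_standardize_rows(x[idx]))[0] for idx in modules]
            )
            r = np.corrcoef(eigs)
            np.fill_diagonal(r, -np.inf)
            i, j = np.unravel_index(np.argmax(r), r.shape)
            if 1.0 - r[i, j] >= self.merge_cut_height:
                break
            merged = sorted(modules[i] + modules[j])
            modules = [m for t, m in enumerate(modules) if t not in (i, j)]
            modules.append(merged)
        return modules

    def _sample_index(self):
        return self.X_.columns

    # ------------------------------------------------------------------
    def module_stats(
        self,
        design: Sequence[SampleDesign] | None = None,
        gs_min: float = 0.8,
        mm_min: float = 0.8,
        trait_p_max: float = 0.01,
    ) -> ModuleStats:
        """Module–trait correlations, GS/MM tables and hub calls."""
        design = list(design) if design is not None else self.design_
        if not design:
            raise ValueError("a sample design is required for module statistics")
        stages = [s for s in STAGES if any(d.stage == s for d in design)]
        for s in stages:
            if sum(d.stage == s for d in design) == 0:
                raise ValueError(f"stage {s} has no samples")
        indicators = np.vstack(
            [[1.0 if d.stage == s else 0.0 for d in design] for s in stages]
        )

        x = self.X_.to_numpy()
        gs_r, _ = corr_with_pvalues(x, indicators)
        gs = pd.DataFrame(gs_r, index=self.feature_ids_, columns=stages)

        modules = list(self.eigengenes_.columns)
        if modules:
            eig = self.eigengenes_.to_numpy().T
            mt_r, mt_p = corr_with_pvalues(eig, indicators)
            mm_r, _ = corr_with_pvalues(x, eig)
        else:
            mt_r = mt_p = np.zeros((0, len(stages)))
            mm_r = np.zeros((len(self.feature_ids_), 0))
        module_trait_r = pd.DataFrame(mt_r, index=modules, columns=stages)
        module_trait_p = pd.DataFrame(mt_p, index=modules, columns=stages)
        mm = pd.DataFrame(mm_r, index=self.feature_ids_, columns=modules)

        hub_rows = []
        for f in self.feature_ids_:
            m = self.module_labels_[f]
            if m == UNASSIGNED:
                continue
            for s in stages:
                if (
                    module_trait_p.loc[m, s] < trait_p_max
                    and abs(gs.loc[f, s]) > gs_min
                    and abs(mm.loc[f, m]) > mm_min
                ):
                    hub_rows.append(
                        {"feature_id": f, "module": m, "stage": s,
                         "gs": gs.loc[f, s], "mm": mm.loc[f, m]}
                    )
        hubs = pd.DataFrame(hub_rows,
                            columns=["feature_id", "module", "stage", "gs", "mm"])
        return ModuleStats(module_trait_r, module_trait_p, gs, mm, hubs)

    # ------------------------------------------------------------------
    def export_top_edges(self, module: str, n_edges: int = 200) -> pd.DataFrame:
        """Strongest intra-module TOM edges, ties broken lexicographically."""
        if module not in set(self.module_labels_):
            raise ValueError(f"unknown module {module!r}")
        idx = [i for i, f in enumerate(self.feature_ids_)
               if self.module_labels_.iloc[i] == module]
        rows = []
        for ai in range(len(idx)):
            for bi in range(ai + 1, len(idx)):
                i, j = idx[ai], idx[bi]
                u, v = sorted((self.feature_ids_[i], self.feature_ids_[j]))
                rows.append((u, v, float(self.tom_[i, j])))
        rows.sort(key=lambda r: (-r[2], r[0], r[1]))
        return pd.DataFrame(rows[:n_edges], columns=["source", "target", "weight"])


def build_tom(values: pd.DataFrame, beta: int) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper: (signed adjacency, TOM) for a features x samples
    table; constant features are an error here (pre-filter them)."""
    sd = values.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = list(values.index[sd == 0])[:5]
        raise ValueError(f"zero-variance features {bad}: filter before build_tom")
    a = signed_adjacency(np.corrcoef(values.to_numpy()), beta)
    return a, topological_overlap(a)
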