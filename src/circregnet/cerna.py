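"""Seed-match MRE prediction and ceRNA triplet assembly.

Target sites are canonical seed matches: a 6mer core pairs target sequence
to miRNA positions 2–7; extending the match to position 8 gives 7mer-m8; an
adenosine opposite miRNA position 1 gives 7mer-A1; both together give an
8mer.  The scanner reports the best class at each core position and can be
floored at a minimum class (default 7mer, i.e. 6mers are discarded).
circRNA targets are scanned on the circle: the spliced sequence is extended
by a short window across the back-splice junction so that sites spanning
the junction — which are real on the circle — are found.

A ceRNA triplet (circRNA, miRNA, mRNA) is emitted when the miRNA has an MRE
on both the circRNA and the gene's 3'UTR, circRNA–miRNA and miRNA–mRNA are
negatively correlated, circRNA–mRNA is positively correlated, and all three
correlations reach p < p_max (0.05 by default), with membership restricted
to differentially expressed features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import ExpressionMatrix
from .parental import pearson_with_p

SEED_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
_CLASS_RANK = {c: i for i, c in enumerate(SEED_CLASSES)}

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _norm_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _revcomp(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MRESite:
    mir_id: str
    target_id: str
    target_kind: str          # "circRNA" or "utr3"
    position: int             # 1-based start of the seed-match core
    seed_class: str


def find_mre_sites(
    mir_sequences: Mapping[str, str],
    target_sequences: Mapping[str, str],
    target_kind: str,
    min_seed_class: str = "7mer-A1",
    bsj_window: int = 7,
) -> list[MRESite]:
    """Scan targets for seed-complementary sites of each miRNA.

    ``position`` is the 1-based start of the full matched site on the
    target (for 7mer-m8/8mer the site begins one nt upstream of the 6mer
    core, at the nucleotide pairing miRNA position 8).  For circRNA targets
    the scan extends ``bsj_window`` nt across the back-splice junction so
    junction-spanning sites are found; their positions stay within 1..L.
    """
    if not mir_sequences or not target_sequences:
        raise ValueError("empty sequence set")
    if min_seed_class not in _CLASS_RANK:
        raise ValueError(f"unknown seed class {min_seed_class!r}")
    if target_kind not in ("circRNA", "utr3"):
        raise ValueError(f"target_kind must be circRNA or utr3, got {target_kind!r}")
    min_rank = _CLASS_RANK[min_seed_class]

    sites: list[MRESite] = []
    for mir_id in sorted(mir_sequences):
        mseq = _norm_dna(mir_sequences[mir_id])
        if len(mseq) < 8:
            raise ValueError(f"miRNA {mir_id!r} shorter than 8 nt")
        core = _revcomp(mseq[1:7])       # complements positions 2-7
        m8 = _revcomp(mseq[7])           # complement of position 8
        for tid in sorted(target_sequences):
            tseq = _norm_dna(target_sequences[tid])
            L = len(tseq)
            scan = tseq + tseq[:bsj_window] if target_kind == "circRNA" else tseq
            start = 0
            while True:
                i = scan.find(core, start)
                if i < 0 or i >= L:
                    break
                start = i + 1
                has_m8 = i >= 1 and scan[i - 1] == m8
                has_a1 = i + 6 < len(scan) and scan[i + 6] == "A"
                if has_m8 and has_a1:
                    cls = "8mer"
                elif has_m8:
                    cls = "7mer-m8"
                elif has_a1:
                    cls = "7mer-A1"
                else:
                    cls = "6mer"
                if _CLASS_RANK[cls] >= min_rank:
                    full_start = i - 1 if has_m8 else i
                    sites.append(
                        MRESite(mir_id, tid, target_kind, full_start + 1, cls)
                    )
    return sites


# ---------------------------------------------------------------------------
# triplet assembly
# ---------------------------------------------------------------------------

@dataclass
class CeRNATriplet:
    circ_id: str
    mir_id: str
    gene_id: str
    r_circ_gene: float
    p_circ_gene: float
    r_circ_mir: float
    p_circ_mir: float
    r_mir_gene: float
    p_mir_gene: float
    circ_site: MRESite
    gene_site: MRESite


def _pairwise_corr(a: pd.DataFrame, b: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """r and p for every (row of a, row of b) pair; constant rows get r=0, p=1."""
    from .network import corr_with_pvalues

    r, p = corr_with_pvalues(a.to_numpy(), b.to_numpy())
    const_a = a.std(axis=1, ddof=0).to_numpy() == 0
    const_b = b.std(axis=1, ddof=0).to_numpy() == 0
    mask = const_a[:, None] | const_b[None, :]
    return np.where(mask, 0.0, r), np.where(mask, 1.0, p)


def build_cerna(
    de_circ: Iterable[str],
    de_mir: Iterable[str],
    de_gene: Iterable[str],
    circ_matrix: ExpressionMatrix,
    mir_matrix: ExpressionMatrix,
    gene_matrix: ExpressionMatrix,
    sites: Iterable[MRESite],
    p_max: float = 0.05,
    require_de: bool = True,
) -> list[CeRNATriplet]:
    """Assemble correlation-constrained sponge triplets.

    Candidate circRNA–miRNA pairs need an MRE on the circle and r < 0 with
    p < p_max; miRNA–mRNA pairs need a 3'UTR MRE and r < 0 with p < p_max;
    the circRNA–mRNA pair must satisfy r > 0 with p < p_max.
    """
    designs = [tuple(d.sample_id for d in m.design)
               for m in (circ_matrix, mir_matrix, gene_matrix)]
    if len(set(designs)) != 1:
        raise ValueError("the three matrices must share one sample design")

    sites = list(sites)
    circ_sites: dict[tuple[str, str], MRESite] = {}
    utr_sites: dict[tuple[str, str], MRESite] = {}
    for s in sites:
        bucket = circ_sites if s.target_kind == "circRNA" else utr_sites
        key = (s.mir_id, s.target_id)
        prev = bucket.get(key)
        if prev is None or _CLASS_RANK[s.seed_class] > _CLASS_RANK[prev.seed_class]:
            bucket[key] = s

    def _members(ids: Iterable[str], matrix: ExpressionMatrix) -> list[str]:
        pool = set(ids) if require_de else set(matrix.feature_ids)
        return [f for f in matrix.feature_ids if f in pool]

    circs = _members(de_circ, circ_matrix)
    mirs = _members(de_mir, mir_matrix)
    genes = _members(de_gene, gene_matrix)
    if not circs or not mirs or not genes:
        return []

    lc = circ_matrix.log2p1().loc[circs]
    lm = mir_matrix.log2p1().loc[mirs]
    lg = gene_matrix.log2p1().loc[genes]
    r_cm, p_cm = _pairwise_corr(lc, lm)
    r_mg, p_mg = _pairwise_corr(lm, lg)
    r_cg, p_cg = _pairwise_corr(lc, lg)
    ci = {f: i for i, f in enumerate(circs)}
    mi = {f: i for i, f in enumerate(mirs)}
    gi = {f: i for i, f in enumerate(genes)}

    triplets: list[CeRNATriplet] = []
    for m in mirs:
        circ_partners = [
            c for c in circs
            if (m, c) in circ_sites
            and r_cm[ci[c], mi[m]] < 0 and p_cm[ci[c], mi[m]] < p_max
        ]
        if not circ_partners:
            continue
        gene_partners = [
            g for g in genes
            if (m, g) in utr_sites
            and r_mg[mi[m], gi[g]] < 0 and p_mg[mi[m], gi[g]] < p_max
        ]
        for c in circ_partners:
            for g in gene_partners:
                if r_cg[ci[c], gi[g]] > 0 and p_cg[ci[c], gi[g]] < p_max:
                    triplets.append(
                        CeRNATriplet(
                            c, m, g,
                            float(r_cg[ci[c], gi[g]]), float(p_cg[ci[c], gi[g]]),
                            float(r_cm[ci[c], mi[m]]), float(p_cm[ci[c], mi[m]]),
                            float(r_mg[mi[m], gi[g]]), float(p_mg[mi[m], gi[g]]),
                            circ_sites[(m, c)], utr_sites[(m, g)],
                        )
                    )
    return triplets


def audit_triplets(triplets: Iterable[CeRNATriplet], p_max: float = 0.05) -> bool:
    """Independent re-check that every emitted triplet satisfies all five
    conditions (three p values below p_max, the two negative signs, the
    positive circ–gene sign, shared miRNA on both sites)."""
    for t in triplets:
        ok = (
            t.r_circ_gene > 0 and t.r_circ_mir < 0 and t.r_mir_gene < 0
            and t.p_circ_gene < p_max and t.p_circ_mir < p_max
            and t.p_mir_gene < p_max
            and t.circ_site.mir_id == t.mir_id == t.gene_site.mir_id
            and t.circ_site.target_id == t.circ_id
            and t.gene_site.target_id == t.gene_id
        )
        if not ok:
            return False
    return True


def triplets_to_frame(triplets: Iterable[CeRNATriplet]) -> pd.DataFrame:
    rows = [
        {"circ_id": t.circ_id, "mir_id": t.mir_id, "gene_id": t.gene_id,
         "r_circ_gene": t.r_circ_gene, "p_circ_gene": t.p_circ_gene,
         "r_circ_mir": t.r_circ_mir, "p_circ_mir": t.p_circ_mir,
         "r_mir_gene": t.r_mir_gene, "p_mir_gene": t.p_mir_gene,
         "circ_site_pos": t.circ_site.position,
         "circ_site_class": t.circ_site.seed_class,
         "gene_site_pos": t.gene_site.position,
         "gene_site_class": t.gene_site.seed_class}
        for t in triplets
    ]
    return pd.DataFrame(
        rows, columns=["circ_id", "mir_id", "gene_id", "r_circ_gene", "p_circ_gene",
                       "r_circ_mir", "p_circ_mir", "r_mir_gene", "p_mir_gene",
                       "circ_site_pos", "circ_site_class", "gene_site_pos",
                       "gene_site_class"]
    )


def cerna_graph(triplets: Iterable[CeRNATriplet], tf_genes: set[str] | None = None):
    """Typed-node network export data: (nodes, edges) for io.write_network."""
    tf_genes = tf_genes or set()
    nodes: dict[str, dict] = {}
    edges = []
    for t in triplets:
        nodes[t.circ_id] = {"kind": "circRNA"}
        nodes[t.mir_id] = {"kind": "miRNA"}
        nodes[t.gene_id] = {
            "kind": "transcription_factor" if t.gene_id in tf_genes else "gene"
        }
        edges.append((t.circ_id, t.mir_id,
                      {"weight": abs(t.r_circ_mir), "interaction": "sponges"}))
        edges.append((t.mir_id, t.gene_id,
                      {"weight": abs(t.r_mir_gene), "interaction": "targets"}))
        edges.append((t.circ_id, t.gene_id,
                      {"weight": t.r_circ_gene, "interaction": "coexpressed"}))
    return [(n, a) for n, a in nodes.items()], edges
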