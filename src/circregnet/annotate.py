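"""circRNA classification against gene models and cohort characterization.

A back-splice locus is classified as *exonic* when both junction endpoints
coincide (within a small tolerance) with annotated exon boundaries of one
gene, *intronic* when it lies entirely within a single intron, and
*intergenic* otherwise.  Spliced length of an exonic circle is the sum of
the overlapped exon segments, not the genomic span — a circle spanning four
exons of a 3.5 kb locus may be only ~650 nt of spliced sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import STAGES, ExpressionMatrix
from .io import CircLocus, GeneModel


@dataclass
class CircRNARecord:
    locus: CircLocus
    circ_class: str                 # exonic | intronic | intergenic
    parental_gene: str | None
    spliced_length_nt: int
    exon_count: int

    def __post_init__(self) -> None:
        if self.circ_class not in ("exonic", "intronic", "intergenic"):
            raise ValueError(f"unknown circRNA class {self.circ_class!r}")
        if self.circ_class == "exonic" and (
            self.exon_count < 1 or self.parental_gene is None
        ):
            raise ValueError("exonic circRNA needs >=1 exon and a parental gene")
        if self.circ_class == "intergenic" and self.exon_count != 0:
            raise ValueError("intergenic circRNA cannot have exons")

    @property
    def circ_id(self) -> str:
        return str(self.locus)


def classify_circ(
    locus: CircLocus,
    genes: Sequence[GeneModel],
    boundary_tolerance: int = 2,
    nearest_gene_window: int = 10_000,
) -> CircRNARecord:
    """Assign one of the three classes to a back-splice locus.

    ``boundary_tolerance`` absorbs small caller offsets at exon boundaries;
    intergenic circles are assigned the nearest gene within
    ``nearest_gene_window`` nt as parental gene, or none.
    """
    chrom_genes = [g for g in genes if g.chrom == locus.chrom]
    if not genes:
        raise ValueError("no annotation loaded")
    if not chrom_genes:
        warnings.warn(
            f"chromosome {locus.chrom!r} absent from annotation; "
            f"classifying {locus} as intergenic"
        )
        return CircRNARecord(locus, "intergenic", None, locus.span, 0)

    tol = boundary_tolerance
    # 1) exact-boundary exonic
    for g in chrom_genes:
        starts = [s for s, _ in g.exons]
        ends = [e for _, e in g.exons]
        if any(abs(locus.start - s) <= tol for s in starts) and any(
            abs(locus.end - e) <= tol for e in ends
        ):
            segs = _overlapped_segments(locus, g, tol)
            if segs:
                return CircRNARecord(
                    locus, "exonic", g.gene_id,
                    sum(e - s + 1 for s, e in segs), len(segs),
                )
    # 2) fully inside a single intron
    for g in chrom_genes:
        for s, e in g.introns():
            if s <= locus.start and locus.end <= e:
                return CircRNARecord(locus, "intronic", g.gene_id, locus.span, 0)
    # 3) boundary-imprecise exonic: overlaps at least one exon
    for g in chrom_genes:
        segs = _overlapped_segments(locus, g, 0)
        if segs:
            return CircRNARecord(
                locus, "exonic", g.gene_id,
                sum(e - s + 1 for s, e in segs), len(segs),
            )
    # 4) inside the gene span but touching no exon (treated as intronic)
    for g in chrom_genes:
        if g.start <= locus.start and locus.end <= g.end:
            return CircRNARecord(locus, "intronic", g.gene_id, locus.span, 0)
    # 5) intergenic: nearest gene within the window, else none
    best, best_d = None, None
    for g in chrom_genes:
        d = max(g.start - locus.end, locus.start - g.end, 0)
        if best_d is None or d < best_d:
            best, best_d = g, d
    parental = best.gene_id if best is not None and best_d <= nearest_gene_window else None
    return CircRNARecord(locus, "intergenic", parental, locus.span, 0)


def _overlapped_segments(
    locus: CircLocus, gene: GeneModel, tol: int
) -> list[tuple[int, int]]:
    lo, hi = locus.start - tol, locus.end + tol
    segs = []
    for s, e in gene.exons:
        a, b = max(s, lo), min(e, hi)
        if a <= b:
            segs.append((max(s, locus.start - tol), min(e, locus.end + tol)))
    return segs


# ---------------------------------------------------------------------------
# cohort characterization
# ---------------------------------------------------------------------------

LENGTH_BIN_EDGES = list(range(0, 3001, 200))  # 200-nt bins up to 3000, then >3000


@dataclass
class CohortSummary:
    n_total: int
    class_counts: dict[str, int]
    class_fractions: dict[str, float]
    length_histogram: dict[str, int]
    chromosome_counts: dict[str, int]
    circs_per_parental_gene: dict[int, int]
    exon_count_histogram: dict[int, int]
    single_parental_gene_count: int
    single_parental_gene_fraction: float
    per_stage_detected: dict[str, int] = field(default_factory=dict)
    stage_specific_counts: dict[str, int] = field(default_factory=dict)


def detect_per_stage(
    counts: ExpressionMatrix, min_detect_reads: int = 1
) -> dict[str, set[str]]:
    """Detection rule: junction count >= min_detect_reads in >=1 replicate."""
    counts.require_unit("raw_count")
    out: dict[str, set[str]] = {}
    for stage in STAGES:
        ids = [d.sample_id for d in counts.design if d.stage == stage]
        if not ids:
            continue
        mask = (counts.values[ids] >= min_detect_reads).any(axis=1)
        out[stage] = set(counts.values.index[mask])
    return out


def characterize_cohort(
    records: Sequence[CircRNARecord],
    per_stage_detection: Mapping[str, Iterable[str]] | None = None,
) -> CohortSummary:
    """Fig.2-style cohort accounting from classified records."""
    if not records:
        raise ValueError("cohort is empty")
    n = len(records)
    classes = pd.Series([r.circ_class for r in records])
    class_counts = classes.value_counts().to_dict()
    class_fracs = {k: round(100.0 * v / n, 2) for k, v in class_counts.items()}

    lengths = np.array([r.spliced_length_nt for r in records])
    hist: dict[str, int] = {}
    for lo, hi in zip(LENGTH_BIN_EDGES[:-1], LENGTH_BIN_EDGES[1:]):
        hist[f"{lo + 1}-{hi}"] = int(((lengths > lo) & (lengths <= hi)).sum())
    hist[">3000"] = int((lengths > 3000).sum())

    chrom_counts = pd.Series([r.locus.chrom for r in records]).value_counts().to_dict()

    per_gene = pd.Series(
        [r.parental_gene for r in records if r.parental_gene is not None]
    ).value_counts()
    circs_per_gene = per_gene.value_counts().sort_index()
    single = int(circs_per_gene.get(1, 0))

    exon_hist = pd.Series([r.exon_count for r in records]).value_counts().sort_index()

    summary = CohortSummary(
        n_total=n,
        class_counts=class_counts,
        class_fractions=class_fracs,
        length_histogram=hist,
        chromosome_counts=chrom_counts,
        circs_per_parental_gene={int(k): int(v) for k, v in circs_per_gene.items()},
        exon_count_histogram={int(k): int(v) for k, v in exon_hist.items()},
        single_parental_gene_count=single,
        single_parental_gene_fraction=round(100.0 * single / n, 2),
    )

    if per_stage_detection is not None:
        detected = {s: set(v) for s, v in per_stage_detection.items()}
        summary.per_stage_detected = {s: len(v) for s, v in detected.items()}
        for s in detected:
            others: set[str] = set()
            for o, v in detected.items():
                if o != s:
                    others |= v
            summary.stage_specific_counts[s] = len(detected[s] - others)
    return summary


# ---------------------------------------------------------------------------
# library QC arithmetic (per-sample sequencing table)
# ---------------------------------------------------------------------------

def summarize_library_qc(table: pd.DataFrame) -> dict[str, float]:
    """Cohort-level arithmetic over a per-library sequencing QC table.

    Expects columns ``clean_base_gb``, ``clean_reads``, ``mapped_reads``,
    ``unique_map_reads``, ``gc_pct``, ``q20_pct``, ``q30_pct``.  Mapping
    ratios are recomputed from the read counts, not taken from any
    pre-formatted percentage column.
    """
    req = {"clean_base_gb", "clean_reads", "mapped_reads", "unique_map_reads",
           "gc_pct", "q30_pct"}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"QC table missing columns {sorted(missing)}")
    mapped_ratio = 100.0 * table["mapped_reads"] / table["clean_reads"]
    unique_ratio = 100.0 * table["unique_map_reads"] / table["clean_reads"]
    return {
        "n_libraries": int(len(table)),
        "total_clean_base_gb": round(float(table["clean_base_gb"].sum()), 2),
        "mean_gc_pct": round(float(table["gc_pct"].mean()), 2),
        "q30_min_pct": round(float(table["q30_pct"].min()), 2),
        "q30_max_pct": round(float(table["q30_pct"].max()), 2),
        "mapped_ratio_min_pct": round(float(mapped_ratio.min()), 2),
        "mapped_ratio_max_pct": round(float(mapped_ratio.max()), 2),
        "unique_map_ratio_min_pct": round(float(unique_ratio.min()), 2),
        "unique_map_ratio_max_pct": round(float(unique_ratio.max()), 2),
    }


def load_example_library_qc() -> pd.DataFrame:
    """The 15-library sequencing QC table of the chicken abdominal
    adipocyte differentiation cohort (5 stages x 3 replicates)."""
    from importlib.resources import files

    path = files("circregnet").joinpath("data/chicken_adipocyte_library_qc.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")
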