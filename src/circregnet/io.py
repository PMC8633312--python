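"""Readers and writers for the on-disk formats.

circRNAs are named by their back-splice locus in the ``chrom:start|end``
convention of the upstream junction callers (1-based, inclusive on both
ends), e.g. ``Z:35565770|35568133``.  Expression tables are plain TSV with a
header row of sample ids; the abundance unit and sample design travel in a
JSON sidecar next to the table.  Gene annotation is a "GTF-lite" subset of
GTF: tab-separated 9-column rows whose feature field is ``gene`` or ``exon``
and whose attribute field carries at least ``gene_id``.

All readers reject malformed input with a :class:`~circregnet.core.FormatError`
naming the offending row or token rather than silently coercing it.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ExpressionMatrix, FormatError, SampleDesign, validate_design

_CIRC_ID_RE = re.compile(r"^(?P<chrom>[^:|\s]+):(?P<start>\d+)\|(?P<end>\d+)$")


@dataclass(frozen=True)
class CircLocus:
    """Back-splice locus, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise FormatError("empty chromosome name")
        if self.start > self.end:
            raise FormatError(
                f"start {self.start} > end {self.end} in circRNA locus"
            )

    @property
    def span(self) -> int:
        """Genomic span in nt (end - start + 1)."""
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}|{self.end}"


def parse_circ_id(id_text: str) -> CircLocus:
    """Parse ``chrom:start|end`` into a :class:`CircLocus`.

    >>> parse_circ_id("Z:35565770|35568133")
    CircLocus(chrom='Z', start=35565770, end=35568133)
    """
    m = _CIRC_ID_RE.match(id_text.strip())
    if m is None:
        raise FormatError(f"malformed circRNA id {id_text!r}; expected chrom:start|end")
    return CircLocus(m.group("chrom"), int(m.group("start")), int(m.group("end")))


@dataclass
class GeneModel:
    """Gene with sorted, non-overlapping exons (1-based inclusive)."""

    gene_id: str
    chrom: str
    strand: str = "."
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise FormatError(f"gene {self.gene_id!r} has no exons")
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"bad strand {self.strand!r} for gene {self.gene_id!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise FormatError(f"overlapping exons in gene {self.gene_id!r}")
        for s, e in self.exons:
            if s > e:
                raise FormatError(f"exon start > end in gene {self.gene_id!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a features x samples TSV plus a JSON sidecar (unit + design)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")
    meta = {
        "unit": matrix.unit,
        "design": [
            {"sample_id": d.sample_id, "stage": d.stage, "replicate": d.replicate}
            for d in matrix.design
        ],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_expression_tsv(path: str | Path, unit: str | None = None) -> ExpressionMatrix:
    """Read a TSV expression table; unit/design come from the sidecar if present."""
    path = Path(path)
    design: list[SampleDesign] = []
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        unit = unit or meta.get("unit")
        design = [SampleDesign(**d) for d in meta.get("design", [])]
    if unit is None:
        raise FormatError(f"no unit given and no sidecar found for {path}")

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: header row has no sample columns")
        n_cols = len(header)
        rows, ids = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise FormatError(f"{path}: ragged row at line {lineno}")
            ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric cell at line {lineno}: {exc}"
                ) from None
    frame = pd.DataFrame(rows, columns=header[1:])
    frame.index = pd.Index(ids, name=header[0])
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    return ExpressionMatrix(frame, unit=unit, design=design)


def read_sample_sheet(path: str | Path) -> list[SampleDesign]:
    """JSON sample sheet: list of {sample_id, stage, replicate}."""
    raw = json.loads(Path(path).read_text())
    design = [SampleDesign(**d) for d in raw]
    validate_design(design)
    return design


def write_sample_sheet(design: Sequence[SampleDesign], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {"sample_id": d.sample_id, "stage": d.stage, "replicate": d.replicate}
                for d in design
            ],
            indent=1,
        )
    )


# ---------------------------------------------------------------------------
# annotation and sequences
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_gtf_lite(path: str | Path) -> list[GeneModel]:
    """Parse the gene/exon GTF subset into :class:`GeneModel` records."""
    path = Path(path)
    found: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns")
            chrom, _, feature, start, end, _, strand, _, attrs = parts
            if feature not in ("gene", "exon"):
                continue
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                raise FormatError(f"{path}: line {lineno}: missing gene_id attribute")
            gid = m.group(1)
            if gid not in found:
                found[gid] = {
                    "chrom": chrom,
                    "strand": strand if strand in "+-" else ".",
                    "exons": [],
                }
                order.append(gid)
            if feature == "exon":
                found[gid]["exons"].append((int(start), int(end)))
    genes = []
    for gid in order:
        g = found[gid]
        if not g["exons"]:
            raise FormatError(f"{path}: gene {gid!r} has no exon rows")
        genes.append(GeneModel(gid, g["chrom"], g["strand"], g["exons"]))
    return genes


def write_gtf_lite(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = []
    for g in genes:
        attr = f'gene_id "{g.gene_id}";'
        lines.append(
            "\t".join(
                [g.chrom, "circregnet", "gene", str(g.start), str(g.end), ".",
                 g.strand, ".", attr]
            )
        )
        for s, e in g.exons:
            lines.append(
                "\t".join(
                    [g.chrom, "circregnet", "exon", str(s), str(e), ".",
                     g.strand, ".", attr]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> id: sequence map; duplicate ids are rejected."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")  # Biopython wraps at 60 columns


# ---------------------------------------------------------------------------
# network export (for Cytoscape-style tools)
# ---------------------------------------------------------------------------

def write_network(
    nodes: Iterable[str | tuple[str, Mapping[str, object]]],
    edges: Iterable[tuple[str, str] | tuple[str, str, Mapping[str, object]]],
    path: str | Path,
    fmt: str = "graphml",
) -> None:
    """Export a network as GraphML, SIF or a weighted edge TSV.

    ``nodes`` may be bare ids or (id, attrs); ``edges`` (u, v) or (u, v, attrs)
    where attrs may include ``weight`` and ``interaction``.
    """
    g = nx.Graph()
    for n in nodes:
        if isinstance(n, tuple):
            g.add_node(n[0], **dict(n[1]))
        else:
            g.add_node(n)
    for e in edges:
        if len(e) == 3:
            g.add_edge(e[0], e[1], **dict(e[2]))
        else:
            g.add_edge(e[0], e[1])

    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, str(path))
    elif fmt == "sif":
        lines = [
            f"{u}\t{d.get('interaction', 'co')}\t{v}" for u, v, d in g.edges(data=True)
        ]
        lines += [f"{n}" for n in g.nodes if g.degree(n) == 0]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "tsv":
        rows = [
            {"source": u, "target": v, "weight": d.get("weight", 1.0),
             "interaction": d.get("interaction", "co")}
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight", "interaction"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format {fmt!r} (graphml, sif, tsv)")
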