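"""End-to-end orchestration: simulate (or ingest) -> normalize -> annotate
-> differential expression -> pattern clustering -> co-expression network
-> parental correlation -> ceRNA assembly -> circular-ORF screening.

A single :class:`PipelineConfig` (JSON-serializable, unknown keys rejected)
drives the run; every stage writes its outputs under the run directory and
is listed in a manifest with content hashes, so identical configurations
reproduce identical runs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .annotate import characterize_cohort, classify_circ, detect_per_stage
from .cerna import (audit_triplets, build_cerna, cerna_graph, find_mre_sites,
                    triplets_to_frame)
from .diffexp import de_all_contrasts
from .io import (parse_circ_id, read_expression_tsv, read_fasta, read_gtf_lite,
                 write_expression_tsv, write_fasta, write_gtf_lite,
                 write_network, write_sample_sheet)
from .network import CoexpressionNetwork
from .normalize import fpkm, srpbm, tpm
from .orf import coding_potential, find_orfs_per_circle
from .parental import classify_pairs
from .patterns import StagePatternClustering
from .simulate import SimulationConfig, simulate_dataset


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


class PipelineConfig(BaseModel):
    """All pipeline parameters with the analysis's operating-point defaults."""

    model_config = ConfigDict(extra="forbid")

    seed: int
    # input paths; when None the synthetic generator provides the layer
    circ_counts_path: str | None = None
    mir_counts_path: str | None = None
    gene_counts_path: str | None = None
    circ_fasta_path: str | None = None
    utr_fasta_path: str | None = None
    mir_fasta_path: str | None = None
    gtf_path: str | None = None
    ires_flags_path: str | None = None
    # synthetic sizes
    n_circ: int = 200
    n_mir: int = 150
    n_gene: int = 500
    n_stages: int = 5
    n_reps: int = 3
    # differential expression
    fc_min: float = 1.5
    p_max_de: float = 0.05
    gene_lfc_min: float = 1.0
    gene_fdr_max: float = 0.01
    pseudocount: float = 1.0
    # clustering
    k: int = 15
    r_min: float = 0.8
    # co-expression network
    power: int | Literal["auto"] = 12
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    gs_min: float = 0.8
    mm_min: float = 0.8
    trait_p_max: float = 0.01
    top_edges: int = 200
    # ceRNA: triplet assembly uses the 8mer floor as the stand-in for the
    # stringency of intersecting two target predictors; the scanner itself
    # defaults to the laxer 7mer floor
    p_max_cerna: float = 0.05
    min_seed_class: str = "8mer"
    # ORF
    orf_min_len: int = 150
    ires_fraction: float = 0.7   # simulated IRES prevalence when no table given


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "parameters": json.loads(config.model_dump_json()),
                      "stages": {}}
    state: dict = {}

    stage_fns = [
        ("simulate", _stage_simulate),
        ("normalize", _stage_normalize),
        ("annotate", _stage_annotate),
        ("de", _stage_de),
        ("cluster", _stage_cluster),
        ("wgcna", _stage_wgcna),
        ("parental", _stage_parental),
        ("cerna", _stage_cerna),
        ("orf", _stage_orf),
    ]
    for name, fn in stage_fns:
        stage_dir = outdir / name
        stage_dir.mkdir(exist_ok=True)
        try:
            files = fn(config, state, stage_dir)
        except Exception as exc:  # abort with the stage name + partial manifest
            _write_manifest(manifest, outdir)
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = {
            str(f.relative_to(outdir)): _sha256(f) for f in sorted(files)
        }
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, state: dict, d: Path) -> list[Path]:
    if cfg.circ_counts_path:
        state["circ_counts"] = read_expression_tsv(cfg.circ_counts_path)
        state["mir_counts"] = read_expression_tsv(cfg.mir_counts_path)
        state["gene_counts"] = read_expression_tsv(cfg.gene_counts_path)
        state["design"] = state["circ_counts"].design
        state["circ_seqs"] = read_fasta(cfg.circ_fasta_path)
        state["utr_seqs"] = read_fasta(cfg.utr_fasta_path)
        state["mir_seqs"] = read_fasta(cfg.mir_fasta_path)
        state["genes"] = read_gtf_lite(cfg.gtf_path)
        state["mapped"] = {
            s: int(v)
            for s, v in pd.read_csv(
                Path(cfg.circ_counts_path).with_suffix(".mapped.tsv"), sep="\t"
            ).itertuples(index=False)
        }
        state["truth"] = None
    else:
        ds = simulate_dataset(
            n_circ=cfg.n_circ, n_mir=cfg.n_mir, n_gene=cfg.n_gene,
            n_stages=cfg.n_stages, n_reps=cfg.n_reps,
            config=SimulationConfig(), seed=cfg.seed,
        )
        state.update(
            design=ds.design, circ_counts=ds.circ_counts,
            mir_counts=ds.mir_counts, gene_counts=ds.gene_counts,
            mapped=ds.mapped_reads, truth=ds.truth, circ_seqs=ds.circ_seqs,
            utr_seqs=ds.utr_seqs, mir_seqs=ds.mir_seqs, genes=ds.genes,
        )
    files = []
    for name in ("circ_counts", "mir_counts", "gene_counts"):
        p = d / f"{name}.tsv"
        write_expression_tsv(state[name], p)
        files += [p, p.with_name(p.name + ".json")]
    p = d / "mapped_reads.tsv"
    pd.Series(state["mapped"], name="mapped_reads").rename_axis("sample_id").to_csv(
        p, sep="\t"
    )
    files.append(p)
    p = d / "sample_sheet.json"
    write_sample_sheet(state["design"], p)
    files.append(p)
    for name in ("circ_seqs", "utr_seqs", "mir_seqs"):
        p = d / f"{name}.fa"
        write_fasta(state[name], p)
        files.append(p)
    p = d / "genes.gtf"
    write_gtf_lite(state["genes"], p)
    files.append(p)
    if state["truth"] is not None:
        p = d / "truth.json"
        p.write_text(json.dumps(state["truth"].to_json_dict(), indent=1,
                                sort_keys=True))
        files.append(p)
    return files


def _stage_normalize(cfg: PipelineConfig, state: dict, d: Path) -> list[Path]:
    circ_len = {c: len(s) for c, s in state["circ_seqs"].items()}
    mir_len = {m: len(s) for m, s in state["mir_seqs"].items()}
    gene_len = {g: max(len(s), 1) for g, s in state["utr_seqs"].items()}
    state["circ_srpbm"] = srpbm(state["circ_counts"], state["mapped"])
    state["mir_tpm"] = tpm(state["mir_counts"], mir_len)
    state["gene_fpkm"] = fpkm(state["gene_counts"], gene_len)
    state["circ_len"] = circ_len
    files = []
    for key, name in (("circ_srpbm", "circ_srpbm"), ("mir_tpm", "mir_tpm"),
                      ("gene_fpkm", "gene_fpkm")):
        p = d / f"{name}.tsv"
        write_expression_tsv(state[key], p)
        files += [p, p.with_name(p.name + ".json")]
    return files


def _stage_annotate(cfg: PipelineConfig, state: dict, d: Path) -> list[Path]:
    records = [
        classify_circ(parse_circ_id(cid), state["genes"])
        for cid in state["circ_counts"].feature_ids
    ]
    state["records"] = records
    detection = detect_per_stage(state["circ_counts"])
    summary = characterize_cohort(records, detection)
    state["cohort"] = summary
    rec_frame = pd.DataFrame(
        [
            {"circ_id": r.circ_id, "class": r.circ_class,
             "parental_gene": r.parental_gene or "",
             "spliced_length_nt": r.spliced_length_nt,
             "exon_count": r.exon_count}
            for r in records
        ]
    )
    p1 = d / "records.tsv"
    rec_frame.to_csv(p1, sep="\t", index=False)
    p2 = d / "cohort_summary.json"
    p2.write_text(json.dumps(summary.__dict__, indent=1, sort_keys=True, default=str))
    return [p1, p2]


def _stage_de(cfg: PipelineConfig, state: dict, d: Path) -> list[Path]:
    lfc = math.log2(cfg.fc_min)
    circ_tab, circ_de = de_all_contrasts(
        state["circ_srpbm"], "circRNA", cfg.pseudocount, lfc, cfg.p_max_de
    )
    mir_tab, mir_de = de_all_contrasts(
        state["mir_tpm"], "miRNA", cfg.pseudocount, lfc, cfg.p_max_de
    )
    gene_tab, gene_de = de_all_contrasts(
        state["gene_fpkm"], "gene", cfg.pseudocount, cfg.gene_lfc_min,
        cfg.gene_fdr_max,
    )
    state.update(circ_de=circ_de, mir_de=mir_de, gene_de=gene_de)
    files = []
    for name, tab in (("circ", circ_tab), ("mir", mir_tab), ("gene", gene_tab)):
        p = d / f"de_{name}.tsv"
        tab.to_csv(p, sep="\t", index=False)
        files.append(p)
    p = d / "de_lists.json"
    p.write_text(json.dumps(
        {"circ": sorted(circ_de), "mir": sorted(mir_de), "gene": sorted(gene_de)},
        indent=1,
    ))
    files.append(p)
    return files


def _stage_cluster(cfg: PipelineConfig, state: dict, d: Path) -> list[Path]:
    circ = state["circ_srpbm"].subset(sorted(state["circ_de"]))
    gene = state["gene_fpkm"].subset(sorted(state["gene_de"]))
    profiles = pd.concat(
        [
            StagePatternClustering._stage_profiles(circ),
            StagePatternClustering._stage_profiles(gene),
        ]
    )
    p = d / "clusters.tsv"
    if len(profiles) < max(cfg.k, 2):
        state["patterns"] = None
        pd.DataFrame(columns=["feature_id", "cluster", "group"]).to_csv(
            p, sep="\t", index=False
        )
        return [p]
    model = StagePatternClustering(
        n_clusters=cfg.k, r_min=cfg.r_min, random_state=cfg.seed
    ).fit(profiles)
    state["patterns"] = model
    frame = pd.DataFrame(
        {"feature_id": model.labels_.index, "cluster": model.labels_.values,
         "group": model.groups_.values}
    )
    frame.to_csv(p, sep="\t", index=False)
    p2 = d / "cluster_centroids.tsv"
    model.cluster_centers_.rename_axis("cluster").to_csv(p2, sep="\t")
    return [p, p2]


def _stage_wgcna(cfg: PipelineConfig, state: dict, d: Path) -> list[Path]:
    combined = pd.concat(
        [state["circ_srpbm"].log2p1(), state["gene_fpkm"].log2p1()]
    )
    net = CoexpressionNetwork(
        power=cfg.power, min_module_size=cfg.min_module_size,
        merge_cut_height=cfg.merge_cut_height, log_transform=False,
    ).fit(combined)
    net.design_ = list(state["circ_srpbm"].design)
    stats = net.module_stats(
        gs_min=cfg.gs_min, mm_min=cfg.mm_min, trait_p_max=cfg.trait_p_max
    )
    state["network"] = net
    state["module_stats"] = stats

    files = []
    p = d / "module_labels.tsv"
    net.module_labels_.rename("module").rename_axis("feature_id").to_csv(p, sep="\t")
    files.append(p)
    p = d / "eigengenes.tsv"
    net.eigengenes_.rename_axis("sample_id").to_csv(p, sep="\t")
    files.append(p)
    p = d / "module_trait.tsv"
    mt = stats.module_trait_r.copy()
    mt.columns = [f"r_{c}" for c in mt.columns]
    mtp = stats.module_trait_p.copy()
    mtp.columns = [f"p_{c}" for c in mtp.columns]
    pd.concat([mt, mtp], axis=1).rename_axis("module").to_csv(p, sep="\t")
    files.append(p)
    p = d / "hubs.tsv"
    stats.hubs.to_csv(p, sep="\t", index=False)
    files.append(p)
    for module in net.eigengenes_.columns:
        edges = net.export_top_edges(module, cfg.top_edges)
        p = d / f"edges_{module}.tsv"
        edges.to_csv(p, sep="\t", index=False)
        files.append(p)
    return files


def _stage_parental(cfg: PipelineConfig, state: dict, d: Path) -> list[Path]:
    pairs = [
        (r.circ_id, r.parental_gene)
        for r in state["records"]
        if r.parental_gene is not None
    ]
    result, summary, skipped = classify_pairs(
        pairs, state["circ_srpbm"], state["gene_fpkm"], state["records"]
    )
    state["parental_pairs"] = result
    files = []
    p = d / "parental_pairs.tsv"
    pd.DataFrame(
        [
            {"circ_id": q.circ_id, "gene_id": q.gene_id, "circ_class": q.circ_class,
             "r": q.r, "p": q.p, "effective": q.effective,
             "sign_class": q.sign_class}
            for q in result
        ],
        columns=["circ_id", "gene_id", "circ_class", "r", "p", "effective",
                 "sign_class"],
    ).to_csv(p, sep="\t", index=False)
    files.append(p)
    p = d / "parental_summary.tsv"
    summary.to_csv(p, sep="\t", index=False)
    files.append(p)
    p = d / "skipped_pairs.tsv"
    pd.DataFrame(skipped, columns=["circ_id", "gene_id"]).to_csv(
        p, sep="\t", index=False
    )
    files.append(p)
    return files


def _stage_cerna(cfg: PipelineConfig, state: dict, d: Path) -> list[Path]:
    circ_sites = find_mre_sites(
        state["mir_seqs"], state["circ_seqs"], "circRNA",
        min_seed_class=cfg.min_seed_class,
    )
    utr_sites = find_mre_sites(
        state["mir_seqs"], state["utr_seqs"], "utr3",
        min_seed_class=cfg.min_seed_class,
    )
    triplets = build_cerna(
        state["circ_de"], state["mir_de"], state["gene_de"],
        state["circ_srpbm"], state["mir_tpm"], state["gene_fpkm"],
        circ_sites + utr_sites, p_max=cfg.p_max_cerna,
    )
    if not audit_triplets(triplets, cfg.p_max_cerna):
        raise RuntimeError("ceRNA triplet audit failed")
    state["triplets"] = triplets
    files = []
    p = d / "triplets.tsv"
    triplets_to_frame(triplets).to_csv(p, sep="\t", index=False)
    files.append(p)
    nodes, edges = cerna_graph(triplets)
    p = d / "cerna_network.graphml"
    write_network(nodes, edges, p, fmt="graphml")
    files.append(p)
    p = d / "cerna_network.sif"
    write_network(nodes, edges, p, fmt="sif")
    files.append(p)
    return files


def _stage_orf(cfg: PipelineConfig, state: dict, d: Path) -> list[Path]:
    orfs = find_orfs_per_circle(state["circ_seqs"], min_len_nt=cfg.orf_min_len)
    if cfg.ires_flags_path:
        tab = pd.read_csv(cfg.ires_flags_path, sep="\t")
        ires = dict(zip(tab.iloc[:, 0], tab.iloc[:, 1].astype(bool)))
    else:
        rng = np.random.default_rng(cfg.seed + 2)
        ires = {c: bool(rng.random() < cfg.ires_fraction)
                for c in state["circ_seqs"]}
    classes = {r.circ_id: r.circ_class for r in state["records"]}
    calls, accounting = coding_potential(orfs, ires, cfg.orf_min_len, classes)
    state["coding_calls"] = calls

    files = []
    p = d / "orfs.tsv"
    pd.DataFrame(
        [
            {"circ_id": o.circ_id, "start": o.start, "length_nt": o.length_nt,
             "frame": o.frame, "crosses_bsj": o.crosses_bsj,
             "no_stop": o.no_stop, "peptide_aa": o.peptide_length_aa}
            for lst in orfs.values() for o in lst
        ],
        columns=["circ_id", "start", "length_nt", "frame", "crosses_bsj",
                 "no_stop", "peptide_aa"],
    ).to_csv(p, sep="\t", index=False)
    files.append(p)
    p = d / "coding_potential.json"
    p.write_text(json.dumps(accounting, indent=1, sort_keys=True))
    files.append(p)

    # candidate regulatory circRNAs: hub in a stage-significant module AND DE
    hubs = set(state["module_stats"].hubs["feature_id"]) if state.get(
        "module_stats") else set()
    candidates = sorted(hubs & set(state["circ_de"]))
    p = d / "candidate_circrnas.json"
    p.write_text(json.dumps({"candidates": candidates}, indent=1))
    files.append(p)
    return files
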