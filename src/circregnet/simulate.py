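"""Stage-course multi-layer synthetic data with known ground truth.

The generator emulates the experimental conditions the pipeline targets: a 5-stage
x 3-replicate differentiation course with three expression layers (circRNA
back-splice junction counts, miRNA read counts, mRNA fragment counts) drawn
from a negative-binomial model whose means follow a small library of stage
trajectories; matched circRNA / 3'UTR / miRNA sequences with planted miRNA
seed-match sites and planted (possibly junction-crossing) open reading
frames; and a GTF-lite annotation from which each circle's planted class
(exonic / intronic / intergenic) is recoverable.

Planted structure is recorded in a :class:`SyntheticTruth` object so every
downstream stage — differential expression, pattern clustering, module
detection, parental-gene correlation, ceRNA assembly and circular-ORF
scanning — can be scored against ground truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core import STAGES, ExpressionMatrix, SampleDesign
from .io import GeneModel

# ---------------------------------------------------------------------------
# stage-trajectory library
# ---------------------------------------------------------------------------
# Seven trajectory families over (A0, A12, A48, A72, A120), values in [0, 1],
# scaled by ``amplitude_log2`` around their own mean.  Three broad families
# carry the bulk co-expression modules; four step-like families are reserved
# for planted ceRNA triplets so that sponge inference has identifiable
# members at desk scale (see docs/methods.md for what this does and does not
# emulate about real data).

MODULE_PROFILES: dict[str, tuple[float, ...]] = {
    "early_peak": (0.5, 1.0, 0.75, 0.0, 0.5),   # transient induction at 12 h
    "late_peak": (0.5, 0.0, 0.25, 1.0, 0.5),    # negation of early_peak
    "mid_peak": (0.5, 0.25, 1.0, 0.25, 0.5),    # transient induction at 48 h
}

TRIPLET_PROFILES: dict[str, tuple[float, ...]] = {
    "early_jump": (0.0, 1.0, 1.0, 1.0, 1.0),    # switched on by induction
    "early_drop": (1.0, 0.0, 0.0, 0.0, 0.0),    # switched off by induction
    "late_burst": (0.0, 0.0, 0.0, 0.0, 1.0),
    "late_decline": (1.0, 1.0, 1.0, 1.0, 0.0),
}

#: family -> its negated family, where the negation is itself in the library.
#: Families are mutually near-orthogonal (|r| <= 0.28) apart from these
#: pairs, so planted structure does not bleed across families through the
#: correlation filters.
NEGATED_FAMILY: dict[str, str] = {
    "early_peak": "late_peak",
    "late_peak": "early_peak",
    "early_jump": "early_drop",
    "early_drop": "early_jump",
    "late_burst": "late_decline",
    "late_decline": "late_burst",
}

PROFILES: dict[str, tuple[float, ...]] = {**MODULE_PROFILES, **TRIPLET_PROFILES}

_STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Effect sizes, noise levels and planted-structure counts.

    Defaults are the generator's study conditions; see docs/methods.md for
    the rationale behind each value.
    """

    amplitude_log2: float = 4.0          # log2 swing of a full trajectory
    base_mean_circ: float = 150.0        # BSJ junction reads per library
    base_mean_mir: float = 500.0
    base_mean_gene: float = 500.0
    dispersion_circ: float = 0.05        # NB dispersion (var = mu + d*mu^2)
    dispersion_mir: float = 0.05
    dispersion_gene: float = 0.02
    baseline_sigma: float = 0.4          # lognormal spread of per-feature means
    frac_planted_circ: float = 0.5       # features carrying a trajectory
    frac_planted_gene: float = 0.5
    n_triplets: int = 8                  # planted ceRNA triplets
    n_parental_negative: int = 30        # exonic circ / parental-gene couplings
    n_parental_positive: int = 15        # intronic couplings
    frac_exonic: float = 0.75
    frac_intronic: float = 0.12
    mapped_reads_low: int = 90_000_000
    mapped_reads_high: int = 130_000_000
    circ_length_low: int = 250
    circ_length_high: int = 600
    utr_length_low: int = 200
    utr_length_high: int = 400
    frac_with_orf: float = 0.7
    frac_orf_crossing: float = 0.3

    def validate(self) -> None:
        for name in ("frac_planted_circ", "frac_planted_gene", "frac_exonic",
                     "frac_intronic", "frac_with_orf", "frac_orf_crossing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_exonic + self.frac_intronic > 1.0:
            raise ValueError("class fractions exceed 1")
        if min(self.dispersion_circ, self.dispersion_mir, self.dispersion_gene) <= 0:
            raise ValueError("dispersions must be positive")


def null_config(**overrides) -> SimulationConfig:
    """A configuration with no planted effects (for calibration checks)."""
    cfg = SimulationConfig(
        frac_planted_circ=0.0,
        frac_planted_gene=0.0,
        n_triplets=0,
        n_parental_negative=0,
        n_parental_positive=0,
        **overrides,
    )
    return cfg


@dataclass
class SyntheticTruth:
    """Planted ground truth used by the recovery tests."""

    seed: int
    module_membership: dict[str, str] = field(default_factory=dict)
    triplets: list[tuple[str, str, str]] = field(default_factory=list)
    parental_coupling: dict[str, tuple[str, int]] = field(default_factory=dict)
    orfs: dict[str, list[tuple[int, int, bool]]] = field(default_factory=dict)
    mre_sites: list[dict] = field(default_factory=list)
    circ_classes: dict[str, str] = field(default_factory=dict)
    mir_ids: list[str] = field(default_factory=list)
    circ_lengths: dict[str, int] = field(default_factory=dict)
    utr_lengths: dict[str, int] = field(default_factory=dict)
    host_gene: dict[str, str] = field(default_factory=dict)
    profiles: dict[str, str] = field(default_factory=dict)
    gene_models: list[GeneModel] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["gene_models"] = [
            {"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
             "exons": list(g.exons)}
            for g in self.gene_models
        ]
        return d


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(n_stages: int, n_reps: int) -> list[SampleDesign]:
    """Stage-major sample sheet with deterministic ids like ``A12-2``.

    Replicate correlation and two-group testing both need at least two
    replicates per stage and two stages.
    """
    if not 2 <= n_stages <= len(STAGES):
        raise ValueError(f"n_stages must be in [2, {len(STAGES)}], got {n_stages}")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (correlation/DE testing needs replicates)")
    return [
        SampleDesign(sample_id=f"{stage}-{rep}", stage=stage, replicate=rep)
        for stage in STAGES[:n_stages]
        for rep in range(1, n_reps + 1)
    ]


def _shape_for(profile: str, n_stages: int) -> np.ndarray:
    shape5 = np.asarray(PROFILES[profile], dtype=float)
    if n_stages == len(shape5):
        return shape5
    return np.interp(np.linspace(0, len(shape5) - 1, n_stages),
                     np.arange(len(shape5)), shape5)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def _simulate_layer(
    rng: np.random.Generator,
    feature_ids: list[str],
    profile_of: dict[str, str | None],
    design: Sequence[SampleDesign],
    base_mean: float,
    dispersion: float,
    amplitude: float,
    baseline_sigma: float,
    negate: set[str] | None = None,
) -> pd.DataFrame:
    """NB counts whose log2 mean follows each feature's trajectory."""
    stages = [s for s in STAGES if any(d.stage == s for d in design)]
    stage_idx = {s: i for i, s in enumerate(stages)}
    col_stage = np.array([stage_idx[d.stage] for d in design])
    negate = negate or set()

    log2_offsets = np.zeros((len(feature_ids), len(stages)))
    for i, fid in enumerate(feature_ids):
        prof = profile_of.get(fid)
        if prof is None:
            continue
        shape = _shape_for(prof, len(stages))
        if fid in negate:
            shape = 1.0 - shape
        log2_offsets[i] = amplitude * (shape - shape.mean())

    baseline = base_mean * rng.lognormal(0.0, baseline_sigma, size=len(feature_ids))
    mu = baseline[:, None] * 2.0 ** log2_offsets[:, col_stage]
    counts = _nb_draw(rng, mu, dispersion)
    return pd.DataFrame(
        counts, index=feature_ids, columns=[d.sample_id for d in design]
    )


# ---------------------------------------------------------------------------
# expression + truth
# ---------------------------------------------------------------------------

def simulate_expression(
    design: Sequence[SampleDesign],
    n_circ: int,
    n_mir: int,
    n_gene: int,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, dict[str, int], SyntheticTruth]:
    """Draw the three raw-count layers plus mapped totals and ground truth."""
    if seed is None:
        raise ValueError("seed is required: synthetic data must be reproducible")
    if min(n_circ, n_mir, n_gene) <= 0:
        raise ValueError("feature counts must be positive")
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    design = list(design)

    # scale the planted-structure counts down for small cohorts so the same
    # configuration drives any layer size
    n_tr = min(cfg.n_triplets, n_mir, n_gene)
    n_neg, n_pos = cfg.n_parental_negative, cfg.n_parental_positive
    budget = min(int(0.6 * n_circ), int(0.6 * n_gene))
    total = n_tr + n_neg + n_pos
    if total > budget > 0:
        scale = budget / total
        n_tr = max(int(n_tr * scale), 1 if n_tr else 0)
        n_neg = int(n_neg * scale)
        n_pos = int(n_pos * scale)
    n_special = n_tr + n_neg + n_pos
    n_planted_circ = max(int(round(cfg.frac_planted_circ * n_circ)), n_special)

    module_families = list(MODULE_PROFILES)
    triplet_families = list(TRIPLET_PROFILES)

    # ---- circRNA roles, classes and loci ----------------------------------
    roles: list[str] = []
    for i in range(n_circ):
        if i < n_tr:
            roles.append("triplet")
        elif i < n_tr + n_neg:
            roles.append("coupled_neg")
        elif i < n_special:
            roles.append("coupled_pos")
        elif i < n_planted_circ:
            roles.append("module")
        else:
            roles.append("flat")

    # class targets across the cohort
    n_exonic = int(round(cfg.frac_exonic * n_circ))
    n_intronic = int(round(cfg.frac_intronic * n_circ))
    n_exonic = max(n_exonic, n_neg)
    n_intronic = max(n_intronic, n_pos)
    n_intergenic = max(n_circ - n_exonic - n_intronic, 0)
    classes: list[str | None] = [None] * n_circ
    free = []
    for i, role in enumerate(roles):
        if role == "coupled_neg":
            classes[i] = "exonic"
        elif role == "coupled_pos":
            classes[i] = "intronic"
        else:
            free.append(i)
    pool = (
        ["exonic"] * (n_exonic - n_neg)
        + ["intronic"] * (n_intronic - n_pos)
        + ["intergenic"] * n_intergenic
    )
    pool = pool[: len(free)]
    while len(pool) < len(free):
        pool.append("exonic")
    rng.shuffle(pool)
    for i, cls in zip(free, pool):
        classes[i] = cls

    circ_lengths_arr = rng.integers(cfg.circ_length_low, cfg.circ_length_high + 1,
                                    size=n_circ)

    gene_ids = [f"G{i + 1:04d}" for i in range(n_gene)]
    mir_ids = [f"miR-{i + 1:03d}" for i in range(n_mir)]

    # ---- gene roles --------------------------------------------------------
    # triplet targets, then dedicated parental partners, then module genes.
    g_triplet = gene_ids[:n_tr]
    g_cpl_neg = gene_ids[n_tr: n_tr + n_neg]
    g_cpl_pos = gene_ids[n_tr + n_neg: n_tr + n_neg + n_pos]
    n_gene_special = len(g_triplet) + len(g_cpl_neg) + len(g_cpl_pos)
    n_module_genes = max(int(round(cfg.frac_planted_gene * n_gene)) - n_gene_special, 0)
    g_module = gene_ids[n_gene_special: n_gene_special + n_module_genes]
    if n_gene_special > n_gene:
        raise ValueError("planted structures exceed the gene layer size")

    # ---- genomic layout: host genes and loci ------------------------------
    truth = SyntheticTruth(seed=int(seed))
    circ_ids: list[str] = []
    host_of: dict[int, str] = {}
    # non-coupled hosted circs draw their host from the non-triplet gene pool;
    # allow sharing so the circs-per-parental-gene histogram is non-trivial.
    shared_pool = list(gene_ids[n_gene_special:]) or list(gene_ids)
    cursor = 1000
    gene_layout: dict[str, list[tuple[int, str, int]]] = {}
    intergenic_cursor = 1000
    cpl_neg_iter = iter(g_cpl_neg)
    cpl_pos_iter = iter(g_cpl_pos)

    for i in range(n_circ):
        cls = classes[i]
        L = int(circ_lengths_arr[i])
        if cls == "intergenic":
            start = intergenic_cursor
            end = start + L - 1
            intergenic_cursor = end + 20_000
            circ_ids.append(f"Z:{start}|{end}")
            continue
        role = roles[i]
        if role == "coupled_neg":
            host = next(cpl_neg_iter)
        elif role == "coupled_pos":
            host = next(cpl_pos_iter)
        else:
            host = shared_pool[int(rng.integers(len(shared_pool)))]
        host_of[i] = host
        gene_layout.setdefault(host, [])
        gene_layout[host].append((i, cls, L))
        circ_ids.append("")  # placed below once coordinates are known

    # lay out chromosome "1": one block per host gene, hosted circles inside
    gene_models: list[GeneModel] = []
    exon_segments: dict[int, list[tuple[int, int]]] = {}
    for host, hosted in gene_layout.items():
        exons: list[tuple[int, int]] = []
        pos = cursor
        exons.append((pos, pos + 99))          # leading flanking exon
        pos += 400
        for (i, cls, L) in hosted:
            if cls == "exonic":
                k = int(rng.integers(1, 4))
                base, rem = divmod(L, k)
                parts = [base + (1 if j < rem else 0) for j in range(k)]
                segs = []
                for part in parts:
                    segs.append((pos, pos + part - 1))
                    pos += part + 300          # 300 nt introns inside the circle
                pos -= 300
                exons.extend(segs)
                exon_segments[i] = segs
                circ_ids[i] = f"1:{segs[0][0]}|{segs[-1][1]}"
                pos += 400
            else:  # intronic: circle sits strictly inside one intron
                start = pos + 200
                end = start + L - 1
                circ_ids[i] = f"1:{start}|{end}"
                pos = end + 400
        exons.append((pos, pos + 99))          # trailing flanking exon
        gene_models.append(GeneModel(host, "1", "+", exons))
        cursor = pos + 20_000

    if any(c == "intergenic" for c in classes):
        # distant decoy gene keeps chromosome Z present in the annotation
        # while leaving every intergenic circle >10 kb from any gene
        z_start = intergenic_cursor + 30_000
        gene_models.append(
            GeneModel("Z_DECOY", "Z", "+",
                      [(z_start, z_start + 99), (z_start + 500, z_start + 599)])
        )

    truth.gene_models = gene_models
    truth.mir_ids = list(mir_ids)
    truth.host_gene = {circ_ids[i]: host for i, host in host_of.items()}
    truth.circ_classes = {circ_ids[i]: classes[i] for i in range(n_circ)}
    truth.circ_lengths = {circ_ids[i]: int(circ_lengths_arr[i]) for i in range(n_circ)}
    truth.utr_lengths = {
        g: int(rng.integers(cfg.utr_length_low, cfg.utr_length_high + 1))
        for g in gene_ids
    }

    # ---- trajectories ------------------------------------------------------
    circ_profiles: dict[str, str | None] = {}
    gene_profiles: dict[str, str | None] = {g: None for g in gene_ids}
    mir_profiles: dict[str, str | None] = {m: None for m in mir_ids}
    mir_negate: set[str] = set()
    negatable = [f for f in module_families if f in NEGATED_FAMILY]

    for i in range(n_circ):
        cid = circ_ids[i]
        role = roles[i]
        if role == "triplet":
            fam = triplet_families[i % len(triplet_families)]
        elif role == "coupled_neg":
            # negative coupling needs the gene's negated trajectory to be a
            # library family itself, so the pattern stage sees 7 families
            fam = negatable[i % len(negatable)]
        elif role in ("coupled_pos", "module"):
            fam = module_families[i % len(module_families)]
        else:
            fam = None
        circ_profiles[cid] = fam
        if fam is not None:
            truth.profiles[cid] = fam
        if role in ("coupled_neg", "coupled_pos", "module"):
            truth.module_membership[cid] = fam  # type: ignore[assignment]

    for t in range(n_tr):
        cid = circ_ids[t]
        fam = circ_profiles[cid]
        mid, gid = mir_ids[t], g_triplet[t]
        mir_profiles[mid] = fam
        mir_negate.add(mid)                      # anti-phased sponge target
        gene_profiles[gid] = fam                 # shared trajectory with the circ
        truth.profiles[mid] = f"anti_{fam}"
        truth.profiles[gid] = fam
        truth.triplets.append((cid, mid, gid))

    for j, gid in enumerate(g_cpl_neg):
        cid = circ_ids[n_tr + j]
        fam = NEGATED_FAMILY[circ_profiles[cid]]  # exonic coupling is negative
        gene_profiles[gid] = fam
        truth.profiles[gid] = fam
        truth.module_membership[gid] = fam
        truth.parental_coupling[cid] = (gid, -1)
    for j, gid in enumerate(g_cpl_pos):
        cid = circ_ids[n_tr + n_neg + j]
        fam = circ_profiles[cid]
        gene_profiles[gid] = fam                 # intronic coupling is positive
        truth.profiles[gid] = fam
        truth.module_membership[gid] = fam
        truth.parental_coupling[cid] = (gid, +1)

    for j, gid in enumerate(g_module):
        fam = module_families[j % len(module_families)]
        gene_profiles[gid] = fam
        truth.profiles[gid] = fam
        truth.module_membership[gid] = fam

    # ---- planted ORFs and MRE sites ---------------------------------------
    for i in range(n_circ):
        cid = circ_ids[i]
        L = int(circ_lengths_arr[i])
        if rng.random() >= cfg.frac_with_orf:
            continue
        max_len = min(300, 3 * (L // 3) - 9)
        length = int(3 * rng.integers(50, max_len // 3 + 1))
        if rng.random() < cfg.frac_orf_crossing:
            start = int(rng.integers(L - length + 1, L))
        else:
            start = int(rng.integers(0, L - length + 1))
        truth.orfs[cid] = [(start, length, start + length > L)]

    def _free_position(L: int, occupied: list[tuple[int, int]], width: int) -> int | None:
        for _ in range(200):
            pos = int(rng.integers(0, L - width + 1))
            if all(pos + width <= a or pos >= b for a, b in occupied):
                return pos
        return None

    for (cid, mid, gid) in truth.triplets:
        L = truth.circ_lengths[cid]
        occupied = []
        for (s, ln, crosses) in truth.orfs.get(cid, []):
            occupied.append((s, min(s + ln, L)))
            if s + ln > L:
                occupied.append((0, (s + ln) % L))
        pos = _free_position(L, occupied, 8)
        if pos is None:  # crowded circle: fall back to overwriting background
            pos = 0
        truth.mre_sites.append(
            {"mir_id": mid, "target_id": cid, "target_kind": "circRNA",
             "position": pos + 1, "seed_class": "8mer"}
        )
        upos = int(rng.integers(0, truth.utr_lengths[gid] - 8 + 1))
        truth.mre_sites.append(
            {"mir_id": mid, "target_id": gid, "target_kind": "utr3",
             "position": upos + 1, "seed_class": "8mer"}
        )

    # ---- counts ------------------------------------------------------------
    circ = _simulate_layer(rng, circ_ids, circ_profiles, design,
                           cfg.base_mean_circ, cfg.dispersion_circ,
                           cfg.amplitude_log2, cfg.baseline_sigma)
    mir = _simulate_layer(rng, mir_ids, mir_profiles, design,
                          cfg.base_mean_mir, cfg.dispersion_mir,
                          cfg.amplitude_log2, cfg.baseline_sigma,
                          negate=mir_negate)
    gene = _simulate_layer(rng, gene_ids, gene_profiles, design,
                           cfg.base_mean_gene, cfg.dispersion_gene,
                           cfg.amplitude_log2, cfg.baseline_sigma)
    mapped = {
        d.sample_id: int(rng.integers(cfg.mapped_reads_low, cfg.mapped_reads_high + 1))
        for d in design
    }

    circ_m = ExpressionMatrix(circ, "raw_count", list(design))
    mir_m = ExpressionMatrix(mir, "raw_count", list(design))
    gene_m = ExpressionMatrix(gene, "raw_count", list(design))
    return circ_m, mir_m, gene_m, mapped, truth


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(np.asarray(list(alphabet))[rng.integers(0, len(alphabet), length)])


def simulate_sequences(
    truth: SyntheticTruth,
    circ_lengths: Sequence[int] | dict[str, int] | None = None,
    seed: int | None = None,
) -> tuple[dict[str, str], dict[str, str], dict[str, str], list[GeneModel]]:
    """Sequences consistent with the planted truth.

    Returns (circRNA spliced sequences, gene 3'UTRs, mature miRNAs,
    GTF-lite gene models).  circRNA/UTR sequences use the DNA alphabet,
    miRNAs are RNA (ACGU); downstream seed matching normalizes U/T.
    """
    if seed is None:
        raise ValueError("seed is required: synthetic data must be reproducible")
    if circ_lengths is None:
        lengths = dict(truth.circ_lengths)
    elif isinstance(circ_lengths, dict):
        lengths = {k: int(v) for k, v in circ_lengths.items()}
    else:
        lengths = {cid: int(v) for cid, v in zip(truth.circ_lengths, circ_lengths)}
    for cid, L in lengths.items():
        if L < 60:
            raise ValueError(f"circle {cid}: length {L} < 60 nt")
        for (s, ln, _c) in truth.orfs.get(cid, []):
            if ln > L:
                raise ValueError(
                    f"circle {cid}: planted ORF of {ln} nt exceeds circle length {L}"
                )
            if s >= L:
                raise ValueError(f"circle {cid}: planted ORF start {s} outside circle")

    rng = np.random.default_rng(seed)
    mir_ids = list(truth.mir_ids)
    for extra in sorted({s["mir_id"] for s in truth.mre_sites}):
        if extra not in mir_ids:
            mir_ids.append(extra)
    mir_seqs = {m: _random_seq(rng, 22, "ACGU") for m in mir_ids}

    circ_seqs: dict[str, str] = {}
    for cid, L in lengths.items():
        seq = list(_random_seq(rng, L))
        for (s, ln, _crosses) in truth.orfs.get(cid, []):
            codons = ["ATG"]
            codons += [
                _NONSTOP_CODONS[int(rng.integers(len(_NONSTOP_CODONS)))]
                for _ in range(ln // 3 - 2)
            ]
            codons.append("TAA")
            orf = "".join(codons)
            for off, base in enumerate(orf):
                seq[(s + off) % L] = base
        circ_seqs[cid] = "".join(seq)

    utr_seqs = {g: _random_seq(rng, L) for g, L in truth.utr_lengths.items()}

    for site in truth.mre_sites:
        mir_dna = mir_seqs[site["mir_id"]].replace("U", "T")
        if site["seed_class"] == "8mer":
            patch = _revcomp_dna(mir_dna[1:8]) + "A"
        elif site["seed_class"] == "7mer-m8":
            patch = _revcomp_dna(mir_dna[1:8])
        elif site["seed_class"] == "7mer-A1":
            patch = _revcomp_dna(mir_dna[1:7]) + "A"
        else:  # 6mer
            patch = _revcomp_dna(mir_dna[1:7])
        pos = site["position"] - 1
        target = circ_seqs if site["target_kind"] == "circRNA" else utr_seqs
        s = target[site["target_id"]]
        target[site["target_id"]] = s[:pos] + patch + s[pos + len(patch):]

    return circ_seqs, utr_seqs, mir_seqs, list(truth.gene_models)


@dataclass
class SyntheticDataset:
    """End-to-end bundle: design, count layers, totals, sequences, truth."""

    design: list[SampleDesign]
    circ_counts: ExpressionMatrix
    mir_counts: ExpressionMatrix
    gene_counts: ExpressionMatrix
    mapped_reads: dict[str, int]
    truth: SyntheticTruth
    circ_seqs: dict[str, str]
    utr_seqs: dict[str, str]
    mir_seqs: dict[str, str]
    genes: list[GeneModel]


def simulate_dataset(
    n_circ: int = 200,
    n_mir: int = 150,
    n_gene: int = 500,
    n_stages: int = 5,
    n_reps: int = 3,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Convenience wrapper drawing expression, truth and sequences together."""
    if seed is None:
        raise ValueError("seed is required: synthetic data must be reproducible")
    design = generate_design(n_stages, n_reps)
    circ, mir, gene, mapped, truth = simulate_expression(
        design, n_circ, n_mir, n_gene, config=config, seed=seed
    )
    circ_seqs, utr_seqs, mir_seqs, genes = simulate_sequences(truth, seed=seed + 1)
    return SyntheticDataset(design, circ, mir, gene, mapped, truth,
                            circ_seqs, utr_seqs, mir_seqs, genes)
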