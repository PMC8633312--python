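"""Seed-match scanning against a brute-force oracle, and triplet assembly."""

import numpy as np
import pandas as pd
import pytest

from circregnet.cerna import (MRESite, audit_triplets, build_cerna,
                              cerna_graph, find_mre_sites, triplets_to_frame)
from circregnet.core import ExpressionMatrix, SampleDesign


COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


def site_oracle(mir, target):
    """Independent scan over all substrings (no junction wrap)."""
    mir = mir.upper().replace("U", "T")
    target = target.upper().replace("U", "T")
    core = revcomp(mir[1:7])
    m8 = revcomp(mir[7])
    hits = []
    for i in range(len(target) - 5):
        if target[i:i + 6] != core:
            continue
        has_m8 = i >= 1 and target[i - 1] == m8
        has_a1 = i + 6 < len(target) and target[i + 6] == "A"
        cls = {(True, True): "8mer", (True, False): "7mer-m8",
               (False, True): "7mer-A1", (False, False): "6mer"}[(has_m8, has_a1)]
        hits.append(((i - 1 if has_m8 else i) + 1, cls))
    return hits


class TestSeedMatch:
    MIR = "UGAGGUAGUAGGUUGUAUAGUU"   # 22-nt RNA

    def test_planted_8mer_found_once(self):
        mir_dna = self.MIR.replace("U", "T")
        site = revcomp(mir_dna[1:8]) + "A"
        target = "C" * 30 + site + "C" * 30
        hits = find_mre_sites({"m": self.MIR}, {"t": target}, "utr3",
                              min_seed_class="6mer")
        assert len(hits) == 1
        assert hits[0].seed_class == "8mer"
        assert hits[0].position == 31

    @pytest.mark.parametrize("cls,build", [
        ("7mer-m8", lambda m: revcomp(m[1:8]) + "G"),
        ("7mer-A1", lambda m: "G" + revcomp(m[1:7]) + "A"),
        ("6mer", lambda m: "G" + revcomp(m[1:7]) + "G"),
    ])
    def test_seed_class_assignment(self, cls, build):
        mir_dna = self.MIR.replace("U", "T")
        target = "C" * 20 + build(mir_dna) + "C" * 20
        hits = find_mre_sites({"m": self.MIR}, {"t": target}, "utr3",
                              min_seed_class="6mer")
        assert [h.seed_class for h in hits] == [cls]

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        for trial in range(30):
            mir = "".join(bases[rng.integers(0, 4, 22)])
            target = "".join(bases[rng.integers(0, 4, 500)])
            got = [(h.position, h.seed_class)
                   for h in find_mre_sites({"m": mir}, {"t": target}, "utr3",
                                           min_seed_class="6mer")]
            assert got == site_oracle(mir, target)

    def test_expected_6mer_density_on_random_targets(self):
        # a random 1,000-nt target carries (1000-5)/4^6 ~ 0.243 6mer cores
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        mir = "".join(bases[rng.integers(0, 4, 22)])
        targets = {f"t{i}": "".join(bases[rng.integers(0, 4, 1000)])
                   for i in range(1000)}
        hits = find_mre_sites({"m": mir}, targets, "utr3", min_seed_class="6mer")
        assert len(hits) / 1000 == pytest.approx(995 / 4096, abs=0.05)

    def test_bsj_crossing_site_found_on_circle_only(self):
        mir_dna = self.MIR.replace("U", "T")
        site = revcomp(mir_dna[1:8]) + "A"
        seq = site[4:] + "G" * 60 + site[:4]   # site wraps the junction
        circ_hits = find_mre_sites({"m": self.MIR}, {"c": seq}, "circRNA")
        linear_hits = find_mre_sites({"m": self.MIR}, {"c": seq}, "utr3")
        assert len(circ_hits) == 1 and circ_hits[0].seed_class == "8mer"
        assert not linear_hits

    def test_u_t_normalization(self):
        mir_dna = self.MIR.replace("U", "T")
        target_rna = ("C" * 10 + revcomp(mir_dna[1:8]) + "A").replace("T", "U")
        hits = find_mre_sites({"m": self.MIR}, {"t": target_rna}, "utr3")
        assert hits and hits[0].seed_class == "8mer"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            find_mre_sites({}, {"t": "ACGT"}, "utr3")

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            find_mre_sites({"m": "ACGU"}, {"t": "ACGT" * 10}, "utr3")


def _triplet_setup(r_cg=0.9, r_cm=-0.85, r_mg=-0.8, with_circ_site=True):
    """Tiny three-layer bundle with controllable correlations."""
    rng = np.random.default_rng(0)
    n = 15
    f = rng.normal(size=n)
    f = (f - f.mean()) / f.std()

    def blend(r, seed):
        e = np.random.default_rng(seed).normal(size=n)
        e = e - e.mean()
        e -= f * (f @ e) / (f @ f)
        e /= np.sqrt((e**2).mean())
        return r * f + np.sqrt(1 - r**2) * e

    design = [SampleDesign(f"A0-{i}", "A0", i) for i in (1, 2, 3)] + [
        SampleDesign(f"A12-{i}", "A12", i) for i in (1, 2, 3)
    ] + [SampleDesign(f"A48-{i}", "A48", i) for i in (1, 2, 3)] + [
        SampleDesign(f"A72-{i}", "A72", i) for i in (1, 2, 3)
    ] + [SampleDesign(f"A120-{i}", "A120", i) for i in (1, 2, 3)]
    cols = [d.sample_id for d in design]

    def mat(vec, name, unit):
        frame = pd.DataFrame([2.0 ** (vec + 8.0) - 1.0], index=[name], columns=cols)
        return ExpressionMatrix(frame, unit, design)

    circ = mat(f, "circ1", "SRPBM")
    gene = mat(blend(r_cg, 1), "gene1", "FPKM")
    mir = mat(blend(r_cm, 2), "mir1", "TPM")
    # note r_mg is implied ~ r_cm * r_cg; pass sites explicitly
    sites = []
    if with_circ_site:
        sites.append(MRESite("mir1", "circ1", "circRNA", 10, "8mer"))
    sites.append(MRESite("mir1", "gene1", "utr3", 20, "8mer"))
    return circ, mir, gene, sites


class TestBuildCerna:
    def test_planted_triplet_emitted(self):
        circ, mir, gene, sites = _triplet_setup()
        trips = build_cerna({"circ1"}, {"mir1"}, {"gene1"}, circ, mir, gene, sites)
        assert len(trips) == 1
        t = trips[0]
        assert (t.circ_id, t.mir_id, t.gene_id) == ("circ1", "mir1", "gene1")
        assert t.r_circ_gene > 0 > t.r_circ_mir
        assert audit_triplets(trips)

    def test_positive_circ_gene_sign_is_required(self):
        circ, mir, gene, sites = _triplet_setup(r_cg=-0.9)
        trips = build_cerna({"circ1"}, {"mir1"}, {"gene1"}, circ, mir, gene, sites)
        assert trips == []

    def test_shared_mre_on_circle_is_required(self):
        circ, mir, gene, sites = _triplet_setup(with_circ_site=False)
        trips = build_cerna({"circ1"}, {"mir1"}, {"gene1"}, circ, mir, gene, sites)
        assert trips == []

    def test_de_membership_restriction(self):
        circ, mir, gene, sites = _triplet_setup()
        trips = build_cerna(set(), {"mir1"}, {"gene1"}, circ, mir, gene, sites)
        assert trips == []

    def test_mismatched_designs_rejected(self):
        circ, mir, gene, sites = _triplet_setup()
        other = ExpressionMatrix(gene.values.copy(), "FPKM", [])
        with pytest.raises(ValueError, match="design"):
            build_cerna({"circ1"}, {"mir1"}, {"gene1"}, circ, mir, other, sites)

    def test_planted_triplets_recovered_with_high_precision(self, dataset,
                                                            normalized, de_sets):
        ds = dataset
        sites = find_mre_sites(ds.mir_seqs, ds.circ_seqs, "circRNA",
                               min_seed_class="8mer")
        sites += find_mre_sites(ds.mir_seqs, ds.utr_seqs, "utr3",
                                min_seed_class="8mer")
        trips = build_cerna(de_sets["circ"], de_sets["mir"], de_sets["gene"],
                            normalized["circ"], normalized["mir"],
                            normalized["gene"], sites)
        assert audit_triplets(trips)
        found = {(t.circ_id, t.mir_id, t.gene_id) for t in trips}
        planted = set(map(tuple, ds.truth.triplets))
        recall = len(found & planted) / len(planted)
        precision = len(found & planted) / max(len(found), 1)
        assert recall >= 0.9
        assert precision >= 0.8

    def test_output_invariant_to_input_order(self):
        circ, mir, gene, sites = _triplet_setup()
        a = build_cerna({"circ1"}, {"mir1"}, {"gene1"}, circ, mir, gene, sites)
        b = build_cerna({"circ1"}, {"mir1"}, {"gene1"}, circ, mir, gene,
                        list(reversed(sites)))
        assert triplets_to_frame(a).equals(triplets_to_frame(b))

    def test_graph_export_types_nodes(self):
        circ, mir, gene, sites = _triplet_setup()
        trips = build_cerna({"circ1"}, {"mir1"}, {"gene1"}, circ, mir, gene, sites)
        nodes, edges = cerna_graph(trips, tf_genes={"gene1"})
        kinds = dict(nodes)
        assert kinds["circ1"]["kind"] == "circRNA"
        assert kinds["gene1"]["kind"] == "transcription_factor"
        assert len(edges) == 3
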