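"""circRNA classification against constructed gene models and cohort math."""

import numpy as np
import pytest

from circregnet.annotate import (CircRNARecord, characterize_cohort,
                                 classify_circ, detect_per_stage,
                                 load_example_library_qc, summarize_library_qc)
from circregnet.core import ExpressionMatrix, SampleDesign
from circregnet.io import CircLocus, GeneModel

import pandas as pd


def _gene_25_exons():
    # 25 exons of 120 nt separated by 500 nt introns
    exons = [(1000 + i * 620, 1000 + i * 620 + 119) for i in range(25)]
    return GeneModel("DOCK7_like", "8", "+", exons)


class TestClassify:
    def test_exonic_circle_spanning_exons_19_to_22(self):
        g = _gene_25_exons()
        locus = CircLocus("8", g.exons[18][0], g.exons[21][1])
        rec = classify_circ(locus, [g])
        assert rec.circ_class == "exonic"
        assert rec.exon_count == 4
        assert rec.parental_gene == "DOCK7_like"
        # spliced length is the sum of exon segments, not the genomic span
        assert rec.spliced_length_nt == 4 * 120
        assert locus.span > rec.spliced_length_nt

    def test_boundary_tolerance_absorbs_small_offsets(self):
        g = _gene_25_exons()
        locus = CircLocus("8", g.exons[18][0] + 2, g.exons[21][1] - 2)
        assert classify_circ(locus, [g]).circ_class == "exonic"

    def test_circle_inside_intron_is_intronic(self):
        g = _gene_25_exons()
        intron = g.introns()[0]
        locus = CircLocus("8", intron[0] + 10, intron[1] - 10)
        rec = classify_circ(locus, [g])
        assert rec.circ_class == "intronic"
        assert rec.exon_count == 0
        assert rec.parental_gene == "DOCK7_like"
        assert rec.spliced_length_nt == locus.span

    def test_gene_free_contig_is_intergenic_without_parent(self):
        g = _gene_25_exons()
        rec = classify_circ(CircLocus("8", 10**7, 10**7 + 400), [g])
        assert rec.circ_class == "intergenic"
        assert rec.parental_gene is None

    def test_intergenic_near_gene_gets_nearest_parent(self):
        g = _gene_25_exons()
        start = g.end + 5000
        rec = classify_circ(CircLocus("8", start, start + 300), [g])
        assert rec.circ_class == "intergenic"
        assert rec.parental_gene == "DOCK7_like"

    def test_absent_chromosome_warns_and_falls_back(self):
        g = _gene_25_exons()
        with pytest.warns(UserWarning, match="absent"):
            rec = classify_circ(CircLocus("W", 100, 400), [g])
        assert rec.circ_class == "intergenic"

    def test_partition_is_total_on_synthetic_truth(self, dataset):
        from circregnet.io import parse_circ_id

        hits = 0
        for cid, cls in dataset.truth.circ_classes.items():
            rec = classify_circ(parse_circ_id(cid), dataset.genes)
            assert rec.circ_class in ("exonic", "intronic", "intergenic")
            hits += rec.circ_class == cls
        # planted classes recoverable with exact endpoints
        assert hits == len(dataset.truth.circ_classes)

    def test_spliced_length_matches_planted_circle_length(self, dataset):
        from circregnet.io import parse_circ_id

        for cid, L in list(dataset.truth.circ_lengths.items())[:50]:
            rec = classify_circ(parse_circ_id(cid), dataset.genes)
            if rec.circ_class in ("exonic", "intronic", "intergenic"):
                assert rec.spliced_length_nt == L


class TestCohort:
    @staticmethod
    def _records(n_exonic=797, n_intronic=127, n_intergenic=144, n_single=566):
        records, gene_idx = [], 0
        kinds = (["exonic"] * n_exonic + ["intronic"] * n_intronic
                 + ["intergenic"] * n_intergenic)
        # the first n_single circles get a private parental gene; the rest
        # share genes pairwise so their parents host two circles each
        for i, kind in enumerate(kinds):
            if i < n_single:
                parent, gene_idx = f"g{gene_idx}", gene_idx + 1
            else:
                parent = f"shared{(i - n_single) // 2}"
            records.append(
                CircRNARecord(CircLocus(str(1 + i % 30), 1000 + i, 1000 + i + 500),
                              kind, parent, 501, 1 if kind == "exonic" else 0)
            )
        return records

    def test_class_percentages_match_printed_arithmetic(self):
        summary = characterize_cohort(self._records())
        assert summary.n_total == 1068
        assert summary.class_fractions["exonic"] == 74.63
        assert summary.class_fractions["intronic"] == 11.89
        assert summary.class_fractions["intergenic"] == 13.48

    def test_single_parental_gene_fraction(self):
        summary = characterize_cohort(self._records())
        assert summary.single_parental_gene_count == 566
        assert summary.single_parental_gene_fraction == 53.0

    def test_fractions_sum_to_100(self):
        summary = characterize_cohort(self._records())
        assert sum(summary.class_fractions.values()) == pytest.approx(100.0, abs=0.02)
        assert sum(summary.length_histogram.values()) == summary.n_total

    def test_all_stages_detected_means_no_stage_specific(self):
        records = self._records(5, 0, 0, 5)
        ids = [r.circ_id for r in records]
        detection = {s: set(ids) for s in ("A0", "A12")}
        summary = characterize_cohort(records, detection)
        assert all(v == 0 for v in summary.stage_specific_counts.values())

    def test_stage_specific_is_set_difference(self):
        records = self._records(3, 0, 0, 3)
        a, b, c = [r.circ_id for r in records]
        summary = characterize_cohort(records, {"A0": {a, b}, "A12": {b, c}})
        assert summary.stage_specific_counts == {"A0": 1, "A12": 1}

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            characterize_cohort([])


class TestDetection:
    def test_detection_rule_counts_any_replicate(self):
        design = [SampleDesign(f"A0-{r}", "A0", r) for r in (1, 2)] + [
            SampleDesign(f"A12-{r}", "A12", r) for r in (1, 2)
        ]
        frame = pd.DataFrame(
            [[0, 3, 0, 0], [0, 0, 1, 0]],
            index=["c1", "c2"],
            columns=[d.sample_id for d in design],
        )
        detected = detect_per_stage(ExpressionMatrix(frame, "raw_count", design))
        assert detected == {"A0": {"c1"}, "A12": {"c2"}}


class TestLibraryQc:
    def test_packaged_table_summary(self):
        summary = summarize_library_qc(load_example_library_qc())
        assert summary["n_libraries"] == 15
        assert summary["total_clean_base_gb"] == pytest.approx(253.30)
        assert summary["mean_gc_pct"] == pytest.approx(46.26)
        assert summary["unique_map_ratio_min_pct"] == pytest.approx(87.03)
        assert summary["unique_map_ratio_max_pct"] == pytest.approx(92.64)
        assert summary["q30_min_pct"] == pytest.approx(93.79)
        assert summary["q30_max_pct"] == pytest.approx(94.53)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            summarize_library_qc(pd.DataFrame({"clean_reads": [1]}))
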