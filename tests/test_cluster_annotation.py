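"""Filter algebra, isoform reconciliation, cluster assembly and classification."""
import random

import pytest

from mxescan import (PredictionParams, apply_filters, assemble_clusters,
                     classify_cluster, detect_annotated_mxe_clusters,
                     detect_constitutive_mxe_like, flag_tandem_or_trans,
                     predict_genome, reconcile_isoforms)
from mxescan.clusters import (RULE_LENGTH_DIFF, RULE_MIN_EXON_LEN, RULE_SCORE,
                              TYPE_INITIAL, TYPE_INTERNAL, TYPE_TERMINAL)
from mxescan.gene_model import ExonUnit, GeneModel, Isoform
from mxescan.predict import MXECandidate
from mxescan.simulate import (FlankDuplication, IsoformPattern, PlantSpec,
                              generate_planted_genome)


class TestFilterAlgebra:
    """The worked example: exon 2b (18 aa) with alternatives 2a, 2c, 2d."""

    def _by_name(self, cands, expected):
        inv = {v: k for k, v in expected["intervals"].items()}
        return {inv[c.interval]: c for c in cands if c.interval in inv}

    def test_default_filters_remove_exactly_the_low_scoring_candidate(
            self, filter_demo_run):
        _, cands, expected = filter_demo_run
        survivors, report = apply_filters(cands, PredictionParams.display())
        assert sorted(self._by_name(survivors, expected)) == ["2a", "2d"]
        failed = {tuple(e["candidate"][3:5]): e["failed_rule"]
                  for e in report.entries if not e["passed"]}
        assert failed == {expected["intervals"]["2c"]: RULE_SCORE}

    def test_length_difference_cap_below_12_removes_the_long_pair(
            self, filter_demo_run):
        _, cands, expected = filter_demo_run
        survivors, report = apply_filters(
            cands, PredictionParams.store(max_len_diff=11))
        assert sorted(self._by_name(survivors, expected)) == ["2c"]
        failed = {e["failed_rule"] for e in report.entries if not e["passed"]}
        assert failed == {RULE_LENGTH_DIFF}

    def test_minimal_exon_length_19_removes_every_candidate(
            self, filter_demo_run):
        _, cands, _ = filter_demo_run
        survivors, report = apply_filters(
            cands, PredictionParams.store(min_exon_len=19))
        assert survivors == []
        assert {e["failed_rule"] for e in report.entries} == {RULE_MIN_EXON_LEN}

    def test_filtering_is_idempotent_and_order_invariant(self, planted_run):
        _, cands = planted_run
        params = PredictionParams.display()
        once, _ = apply_filters(cands, params)
        twice, _ = apply_filters(once, params)
        assert [c.to_dict() for c in twice] == [c.to_dict() for c in once]
        shuffled = list(cands)
        random.Random(0).shuffle(shuffled)
        reshuffled, _ = apply_filters(shuffled, params)
        assert {id(c) for c in reshuffled} == {id(c) for c in once}

    def test_every_candidate_reported_exactly_once(self, filter_demo_run):
        _, cands, _ = filter_demo_run
        _, report = apply_filters(cands, PredictionParams.display())
        assert len(report.entries) == len(cands)


def _manual_gene(iso_exons, gene_id="g", target="c", strand="+",
                 neighbour_exons=()):
    isoforms = []
    for t, exons in enumerate(iso_exons, 1):
        units = [ExonUnit(index=i + 1, start=s, end=e, strand=strand,
                          start_phase=0, peptide="A" * ((e - s) // 3),
                          is_initial=(i == 0), is_terminal=(i == len(exons) - 1))
                 for i, (s, e) in enumerate(exons)]
        isoforms.append(Isoform(protein_id=f"{gene_id}.t{t}", exons=units))
    return GeneModel(gene_id=gene_id, target_id=target, strand=strand,
                     isoforms=isoforms, neighbour_exons=list(neighbour_exons))


def _manual_cand(gene, transcript, exon_index, start, end, score=50.0):
    iso = next(i for i in gene.isoforms if i.protein_id == transcript)
    src = iso.exons[exon_index - 1]
    return MXECandidate(
        gene_id=gene.gene_id, transcript_id=transcript, exon_index=exon_index,
        source_start=src.start, source_end=src.end, source_nt_len=src.nt_len,
        source_aa_len=src.aa_len, target_id=gene.target_id, start=start,
        end=end, strand=gene.strand, location="downstream_intron",
        acceptor="AG", donor="GT", score=score, peptide="A" * ((end - start) // 3))


class TestReconcileIsoforms:
    def test_single_isoform_no_neighbours_all_flags_false(self):
        g = _manual_gene([[(0, 60), (100, 160)]])
        c = _manual_cand(g, "g.t1", 1, 70, 94)
        reconcile_isoforms(g, [c])
        assert not any(c.flags.values())

    def test_exact_match_with_other_isoform_confirms(self):
        g = _manual_gene([[(0, 60), (200, 260)],
                          [(0, 60), (100, 160), (200, 260)]])
        c = _manual_cand(g, "g.t1", 1, 100, 160)
        reconcile_isoforms(g, [c])
        assert c.flags["exact_match_other_isoform"]
        assert not c.flags["overlaps_other_isoform"]

    def test_shifted_overlap_is_flagged_as_potential_false_positive(self):
        g = _manual_gene([[(0, 60), (200, 260)],
                          [(0, 60), (100, 160), (200, 260)]])
        c = _manual_cand(g, "g.t1", 1, 103, 163)
        reconcile_isoforms(g, [c])
        assert c.flags["overlaps_other_isoform"]
        assert not c.flags["exact_match_other_isoform"]
        survivors, _ = apply_filters([c], PredictionParams.display(flank_nt=0))
        assert survivors == []
        kept, _ = apply_filters(
            [c], PredictionParams.display(exclude_isoform_overlaps=False))
        assert kept == [c]

    def test_neighbour_gene_overlap_flagged(self):
        g = _manual_gene([[(0, 60), (200, 260)]],
                         neighbour_exons=[(300, 400)])
        c = _manual_cand(g, "g.t1", 2, 290, 350)
        reconcile_isoforms(g, [c])
        assert c.flags["overlaps_neighbour_gene"]


class TestAnnotatedMXEDetection:
    def test_single_isoform_yields_no_clusters(self):
        g = _manual_gene([[(0, 60), (100, 160), (200, 260)]])
        assert detect_annotated_mxe_clusters(g) == []

    def test_swapped_exon_pair_is_a_cluster(self):
        g = _manual_gene([[(0, 60), (100, 160), (300, 360)],
                          [(0, 60), (200, 260), (300, 360)]])
        clusters = detect_annotated_mxe_clusters(g)
        assert len(clusters) == 1
        assert clusters[0].intervals() == [(100, 160), (200, 260)]
        assert clusters[0].cluster_type == TYPE_INTERNAL

    def test_cassette_pattern_disqualifies_the_group(self):
        g = _manual_gene([[(0, 60), (100, 160), (300, 360)],
                          [(0, 60), (100, 160), (200, 260), (300, 360)]])
        assert detect_annotated_mxe_clusters(g) == []

    def test_isoform_skipping_the_cluster_disqualifies(self):
        g = _manual_gene([[(0, 60), (100, 160), (300, 360)],
                          [(0, 60), (200, 260), (300, 360)],
                          [(0, 60), (300, 360)]])
        assert detect_annotated_mxe_clusters(g) == []

    def test_three_way_cluster_across_three_isoforms(self):
        g = _manual_gene([[(0, 60), (100, 160), (400, 460)],
                          [(0, 60), (200, 260), (400, 460)],
                          [(0, 60), (300, 360), (400, 460)]])
        clusters = detect_annotated_mxe_clusters(g)
        assert len(clusters) == 1 and len(clusters[0].members) == 3


class TestConstitutiveMXELike:
    def test_identical_adjacent_exons_flagged(self):
        g = _manual_gene([[(0, 60), (100, 160), (200, 260)]])
        pairs = detect_constitutive_mxe_like(g, PredictionParams.display())
        assert ((0, 60), (100, 160)) in pairs

    def test_frame_incompatible_neighbours_not_flagged(self):
        g = _manual_gene([[(0, 60), (100, 161), (200, 260)]])
        pairs = detect_constitutive_mxe_like(g, PredictionParams.display())
        assert ((0, 60), (100, 161)) not in pairs

    def test_duplicated_exon_block_at_70_percent_identity_flagged(self):
        spec = PlantSpec(genes=1, seed=17, isoform_patterns={
            0: IsoformPattern("constitutive_duplicate", 2, identity=0.7,
                              ensure_score_above=15.0)})
        ds = generate_planted_genome(spec)
        g = ds.gene_models()[0]
        pairs = detect_constitutive_mxe_like(g, PredictionParams.display())
        assert len(pairs) == 1


class TestAssembleAndClassify:
    def test_one_source_with_two_disjoint_candidates_is_one_cluster_of_three(self):
        g = _manual_gene([[(0, 60), (300, 360), (600, 660)]])
        cands = [_manual_cand(g, "g.t1", 2, 400, 460, 80.0),
                 _manual_cand(g, "g.t1", 2, 480, 540, 60.0)]
        clusters = assemble_clusters(g, cands)
        assert len(clusters) == 1 and len(clusters[0].members) == 3
        assert clusters[0].cluster_type == TYPE_INTERNAL

    def test_worked_example_cluster_of_four_is_internal(self, filter_demo_run):
        genes, cands, expected = filter_demo_run
        clusters = assemble_clusters(genes[0], cands)
        assert len(clusters) == 1
        cl = clusters[0]
        assert len(cl.members) == 4
        assert cl.cluster_type == TYPE_INTERNAL
        assert set(cl.intervals()) == \
            set(expected["intervals"].values()) | {expected["source_interval"]}

    def test_mutually_predicting_exons_merge_into_one_cluster(self):
        ds = generate_planted_genome(PlantSpec(genes=1, seed=5, isoform_patterns={
            0: IsoformPattern("annotated_mxe", 2, identity=0.85,
                              ensure_score_above=25.0)}))
        genes = ds.gene_models()
        cands = predict_genome(genes, ds.genome, PredictionParams.display())
        survivors, _ = apply_filters(cands, PredictionParams.display())
        assert len({c.transcript_id for c in survivors}) == 2
        clusters = assemble_clusters(genes[0], survivors)
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_cluster_containing_first_exon_is_initial(self):
        g = _manual_gene([[(0, 60), (300, 360), (600, 660)]])
        cands = [_manual_cand(g, "g.t1", 1, 100, 160, 70.0)]
        (cl,) = assemble_clusters(g, cands)
        assert cl.cluster_type == TYPE_INITIAL

    def test_cluster_containing_last_exon_is_terminal(self):
        g = _manual_gene([[(0, 60), (300, 360), (600, 660)]])
        cands = [_manual_cand(g, "g.t1", 3, 400, 460, 70.0)]
        (cl,) = assemble_clusters(g, cands)
        assert cl.cluster_type == TYPE_TERMINAL

    def test_two_exon_isoform_tie_breaks_to_initial(self):
        # exons 1 and 2 mutually predict each other, so the merged cluster
        # contains both the first and the last coding exon
        g = _manual_gene([[(0, 60), (300, 360)]])
        cands = [_manual_cand(g, "g.t1", 1, 300, 360, 70.0),
                 _manual_cand(g, "g.t1", 2, 0, 60, 70.0)]
        (cl,) = assemble_clusters(g, cands)
        assert set(cl.intervals()) == {(0, 60), (300, 360)}
        assert cl.cluster_type == TYPE_INITIAL

    def test_each_candidate_in_at_most_one_cluster(self, planted_run):
        genes, cands = planted_run
        survivors, _ = apply_filters(cands, PredictionParams.display())
        seen = set()
        for g in genes:
            for cl in assemble_clusters(
                    g, [c for c in survivors if c.gene_id == g.gene_id]):
                for m in cl.members:
                    key = (g.gene_id, m.interval)
                    assert key not in seen
                    seen.add(key)


class TestTandemOrTrans:
    def _run(self, preserve_order):
        spec = PlantSpec(genes=1, seed=23, strands="+", flank_duplications={
            0: FlankDuplication(exons=(2, 3), preserve_order=preserve_order)})
        ds = generate_planted_genome(spec)
        genes = ds.gene_models()
        cands = predict_genome(genes, ds.genome, PredictionParams.store())
        return genes[0], cands

    def test_no_flank_candidates_is_false(self, planted_run):
        genes, cands = planted_run
        for g in genes:
            own = [c for c in cands if c.gene_id == g.gene_id
                   and c.location.endswith("flank")]
            if not own:
                flagged, support = flag_tandem_or_trans(g, own)
                assert flagged is False and support == []

    def test_ordered_downstream_copies_flag_the_gene(self):
        gene, cands = self._run(preserve_order=True)
        flagged, support = flag_tandem_or_trans(gene, cands)
        assert flagged is True
        assert len({c.exon_index for c in support}) >= 2

    def test_inverted_order_copies_do_not_flag(self):
        gene, cands = self._run(preserve_order=False)
        flagged, _ = flag_tandem_or_trans(gene, cands)
        assert flagged is False
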