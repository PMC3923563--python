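"""Similarity scoring, candidate enumeration and prediction properties."""
import numpy as np
import pytest

from _oracles import (brute_force_candidates, gotoh_global_score,
                      naive_overlap_resolution, similarity_percent_oracle)
from mxescan import (PredictionParams, enumerate_candidates, frame_compatible,
                     predict_gene, predict_genome, resolve_overlapping_candidates,
                     similarity_score)
from mxescan.formats_io import RawGene, RawIsoform, TargetSequence
from mxescan.gene_model import ExonUnit, build_gene_models, reverse_complement
from mxescan.predict import MXECandidate, SearchRegion
from mxescan.simulate import PlantSpec, _back_translate, generate_planted_genome

AA = "ACDEFGHIKLMNPQRSTVWY"


def _pep(rng, n):
    return "".join(AA[i] for i in rng.integers(0, 20, size=n))


class TestSimilarityScore:
    def test_identical_peptides_score_exactly_100(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = _pep(rng, int(rng.integers(5, 60)))
            assert similarity_score(p, p) == 100.0

    def test_matches_independent_dp_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a = _pep(rng, int(rng.integers(3, 50)))
            b = _pep(rng, int(rng.integers(3, 50)))
            assert similarity_score(a, b) == \
                pytest.approx(similarity_percent_oracle(a, b), abs=1e-9)

    def test_shuffled_pairs_rarely_reach_the_default_threshold(self):
        rng = np.random.default_rng(5)
        below = 0
        for _ in range(100):
            p = _pep(rng, 30)
            q = "".join(rng.permutation(list(p)))
            if similarity_score(p, q) < 15.0:
                below += 1
        assert below >= 95

    def test_error_contracts(self):
        with pytest.raises(ValueError, match="empty"):
            similarity_score("", "MKV")
        with pytest.raises(ValueError, match="residues"):
            similarity_score("MKX", "MKV")
        with pytest.raises(ValueError, match="self-alignment"):
            # no positive self-score is possible only via the override
            similarity_score("MKV", "MKV", self_score=-1.0)


class TestFrameCompatible:
    @pytest.mark.parametrize("a,b,ok", [(60, 63, True), (60, 62, False),
                                        (60, 60, True), (60, 57, True),
                                        (60, 59, False)])
    def test_examples(self, a, b, ok):
        assert frame_compatible(a, b) is ok

    def test_rejects_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            frame_compatible(0, 60)


def _region(seq, loc="downstream_intron", strand="+", gstart=0):
    return SearchRegion(target_id="c", gstart=gstart, gend=gstart + len(seq),
                        strand=strand, seq=seq, location=loc)


def _source(rng, n_aa=20, phase=0):
    pep = _pep(rng, n_aa)
    seq = "N" * 0 + _back_translate(rng, pep)
    return ExonUnit(index=2, start=1000, end=1000 + len(seq), strand="+",
                    start_phase=phase, peptide=pep), seq


class TestEnumerateCandidates:
    def test_region_without_acceptor_yields_nothing(self):
        rng = np.random.default_rng(6)
        src, _ = _source(rng)
        seq = ("GT" + "C" * 200).replace("AG", "CC")
        assert enumerate_candidates(_region(seq), src, PredictionParams.store()) == []

    def test_planted_exact_copy_found_with_score_100(self):
        rng = np.random.default_rng(7)
        src, seq = _source(rng, 25)
        intron = "GT" + "T" * 40 + "AG" + seq + "GT" + "T" * 40 + "AG"
        out = enumerate_candidates(_region(intron), src, PredictionParams.store())
        exact = [c for c in out if c.interval == (44, 44 + len(seq))]
        assert len(exact) == 1
        c = exact[0]
        assert c.score == 100.0 and c.len_diff_aa == 0
        assert c.acceptor == "AG" and c.donor == "GT"

    def test_candidates_spanning_n_are_skipped(self):
        rng = np.random.default_rng(8)
        src, seq = _source(rng, 20)
        half = len(seq) // 2
        seq_n = seq[:half] + "N" + seq[half + 1:]
        intron = "GT" + "T" * 40 + "AG" + seq_n + "GT" + "T" * 40 + "AG"
        out = enumerate_candidates(_region(intron), src, PredictionParams.store())
        assert all("N" not in c.peptide for c in out)
        assert not any(c.start <= 44 + half < c.end for c in out)

    @pytest.mark.parametrize("seed", range(1, 9))
    def test_matches_literal_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        src, src_seq = _source(rng, int(rng.integers(15, 30)))
        n = int(rng.integers(400, 1200))
        intron = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
        params = PredictionParams.store()
        got = enumerate_candidates(_region(intron), src, params,
                                   resolve_overlaps=False)
        want = brute_force_candidates(
            intron, src.nt_len, src.start_phase, src.peptide,
            min_score=params.min_score, max_len_diff=params.max_len_diff,
            margin=params.min_candidate_margin,
            score_fn=lambda a, b: similarity_score(a, b))
        assert {(c.start, c.end, round(c.score, 9)) for c in got} == \
            {(s, e, round(sc, 9)) for (s, e, sc) in want}


def _cand(start, end, score, len_diff=0):
    return MXECandidate(
        gene_id="g", transcript_id="t", exon_index=2, source_start=0,
        source_end=60, source_nt_len=60, source_aa_len=20, target_id="c",
        start=start, end=end, strand="+", location="downstream_intron",
        acceptor="AG", donor="GT", score=score,
        peptide="A" * (20 + len_diff))


class TestResolveOverlaps:
    def test_disjoint_candidates_all_kept(self):
        a, b = _cand(0, 60, 50.0), _cand(100, 160, 20.0)
        assert resolve_overlapping_candidates([a, b]) == [a, b]

    def test_higher_score_wins_overlap(self):
        a, b = _cand(0, 60, 80.0), _cand(30, 90, 40.0)
        assert resolve_overlapping_candidates([a, b]) == [a]

    def test_random_sets_match_naive_repeated_maximum(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            cands = []
            for _ in range(int(rng.integers(2, 12))):
                s = int(rng.integers(0, 300))
                cands.append(_cand(s, s + int(rng.integers(30, 90)),
                                   float(rng.integers(10, 100)),
                                   len_diff=int(rng.integers(0, 5))))
            got = resolve_overlapping_candidates(cands)
            want = naive_overlap_resolution(cands)
            assert [(c.start, c.end) for c in got] == \
                [(c.start, c.end) for c in want]


class TestPredictGene:
    def test_single_exon_gene_without_flanks_has_no_candidates(self):
        seq = "ATG" + "GCC" * 30 + "TAA"
        genome = {"c": TargetSequence("c", "T" * 50 + seq + "T" * 50)}
        rg = RawGene("g", "c", "+", [RawIsoform("t", "+", [(50, 50 + len(seq), 0)])])
        gene = build_gene_models([rg], genome)[0]
        assert predict_gene(gene, genome, PredictionParams.display()) == []

    def test_scope_all_is_superset_of_flanking(self, planted_ds):
        genes = planted_ds.gene_models()
        flanking = predict_genome(genes, planted_ds.genome,
                                  PredictionParams.display())
        everything = predict_genome(genes, planted_ds.genome,
                                    PredictionParams.display(scope="all"))
        key = lambda cs: {(c.transcript_id, c.exon_index) + c.interval for c in cs}
        assert key(flanking) <= key(everything)

    def test_store_profile_is_superset_of_display(self, planted_ds, planted_run):
        genes, store = planted_run
        display = predict_genome(genes, planted_ds.genome,
                                 PredictionParams.display())
        key = lambda cs: {(c.transcript_id, c.exon_index) + c.interval for c in cs}
        assert key(display) <= key(store)

    def test_prediction_is_deterministic(self, planted_ds):
        genes = planted_ds.gene_models()
        a = predict_genome(genes, planted_ds.genome, PredictionParams.display())
        b = predict_genome(genes, planted_ds.genome, PredictionParams.display())
        assert [c.to_dict() for c in a] == [c.to_dict() for c in b]

    def test_rescoring_reproduces_stored_scores(self, planted_ds, planted_run):
        genes, cands = planted_run
        by_id = {(g.gene_id, iso.protein_id): iso for g in genes
                 for iso in g.isoforms}
        for c in cands:
            iso = by_id[(c.gene_id, c.transcript_id)]
            src = iso.exons[c.exon_index - 1]
            assert similarity_score(src.scoring_peptide, c.peptide) == c.score

    def test_intronic_candidates_have_splice_sites_in_genome(self, planted_ds,
                                                             planted_run):
        genes, cands = planted_run
        contig = planted_ds.genome[genes[0].target_id].seq
        intronic = [c for c in cands if c.location.endswith("intron")]
        assert intronic
        for c in intronic:
            if c.strand == "+":
                acc = contig[c.start - 2:c.start]
                don = contig[c.end:c.end + 2]
            else:
                acc = reverse_complement(contig[c.end:c.end + 2])
                don = reverse_complement(contig[c.start - 2:c.start])
            assert acc == "AG" and don in ("GT", "GC")

    def test_strand_symmetry_of_predictions(self):
        ds = generate_planted_genome(
            PlantSpec.one_internal_cluster_per_gene(4, 0.8, seed=33, strands="+"))
        genes = ds.gene_models()
        contig = next(iter(ds.genome.values()))
        L = contig.length
        mirror = {contig.id: TargetSequence(contig.id,
                                            reverse_complement(contig.seq))}
        mirrored_raw = []
        for rg in ds.raw_genes:
            mrg = RawGene(rg.gene_id, rg.target_id, "-", [])
            for iso in rg.isoforms:
                cds = [(L - e, L - s, ph) for (s, e, ph) in iso.cds]
                mrg.isoforms.append(RawIsoform(iso.transcript_id, "-", cds))
            mirrored_raw.append(mrg)
        mirror_genes = build_gene_models(mirrored_raw, mirror)
        params = PredictionParams.display()
        fwd = predict_genome(genes, ds.genome, params)
        rev = predict_genome(mirror_genes, mirror, params)
        fwd_key = sorted((c.transcript_id, c.exon_index, c.start, c.end,
                          round(c.score, 9)) for c in fwd)
        rev_key = sorted((c.transcript_id, c.exon_index, L - c.end, L - c.start,
                          round(c.score, 9)) for c in rev)
        assert fwd_key == rev_key and len(fwd) > 0
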