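"""Enumeration and scoring of mutually-exclusive-exon candidates.

For every sufficiently long coding exon, the search walks the configured
regions (the surrounding introns, optionally all introns, optionally the gene
flanks) and considers every stretch bounded by an ``AG`` acceptor immediately
5' and a ``GT``/``GC`` donor immediately 3' on the coding strand.  A stretch
survives enumeration if its length is reading-frame compatible with the
original exon, the length difference stays within the allowed number of
codons, its complete codons (in the frame imposed by the original exon's
start phase) contain no stop, it keeps a safety margin to the region edges,
and its peptide scores at least ``min_score`` percent of the original exon's
self-alignment score.  Mutually overlapping candidates within one region are
reduced to the best-scoring one.
"""
from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from .align import alignment_score, similarity_score
from .gene_model import ExonUnit, GeneModel, Isoform, exon_peptide, reverse_complement
from .params import SCOPE_ALL, SCOPE_FLANKING, PredictionParams

log = logging.getLogger(__name__)

LOC_UPSTREAM_INTRON = "upstream_intron"
LOC_DOWNSTREAM_INTRON = "downstream_intron"
LOC_OTHER_INTRON = "other_intron"
LOC_UPSTREAM_FLANK = "upstream_flank"
LOC_DOWNSTREAM_FLANK = "downstream_flank"

INTRON_LOCATIONS = (LOC_UPSTREAM_INTRON, LOC_DOWNSTREAM_INTRON, LOC_OTHER_INTRON)
FLANK_LOCATIONS = (LOC_UPSTREAM_FLANK, LOC_DOWNSTREAM_FLANK)

_LOCATION_RANK = {loc: i for i, loc in enumerate(
    (LOC_UPSTREAM_FLANK, LOC_UPSTREAM_INTRON, LOC_DOWNSTREAM_INTRON,
     LOC_OTHER_INTRON, LOC_DOWNSTREAM_FLANK))}

_STOPS = {"TAA", "TAG", "TGA"}


def frame_compatible(original_nt_len: int, candidate_nt_len: int) -> bool:
    """True iff replacing the original exon preserves the reading frame."""
    if original_nt_len < 1 or candidate_nt_len < 1:
        raise ValueError("exon lengths must be >= 1 nt")
    return (candidate_nt_len - original_nt_len) % 3 == 0


@dataclass
class SearchRegion:
    """A stretch of genome searched for candidates, in coding orientation.

    ``seq`` is the region on the coding strand; ``gstart``/``gend`` are its
    forward-strand genomic bounds.  ``require_acceptor``/``require_donor``
    relax the splice-site requirement on the gene-terminal side of flank
    searches for initial/terminal exons (an initial exon has no acceptor, a
    terminal exon no donor).
    """

    target_id: str
    gstart: int
    gend: int
    strand: str
    seq: str
    location: str
    require_acceptor: bool = True
    require_donor: bool = True

    def local_to_genomic(self, s: int, e: int) -> tuple[int, int]:
        if self.strand == "+":
            return (self.gstart + s, self.gstart + e)
        return (self.gend - e, self.gend - s)


@dataclass
class MXECandidate:
    """A predicted alternative exon for one source exon of one isoform."""

    gene_id: str
    transcript_id: str
    exon_index: int
    source_start: int
    source_end: int
    source_nt_len: int
    source_aa_len: int
    target_id: str
    start: int
    end: int
    strand: str
    location: str
    acceptor: str               # "AG", or "" where the requirement was waived
    donor: str                  # "GT"/"GC", or ""
    score: float
    peptide: str
    flags: dict = field(default_factory=lambda: {
        "exact_match_other_isoform": False,
        "overlaps_other_isoform": False,
        "overlaps_neighbour_gene": False,
        "matches_annotated_same_isoform": False,
    })

    @property
    def nt_len(self) -> int:
        return self.end - self.start

    @property
    def len_diff_aa(self) -> int:
        return abs(self.nt_len - self.source_nt_len) // 3

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def source_interval(self) -> tuple[int, int]:
        return (self.source_start, self.source_end)

    def sort_key(self):
        return (self.gene_id, self.transcript_id, self.exon_index,
                _LOCATION_RANK[self.location], self.start, self.end)

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id, "transcript_id": self.transcript_id,
            "exon_index": self.exon_index,
            "source_start": self.source_start, "source_end": self.source_end,
            "source_nt_len": self.source_nt_len,
            "source_aa_len": self.source_aa_len,
            "target_id": self.target_id, "start": self.start, "end": self.end,
            "strand": self.strand, "location": self.location,
            "acceptor": self.acceptor, "donor": self.donor,
            "nt_len": self.nt_len, "len_diff_aa": self.len_diff_aa,
            "score": self.score, "peptide": self.peptide,
            "flags": dict(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MXECandidate":
        d = dict(d)
        d.pop("nt_len", None)
        d.pop("len_diff_aa", None)
        d["flags"] = dict(d.get("flags") or {})
        return cls(**d)


# ---------------------------------------------------------------------------
# enumeration

def enumerate_candidates(region: SearchRegion, source: ExonUnit,
                         params: PredictionParams, *,
                         gene_id: str = "", transcript_id: str = "",
                         resolve_overlaps: bool = True) -> list[MXECandidate]:
    """All candidates for ``source`` within one search region.

    Works in region-local coordinates on the coding strand and maps hits back
    to forward-strand genomic intervals.  Candidates spanning an ``N`` are
    skipped with a warning.  By default mutually overlapping candidates are
    reduced via :func:`resolve_overlapping_candidates`.
    """
    seq = region.seq
    n = len(seq)
    orig_pep = source.scoring_peptide
    if not orig_pep:
        return []
    orig_len = source.nt_len
    phase = source.start_phase
    margin = params.min_candidate_margin
    max_diff_nt = 3 * params.max_len_diff

    self_score = alignment_score(orig_pep, orig_pep, params.matrix,
                                 params.gap_open, params.gap_extend)
    if self_score <= 0:
        raise ValueError(f"degenerate source exon {source.index}: self-score <= 0")

    starts = _acceptor_starts(seq, margin, region.require_acceptor)
    ends = _donor_ends(seq, margin, region.require_donor)

    out: list[MXECandidate] = []
    lo_len = max(orig_len - max_diff_nt, phase + 3)
    hi_len = orig_len + max_diff_nt
    for s in starts:
        i = bisect_left(ends, s + lo_len)
        j = bisect_right(ends, s + hi_len)
        for e in ends[i:j]:
            cand_len = e - s
            if (cand_len - orig_len) % 3 != 0:
                continue
            cand = _try_candidate(region, seq, s, e, source, orig_pep,
                                  self_score, params, gene_id, transcript_id)
            if cand is not None:
                out.append(cand)
    out.sort(key=lambda c: (c.start, c.end))
    if resolve_overlaps:
        out = resolve_overlapping_candidates(out)
    return out


def _acceptor_starts(seq: str, margin: int, require: bool) -> list[int]:
    n = len(seq)
    lo = max(margin, 2)
    if not require:
        return list(range(margin, n - margin + 1))
    return [s for s in range(lo, n - margin + 1) if seq[s - 2:s] == "AG"]


def _donor_ends(seq: str, margin: int, require: bool) -> list[int]:
    n = len(seq)
    if not require:
        return list(range(margin, n - margin + 1))
    return [e for e in range(margin, n - margin + 1)
            if seq[e:e + 2] in ("GT", "GC")]


def _try_candidate(region, seq, s, e, source, orig_pep, self_score, params,
                   gene_id, transcript_id):
    cand_seq = seq[s:e]
    window = seq[max(s - 2, 0):min(e + 2, len(seq))]
    if "N" in window:
        log.warning("candidate [%d,%d) in %s region skipped: contains N",
                    s, e, region.location)
        return None
    phase = source.start_phase
    body = cand_seq[phase:]
    body = body[: len(body) - len(body) % 3]
    if not body:
        return None
    for k in range(0, len(body), 3):
        if body[k:k + 3] in _STOPS:
            return None
    pep = exon_peptide(cand_seq, phase)
    if not pep:
        return None
    score = similarity_score(orig_pep, pep, params.matrix, params.gap_open,
                             params.gap_extend, self_score=self_score)
    if score < params.min_score:
        return None
    gs, ge = region.local_to_genomic(s, e)
    acceptor = seq[s - 2:s] if region.require_acceptor else \
        (seq[s - 2:s] if seq[s - 2:s] == "AG" and s >= 2 else "")
    donor = seq[e:e + 2] if region.require_donor else \
        (seq[e:e + 2] if seq[e:e + 2] in ("GT", "GC") else "")
    return MXECandidate(
        gene_id=gene_id, transcript_id=transcript_id, exon_index=source.index,
        source_start=source.start, source_end=source.end,
        source_nt_len=source.nt_len, source_aa_len=source.aa_len,
        target_id=region.target_id, start=gs, end=ge, strand=region.strand,
        location=region.location, acceptor=acceptor, donor=donor,
        score=score, peptide=pep)


def resolve_overlapping_candidates(cands: list[MXECandidate]) -> list[MXECandidate]:
    """Reduce mutually overlapping candidates to the best one.

    Repeatedly keeps the highest-scoring remaining candidate (ties: smaller
    length difference, then 5'-most genomic start) and discards everything
    overlapping it.  Disjoint candidates are all retained.
    """
    remaining = sorted(cands, key=lambda c: (-c.score, c.len_diff_aa, c.start, c.end))
    kept: list[MXECandidate] = []
    for c in remaining:
        if all(c.end <= k.start or k.end <= c.start for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: (c.start, c.end))
    return kept


# ---------------------------------------------------------------------------
# per-gene / per-genome prediction

def predict_gene(gene: GeneModel, genome, params: PredictionParams) -> list[MXECandidate]:
    """Predict candidates for every isoform of a gene, independently.

    Each original exon with ``aa_len >= min_exon_len`` seeds a search over
    the regions implied by ``params.scope`` (plus the gene flanks when
    ``flank_nt > 0``); overlapping candidates are resolved per region.  The
    result is deterministically ordered by source exon, location and start.
    """
    target = genome[gene.target_id]
    out: list[MXECandidate] = []
    for iso in gene.isoforms:
        for exon in iso.exons:
            if exon.aa_len < params.min_exon_len:
                continue
            for region in _regions_for_exon(gene, iso, exon, target, params):
                out.extend(enumerate_candidates(
                    region, exon, params, gene_id=gene.gene_id,
                    transcript_id=iso.protein_id))
    out.sort(key=MXECandidate.sort_key)
    return out


def _regions_for_exon(gene: GeneModel, iso: Isoform, exon: ExonUnit,
                      target, params: PredictionParams) -> list[SearchRegion]:
    regions: list[SearchRegion] = []
    introns = iso.introns             # transcription order
    k = exon.index                    # 1-based
    for idx, (istart, iend) in enumerate(introns, start=1):
        if idx == k - 1:
            loc = LOC_UPSTREAM_INTRON
        elif idx == k:
            loc = LOC_DOWNSTREAM_INTRON
        else:
            loc = LOC_OTHER_INTRON
        if params.scope == SCOPE_FLANKING and loc == LOC_OTHER_INTRON:
            continue
        if iend - istart < 4:
            continue
        regions.append(_make_region(target, istart, iend, iso.strand, loc))
    if params.flank_nt > 0:
        regions.extend(_flank_regions(gene, exon, target, params))
    return regions


def _flank_regions(gene, exon, target, params):
    ls, le = gene.locus
    flank = params.flank_nt
    regions = []
    # genomic-left window; transcription-upstream for "+", downstream for "-"
    left = (max(0, ls - flank), ls)
    right = (le, min(target.length, le + flank))
    if gene.strand == "+":
        pairs = [(left, LOC_UPSTREAM_FLANK), (right, LOC_DOWNSTREAM_FLANK)]
    else:
        pairs = [(right, LOC_UPSTREAM_FLANK), (left, LOC_DOWNSTREAM_FLANK)]
    for (gs, ge), loc in pairs:
        if ge - gs < 2 * params.min_candidate_margin + 3:
            continue
        region = _make_region(target, gs, ge, gene.strand, loc)
        # an initial exon has no acceptor, a terminal exon no donor: waive the
        # corresponding requirement on the gene-terminal side only
        if loc == LOC_UPSTREAM_FLANK and exon.is_initial:
            region.require_acceptor = False
        if loc == LOC_DOWNSTREAM_FLANK and exon.is_terminal:
            region.require_donor = False
        regions.append(region)
    return regions


def _make_region(target, gstart, gend, strand, location) -> SearchRegion:
    raw = target.seq[gstart:gend]
    seq = raw if strand == "+" else reverse_complement(raw)
    return SearchRegion(target_id=target.id, gstart=gstart, gend=gend,
                        strand=strand, seq=seq, location=location)


def predict_genome(genes: list[GeneModel], genome,
                   params: PredictionParams) -> list[MXECandidate]:
    """Run prediction over every gene and reconcile isoform/neighbour overlaps."""
    from .clusters import reconcile_isoforms
    out: list[MXECandidate] = []
    for gene in genes:
        cands = predict_gene(gene, genome, params)
        reconcile_isoforms(gene, cands)
        out.extend(cands)
    return out
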