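"""Filtering, reconciliation, cluster assembly and classification.

Prediction stores a relaxed candidate set; everything here is pure
post-processing, so the stored set can be re-filtered with stricter display
parameters without re-running the genome scan.  Clusters group each original
exon with its surviving alternatives; clusters that share a member, or whose
source exons predict each other, are merged by transitive closure.  A cluster
containing a first coding exon is "initial" (multiple-promoters mechanism),
one containing a last coding exon is "terminal" (multiple poly(A) sites), and
everything else is "internal" — the class whose inclusion is controlled at
the level of splicing proper.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import similarity_score
from .gene_model import GeneModel
from .params import SCOPE_FLANKING, PredictionParams
from .predict import (FLANK_LOCATIONS, LOC_DOWNSTREAM_INTRON, LOC_UPSTREAM_INTRON,
                      MXECandidate, frame_compatible)

log = logging.getLogger(__name__)

RULE_SCORE = "score"
RULE_LENGTH_DIFF = "length_diff"
RULE_MIN_EXON_LEN = "min_exon_len"
RULE_SCOPE = "scope"
RULE_OVERLAP = "overlap"
FILTER_RULES = (RULE_SCORE, RULE_LENGTH_DIFF, RULE_MIN_EXON_LEN,
                RULE_SCOPE, RULE_OVERLAP)

PROV_ANNOTATED = "annotated_mxe"
PROV_PREDICTED = "predicted_new"
PROV_CONSTITUTIVE_LIKE = "constitutive_mxe_like"

TYPE_INITIAL = "initial"
TYPE_INTERNAL = "internal"
TYPE_TERMINAL = "terminal"


@dataclass
class ClusterMember:
    start: int
    end: int
    provenance: str                    # annotated_mxe | predicted_new | constitutive_mxe_like
    score: float | None = None         # None for annotated members
    source_exon: tuple | None = None   # (transcript_id, exon_index) for predictions

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def to_dict(self) -> dict:
        return {"start": self.start, "end": self.end,
                "provenance": self.provenance, "score": self.score,
                "source_exon": list(self.source_exon) if self.source_exon else None}

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterMember":
        d = dict(d)
        if d.get("source_exon"):
            d["source_exon"] = tuple(d["source_exon"])
        return cls(**d)


@dataclass
class MXECluster:
    """An ordered group of mutually exclusive exons within one gene."""

    gene_id: str
    target_id: str
    cluster_id: str
    members: list[ClusterMember]
    cluster_type: str = TYPE_INTERNAL

    def intervals(self) -> list[tuple[int, int]]:
        return [m.interval for m in self.members]

    def to_dict(self) -> dict:
        return {"gene_id": self.gene_id, "target_id": self.target_id,
                "cluster_id": self.cluster_id,
                "cluster_type": self.cluster_type,
                "members": [m.to_dict() for m in self.members]}

    @classmethod
    def from_dict(cls, d: dict) -> "MXECluster":
        return cls(gene_id=d["gene_id"], target_id=d["target_id"],
                   cluster_id=d["cluster_id"], cluster_type=d["cluster_type"],
                   members=[ClusterMember.from_dict(m) for m in d["members"]])


@dataclass
class FilterReport:
    """Per-candidate outcome of :func:`apply_filters`."""

    entries: list[dict] = field(default_factory=list)

    def add(self, candidate: MXECandidate, failed_rule: str | None) -> None:
        self.entries.append({
            "candidate": (candidate.gene_id, candidate.transcript_id,
                          candidate.exon_index, candidate.start, candidate.end),
            "passed": failed_rule is None,
            "failed_rule": failed_rule,
        })

    @property
    def n_passed(self) -> int:
        return sum(1 for e in self.entries if e["passed"])


# ---------------------------------------------------------------------------
# filtering

def apply_filters(candidates: list[MXECandidate], params: PredictionParams
                  ) -> tuple[list[MXECandidate], FilterReport]:
    """Pure re-filtering of stored candidates under display parameters.

    Each rule is an independent predicate (score, length difference, minimal
    original exon length, search scope, isoform-overlap exclusion), so the
    surviving set does not depend on rule order; the report records the first
    failing rule per candidate in the canonical order.
    """
    report = FilterReport()
    survivors = []
    for c in candidates:
        failed = _first_failing_rule(c, params)
        report.add(c, failed)
        if failed is None:
            survivors.append(c)
    return survivors, report


def _first_failing_rule(c: MXECandidate, params: PredictionParams) -> str | None:
    if c.score < params.min_score:
        return RULE_SCORE
    if c.len_diff_aa > params.max_len_diff:
        return RULE_LENGTH_DIFF
    if c.source_aa_len < params.min_exon_len:
        return RULE_MIN_EXON_LEN
    if not _scope_allows(c, params):
        return RULE_SCOPE
    if (params.exclude_isoform_overlaps
            and c.flags.get("overlaps_other_isoform")
            and not c.flags.get("exact_match_other_isoform")):
        return RULE_OVERLAP
    return None


def _scope_allows(c: MXECandidate, params: PredictionParams) -> bool:
    if c.location in FLANK_LOCATIONS:
        return params.flank_nt > 0
    if params.scope == SCOPE_FLANKING:
        return c.location in (LOC_UPSTREAM_INTRON, LOC_DOWNSTREAM_INTRON)
    return True


# ---------------------------------------------------------------------------
# reconciliation across isoforms and neighbour genes

def reconcile_isoforms(gene: GeneModel, candidates: list[MXECandidate]) -> list[MXECandidate]:
    """Set overlap/exact-match flags on candidates, in place.

    A candidate exactly matching an exon of another isoform is confirmation;
    one merely overlapping it is a potential false positive (deselectable);
    overlap with an exon of a neighbouring gene is flagged separately.
    """
    exons_by_iso = {iso.protein_id: [e.interval for e in iso.exons]
                    for iso in gene.isoforms}
    for c in candidates:
        own = set(exons_by_iso.get(c.transcript_id, []))
        exact = overlap = False
        for iso_id, intervals in exons_by_iso.items():
            if iso_id == c.transcript_id:
                continue
            for (s, e) in intervals:
                if (s, e) == c.interval:
                    exact = True
                elif s < c.end and c.start < e:
                    overlap = True
        c.flags["exact_match_other_isoform"] = exact
        c.flags["overlaps_other_isoform"] = overlap
        c.flags["matches_annotated_same_isoform"] = c.interval in own
        c.flags["overlaps_neighbour_gene"] = any(
            s < c.end and c.start < e for (s, e) in gene.neighbour_exons)
    return candidates


# ---------------------------------------------------------------------------
# annotated clusters

def detect_annotated_mxe_clusters(gene: GeneModel) -> list[MXECluster]:
    """Clusters of mutually exclusive exons already present in the annotation.

    A group of >=2 neighbouring, mutually non-overlapping exons qualifies iff
    every annotated isoform of the gene includes exactly and only one member;
    an isoform containing two members (cassette pattern) or none disqualifies
    the group.  "Neighbouring" means no annotated exon of any isoform lies
    strictly between group members.
    """
    if len(gene.isoforms) < 2:
        return []
    intervals = gene.annotated_exon_intervals()
    iso_sets = [frozenset(e.interval for e in iso.exons) for iso in gene.isoforms]

    parent = {iv: iv for iv in intervals}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i, a in enumerate(intervals):
        for b in intervals[i + 1:]:
            if _alternative_pair(a, b, intervals, iso_sets):
                union(a, b)

    groups: dict[tuple, list[tuple[int, int]]] = {}
    for iv in intervals:
        groups.setdefault(find(iv), []).append(iv)

    clusters = []
    for members in groups.values():
        members.sort()
        if len(members) < 2:
            continue
        if any(a[1] > b[0] for a, b in zip(members, members[1:])):
            continue
        mset = set(members)
        if not all(len(mset & s) == 1 for s in iso_sets):
            continue
        clusters.append(MXECluster(
            gene_id=gene.gene_id, target_id=gene.target_id,
            cluster_id=f"{gene.gene_id}.annot{len(clusters) + 1}",
            members=[ClusterMember(s, e, PROV_ANNOTATED) for (s, e) in members]))
    clusters.sort(key=lambda cl: cl.members[0].interval)
    for cl in clusters:
        cl.cluster_type = classify_cluster(cl, gene)
    return clusters


def _alternative_pair(a, b, intervals, iso_sets) -> bool:
    if a[1] > b[0] and b[1] > a[0]:          # overlapping: never alternatives
        return False
    lo, hi = (a, b) if a <= b else (b, a)
    for s in iso_sets:
        if a in s and b in s:
            return False
    for w in intervals:
        if w in (a, b):
            continue
        if w[0] >= lo[1] and w[1] <= hi[0]:  # strictly between
            return False
    return True


def detect_constitutive_mxe_like(gene: GeneModel, params: PredictionParams
                                 ) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Neighbouring same-isoform exon pairs that meet the MXE criteria.

    Such pairs are annotated as constitutive or cassette exons yet satisfy
    frame compatibility, the length-difference bound, the minimal exon length
    and the similarity threshold — false-positive seeds or mis-annotations
    that only experimental data can distinguish.  Returns de-duplicated
    genomically ordered interval pairs.
    """
    found = set()
    for iso in gene.isoforms:
        for a, b in zip(iso.exons, iso.exons[1:]):
            if a.aa_len < params.min_exon_len or b.aa_len < params.min_exon_len:
                continue
            if not frame_compatible(a.nt_len, b.nt_len):
                continue
            if abs(a.nt_len - b.nt_len) // 3 > params.max_len_diff:
                continue
            pa, pb = a.scoring_peptide, b.scoring_peptide
            if not pa or not pb:
                continue
            # the score is asymmetric (self-normalized); accept either direction
            s = max(similarity_score(pa, pb, params.matrix, params.gap_open,
                                     params.gap_extend),
                    similarity_score(pb, pa, params.matrix, params.gap_open,
                                     params.gap_extend))
            if s >= params.min_score:
                found.add(tuple(sorted((a.interval, b.interval))))
    return sorted(found)


# ---------------------------------------------------------------------------
# cluster assembly and classification

def assemble_clusters(gene: GeneModel, survivors: list[MXECandidate]
                      ) -> list[MXECluster]:
    """Group each source exon with its surviving candidates into clusters.

    Clusters sharing a member interval, or whose source exons mutually
    predict each other, are merged (union-find on intervals).  Members are
    ordered genomically; if merged members overlap, the lower-scoring
    candidate is dropped with a warning (annotated exons are never dropped).
    """
    annotated = set(gene.annotated_exon_intervals())
    nodes: set[tuple[int, int]] = set()
    info: dict[tuple[int, int], ClusterMember] = {}
    parent: dict[tuple[int, int], tuple[int, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    def add_node(iv, member):
        if iv not in nodes:
            nodes.add(iv)
            parent[iv] = iv
            info[iv] = member
        else:
            old = info[iv]
            if member.provenance == PROV_ANNOTATED:
                info[iv] = member
            elif old.provenance != PROV_ANNOTATED and \
                    (member.score or 0) > (old.score or 0):
                info[iv] = member

    for c in survivors:
        src = c.source_interval
        add_node(src, ClusterMember(*src, PROV_ANNOTATED))
        prov = PROV_ANNOTATED if c.interval in annotated else PROV_PREDICTED
        add_node(c.interval, ClusterMember(c.start, c.end, prov, score=c.score,
                                           source_exon=(c.transcript_id,
                                                        c.exon_index)))
        union(src, c.interval)

    groups: dict[tuple, list[tuple[int, int]]] = {}
    for iv in nodes:
        groups.setdefault(find(iv), []).append(iv)

    clusters = []
    for ivs in sorted(groups.values(), key=min):
        members = sorted((info[iv] for iv in ivs), key=lambda m: m.interval)
        members = _drop_overlapping_members(members, gene.gene_id)
        if len(members) < 2:
            continue
        cl = MXECluster(gene_id=gene.gene_id, target_id=gene.target_id,
                        cluster_id=f"{gene.gene_id}.mxe{len(clusters) + 1}",
                        members=members)
        cl.cluster_type = classify_cluster(cl, gene)
        clusters.append(cl)
    return clusters


def _drop_overlapping_members(members, gene_id):
    kept: list[ClusterMember] = []
    for m in members:
        clash = next((k for k in kept if k.end > m.start and m.end > k.start), None)
        if clash is None:
            kept.append(m)
            continue
        # keep annotated members; otherwise the higher score
        if clash.provenance == PROV_ANNOTATED and m.provenance != PROV_ANNOTATED:
            drop = m
        elif m.provenance == PROV_ANNOTATED and clash.provenance != PROV_ANNOTATED:
            kept[kept.index(clash)] = m
            drop = clash
        elif (m.score or 0) > (clash.score or 0):
            kept[kept.index(clash)] = m
            drop = clash
        else:
            drop = m
        log.warning("gene %s: overlapping cluster members after merge; "
                    "dropped [%d,%d)", gene_id, drop.start, drop.end)
    return kept


def classify_cluster(cluster: MXECluster, gene: GeneModel) -> str:
    """initial | internal | terminal, from the annotated exons it contains.

    A cluster containing any isoform's first coding exon is initial; one
    containing a last coding exon is terminal; a cluster qualifying as both
    (two-exon isoform) is labeled initial — an arbitrary but deterministic
    tie-break, logged.
    """
    member_ivs = set(cluster.intervals())
    is_initial = is_terminal = False
    for iso in gene.isoforms:
        if iso.exons[0].interval in member_ivs:
            is_initial = True
        if iso.exons[-1].interval in member_ivs:
            is_terminal = True
    if is_initial and is_terminal:
        log.info("cluster %s is both initial and terminal; labeling initial",
                 cluster.cluster_id)
        return TYPE_INITIAL
    if is_initial:
        return TYPE_INITIAL
    if is_terminal:
        return TYPE_TERMINAL
    return TYPE_INTERNAL


# ---------------------------------------------------------------------------
# flank-copy signature

def flag_tandem_or_trans(gene: GeneModel, candidates: list[MXECandidate]
                         ) -> tuple[bool, list[MXECandidate]]:
    """Detect the tandem-duplicate / trans-spliced-gene signature.

    True iff at least two distinct source exons each have a flank candidate on
    the same side with genomic order preserved relative to the source exons —
    i.e. an ordered copy of part of the gene sits in the flank.
    """
    for side in FLANK_LOCATIONS:
        side_cands = [c for c in candidates if c.location == side]
        by_exon: dict[int, list[MXECandidate]] = {}
        for c in side_cands:
            by_exon.setdefault(c.exon_index, []).append(c)
        if len(by_exon) < 2:
            continue
        # transcription-sense position: ascending start on "+", descending end on "-"
        def pos(c):
            return c.start if c.strand == "+" else -c.end
        # longest chain of candidates with strictly increasing exon index and
        # strictly increasing transcription-sense position (one per exon)
        cands = sorted(side_cands, key=lambda c: (c.exon_index, pos(c)))
        best: list[list[MXECandidate]] = [[c] for c in cands]
        for i, c in enumerate(cands):
            for j in range(i):
                p = cands[j]
                if (p.exon_index < c.exon_index and pos(p) < pos(c)
                        and len(best[j]) + 1 > len(best[i])):
                    best[i] = best[j] + [c]
        chain = max(best, key=len, default=[])
        if len({c.exon_index for c in chain}) >= 2:
            return True, chain
    return False, []
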