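"""Per-dataset summaries of a mutually exclusive exome and prediction sensitivity.

All counts are per-gene aggregates of distinct genomic exons (an exon shared
by several isoforms counts once), so summaries are additive over disjoint
gene sets and reproducible from the YAML master output alone.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .clusters import (TYPE_INITIAL, TYPE_INTERNAL, TYPE_TERMINAL, MXECluster,
                       detect_annotated_mxe_clusters, detect_constitutive_mxe_like)
from .gene_model import GeneModel
from .params import PredictionParams
from .predict import MXECandidate

SUMMARY_ROWS = [
    ("genes", "Genes"),
    ("proteins", "Proteins"),
    ("genes_multi_exon", "Genes with multiple exons"),
    ("genes_with_predicted_mxes", "Genes with predicted MXEs"),
    ("genes_with_annotated_mxes", "Genes with MXEs based on the original annotation"),
    ("genes_with_constitutive_like", "Genes with constitutive exons sharing the criteria of MXEs"),
    ("exons_annotated", "Exons in original annotation"),
    ("predicted_mxes", "Predicted MXEs"),
    ("annotated_mxes", "MXEs based on the original annotation"),
    ("constitutive_like_exons", "Constitutive exons sharing the criteria of MXEs"),
    ("clusters_initial", "Initial clusters"),
    ("clusters_internal", "Internal clusters"),
    ("clusters_terminal", "3'-terminal clusters"),
]


@dataclass
class ExomeSummary:
    genes: int = 0
    proteins: int = 0
    genes_multi_exon: int = 0
    genes_with_predicted_mxes: int = 0
    genes_with_annotated_mxes: int = 0
    genes_with_constitutive_like: int = 0
    exons_annotated: int = 0
    predicted_mxes: int = 0
    annotated_mxes: int = 0
    constitutive_like_exons: int = 0
    clusters_initial: int = 0
    clusters_internal: int = 0
    clusters_terminal: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.to_dict().values()):
            raise ValueError("summary counts must be non-negative")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k, _ in SUMMARY_ROWS}

    @classmethod
    def from_dict(cls, d: dict) -> "ExomeSummary":
        return cls(**d)

    def __add__(self, other: "ExomeSummary") -> "ExomeSummary":
        return ExomeSummary(**{k: getattr(self, k) + getattr(other, k)
                               for k, _ in SUMMARY_ROWS})

    def as_table(self) -> str:
        width = max(len(label) for _, label in SUMMARY_ROWS)
        return "\n".join(f"{label:<{width}}  {getattr(self, key)}"
                         for key, label in SUMMARY_ROWS)


@dataclass
class SensitivityResult:
    """Recovery of annotated (internal) mutually exclusive exons by prediction."""

    considered: int
    reconstructed: int
    applicable: bool = True

    @property
    def sensitivity(self) -> float | None:
        if not self.applicable or self.considered == 0:
            return None
        return 100.0 * self.reconstructed / self.considered

    def to_dict(self) -> dict:
        return {"considered": self.considered,
                "reconstructed": self.reconstructed,
                "applicable": self.applicable,
                "sensitivity": self.sensitivity}


def summarize_exome(genes: list[GeneModel], clusters: list[MXECluster],
                    candidates: list[MXECandidate],
                    params: PredictionParams) -> ExomeSummary:
    """Dataset-level statistics under the given display parameters.

    ``candidates`` is the *filtered* candidate set and ``clusters`` the
    clusters assembled from it; annotated-MXE clusters and MXE-like
    constitutive exon pairs are (re)derived here from the gene models.
    """
    s = ExomeSummary()
    cands_by_gene: dict[str, list[MXECandidate]] = {}
    for c in candidates:
        cands_by_gene.setdefault(c.gene_id, []).append(c)
    clusters_by_gene: dict[str, list[MXECluster]] = {}
    for cl in clusters:
        clusters_by_gene.setdefault(cl.gene_id, []).append(cl)

    for g in genes:
        s.genes += 1
        s.proteins += len(g.isoforms)
        if any(len(iso.exons) >= 2 for iso in g.isoforms):
            s.genes_multi_exon += 1
        s.exons_annotated += len(g.annotated_exon_intervals())

        gcands = cands_by_gene.get(g.gene_id, [])
        if gcands:
            s.genes_with_predicted_mxes += 1
            s.predicted_mxes += len({c.interval for c in gcands})

        annotated = detect_annotated_mxe_clusters(g)
        if annotated:
            s.genes_with_annotated_mxes += 1
            s.annotated_mxes += len({m.interval for cl in annotated
                                     for m in cl.members})

        const_like = detect_constitutive_mxe_like(g, params)
        if const_like:
            s.genes_with_constitutive_like += 1
            s.constitutive_like_exons += len({iv for pair in const_like
                                              for iv in pair})

        for cl in clusters_by_gene.get(g.gene_id, []):
            if cl.cluster_type == TYPE_INITIAL:
                s.clusters_initial += 1
            elif cl.cluster_type == TYPE_TERMINAL:
                s.clusters_terminal += 1
            else:
                s.clusters_internal += 1
    return s


def compute_sensitivity(candidates: list[MXECandidate],
                        annotated_clusters: list[MXECluster],
                        restrict_internal: bool = True) -> SensitivityResult:
    """Fraction of annotated MXEs exactly reconstructed by prediction.

    An annotated exon counts as reconstructed iff some candidate sourced from
    a *different* exon of its cluster matches its genomic interval exactly
    (both boundaries).  By default only internal clusters are considered —
    initial and terminal clusters can arise from alternative transcription
    start / poly(A) site use rather than splicing.  With zero considered
    exons the sensitivity is undefined and reported as not applicable.
    """
    clusters = [cl for cl in annotated_clusters
                if not restrict_internal or cl.cluster_type == TYPE_INTERNAL]
    cand_index: dict[tuple, set[tuple[int, int]]] = {}
    for c in candidates:
        cand_index.setdefault((c.target_id,) + c.interval, set()).add(
            c.source_interval)
    considered = reconstructed = 0
    for cl in clusters:
        ivs = set(cl.intervals())
        for m in cl.members:
            considered += 1
            sources = cand_index.get((cl.target_id,) + m.interval, set())
            if any(src in ivs and src != m.interval for src in sources):
                reconstructed += 1
    if considered == 0:
        return SensitivityResult(0, 0, applicable=False)
    return SensitivityResult(considered, reconstructed)
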