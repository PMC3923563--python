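"""Coding gene structures: exons, introns, phases, translations, validation.

All coordinates are 0-based half-open on the forward genomic strand; strand is
carried separately and sequences are reverse-complemented at access time for
minus-strand genes.  Exons are stored in transcription order, so on the minus
strand exon 1 has the highest genomic coordinates.

Phase follows GFF3 semantics: the number of 5' nucleotides of an exon that
belong to a codon begun in the previous exon, i.e. bases to skip before the
first complete codon.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

ISSUE_NONCANONICAL_INTRON = "noncanonical_intron"
ISSUE_INTERNAL_STOP = "internal_stop"
ISSUE_MISSING_STOP = "missing_stop"
ISSUE_FRAME_INCONSISTENCY = "frame_inconsistency"
ISSUE_PROTEIN_MISMATCH = "protein_mismatch"


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def exon_peptide(seq: str, start_phase: int) -> str:
    """Translate the complete codons of an exon sequence (coding strand).

    Skips ``start_phase`` nucleotides, translates complete codons with the
    standard nuclear code (stops render ``*``), and drops any trailing
    partial codon.

    Raises ``ValueError`` on non-ACGT characters (callers pre-screen N runs).
    """
    if start_phase not in (0, 1, 2):
        raise ValueError(f"start_phase must be 0, 1 or 2, got {start_phase}")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in exon sequence: {sorted(bad)}")
    trimmed = seq[start_phase:]
    trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
    return str(Seq(trimmed).translate(table=1))


@dataclass
class ExonUnit:
    """One coding exon of one isoform.

    ``peptide`` holds the translation of the exon's complete internal codons
    (junction codons split across a splice site are excluded); this is the
    object all similarity scoring operates on.
    """

    index: int                # 1-based ordinal in transcription order
    start: int                # genomic, 0-based half-open, forward strand
    end: int
    strand: str               # "+" or "-"
    start_phase: int          # GFF3 phase: nt to skip to the first full codon
    peptide: str = ""
    is_initial: bool = False
    is_terminal: bool = False

    @property
    def nt_len(self) -> int:
        return self.end - self.start

    @property
    def aa_len(self) -> int:
        # floor(nt/3): partial codons never count toward the length thresholds
        return self.nt_len // 3

    @property
    def end_phase(self) -> int:
        """Phase the next exon must start with."""
        return (3 - (self.nt_len - self.start_phase) % 3) % 3

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def scoring_peptide(self) -> str:
        """Peptide used as alignment subject: internal codons, stop stripped."""
        return self.peptide.rstrip("*")

    def to_dict(self) -> dict:
        return {
            "index": self.index, "start": self.start, "end": self.end,
            "strand": self.strand, "start_phase": self.start_phase,
            "peptide": self.peptide, "is_initial": self.is_initial,
            "is_terminal": self.is_terminal,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExonUnit":
        return cls(**d)


@dataclass
class Isoform:
    """One protein isoform: ordered exons plus derived introns and validity."""

    protein_id: str
    exons: list[ExonUnit]
    completeness: str = "complete"         # "complete" | "incomplete"
    issues: list[str] = field(default_factory=list)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic forward-strand intervals, in transcription order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if a.strand == "+":
                out.append((a.end, b.start))
            else:
                out.append((b.end, a.start))
        return out

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> tuple[int, int]:
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))

    def to_dict(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "exons": [e.to_dict() for e in self.exons],
            "completeness": self.completeness,
            "issues": list(self.issues),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Isoform":
        return cls(protein_id=d["protein_id"],
                   exons=[ExonUnit.from_dict(e) for e in d["exons"]],
                   completeness=d.get("completeness", "complete"),
                   issues=list(d.get("issues", [])))


@dataclass
class GeneModel:
    """A coding gene: one or more isoforms on one target sequence."""

    gene_id: str
    target_id: str
    strand: str
    isoforms: list[Isoform]
    neighbour_exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def locus(self) -> tuple[int, int]:
        starts = [iso.span[0] for iso in self.isoforms]
        ends = [iso.span[1] for iso in self.isoforms]
        return (min(starts), max(ends))

    def annotated_exon_intervals(self) -> list[tuple[int, int]]:
        """Distinct genomic exon intervals across all isoforms, sorted."""
        seen = {e.interval for iso in self.isoforms for e in iso.exons}
        return sorted(seen)

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id, "target_id": self.target_id,
            "strand": self.strand,
            "isoforms": [iso.to_dict() for iso in self.isoforms],
            "neighbour_exons": [list(t) for t in self.neighbour_exons],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        return cls(gene_id=d["gene_id"], target_id=d["target_id"],
                   strand=d["strand"],
                   isoforms=[Isoform.from_dict(i) for i in d["isoforms"]],
                   neighbour_exons=[tuple(t) for t in d.get("neighbour_exons", [])])


# ---------------------------------------------------------------------------
# construction

def exon_coding_seq(genome_seq: str, start: int, end: int, strand: str) -> str:
    s = genome_seq[start:end]
    return s if strand == "+" else reverse_complement(s)


def build_gene_models(raw_genes, genome) -> list[GeneModel]:
    """Build validated gene models from raw annotation records.

    ``raw_genes`` is the output of :func:`mxescan.formats_io.read_annotation`;
    ``genome`` maps target id to :class:`~mxescan.formats_io.TargetSequence`.

    Isoforms whose CDS segment lengths are inconsistent with their declared
    phases are marked incomplete, never dropped.  After construction the
    neighbour context (exon intervals of the adjacent genes on the same
    target) is attached to every gene.
    """
    models: list[GeneModel] = []
    for rg in raw_genes:
        target = genome[rg.target_id]
        isoforms = []
        for riso in rg.isoforms:
            exons = _build_exons(riso, target.seq)
            iso = Isoform(protein_id=riso.transcript_id, exons=exons)
            validate_structure(iso, genome, target_id=rg.target_id)
            isoforms.append(iso)
        models.append(GeneModel(gene_id=rg.gene_id, target_id=rg.target_id,
                                strand=rg.strand, isoforms=isoforms))
    _attach_neighbours(models)
    return models


def _build_exons(riso, genome_seq: str) -> list[ExonUnit]:
    exons = []
    phase = None
    for i, (start, end, gff_phase) in enumerate(riso.cds):
        if i == 0:
            phase = gff_phase if gff_phase is not None else 0
        elif gff_phase is not None:
            phase = gff_phase
        seq = exon_coding_seq(genome_seq, start, end, riso.strand)
        try:
            pep = exon_peptide(seq, phase)
        except ValueError:
            pep = ""
            log.warning("exon %d of %s contains ambiguous bases; peptide empty",
                        i + 1, riso.transcript_id)
        exons.append(ExonUnit(index=i + 1, start=start, end=end,
                              strand=riso.strand, start_phase=phase,
                              peptide=pep,
                              is_initial=(i == 0),
                              is_terminal=(i == len(riso.cds) - 1)))
        phase = exons[-1].end_phase
    return exons


def _attach_neighbours(models: list[GeneModel]) -> None:
    by_target: dict[str, list[GeneModel]] = {}
    for g in models:
        by_target.setdefault(g.target_id, []).append(g)
    for genes in by_target.values():
        genes.sort(key=lambda g: g.locus)
        for i, g in enumerate(genes):
            nbrs = []
            if i > 0:
                nbrs.append(genes[i - 1])
            if i + 1 < len(genes):
                nbrs.append(genes[i + 1])
            g.neighbour_exons = sorted(
                {e.interval for n in nbrs for iso in n.isoforms for e in iso.exons})


# ---------------------------------------------------------------------------
# validation

def validate_structure(isoform: Isoform, genome, protein: str | None = None,
                       target_id: str | None = None) -> tuple[str, list[str]]:
    """Label an isoform's structural validity; never raises.

    Flags non-canonical introns (splice-site pattern other than GT..AG or
    GC..AG on the coding strand), in-frame internal stop codons, a missing
    terminal stop codon, phase-chain inconsistencies, and — when a reference
    protein is supplied — translation/protein mismatches.  Any flag marks the
    isoform incomplete.  The isoform is updated in place and the
    (completeness, issues) pair returned.
    """
    issues: list[str] = []
    exons = isoform.exons
    tid = target_id if target_id is not None else getattr(isoform, "target_id", None)
    genome_seq = None
    if tid is not None and tid in genome:
        genome_seq = genome[tid].seq
    elif len(genome) == 1:
        genome_seq = next(iter(genome.values())).seq

    # phase chain
    for a, b in zip(exons, exons[1:]):
        if b.start_phase != a.end_phase:
            issues.append(ISSUE_FRAME_INCONSISTENCY)
            break

    if genome_seq is not None:
        for (istart, iend) in isoform.introns:
            iseq = exon_coding_seq(genome_seq, istart, iend, isoform.strand)
            if len(iseq) < 4 or not (
                    (iseq.startswith("GT") or iseq.startswith("GC"))
                    and iseq.endswith("AG")):
                issues.append(ISSUE_NONCANONICAL_INTRON)

        cds = "".join(exon_coding_seq(genome_seq, e.start, e.end, e.strand)
                      for e in exons)
        offset = exons[0].start_phase
        cds = cds[offset:]
        cds = cds[: len(cds) - len(cds) % 3]
        if cds and set(cds) <= set("ACGT"):
            translation = str(Seq(cds).translate(table=1))
            if "*" in translation[:-1]:
                issues.append(ISSUE_INTERNAL_STOP)
            if not translation.endswith("*"):
                issues.append(ISSUE_MISSING_STOP)
            if protein is not None and translation.rstrip("*") != protein.rstrip("*"):
                issues.append(ISSUE_PROTEIN_MISMATCH)

    isoform.issues = issues
    isoform.completeness = "complete" if not issues else "incomplete"
    return isoform.completeness, issues
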