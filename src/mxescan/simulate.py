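"""Deterministic synthetic genomes with planted mutually exclusive exons.

The generator emulates the preconditions the predictor relies on: coding
genes with canonical GT..AG (or GC..AG) introns, an ATG start, a single
terminal stop and no internal stops; planted alternative exons that are
codon-level mutated copies of their source exon at a requested amino-acid
identity, installed inside an intron between an ``AG`` acceptor context and a
``GT`` donor context with safety margins; and decoy intron sequence that is
rejection-sampled until it contains no frame-compatible, splice-site-bounded
lookalike of the flanking exons above a permissive score bar.  Everything is
driven by a single seed; the same seed yields byte-identical FASTA, GFF3 and
ground truth.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .align import similarity_score
from .formats_io import RawGene, RawIsoform, TargetSequence, write_annotation_gff3, write_genome
from .gene_model import ExonUnit, GeneModel, build_gene_models, exon_peptide
from .params import PredictionParams
from .predict import LOC_DOWNSTREAM_INTRON, LOC_UPSTREAM_INTRON, SearchRegion, enumerate_candidates

log = logging.getLogger(__name__)

_TABLE = unambiguous_dna_by_id[1]
AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_OF: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _CODONS_OF.setdefault(aa, []).append(codon)
_NT = np.array(list("ACGT"))

# permissive bar used when rejection-sampling decoy sequence: matches the
# relaxed store-stage minimal score, so stored predictions on decoys are clean
REJECT_PARAMS = PredictionParams(min_score=10.0, max_len_diff=20,
                                 min_exon_len=0, scope="all")
_MAX_RESAMPLE = 60


# ---------------------------------------------------------------------------
# specs and ground truth

@dataclass
class PlantedAlternative:
    """One alternative exon to plant for a source exon, inside an intron."""

    source_exon: int                  # 1-based, transcription order
    identity: float = 1.0             # target amino-acid identity to the source
    length_offset_codons: int = 0     # whole codons inserted (+) or deleted (-)
    side: str = "downstream"          # "upstream" | "downstream" intron

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")
        if self.side not in ("upstream", "downstream"):
            raise ValueError("side must be 'upstream' or 'downstream'")


@dataclass
class IsoformPattern:
    """Multi-isoform or duplicated-exon layout for one gene.

    kind:
      ``annotated_mxe`` — a variant copy of ``exon`` becomes a second
        annotated isoform's exon (the swapped-exon, mutually exclusive
        pattern);
      ``cassette`` — the variant exon is an extra exon of a second isoform
        that also retains the original (differential inclusion, which
        disqualifies the pair as annotated MXEs);
      ``constitutive_duplicate`` — the variant exon sits next to the original
        within the single isoform (a tandem exon duplication annotated as
        constitutive, the myosin-heavy-chain-like false-annotation pattern).
    """

    kind: str
    exon: int
    identity: float = 0.9
    ensure_score_below: float | None = None   # resample mutations until both
    ensure_score_above: float | None = None   # direction scores obey these

    def __post_init__(self):
        if self.kind not in ("annotated_mxe", "cassette", "constitutive_duplicate"):
            raise ValueError(f"unknown isoform pattern kind {self.kind!r}")


@dataclass
class FlankDuplication:
    """Ordered copies of some exons in a gene flank (tandem/trans signature)."""

    exons: tuple[int, ...] = (2, 3)
    side: str = "downstream"
    identity: float = 1.0
    preserve_order: bool = True


@dataclass
class PlantSpec:
    """Full recipe for a synthetic genome; the seed determines everything."""

    genes: int = 10
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_aa: tuple[int, int] = (18, 40)
    intron_nt: tuple[int, int] = (120, 300)
    intergenic_nt: tuple[int, int] = (150, 300)
    planted: dict[int, list[PlantedAlternative]] = field(default_factory=dict)
    isoform_patterns: dict[int, IsoformPattern] = field(default_factory=dict)
    flank_duplications: dict[int, FlankDuplication] = field(default_factory=dict)
    strands: str = "mixed"            # "mixed" | "+" | "-"
    gc_intron_fraction: float = 0.0   # fraction of introns with a GC donor
    contig_id: str = "chrS"
    seed: int = 0

    def validate(self) -> None:
        if self.genes < 0:
            raise ValueError("genes must be >= 0")
        if self.exon_aa[0] < 2 or self.exon_aa[0] > self.exon_aa[1]:
            raise ValueError("invalid exon_aa range")
        if self.exons_per_gene[0] < 1:
            raise ValueError("exons_per_gene must be >= 1")
        need = 2 * REJECT_PARAMS.min_candidate_margin + 10
        if self.intron_nt[0] < need:
            raise ValueError(
                f"intron_nt minimum {self.intron_nt[0]} is too short for a "
                f"canonical intron with candidate margins (need >= {need})")
        for plants in self.planted.values():
            for p in plants:
                if p.source_exon < 1:
                    raise ValueError("source_exon indices are 1-based")

    @classmethod
    def one_internal_cluster_per_gene(cls, genes: int, identity: float,
                                      n_alternatives: int = 1, seed: int = 0,
                                      **kw) -> "PlantSpec":
        """Every gene carries one planted internal cluster (middle exon)."""
        spec = cls(genes=genes, seed=seed, **kw)
        for g in range(genes):
            spec.planted[g] = [
                PlantedAlternative(source_exon=2, identity=identity,
                                   side="downstream" if a % 2 == 0 else "upstream")
                for a in range(n_alternatives)]
        return spec

    @classmethod
    def negative_control(cls, genes: int, seed: int, **kw) -> "PlantSpec":
        """No plants at all: every intron is rejection-sampled decoy."""
        return cls(genes=genes, seed=seed, **kw)


@dataclass
class PlantedExonRecord:
    """Ground truth for one planted (or annotated-variant) exon."""

    kind: str                 # "intron_plant" | "annotated_variant" | "flank_copy"
    gene_id: str
    target_id: str
    start: int
    end: int
    strand: str
    source_exon_index: int
    source_start: int
    source_end: int
    identity_target: float
    identity_realized: float
    score: float              # similarity vs the source exon, default alignment
    side: str

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def passes(self, params: PredictionParams) -> bool:
        """Expected pass/fail of this plant under the given parameters."""
        len_diff = abs((self.end - self.start)
                       - (self.source_end - self.source_start)) // 3
        src_aa = (self.source_end - self.source_start) // 3
        return (self.score >= params.min_score
                and len_diff <= params.max_len_diff
                and src_aa >= params.min_exon_len)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        return d


@dataclass
class GroundTruth:
    plants: list[PlantedExonRecord] = field(default_factory=list)
    seed: int = 0

    def of_kind(self, kind: str) -> list[PlantedExonRecord]:
        return [p for p in self.plants if p.kind == kind]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"seed": self.seed,
                            "plants": [p.to_dict() for p in self.plants]},
                           fh, sort_keys=False)


@dataclass
class SyntheticDataset:
    genome: dict[str, TargetSequence]
    raw_genes: list[RawGene]
    ground_truth: GroundTruth
    #: per gene, per isoform: the designed protein string (no stop); an
    #: independent oracle for translation-based validation
    proteins: list[list[str]] = field(default_factory=list)

    def gene_models(self) -> list[GeneModel]:
        return build_gene_models(self.raw_genes, self.genome)

    def write(self, out_dir) -> dict[str, str]:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"fasta": out / "genome.fasta", "gff3": out / "annotation.gff3",
                 "truth": out / "ground_truth.yaml"}
        write_genome(self.genome, paths["fasta"])
        write_annotation_gff3(self.gene_models(), paths["gff3"])
        self.ground_truth.write(paths["truth"])
        return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# low-level sequence helpers

def _random_dna(rng, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def _random_peptide(rng, n: int, start_m: bool = False) -> str:
    pep = "".join(AA20[i] for i in rng.integers(0, 20, size=n))
    return ("M" + pep[1:]) if start_m else pep


def _back_translate(rng, pep: str) -> str:
    out = []
    for aa in pep:
        codons = _CODONS_OF[aa]
        out.append(codons[rng.integers(0, len(codons))])
    return "".join(out)


def _mutate_exon_copy(rng, exon_seq: str, phase: int, identity: float,
                      offset_codons: int = 0) -> tuple[str, float]:
    """Codon-level mutated copy of an exon; frame-safe by construction.

    Substitutions replace whole codons with a codon of a different residue;
    indels insert/delete whole codons, so the length difference is always a
    multiple of three.  Returns (sequence, realized identity over the aligned
    original positions).
    """
    prefix = exon_seq[:phase]
    body = exon_seq[phase:]
    tail = body[len(body) - len(body) % 3:]
    codons = [body[i:i + 3] for i in range(0, len(body) - len(tail), 3)]
    n = len(codons)
    n_sub = int(round((1.0 - identity) * n))
    sub_pos = set(rng.choice(n, size=min(n_sub, n), replace=False).tolist()) \
        if n_sub else set()
    new_codons = []
    for i, c in enumerate(codons):
        if i in sub_pos:
            aa = str(Seq(c).translate())
            alt_aa = AA20[rng.integers(0, 20)]
            while alt_aa == aa:
                alt_aa = AA20[rng.integers(0, 20)]
            opts = _CODONS_OF[alt_aa]
            new_codons.append(opts[rng.integers(0, len(opts))])
        else:
            new_codons.append(c)
    if offset_codons > 0:
        at = int(rng.integers(1, max(2, n)))
        ins = []
        for _ in range(offset_codons):
            opts = _CODONS_OF[AA20[rng.integers(0, 20)]]
            ins.append(opts[rng.integers(0, len(opts))])
        new_codons = new_codons[:at] + ins + new_codons[at:]
    elif offset_codons < 0:
        k = min(-offset_codons, len(new_codons) - 1)
        at = int(rng.integers(0, len(new_codons) - k + 1))
        del new_codons[at:at + k]
    realized = 1.0 - (len(sub_pos) / n if n else 0.0)
    return prefix + "".join(new_codons) + tail, realized


def _source_exon_unit(exon_seq: str, phase: int, index: int = 1) -> ExonUnit:
    return ExonUnit(index=index, start=0, end=len(exon_seq), strand="+",
                    start_phase=phase, peptide=exon_peptide(exon_seq, phase))


def _intron_is_clean(intron_seq: str, flank_exons: list[ExonUnit],
                     allowed: list[tuple[int, int]]) -> bool:
    """No candidate above the rejection bar outside the allowed intervals."""
    region = SearchRegion(target_id="scan", gstart=0, gend=len(intron_seq),
                          strand="+", seq=intron_seq, location=LOC_DOWNSTREAM_INTRON)
    for exon in flank_exons:
        if not exon.scoring_peptide:
            continue
        for cand in enumerate_candidates(region, exon, REJECT_PARAMS,
                                         resolve_overlaps=False):
            if not any(s < cand.end and cand.start < e for (s, e) in allowed):
                return False
    return True


# ---------------------------------------------------------------------------
# gene assembly in block (coding-orientation) coordinates

@dataclass
class _BuiltGene:
    block: str
    isoform_exons: list[list[tuple[int, int]]]   # block intervals, transcription order
    backbone_iv: list[tuple[int, int]]            # original exons, block intervals
    plant_intervals: list[dict]                   # block-interval plant records
    exon_seqs: list[str]
    phases: list[int]
    proteins: list[str] = field(default_factory=list)  # per isoform, no stop


def _build_exon_backbone(rng, spec: PlantSpec, n_ex: int,
                         codon_aligned: bool = False):
    aa_lens = [int(rng.integers(spec.exon_aa[0], spec.exon_aa[1] + 1))
               for _ in range(n_ex)]
    protein = _random_peptide(rng, sum(aa_lens), start_m=True)
    cds = _back_translate(rng, protein) + "TAA"
    # non-aligned cut points put exon boundaries inside codons, exercising
    # phases; genes that will gain/lose a whole exon (isoform patterns) need
    # codon-aligned boundaries so the insertion preserves the frame
    cuts = [0]
    cum = 0
    for aa in aa_lens[:-1]:
        cum += aa
        jitter = 0 if codon_aligned else int(rng.integers(0, 3))
        cuts.append(3 * cum + jitter)
    cuts.append(len(cds))
    exon_seqs = [cds[a:b] for a, b in zip(cuts, cuts[1:])]
    phases = [0]
    for seq in exon_seqs[:-1]:
        unit = ExonUnit(index=1, start=0, end=len(seq), strand="+",
                        start_phase=phases[-1])
        phases.append(unit.end_phase)
    return exon_seqs, phases, protein, aa_lens


def _clean_intron(rng, spec: PlantSpec, flank_exons: list[ExonUnit],
                  donor: str = "GT") -> str:
    length = int(rng.integers(spec.intron_nt[0], spec.intron_nt[1] + 1))
    for attempt in range(_MAX_RESAMPLE):
        intron = donor + _random_dna(rng, length - 4) + "AG"
        if _intron_is_clean(intron, flank_exons, allowed=[]):
            return intron
    log.warning("decoy intron still has a chance lookalike after %d resamples; "
                "keeping the last draw", _MAX_RESAMPLE)
    return intron


def _planted_intron(rng, spec: PlantSpec, plants_seqs: list[str],
                    flank_exons: list[ExonUnit], donor: str = "GT"
                    ) -> tuple[str, list[tuple[int, int]]]:
    """Intron carrying planted exon copies: GT f0 AG p1 GT f1 AG ... fk AG."""
    fill = lambda: 24 + int(rng.integers(0, 17))
    for attempt in range(_MAX_RESAMPLE):
        parts = [donor + _random_dna(rng, fill()) + "AG"]
        intervals = []
        for pseq in plants_seqs:
            pos = sum(len(p) for p in parts)
            intervals.append((pos, pos + len(pseq)))
            parts.append(pseq)
            parts.append("GT" + _random_dna(rng, fill()) + "AG")
        intron = "".join(parts)
        if _intron_is_clean(intron, flank_exons, allowed=intervals):
            return intron, intervals
    log.warning("planted intron kept after %d resamples with a chance "
                "lookalike outside the plants", _MAX_RESAMPLE)
    return intron, intervals


def _build_gene(rng, spec: PlantSpec, gene_idx: int) -> _BuiltGene:
    n_ex = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
    pattern = spec.isoform_patterns.get(gene_idx)
    plants = spec.planted.get(gene_idx, [])
    if pattern is not None:
        n_ex = max(n_ex, 3)
        if not 1 < pattern.exon < n_ex and pattern.kind != "constitutive_duplicate":
            raise ValueError("pattern exon must be internal")
    for p in plants:
        if not 1 < p.source_exon <= n_ex:
            raise ValueError(
                f"gene {gene_idx}: plant source exon {p.source_exon} out of "
                f"range for {n_ex} exons (exon 1 and beyond-terminal are not "
                f"plantable)")
        if p.source_exon == n_ex:
            raise ValueError("cannot plant alternatives for the terminal "
                             "(stop-carrying) exon")

    exon_seqs, phases, protein, aa_lens = _build_exon_backbone(
        rng, spec, n_ex, codon_aligned=pattern is not None)
    units = [_source_exon_unit(s, p, i + 1)
             for i, (s, p) in enumerate(zip(exon_seqs, phases))]

    # plants per intron slot (intron j sits between exons j and j+1, 1-based)
    plant_by_intron: dict[int, list[tuple[PlantedAlternative, str, float]]] = {}
    for p in plants:
        intron_idx = p.source_exon - 1 if p.side == "upstream" else p.source_exon
        alt, realized = _mutate_exon_copy(
            rng, exon_seqs[p.source_exon - 1], phases[p.source_exon - 1],
            p.identity, p.length_offset_codons)
        plant_by_intron.setdefault(intron_idx, []).append((p, alt, realized))

    variant = None
    if pattern is not None:
        variant = _make_variant_exon(rng, pattern, exon_seqs, phases)

    # assemble block
    parts: list[str] = []
    exon_iv: list[tuple[int, int]] = []
    variant_iv = None
    plant_records: list[dict] = []
    pos = 0

    def push(seq: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(seq)
        iv = (pos, pos + len(seq))
        pos += len(seq)
        return iv

    for j, seq in enumerate(exon_seqs, start=1):
        exon_iv.append(push(seq))
        if j == n_ex:
            break
        donor = "GC" if rng.random() < spec.gc_intron_fraction else "GT"
        flank = [units[j - 1], units[j]]
        if pattern is not None and j == pattern.exon:
            # the variant exon lives between exon j and exon j+1
            intron_mid = _clean_intron(rng, spec, flank, donor)
            push(intron_mid)
            variant_iv = push(variant[0])
            intron_post = _clean_intron(rng, spec, flank, "GT")
            push(intron_post)
        elif j in plant_by_intron:
            triples = plant_by_intron[j]
            intron, ivs = _planted_intron(rng, spec, [t[1] for t in triples],
                                          flank, donor)
            base = pos
            push(intron)
            for (p, alt, realized), (s, e) in zip(triples, ivs):
                src = p.source_exon
                plant_records.append({
                    "interval": (base + s, base + e), "source_exon": src,
                    "identity_target": p.identity,
                    "identity_realized": realized,
                    "side": p.side,
                    "score": _plant_score(units[src - 1], alt,
                                          phases[src - 1])})
        else:
            push(_clean_intron(rng, spec, flank, donor))

    isoforms = [list(exon_iv)]
    proteins = [protein]
    if pattern is not None and variant_iv is not None:
        k = pattern.exon
        a_aa, b_aa = sum(aa_lens[:k - 1]), sum(aa_lens[:k])
        var_pep = exon_peptide(variant[0], phases[k - 1]).rstrip("*")
        if pattern.kind == "annotated_mxe":
            second = [variant_iv if iv == exon_iv[k - 1] else iv
                      for iv in exon_iv]
            isoforms.append(second)
            proteins.append(protein[:a_aa] + var_pep + protein[b_aa:])
        elif pattern.kind == "cassette":
            # isoform A carries original + variant, isoform B only the original
            first = sorted(exon_iv + [variant_iv])
            isoforms = [first, list(exon_iv)]
            proteins = [protein[:b_aa] + var_pep + protein[b_aa:], protein]
        elif pattern.kind == "constitutive_duplicate":
            isoforms = [sorted(exon_iv + [variant_iv])]
            proteins = [protein[:b_aa] + var_pep + protein[b_aa:]]
        plant_records.append({
            "interval": variant_iv, "source_exon": pattern.exon,
            "identity_target": pattern.identity,
            "identity_realized": variant[1], "side": "annotated",
            "score": _plant_score(units[pattern.exon - 1], variant[0],
                                  phases[pattern.exon - 1]),
            "kind": "annotated_variant"})

    return _BuiltGene(block="".join(parts), isoform_exons=isoforms,
                      backbone_iv=exon_iv, plant_intervals=plant_records,
                      exon_seqs=exon_seqs, phases=phases, proteins=proteins)


def _plant_score(source_unit: ExonUnit, alt_seq: str, phase: int) -> float:
    pep = exon_peptide(alt_seq, phase).rstrip("*")
    src = source_unit.scoring_peptide
    if not pep or not src:
        return float("-inf")
    return similarity_score(src, pep)


def _make_variant_exon(rng, pattern: IsoformPattern, exon_seqs, phases):
    src_seq = exon_seqs[pattern.exon - 1]
    phase = phases[pattern.exon - 1]
    src_unit = _source_exon_unit(src_seq, phase)
    for attempt in range(_MAX_RESAMPLE * 4):
        alt, realized = _mutate_exon_copy(rng, src_seq, phase, pattern.identity)
        s1 = _plant_score(src_unit, alt, phase)
        alt_unit = _source_exon_unit(alt, phase)
        s2 = (similarity_score(alt_unit.scoring_peptide, src_unit.scoring_peptide)
              if alt_unit.scoring_peptide else float("-inf"))
        hi = max(s1, s2)
        if pattern.ensure_score_below is not None and hi >= pattern.ensure_score_below:
            continue
        if pattern.ensure_score_above is not None and hi < pattern.ensure_score_above:
            continue
        return alt, realized
    raise RuntimeError("could not realize the requested variant-exon score window")


# ---------------------------------------------------------------------------
# genome assembly

def generate_planted_genome(spec: PlantSpec) -> SyntheticDataset:
    """Generate a synthetic genome, its annotation and the planted ground truth.

    Raises ``ValueError`` on an infeasible spec before anything is assembled.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    contig_parts: list[str] = []
    pos = 0
    raw_genes: list[RawGene] = []
    proteins: list[list[str]] = []
    truth = GroundTruth(seed=spec.seed)

    for g in range(spec.genes):
        gap = int(rng.integers(spec.intergenic_nt[0], spec.intergenic_nt[1] + 1))
        contig_parts.append(_random_dna(rng, gap))
        pos += gap
        if spec.strands == "mixed":
            strand = "+" if rng.random() < 0.5 else "-"
        else:
            strand = spec.strands
        built = _build_gene(rng, spec, g)
        proteins.append(list(built.proteins))
        gene_id = f"g{g + 1:03d}"
        block = built.block
        dup = spec.flank_duplications.get(g)
        dup_seq, dup_records = ("", [])
        if dup is not None:
            dup_seq, dup_records = _flank_copy(rng, built, dup)

        up_pad = ""
        down_pad = dup_seq
        block_full = up_pad + block + down_pad
        L = len(block_full)

        def b2g(iv, off=pos, L=L, strand=strand):
            s, e = iv
            if strand == "+":
                return (off + s, off + e)
            return (off + L - e, off + L - s)

        placed = block_full if strand == "+" else \
            str(Seq(block_full).reverse_complement())
        contig_parts.append(placed)

        rg = RawGene(gene_id=gene_id, target_id=spec.contig_id, strand=strand)
        for t, iso_ivs in enumerate(built.isoform_exons, start=1):
            cds = []
            phase = 0
            for (s, e) in iso_ivs:           # block order == transcription order
                gs, ge = b2g((s, e))
                cds.append((gs, ge, phase))
                unit = ExonUnit(index=1, start=0, end=e - s, strand="+",
                                start_phase=phase)
                phase = unit.end_phase
            if strand == "-":
                cds.sort(key=lambda c: c[0], reverse=True)
            rg.isoforms.append(RawIsoform(transcript_id=f"{gene_id}.t{t}",
                                          strand=strand, cds=cds))
        raw_genes.append(rg)

        exon_iv_tx = built.backbone_iv
        for rec in built.plant_intervals + dup_records:
            src = rec["source_exon"]
            gs, ge = b2g(rec["interval"])
            ss, se = b2g(exon_iv_tx[src - 1])
            truth.plants.append(PlantedExonRecord(
                kind=rec.get("kind", "intron_plant"), gene_id=gene_id,
                target_id=spec.contig_id, start=gs, end=ge, strand=strand,
                source_exon_index=src, source_start=ss, source_end=se,
                identity_target=rec["identity_target"],
                identity_realized=rec["identity_realized"],
                score=rec["score"], side=rec["side"]))
        pos += L

    tail = int(rng.integers(spec.intergenic_nt[0], spec.intergenic_nt[1] + 1))
    contig_parts.append(_random_dna(rng, tail))
    genome = {spec.contig_id: TargetSequence(id=spec.contig_id,
                                             seq="".join(contig_parts))}
    return SyntheticDataset(genome=genome, raw_genes=raw_genes,
                            ground_truth=truth, proteins=proteins)


def _flank_copy(rng, built: _BuiltGene, dup: FlankDuplication):
    """Sequence appended after the gene block carrying ordered exon copies."""
    order = list(dup.exons) if dup.preserve_order else list(dup.exons)[::-1]
    parts = [_random_dna(rng, 30)]
    records = []
    base = len(built.block)
    for idx in order:
        seq = built.exon_seqs[idx - 1]
        alt, realized = _mutate_exon_copy(rng, seq, built.phases[idx - 1],
                                          dup.identity)
        parts.append("AG")
        start = base + sum(len(p) for p in parts)
        parts.append(alt)
        end = start + len(alt)
        parts.append("GT" + _random_dna(rng, 30))
        unit = _source_exon_unit(seq, built.phases[idx - 1])
        records.append({"interval": (start, end), "source_exon": idx,
                        "identity_target": dup.identity,
                        "identity_realized": realized, "side": dup.side,
                        "score": _plant_score(unit, alt, built.phases[idx - 1]),
                        "kind": "flank_copy"})
    return "".join(parts), records


# ---------------------------------------------------------------------------
# the worked filter-demonstration fixture

FILTER_DEMO_SEED = 424242


def filter_demo_fixture() -> tuple[SyntheticDataset, dict]:
    """A three-exon gene with a planted cluster of four mutually exclusive exons.

    The annotation contains exons 1, 2b and 3.  One alternative (2a) sits in
    the intron 5' of exon 2b, two more (2c, 2d) in the intron between 2b and
    exon 3.  The construction pins the properties that make the filter
    algebra demonstrable:

    * exon 2b is exactly 18 aa long, so a minimal-exon-length filter of 19
      removes every candidate;
    * 2a and 2d differ from 2b by 13 and 12 codons with similarity >= 15%,
      so a length-difference cap below 12 removes exactly these two;
    * 2c has the same length as 2b but a similarity in [10, 15), so the
      default 15% score filter removes exactly 2c (while the relaxed
      store-stage scan at 10% still finds it).

    Construction is deterministic and self-verifying: candidate enumeration
    at store-stage parameters must recover exactly {2a, 2c, 2d}, all sourced
    from exon 2b, otherwise the fixture is rebuilt from the next derived
    seed.  Returns (dataset, expected) where ``expected`` records the planted
    intervals, scores and length differences.
    """
    for attempt in range(300):
        rng = np.random.default_rng(FILTER_DEMO_SEED + attempt)
        built = _try_build_filter_demo(rng)
        if built is not None:
            return built
    raise RuntimeError("could not realize the fixture constraints")


def _try_build_filter_demo(rng):
    from .params import PredictionParams
    from .predict import predict_gene

    pep1 = _random_peptide(rng, 20, start_m=True)
    pep2 = _random_peptide(rng, 18)
    pep3 = _random_peptide(rng, 20)
    e1 = _back_translate(rng, pep1)
    e2 = _back_translate(rng, pep2)
    e3 = _back_translate(rng, pep3) + "TAA"

    a2, _ = _mutate_exon_copy(rng, e2, 0, 1.0, offset_codons=13)
    d2, _ = _mutate_exon_copy(rng, e2, 0, 1.0, offset_codons=12)
    c2 = _find_scored_variant(rng, e2, lo=10.5, hi=14.4)
    if c2 is None:
        return None

    unit2 = _source_exon_unit(e2, 0, index=2)
    score_a = _plant_score(unit2, a2, 0)
    score_c = _plant_score(unit2, c2, 0)
    score_d = _plant_score(unit2, d2, 0)
    if not (score_a >= 16.0 and score_d >= 16.0 and 10.5 <= score_c < 14.5):
        return None

    fill = lambda: _random_dna(rng, 24 + int(rng.integers(0, 13)))
    i1 = "GT" + fill() + "AG" + a2 + "GT" + fill() + "AG"
    i2 = ("GT" + fill() + "AG" + c2 + "GT" + fill() + "AG"
          + d2 + "GT" + fill() + "AG")
    pad5 = _random_dna(rng, 30)
    pad3 = _random_dna(rng, 30)

    block = e1 + i1 + e2 + i2 + e3
    contig = pad5 + block + pad3
    off = len(pad5)

    def iv(rel_start, seq):
        return (off + rel_start, off + rel_start + len(seq))

    pos_e1 = 0
    pos_2a = len(e1) + 2 + (i1.index("AG" + a2) - 0) + 2 \
        if False else None  # computed below from explicit offsets
    # explicit cumulative offsets
    p = len(e1)
    i1_a_start = p + i1.index("AG" + a2) + 2
    p2b = len(e1) + len(i1)
    p_i2 = p2b + len(e2)
    i2_c_start = p_i2 + i2.index("AG" + c2) + 2
    i2_d_start = p_i2 + i2.index("AG" + d2) + 2
    p_e3 = p_i2 + len(i2)

    intervals = {
        "1": iv(pos_e1, e1),
        "2a": iv(i1_a_start, a2),
        "2b": iv(p2b, e2),
        "2c": iv(i2_c_start, c2),
        "2d": iv(i2_d_start, d2),
        "3": iv(p_e3, e3),
    }

    genome = {"demo": TargetSequence(id="demo", seq=contig)}
    rg = RawGene(gene_id="demo_gene", target_id="demo", strand="+")
    cds = []
    phase = 0
    for name, seq in (("1", e1), ("2b", e2), ("3", e3)):
        s, e = intervals[name]
        cds.append((s, e, phase))
        phase = ExonUnit(index=1, start=0, end=e - s, strand="+",
                         start_phase=phase).end_phase
    rg.isoforms.append(RawIsoform(transcript_id="demo_gene.t1", strand="+",
                                  cds=cds))

    models = build_gene_models([rg], genome)
    store = PredictionParams.store()
    cands = predict_gene(models[0], genome, store)
    found = sorted((c.interval, c.exon_index) for c in cands)
    want = sorted((intervals[n], 2) for n in ("2a", "2c", "2d"))
    if found != want:
        return None

    truth = GroundTruth(seed=FILTER_DEMO_SEED)
    for name, alt, score in (("2a", a2, score_a), ("2c", c2, score_c),
                             ("2d", d2, score_d)):
        s, e = intervals[name]
        truth.plants.append(PlantedExonRecord(
            kind="intron_plant", gene_id="demo_gene", target_id="demo",
            start=s, end=e, strand="+", source_exon_index=2,
            source_start=intervals["2b"][0], source_end=intervals["2b"][1],
            identity_target=1.0, identity_realized=1.0, score=score,
            side="upstream" if name == "2a" else "downstream"))

    dataset = SyntheticDataset(genome=genome, raw_genes=[rg],
                               ground_truth=truth,
                               proteins=[[pep1 + pep2 + pep3]])
    expected = {
        "gene_id": "demo_gene",
        "intervals": {n: intervals[n] for n in ("2a", "2c", "2d")},
        "source_interval": intervals["2b"],
        "scores": {"2a": score_a, "2c": score_c, "2d": score_d},
        "len_diff_aa": {"2a": 13, "2c": 0, "2d": 12},
        "source_aa_len": 18,
    }
    return dataset, expected


def _find_scored_variant(rng, exon_seq, lo, hi, tries=400):
    """Mutated same-length copy whose similarity to the source lies in [lo, hi]."""
    unit = _source_exon_unit(exon_seq, 0)
    n = len(unit.scoring_peptide)
    for _ in range(tries):
        k = int(rng.integers(max(1, n // 3), n + 1))
        alt, _ = _mutate_exon_copy(rng, exon_seq, 0, 1.0 - k / n)
        score = _plant_score(unit, alt, 0)
        if lo <= score <= hi:
            return alt
    return None
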