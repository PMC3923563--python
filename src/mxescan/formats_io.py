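"""Reading genomes and annotations; writing results as YAML, TSV, GFF3, BED.

Internal coordinates are 0-based half-open on the forward strand everywhere;
conversion to/from GFF3's 1-based inclusive convention happens only here, at
the format boundary.  The YAML "master" file is the lossless output of a
prediction run: it carries the parameters, the gene structures and every
stored candidate, so that filtering and summarizing can be re-run from the
YAML alone without touching the genome again.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import yaml
from Bio import SeqIO

from .gene_model import GeneModel
from .params import PredictionParams

log = logging.getLogger(__name__)

MASTER_SCHEMA_VERSION = 1
SUPPORTED_FORMATS = ("yaml", "tsv", "gff3", "bed")

TSV_COLUMNS = [
    "gene_id", "transcript_id", "exon_index", "target_id", "start", "end",
    "strand", "location", "acceptor", "donor", "nt_len", "len_diff_aa",
    "score", "peptide", "exact_match_other_isoform", "overlaps_other_isoform",
    "overlaps_neighbour_gene", "matches_annotated_same_isoform",
]


@dataclass
class TargetSequence:
    """One contig/chromosome of the genome target."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class RawIsoform:
    transcript_id: str
    strand: str
    cds: list[tuple[int, int, int | None]]  # (start, end, phase), transcription order


@dataclass
class RawGene:
    gene_id: str
    target_id: str
    strand: str
    isoforms: list[RawIsoform] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genome FASTA

def read_genome(path) -> dict[str, TargetSequence]:
    """Read a genome FASTA into target sequences keyed by id.

    Record id is the first whitespace-delimited header token; sequences are
    uppercased and U is mapped to T.  Duplicate ids or a malformed file raise
    ``ValueError``; an empty file yields an empty collection with a warning.
    """
    path = Path(path)
    text_head = path.read_text()[:1000]
    stripped = text_head.lstrip()
    if stripped and not stripped.startswith(">"):
        line_no = next(i for i, line in enumerate(text_head.splitlines(), 1)
                       if line.strip())
        raise ValueError(f"malformed FASTA {path}: first record at line "
                         f"{line_no} does not start with '>'")
    targets: dict[str, TargetSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in targets:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id}")
        targets[rec.id] = TargetSequence(
            id=rec.id, seq=str(rec.seq).upper().replace("U", "T"))
    if not targets:
        log.warning("FASTA file %s contains no records", path)
    return targets


def write_genome(targets: dict[str, TargetSequence], path) -> None:
    with open(path, "w") as fh:
        for t in targets.values():
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.seq), 70):
                fh.write(t.seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# GFF3 annotation

def read_annotation(path, genome: dict[str, TargetSequence]) -> list[RawGene]:
    """Read a GFF3 coding-gene annotation into raw gene records.

    Returns genes with their isoforms (mRNA/transcript features) and ordered
    CDS segments, converted to 0-based half-open coordinates and sorted in
    transcription order (descending genomic order on the minus strand).
    CDS rows referencing an unknown contig, or with coordinates outside the
    contig, raise; features without a resolvable parent are skipped with a
    warning.
    """
    path = Path(path)
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: list[RawGene] = []
    claimed_mrnas: set[str] = set()
    for gene in db.features_of_type("gene", order_by="start"):
        rg = RawGene(gene_id=gene.id, target_id=gene.seqid, strand=gene.strand)
        for mrna in db.children(gene, featuretype=("mRNA", "transcript"),
                                order_by="start"):
            claimed_mrnas.add(mrna.id)
            riso = _read_isoform(db, mrna, genome, path)
            if riso is not None:
                rg.isoforms.append(riso)
        if rg.isoforms:
            genes.append(rg)
        else:
            log.warning("gene %s in %s has no CDS-bearing isoforms; skipped",
                        gene.id, path)
    for mrna in db.features_of_type(("mRNA", "transcript"), order_by="start"):
        if mrna.id not in claimed_mrnas:
            log.warning("transcript %s in %s has no gene parent; skipped",
                        mrna.id, path)
    return genes


def _read_isoform(db, mrna, genome, path) -> RawIsoform | None:
    segs = []
    for cds in db.children(mrna, featuretype="CDS", order_by="start"):
        if cds.seqid not in genome:
            raise ValueError(f"CDS in {path} references unknown contig {cds.seqid}")
        start, end = cds.start - 1, cds.end       # GFF3 1-based incl -> half-open
        if start < 0 or end > genome[cds.seqid].length or start >= end:
            raise ValueError(
                f"CDS {cds.id} coordinates [{cds.start},{cds.end}] outside "
                f"contig {cds.seqid} (length {genome[cds.seqid].length})")
        phase = None if cds.frame in (None, ".", "") else int(cds.frame)
        segs.append((start, end, phase))
    if not segs:
        return None
    segs.sort(key=lambda t: t[0], reverse=(mrna.strand == "-"))
    return RawIsoform(transcript_id=mrna.id, strand=mrna.strand, cds=segs)


def write_annotation_gff3(genes: list[GeneModel], path) -> None:
    """Write gene models back out as GFF3 (gene/mRNA/CDS rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ls, le = g.locus
            fh.write(_gff_row(g.target_id, "gene", ls, le, ".", g.strand, ".",
                              f"ID={g.gene_id}"))
            for iso in g.isoforms:
                s, e = iso.span
                fh.write(_gff_row(g.target_id, "mRNA", s, e, ".", g.strand, ".",
                                  f"ID={iso.protein_id};Parent={g.gene_id}"))
                for ex in iso.exons:
                    fh.write(_gff_row(
                        g.target_id, "CDS", ex.start, ex.end, ".", ex.strand,
                        str(ex.start_phase),
                        f"ID=cds-{iso.protein_id}-{ex.index};Parent={iso.protein_id}"))


def _gff_row(seqid, ftype, start, end, score, strand, phase, attrs) -> str:
    # internal half-open -> GFF3 1-based inclusive
    return (f"{seqid}\tmxescan\t{ftype}\t{start + 1}\t{end}\t{score}\t"
            f"{strand}\t{phase}\t{attrs}\n")


# ---------------------------------------------------------------------------
# results

def write_results(out_dir, fmt: str, candidates, clusters=None, summary=None,
                  genes=None, params: PredictionParams | None = None,
                  dataset_name: str = "dataset", seed: int | None = None,
                  stem: str = "mxe") -> Path:
    """Write prediction results in one of the supported formats.

    YAML is the lossless master output; GFF3/BED/TSV are coordinate exports
    whose score field carries the similarity percent.  Returns the path
    written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "yaml":
        path = out_dir / f"{stem}.yaml"
        write_master_yaml(path, candidates, clusters=clusters, summary=summary,
                          genes=genes, params=params,
                          dataset_name=dataset_name, seed=seed)
    elif fmt == "tsv":
        path = out_dir / f"{stem}.tsv"
        _write_tsv(path, candidates)
    elif fmt == "gff3":
        path = out_dir / f"{stem}.gff3"
        _write_gff3(path, candidates, clusters)
    elif fmt == "bed":
        path = out_dir / f"{stem}.bed"
        _write_bed(path, candidates)
    else:
        raise ValueError(f"unknown output format {fmt!r}; "
                         f"supported: {', '.join(SUPPORTED_FORMATS)}")
    return path


def _write_tsv(path, candidates) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for c in candidates:
            d = c.to_dict()
            flags = d.pop("flags")
            d.update(flags)
            fh.write("\t".join(str(d[k]) for k in TSV_COLUMNS) + "\n")


def _write_gff3(path, candidates, clusters=None) -> None:
    member_cluster = {}
    if clusters:
        for cl in clusters:
            for m in cl.members:
                member_cluster[(m.start, m.end)] = (cl.cluster_id, cl.cluster_type)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(candidates, 1):
            attrs = (f"ID=mxe-{i};source_gene={c.gene_id};"
                     f"source_transcript={c.transcript_id};"
                     f"source_exon={c.exon_index};location={c.location}")
            cl = member_cluster.get((c.start, c.end))
            if cl:
                attrs += f";cluster_id={cl[0]};cluster_type={cl[1]}"
            fh.write(_gff_row(c.target_id, "exon", c.start, c.end,
                              f"{c.score:.2f}", c.strand, ".", attrs))


def _write_bed(path, candidates) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(candidates, 1):
            fh.write(f"{c.target_id}\t{c.start}\t{c.end}\tmxe-{i}\t"
                     f"{c.score:.2f}\t{c.strand}\n")


# ---------------------------------------------------------------------------
# YAML master

def write_master_yaml(path, candidates, clusters=None, summary=None,
                      genes=None, params: PredictionParams | None = None,
                      dataset_name: str = "dataset",
                      seed: int | None = None) -> None:
    doc = {
        "schema_version": MASTER_SCHEMA_VERSION,
        "metadata": {
            "dataset": dataset_name,
            "seed": seed,
            "params": params.to_dict() if params is not None else None,
        },
        "genes": [g.to_dict() for g in genes] if genes is not None else None,
        "candidates": [c.to_dict() for c in candidates],
        "clusters": [cl.to_dict() for cl in clusters] if clusters is not None else None,
        "summary": summary.to_dict() if summary is not None else None,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_master_yaml(path):
    """Load a master YAML; returns (metadata, genes, candidates).

    ``genes`` are reconstructed :class:`GeneModel` objects (peptides were
    stored, so no genome is needed); ``candidates`` are
    :class:`~mxescan.predict.MXECandidate` objects.
    """
    from .predict import MXECandidate  # local import to avoid a cycle
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("schema_version") != MASTER_SCHEMA_VERSION:
        raise ValueError(f"unsupported master schema version in {path}")
    meta = doc["metadata"]
    if meta.get("params") is not None:
        meta["params"] = PredictionParams.from_dict(meta["params"])
    genes = ([GeneModel.from_dict(g) for g in doc["genes"]]
             if doc.get("genes") else [])
    candidates = [MXECandidate.from_dict(c) for c in doc["candidates"]]
    return meta, genes, candidates
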