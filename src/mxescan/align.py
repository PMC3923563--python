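"""Peptide similarity scoring for exon comparison.

The similarity between an original exon and a candidate exon is the global
alignment score of the two encoded peptides, normalized by the original
peptide's self-alignment score and expressed in percent:

    score = 100 * align(original, candidate) / align(original, original)

Identical peptides therefore score exactly 100; unrelated peptides may score
negative.  Global (end-gap-penalized) alignment is used because mutually
exclusive exons are expected to encode the same protein region end to end.
"""
from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # Biopython convention: a gap of length L costs open + (L-1) * extend.
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def alignment_score(a: str, b: str, matrix: str = "BLOSUM62",
                    gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Raw global alignment score of two peptides."""
    _check_peptide(a)
    _check_peptide(b)
    return float(_aligner(matrix, gap_open, gap_extend).score(a, b))


def similarity_score(original: str, candidate: str, matrix: str = "BLOSUM62",
                     gap_open: float = 11.0, gap_extend: float = 1.0,
                     self_score: float | None = None) -> float:
    """Percent similarity of ``candidate`` to ``original`` (self-normalized).

    ``self_score`` may be supplied to amortize the original's self-alignment
    over many candidates; it must equal ``alignment_score(original, original)``.

    Raises
    ------
    ValueError
        If either peptide is empty or contains a non-standard residue, or if
        the original's self-score is not positive (degenerate original).
    """
    if self_score is None:
        self_score = alignment_score(original, original, matrix, gap_open, gap_extend)
    else:
        _check_peptide(original)
    if self_score <= 0:
        raise ValueError("degenerate original peptide: self-alignment score <= 0")
    raw = alignment_score(original, candidate, matrix, gap_open, gap_extend)
    return 100.0 * raw / self_score


def _check_peptide(p: str) -> None:
    if not p:
        raise ValueError("empty peptide")
    bad = set(p) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues in peptide: {sorted(bad)}")
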