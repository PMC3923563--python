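"""Prediction parameter sets.

Two canonical profiles exist.  The *store* profile is deliberately relaxed so
that a single expensive genome scan keeps divergent candidates which can later
be re-filtered without re-running the prediction; the *display* profile is the
strict default a user sees when filtering stored results.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

SCOPE_FLANKING = "flanking"
SCOPE_ALL = "all"


@dataclass(frozen=True)
class PredictionParams:
    """Thresholds and settings governing candidate enumeration and filtering.

    Parameters
    ----------
    min_score:
        Minimal similarity score, in percent of the original exon's
        self-alignment score.  Display default 15, store profile 10.
    max_len_diff:
        Maximal length difference between original and candidate exon, in
        amino acids (whole codons).  Default 20.
    min_exon_len:
        Minimal length of the *original* exon, in amino acids; prevents
        predictions seeded from very short exons.  Display default 15,
        store profile 10.
    scope:
        ``"flanking"`` searches only the two introns surrounding each exon;
        ``"all"`` searches every intron of the isoform.
    flank_nt:
        Nucleotides of up-/downstream gene flank to search (0 disables).
        Store profile 20000.
    matrix, gap_open, gap_extend:
        Global-alignment settings for the similarity score.  A gap of length
        L costs ``gap_open + (L - 1) * gap_extend``; end gaps are penalized.
    min_candidate_margin:
        Minimal distance (nt) a candidate must keep to either edge of its
        search region, so that residual introns never collapse to nothing.
    exclude_isoform_overlaps:
        Drop candidates that overlap — without exactly matching — an exon of
        another annotated isoform (potential false positives).
    """

    min_score: float = 15.0
    max_len_diff: int = 20
    min_exon_len: int = 15
    scope: str = SCOPE_FLANKING
    flank_nt: int = 0
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_candidate_margin: int = 20
    exclude_isoform_overlaps: bool = True

    def __post_init__(self) -> None:
        if self.min_score > 100:
            raise ValueError("min_score cannot exceed 100 percent")
        if self.max_len_diff < 0 or self.min_exon_len < 0 or self.flank_nt < 0:
            raise ValueError("thresholds must be non-negative")
        if self.scope not in (SCOPE_FLANKING, SCOPE_ALL):
            raise ValueError(f"scope must be '{SCOPE_FLANKING}' or '{SCOPE_ALL}'")

    @classmethod
    def display(cls, **overrides) -> "PredictionParams":
        """Strict defaults used when presenting/filtering results."""
        return cls(**overrides)

    @classmethod
    def store(cls, **overrides) -> "PredictionParams":
        """Relaxed pipeline profile: keep divergent candidates for later filtering."""
        base = dict(min_score=10.0, min_exon_len=10, scope=SCOPE_ALL, flank_nt=20000)
        base.update(overrides)
        return cls(**base)

    def replace(self, **changes) -> "PredictionParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionParams":
        return cls(**d)
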