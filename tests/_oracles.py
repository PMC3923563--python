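"""Independent reference implementations used only as test oracles.

These are deliberately naive and written against the documented contracts,
not against the package internals: a Gotoh affine-gap global aligner with
penalized end gaps (gap of length L costs open + (L-1)*extend), a literal
O(n^2) candidate enumerator over all splice-site-bounded position pairs, and
a naive repeated-maximum overlap resolver.
"""
from __future__ import annotations

from Bio.Align import substitution_matrices

NEG = float("-inf")
_STOPS = {"TAA", "TAG", "TGA"}

_B62 = substitution_matrices.load("BLOSUM62")


def gotoh_global_score(a: str, b: str, gap_open: float = 11.0,
                       gap_extend: float = 1.0) -> float:
    """Global alignment score, affine gaps, end gaps penalized."""
    n, m = len(a), len(b)
    sub = lambda i, j: float(_B62[a[i - 1], b[j - 1]])
    M = [[NEG] * (m + 1) for _ in range(n + 1)]   # ends in a match/mismatch
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # ends in gap in b (a vs -)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # ends in gap in a (- vs b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + sub(i, j)
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def similarity_percent_oracle(original: str, candidate: str) -> float:
    return 100.0 * gotoh_global_score(original, candidate) / \
        gotoh_global_score(original, original)


def translate_codons(seq: str) -> str:
    """Codon-by-codon translation using the raw standard-code table."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id
    fwd = unambiguous_dna_by_id[1].forward_table
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        out.append("*" if codon in _STOPS else fwd[codon])
    return "".join(out)


def brute_force_candidates(seq: str, orig_nt_len: int, orig_phase: int,
                           orig_peptide: str, *, min_score: float,
                           max_len_diff: int, margin: int,
                           score_fn) -> list[tuple[int, int, float]]:
    """Literal scan over all AG/GT(GC)-bounded position pairs in a region.

    Applies exactly the documented predicates: splice sites immediately
    outside the candidate, edge margins, frame compatibility, the codon
    length-difference cap, no in-frame internal stop, non-empty peptide and
    the score threshold.  Returns (start, end, score) triples.
    """
    n = len(seq)
    out = []
    for s in range(0, n + 1):
        if s < margin or s < 2 or seq[s - 2:s] != "AG":
            continue
        for e in range(s + 1, n + 1):
            if n - e < margin or seq[e:e + 2] not in ("GT", "GC"):
                continue
            if (e - s - orig_nt_len) % 3 != 0:
                continue
            if abs(e - s - orig_nt_len) // 3 > max_len_diff:
                continue
            if "N" in seq[s - 2:e + 2]:
                continue
            body = seq[s + orig_phase:e]
            body = body[: len(body) - len(body) % 3]
            if not body:
                continue
            if any(body[k:k + 3] in _STOPS for k in range(0, len(body), 3)):
                continue
            pep = translate_codons(body)
            score = score_fn(orig_peptide, pep)
            if score >= min_score:
                out.append((s, e, score))
    return out


def naive_overlap_resolution(items: list) -> list:
    """Repeatedly keep the best (score, -len_diff, 5'-most) item, drop overlaps."""
    pool = list(items)
    kept = []
    while pool:
        best = min(pool, key=lambda c: (-c.score, c.len_diff_aa, c.start, c.end))
        kept.append(best)
        pool = [c for c in pool
                if c is not best and (c.end <= best.start or best.end <= c.start)]
    return sorted(kept, key=lambda c: (c.start, c.end))
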