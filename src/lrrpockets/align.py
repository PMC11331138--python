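"""Pairwise alignment helpers shared by the mining and homology modules.

Thin wrappers around :class:`Bio.Align.PairwiseAligner` with one scoring
scheme (BLOSUM62, affine gaps 11/1) so that local links, clustering
identities and global similarities are all computed consistently.
E-values follow the Karlin-Altschul formalism with the standard gapped
BLOSUM62 parameters; exact parity with any particular BLAST release is
not a goal.
"""

from __future__ import annotations

import math
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

# Karlin-Altschul parameters for gapped BLOSUM62, gap open 11 / extend 1
# (the classic blastp defaults).
KA_LAMBDA = 0.267
KA_K = 0.041


@lru_cache(maxsize=None)
def make_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = mode
    return aligner


def _best_alignment(a: str, b: str, mode: str):
    aligner = make_aligner(mode)
    alignments = aligner.align(a, b)
    return alignments[0]


def local_score(a: str, b: str) -> float:
    """Raw local alignment score (0 for empty inputs)."""
    if not a or not b:
        return 0.0
    return float(make_aligner("local").score(a, b))


def alignment_columns(alignment):
    """Yield (char_a, char_b) pairs over the aligned region, gaps as '-'."""
    sa, sb = str(alignment[0]), str(alignment[1])
    for ca, cb in zip(sa, sb):
        yield ca, cb


def local_identity(a: str, b: str, min_length: int = 1) -> float:
    """Identity of the optimal local alignment.

    Identities are divided by max(alignment length, ``min_length``): the
    floor damps the short, near-perfect local hits that any two unrelated
    sequences share, which would otherwise saturate single-linkage
    clustering.
    """
    if not a or not b:
        return 0.0
    aln = _best_alignment(a, b, "local")
    matches = 0
    length = 0
    for ca, cb in alignment_columns(aln):
        length += 1
        if ca == cb and ca != "-":
            matches += 1
    if length == 0:
        return 0.0
    return matches / max(length, min_length)


def global_similarity(a: str, b: str) -> float:
    """Fraction of positive-scoring matched columns in the optimal global
    alignment, over the alignment length (percent/100)."""
    if not a or not b:
        return 0.0
    aln = _best_alignment(a, b, "global")
    matrix = make_aligner("global").substitution_matrix
    positive = 0
    length = 0
    for ca, cb in alignment_columns(aln):
        length += 1
        if ca != "-" and cb != "-" and matrix[ca, cb] > 0:
            positive += 1
    return positive / length if length else 0.0


def global_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    aln = _best_alignment(a, b, "global")
    matches = 0
    length = 0
    for ca, cb in alignment_columns(aln):
        length += 1
        if ca == cb and ca != "-":
            matches += 1
    return matches / length if length else 0.0


def bit_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def evalue(raw_score: float, m: int, n: int) -> float:
    """Karlin-Altschul expected number of chance local alignments with at
    least this raw score, for query/target lengths m and n."""
    return m * n * math.pow(2.0, -bit_score(raw_score))
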