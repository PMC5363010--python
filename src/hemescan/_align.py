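"""Shared pairwise-alignment machinery (BLOSUM62, affine gaps).

Both the local screening aligner and the global reference-mapping
aligner use BLOSUM62 with gap open 11 / extend 1, the parameters
recorded in every run report.  The matrix is modified so that 'X'
(unknown residue, e.g. from an N-containing codon) scores 0 against
everything: an X column neither rewards nor penalizes.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

GAP_OPEN = -11
GAP_EXTEND = -1


@lru_cache(maxsize=1)
def scoring_matrix():
    """BLOSUM62 with the 'X' row/column neutralized to 0."""
    m = substitution_matrices.load("BLOSUM62")
    for a in m.alphabet:
        m["X", a] = 0.0
        m[a, "X"] = 0.0
    return m


def local_aligner() -> Align.PairwiseAligner:
    """Smith-Waterman aligner with affine gaps."""
    a = Align.PairwiseAligner()
    a.substitution_matrix = scoring_matrix()
    a.mode = "local"
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


def global_aligner() -> Align.PairwiseAligner:
    """Needleman-Wunsch aligner with affine internal gaps, free end gaps.

    End gaps are free so that 5'/3' extensions of a candidate do not
    distort its mapping onto the reference.
    """
    a = Align.PairwiseAligner()
    a.substitution_matrix = scoring_matrix()
    a.mode = "global"
    a.open_internal_gap_score = GAP_OPEN
    a.extend_internal_gap_score = GAP_EXTEND
    a.end_gap_score = 0
    return a


def self_score(protein: str) -> float:
    """Score of a protein aligned to itself (sum of diagonal scores)."""
    m = scoring_matrix()
    return float(sum(m[aa, aa] for aa in protein))
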