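"""Whole-sequence identity and greedy redundancy filtering.

Training and test sets are de-redundified so that no two proteins share
>= 25% identity over their entire sequence, preventing the classifier from
scoring a protein by recognising a close homologue.
"""

from __future__ import annotations

from functools import lru_cache
from typing import List, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .types import STANDARD_RESIDUES, ProteinRecord

__all__ = ["pairwise_identity", "redundancy_filter"]

_ALPHABET = "ACDEFGHIKLMNPQRSTVWYXUB"


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    # identity scoring: non-standard residues (X, U, B) never count as a
    # match, even against themselves
    matrix = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            matrix[a, b] = match if (a == b and a in STANDARD_RESIDUES) else mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_identity(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> float:
    """Fraction of identical columns in an optimal global alignment.

    The alignment uses match/mismatch/linear-gap scoring (defaults 1/0/-1)
    and the identity denominator is the total number of alignment columns,
    gaps included.  Arguments are canonically ordered before aligning, so
    the value is exactly symmetric even when co-optimal alignments differ.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    s1, s2 = sorted((a.upper(), b.upper()))
    alignment = _aligner(match, mismatch, gap).align(s1, s2)[0]
    row1, row2 = str(alignment[0]), str(alignment[1])
    columns = len(row1)
    identical = sum(
        1 for x, y in zip(row1, row2) if x == y and x in STANDARD_RESIDUES
    )
    return identical / columns


def redundancy_filter(
    records: Sequence[ProteinRecord],
    threshold: float = 0.25,
    **alignment_params,
) -> List[ProteinRecord]:
    """Greedy keep-first sweep: a record is kept iff its identity to every
    already-kept record is below ``threshold``.  Output preserves input
    order."""
    kept: List[ProteinRecord] = []
    for rec in records:
        if all(
            pairwise_identity(rec.sequence, k.sequence, **alignment_params) < threshold
            for k in kept
        ):
            kept.append(rec)
    return kept
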