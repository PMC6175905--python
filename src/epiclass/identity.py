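"""Pairwise percent-identity matrix for antigen panels.

Sequence identity between panel members contextualizes cross-reactivity:
closely related metalloproteinases share epitope-bearing regions.  Pairs are
aligned globally with affine gap penalties (Needleman-Wunsch/Gotoh, via
Biopython's PairwiseAligner) under BLOSUM62 with gap open 10 and extend 0.5;
percent identity is the fraction of identical columns among columns where
neither row is a gap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .io import Antigen


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: str, b: str, aligner: PairwiseAligner | None = None
) -> tuple[str, str]:
    """Optimal global alignment of two sequences as two gapped strings."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = aligner or make_aligner()
    alignment = aligner.align(a, b)[0]
    rows = str(alignment).splitlines()
    # Alignment str format: target / pipes / query blocks; use indices instead
    return alignment[0], alignment[1]


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """100 x identical columns / columns where neither sequence is gapped."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    pairs = [(x, y) for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-"]
    if not pairs:
        raise ValueError("alignment has no gap-free columns")
    same = sum(1 for x, y in pairs if x == y)
    return 100.0 * same / len(pairs)


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    return percent_identity(*global_align(a, b, aligner))


def identity_matrix(
    antigens: list[Antigen], aligner: PairwiseAligner | None = None
) -> pd.DataFrame:
    """Symmetric percent-identity matrix over a panel, diagonal 100."""
    aligner = aligner or make_aligner()
    ids = [ag.id for ag in antigens]
    n = len(ids)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_identity(antigens[i].sequence, antigens[j].sequence, aligner)
            values[i, j] = values[j, i] = pid
    return pd.DataFrame(values, index=ids, columns=ids)
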