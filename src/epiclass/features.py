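"""The 33-attribute physicochemical profile of a peptide.

Every attribute is a function of amino-acid composition alone, which is what
lets a composition-only classifier generalize across antigens of one protein
class.  The attribute set:

* mole percent of each of the 20 canonical residues;
* five group percents — positively charged (R,H,K), negatively charged (D,E),
  uncharged polar (S,T,N,Q), special (C,G,P) and hydrophobic (A,V,I,L,M,F,W);
* GRAVY — mean Kyte-Doolittle hydropathy (dimensionless);
* aliphatic index (Ikai): AI = X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu),
  X in mole percent;
* atom percents of C, H, N, O and S over the whole peptide, counted from
  free-amino-acid molecular formulas minus one water per peptide bond (so a
  1-mer equals the free amino acid);
* isoelectric point — the pH where the Henderson-Hasselbalch net charge over
  the two termini and the ionizable side chains (R, K, H positive; D, E, C, Y
  negative) crosses zero, found by bisection on [0, 14].

Everything is computed from a residue-count vector, so featurizing all
k-mers of an antigen costs one cumulative-sum pass over the sequence.
Peptide length is deliberately not an attribute by default (33 attributes);
``include_length=True`` appends it as a 34th column.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .io import CANONICAL_AA, AnnotationError
from .kmers import Kmer

AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}

# Kyte-Doolittle hydropathy, indexed like CANONICAL_AA
KYTE_DOOLITTLE = np.array(
    [
        1.8,  # A
        2.5,  # C
        -3.5,  # D
        -3.5,  # E
        2.8,  # F
        -0.4,  # G
        -3.2,  # H
        4.5,  # I
        -3.9,  # K
        3.8,  # L
        1.9,  # M
        -3.5,  # N
        -1.6,  # P
        -3.5,  # Q
        -4.5,  # R
        -0.8,  # S
        -0.7,  # T
        4.2,  # V
        -0.9,  # W
        -1.3,  # Y
    ]
)

# Free amino-acid molecular formulas, columns C, H, N, O, S
ATOM_FORMULAS = np.array(
    [
        [3, 7, 1, 2, 0],  # A
        [3, 7, 1, 2, 1],  # C
        [4, 7, 1, 4, 0],  # D
        [5, 9, 1, 4, 0],  # E
        [9, 11, 1, 2, 0],  # F
        [2, 5, 1, 2, 0],  # G
        [6, 9, 3, 2, 0],  # H
        [6, 13, 1, 2, 0],  # I
        [6, 14, 2, 2, 0],  # K
        [6, 13, 1, 2, 0],  # L
        [5, 11, 1, 2, 1],  # M
        [4, 8, 2, 3, 0],  # N
        [5, 9, 1, 2, 0],  # P
        [5, 10, 2, 3, 0],  # Q
        [6, 14, 4, 2, 0],  # R
        [3, 7, 1, 3, 0],  # S
        [4, 9, 1, 3, 0],  # T
        [5, 11, 1, 2, 0],  # V
        [11, 12, 2, 2, 0],  # W
        [9, 11, 1, 3, 0],  # Y
    ],
    dtype=float,
)

GROUPS = {
    "pct_positive": "RHK",
    "pct_negative": "DE",
    "pct_uncharged": "STNQ",
    "pct_special": "CGP",
    "pct_hydrophobic": "AVILMFW",
}

# Pinned pKa table (Bjellqvist-style values used by ProtParam-equivalent tools)
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}

ATTRIBUTE_NAMES: list[str] = (
    [f"pct_{aa}" for aa in CANONICAL_AA]
    + list(GROUPS)
    + ["gravy", "aliphatic_index"]
    + [f"pct_atom_{a}" for a in "CHNOS"]
    + ["isoelectric_point"]
)
assert len(ATTRIBUTE_NAMES) == 33

_GROUP_MATRIX = np.zeros((20, len(GROUPS)))
for gi, members in enumerate(GROUPS.values()):
    for aa in members:
        _GROUP_MATRIX[AA_INDEX[aa], gi] = 1.0


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """Named view over one row of the attribute matrix."""

    values: np.ndarray
    names: tuple[str, ...] = tuple(ATTRIBUTE_NAMES)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("value/name length mismatch")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


def sequence_counts(sequence: str) -> np.ndarray:
    """Residue counts over CANONICAL_AA order; rejects non-canonical input."""
    if not sequence:
        raise AnnotationError("cannot featurize an empty sequence")
    counts = np.zeros(20)
    for ch in sequence.upper():
        idx = AA_INDEX.get(ch)
        if idx is None:
            raise AnnotationError(f"non-canonical residue {ch!r} in {sequence!r}")
        counts[idx] += 1
    return counts


def isoelectric_points(counts: np.ndarray, n_iter: int = 60) -> np.ndarray:
    """Vectorized pI by bisection for each row of a residue-count matrix."""
    counts = np.atleast_2d(counts)
    pos_pka = np.array([PKA_POSITIVE["Nterm"]] + [PKA_POSITIVE[a] for a in "RKH"])
    neg_pka = np.array([PKA_NEGATIVE["Cterm"]] + [PKA_NEGATIVE[a] for a in "DECY"])
    ones = np.ones((counts.shape[0], 1))
    pos_n = np.hstack([ones, counts[:, [AA_INDEX[a] for a in "RKH"]]])
    neg_n = np.hstack([ones, counts[:, [AA_INDEX[a] for a in "DECY"]]])

    def net_charge(ph: np.ndarray) -> np.ndarray:
        ph = ph[:, None]
        pos = (pos_n / (1.0 + 10.0 ** (ph - pos_pka))).sum(axis=1)
        neg = (neg_n / (1.0 + 10.0 ** (neg_pka - ph))).sum(axis=1)
        return pos - neg

    lo = np.zeros(counts.shape[0])
    hi = np.full(counts.shape[0], 14.0)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        positive = net_charge(mid) > 0
        lo = np.where(positive, mid, lo)
        hi = np.where(positive, hi, mid)
    return 0.5 * (lo + hi)


def features_from_counts(counts: np.ndarray, include_length: bool = False) -> np.ndarray:
    """Attribute matrix (n, 33) from a residue-count matrix (n, 20)."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    k = counts.sum(axis=1)
    if np.any(k < 1):
        raise AnnotationError("cannot featurize an empty sequence")
    pct = 100.0 * counts / k[:, None]
    groups = pct @ _GROUP_MATRIX
    gravy = counts @ KYTE_DOOLITTLE / k
    ai = (
        pct[:, AA_INDEX["A"]]
        + 2.9 * pct[:, AA_INDEX["V"]]
        + 3.9 * (pct[:, AA_INDEX["I"]] + pct[:, AA_INDEX["L"]])
    )
    atoms = counts @ ATOM_FORMULAS
    # one water (H2O) lost per peptide bond
    atoms[:, 1] -= 2.0 * (k - 1)
    atoms[:, 3] -= k - 1
    atom_pct = 100.0 * atoms / atoms.sum(axis=1)[:, None]
    pi = isoelectric_points(counts)
    cols = [pct, groups, gravy[:, None], ai[:, None], atom_pct, pi[:, None]]
    if include_length:
        cols.append(k[:, None])
    return np.hstack(cols)


def featurize(sequence: str, include_length: bool = False) -> FeatureVector:
    """The 33-attribute profile of one peptide."""
    row = features_from_counts(sequence_counts(sequence), include_length)[0]
    names = ATTRIBUTE_NAMES + (["length"] if include_length else [])
    return FeatureVector(values=row, names=tuple(names))


def atom_percentages(sequence: str) -> dict[str, float]:
    """Percent of C, H, N, O, S atoms in the peptide (terminal water included)."""
    row = features_from_counts(sequence_counts(sequence))[0]
    off = 20 + len(GROUPS) + 2
    return {a: float(row[off + i]) for i, a in enumerate("CHNOS")}


def gravy(sequence: str) -> float:
    return featurize(sequence)["gravy"]


def aliphatic_index(sequence: str) -> float:
    return featurize(sequence)["aliphatic_index"]


def isoelectric_point(sequence: str) -> float:
    return float(isoelectric_points(sequence_counts(sequence))[0])


def antigen_kmer_counts(sequence: str, starts: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Residue-count rows for many k-mers of one sequence via cumulative sums.

    starts are 1-based; row i covers sequence[starts[i]-1 : starts[i]-1+ks[i]].
    """
    idx = np.array([AA_INDEX[ch] for ch in sequence])
    onehot = np.zeros((len(sequence) + 1, 20))
    onehot[np.arange(1, len(sequence) + 1), idx] = 1.0
    csum = np.cumsum(onehot, axis=0)
    a = np.asarray(starts) - 1
    b = a + np.asarray(ks)
    return csum[b] - csum[a]


def kmer_feature_matrix(
    kmers: Sequence[Kmer],
    sequences: dict[str, str],
    include_length: bool = False,
) -> np.ndarray:
    """Attribute matrix for labeled k-mers, grouped by antigen for speed."""
    if not kmers:
        return np.empty((0, len(ATTRIBUTE_NAMES) + bool(include_length)))
    rows = np.empty((len(kmers), 20))
    order: dict[str, list[int]] = {}
    for i, km in enumerate(kmers):
        order.setdefault(km.antigen_id, []).append(i)
    for ag_id, idxs in order.items():
        starts = np.array([kmers[i].start for i in idxs])
        ks = np.array([kmers[i].k for i in idxs])
        rows[idxs] = antigen_kmer_counts(sequences[ag_id], starts, ks)
    return features_from_counts(rows, include_length)


def write_matrix_tsv(path, matrix: np.ndarray, labels: Iterable[str] | None = None) -> None:
    names = list(ATTRIBUTE_NAMES)
    if matrix.shape[1] == len(names) + 1:
        names.append("length")
    header = "\t".join(names + (["label"] if labels is not None else []))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        labels = list(labels) if labels is not None else None
        for i, row in enumerate(matrix):
            cells = [repr(float(v)) for v in row]
            if labels is not None:
                cells.append(labels[i])
            fh.write("\t".join(cells) + "\n")
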