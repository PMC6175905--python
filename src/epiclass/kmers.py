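"""Frame-shifted k-mer decomposition and class labeling.

A sequence of length L yields, for every k in [k_min, k_max], the substrings
starting at offsets 1, 1+step, ... — ``max(0, (L - k)//step + 1)`` of them.
Each k-mer is labeled against the antigen's annotated regions under one of
three rules, all phrased in terms of the fraction of the k-mer's residues
lying inside regions of a class:

* ``any_overlap``       — fraction > 0
* ``majority``          — fraction >= 0.5 (ties count; "50% or more")
* ``full_containment``  — fraction == 1

The epitope test is applied first; if it fails, the same test is applied to
nonepitope coverage; otherwise the k-mer is ``unassigned``.  Residues covered
by neither label count toward neither class, but the denominator stays k, so
k-mers straddling unannotated sequence are conservatively down-weighted.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .io import Antigen, Region

RULE_NAMES = ("any_overlap", "majority", "full_containment")


@dataclasses.dataclass(frozen=True)
class LabelingRule:
    name: str = "majority"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.name not in RULE_NAMES:
            raise ValueError(f"unknown rule {self.name!r}; expected one of {RULE_NAMES}")
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")

    def admits(self, fraction: float) -> bool:
        if self.name == "any_overlap":
            return fraction > 0.0
        if self.name == "majority":
            return fraction >= self.threshold
        return fraction == 1.0


@dataclasses.dataclass
class Kmer:
    antigen_id: str
    start: int  # 1-based inclusive
    k: int
    sequence: str
    label: str = "unassigned"
    overlap_fraction: float = 0.0

    @property
    def end(self) -> int:
        return self.start + self.k - 1


def _coverage_mask(length: int, regions: Iterable[Region]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for r in regions:
        mask[r.start - 1 : r.end] = True
    return mask


def coverage_fractions(antigen: Antigen, label: str, starts: np.ndarray, k: int) -> np.ndarray:
    """Fraction of each k-mer's residues inside regions with ``label``."""
    mask = _coverage_mask(len(antigen), antigen.regions_with_label(label))
    csum = np.concatenate([[0], np.cumsum(mask)])
    return (csum[starts - 1 + k] - csum[starts - 1]) / k


def generate_kmers(
    antigen: Antigen, k_min: int = 3, k_max: int = 15, step: int = 1
) -> list[Kmer]:
    """All frame-shifted k-mers of the antigen, ordered by k then offset."""
    if k_min < 1 or k_max < k_min or step < 1:
        raise ValueError("need k_min >= 1, k_max >= k_min, step >= 1")
    L = len(antigen)
    out: list[Kmer] = []
    for k in range(k_min, k_max + 1):
        for start in range(1, L - k + 2, step):
            out.append(
                Kmer(
                    antigen_id=antigen.id,
                    start=start,
                    k=k,
                    sequence=antigen.sequence[start - 1 : start - 1 + k],
                )
            )
    return out


def expected_kmer_count(L: int, k_min: int, k_max: int, step: int = 1) -> int:
    """Closed-form count: sum over k of max(0, floor((L-k)/step) + 1)."""
    return sum(max(0, (L - k) // step + 1) for k in range(k_min, k_max + 1))


def label_kmer(kmer: Kmer, regions: Sequence[Region], rule: LabelingRule) -> Kmer:
    """Label one k-mer in place against its antigen's regions; returns it."""
    epi = [r for r in regions if r.label == "epitope"]
    non = [r for r in regions if r.label == "nonepitope"]
    length = max([kmer.end] + [r.end for r in regions]) if regions else kmer.end
    epi_mask = _coverage_mask(length, epi)
    non_mask = _coverage_mask(length, non)
    sl = slice(kmer.start - 1, kmer.end)
    epi_frac = float(epi_mask[sl].sum()) / kmer.k
    non_frac = float(non_mask[sl].sum()) / kmer.k
    kmer.overlap_fraction = epi_frac
    if rule.admits(epi_frac):
        kmer.label = "epitope"
    elif rule.admits(non_frac):
        kmer.label = "nonepitope"
    else:
        kmer.label = "unassigned"
    return kmer


def label_antigen_kmers(
    antigen: Antigen,
    rule: LabelingRule,
    k_min: int = 3,
    k_max: int = 15,
    step: int = 1,
) -> list[Kmer]:
    """Vectorized generate + label for one antigen."""
    kmers = generate_kmers(antigen, k_min, k_max, step)
    if not kmers:
        return kmers
    epi_mask = _coverage_mask(len(antigen), antigen.regions_with_label("epitope"))
    non_mask = _coverage_mask(len(antigen), antigen.regions_with_label("nonepitope"))
    epi_csum = np.concatenate([[0], np.cumsum(epi_mask)])
    non_csum = np.concatenate([[0], np.cumsum(non_mask)])
    for km in kmers:
        a, b = km.start - 1, km.end
        epi_frac = (epi_csum[b] - epi_csum[a]) / km.k
        non_frac = (non_csum[b] - non_csum[a]) / km.k
        km.overlap_fraction = float(epi_frac)
        if rule.admits(epi_frac):
            km.label = "epitope"
        elif rule.admits(non_frac):
            km.label = "nonepitope"
        else:
            km.label = "unassigned"
    return kmers


def build_labeled_set(
    antigens: Sequence[Antigen],
    rule: LabelingRule = LabelingRule(),
    k_min: int = 3,
    k_max: int = 15,
    step: int = 1,
) -> list[Kmer]:
    """Labeled k-mers over a panel of annotated antigens, in panel order."""
    if not any(ag.regions for ag in antigens):
        raise ValueError("no annotated regions on any antigen; nothing to label")
    out: list[Kmer] = []
    for ag in antigens:
        out.extend(label_antigen_kmers(ag, rule, k_min, k_max, step))
    return out


def class_counts(kmers: Iterable[Kmer]) -> dict[str, int]:
    counts = {"epitope": 0, "nonepitope": 0, "unassigned": 0}
    for km in kmers:
        counts[km.label] += 1
    return counts


def write_kmers_tsv(path, kmers: Iterable[Kmer]) -> None:
    with open(path, "w") as fh:
        fh.write("antigen_id\tstart\tk\tsequence\tlabel\toverlap_fraction\n")
        for km in kmers:
            fh.write(
                f"{km.antigen_id}\t{km.start}\t{km.k}\t{km.sequence}"
                f"\t{km.label}\t{km.overlap_fraction!r}\n"
            )


def read_kmers_tsv(path) -> list[Kmer]:
    out: list[Kmer] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("antigen_id"):
                continue
            ag_id, start, k, seq, label, frac = line.split("\t")
            out.append(Kmer(ag_id, int(start), int(k), seq, label, float(frac)))
    return out
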