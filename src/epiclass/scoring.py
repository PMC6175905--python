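"""From k-mer predictions to per-residue scores, region calls and peptides.

The per-residue epitope score of position i is the fraction of k-mers
covering i that the classifier calls positive (at the k-mer-level cutoff);
residues covered by no k-mer score 0.  A region call is a maximal run of
residues at or above the sequence-level cutoff (0.2 by default), discarding
runs shorter than the smallest k-mer (3).  Predicted cores are expanded by a
fixed pad on each side (clamped to the sequence) to reach synthesis-ready
peptide length — e.g. a 9-residue core padded by 3 gives a 15-mer.

SPOT reactivity tracks mirror the cellulose-membrane immunoassay geometry:
overlapping 15-mer peptides frame-shifted by 3 residues tile the antigen;
the raw per-residue score is the number of reactive peptides covering the
residue, rescaled so the maximum is exactly 1.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .io import Antigen, Region, ScoreTrack
from .kmers import Kmer

SPOT_LENGTH = 15
SPOT_STRIDE = 3


@dataclasses.dataclass(frozen=True)
class RegionCall:
    region: Region
    mean_score: float

    @property
    def start(self) -> int:
        return self.region.start

    @property
    def end(self) -> int:
        return self.region.end


@dataclasses.dataclass(frozen=True)
class SpotPeptide:
    start: int  # 1-based
    reactive: bool
    length: int = SPOT_LENGTH


def residue_scores(
    kmers: Sequence[Kmer],
    probabilities: Sequence[float],
    antigen_id: str,
    L: int,
    kmer_cutoff: float = 0.5,
) -> ScoreTrack:
    """Fraction of positive-predicted covering k-mers at each residue."""
    if len(kmers) != len(probabilities):
        raise ValueError("one probability per k-mer required")
    covered = np.zeros(L)
    positive = np.zeros(L)
    for km, p in zip(kmers, probabilities):
        if km.start < 1 or km.end > L:
            raise ValueError(f"k-mer ({km.start}, {km.end}) outside [1, {L}]")
        sl = slice(km.start - 1, km.end)
        covered[sl] += 1
        if p >= kmer_cutoff:
            positive[sl] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(covered > 0, positive / np.maximum(covered, 1), 0.0)
    return ScoreTrack(antigen_id=antigen_id, scores=list(scores))


def mean_probability_scores(
    kmers: Sequence[Kmer],
    probabilities: Sequence[float],
    antigen_id: str,
    L: int,
) -> ScoreTrack:
    """Alternative aggregation: mean predicted probability of covering k-mers."""
    covered = np.zeros(L)
    total = np.zeros(L)
    for km, p in zip(kmers, probabilities):
        sl = slice(km.start - 1, km.end)
        covered[sl] += 1
        total[sl] += p
    scores = np.where(covered > 0, total / np.maximum(covered, 1), 0.0)
    return ScoreTrack(antigen_id=antigen_id, scores=list(np.clip(scores, 0.0, 1.0)))


def call_regions(
    track: ScoreTrack, cutoff: float = 0.2, min_length: int = 3
) -> list[RegionCall]:
    """Maximal runs of residues scoring >= cutoff, at least min_length long."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    scores = np.asarray(track.scores)
    above = scores >= cutoff
    calls: list[RegionCall] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if j - i + 1 >= min_length:
                mean = float(scores[i : j + 1].mean())
                calls.append(
                    RegionCall(
                        region=Region(i + 1, j + 1, "predicted", round(mean, 12)),
                        mean_score=mean,
                    )
                )
            i = j + 1
        else:
            i += 1
    return calls


def expand_region(region: Region, pad: int, L: int) -> Region:
    """Pad a region by ``pad`` residues per side, clamped to [1, L]."""
    return Region(
        start=max(1, region.start - pad),
        end=min(L, region.end + pad),
        label=region.label,
        score=region.score,
    )


def make_spot_peptides(L: int, reactive_starts: Iterable[int] = ()) -> list[SpotPeptide]:
    """The pentadecapeptide tiling of a length-L antigen, stride 3."""
    reactive = set(reactive_starts)
    starts = list(range(1, L - SPOT_LENGTH + 2, SPOT_STRIDE))
    if not starts:
        raise ValueError(f"sequence of length {L} is shorter than one spot ({SPOT_LENGTH})")
    unknown = reactive - set(starts)
    if unknown:
        raise ValueError(f"reactive starts {sorted(unknown)} are not on the stride-3 tiling")
    return [SpotPeptide(start=s, reactive=s in reactive) for s in starts]


def spot_track(spots: Sequence[SpotPeptide], L: int) -> ScoreTrack:
    """Reactivity score: reactive-spot coverage count, scaled to max 1."""
    starts = sorted(s.start for s in spots)
    if not starts:
        raise ValueError("no spots given")
    diffs = set(b - a for a, b in zip(starts, starts[1:]))
    if diffs - {SPOT_STRIDE}:
        raise ValueError(f"malformed tiling: consecutive starts must differ by {SPOT_STRIDE}")
    raw = np.zeros(L)
    for s in spots:
        if s.reactive:
            raw[s.start - 1 : min(L, s.start + s.length - 1)] += 1
    peak = raw.max()
    scores = raw / peak if peak > 0 else raw
    return ScoreTrack(antigen_id="", scores=list(scores))


def truth_mask(antigen: Antigen, label: str = "epitope") -> np.ndarray:
    """Boolean per-residue mask of regions with the given label."""
    mask = np.zeros(len(antigen), dtype=bool)
    for r in antigen.regions_with_label(label):
        mask[r.start - 1 : r.end] = True
    return mask


def region_jaccard(a: Region, b: Region) -> float:
    inter = max(0, min(a.end, b.end) - max(a.start, b.start) + 1)
    union = len(a) + len(b) - inter
    return inter / union
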