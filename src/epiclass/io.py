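"""Sequence, annotation and score-track containers plus their file formats.

Coordinate convention, used everywhere in the package: intervals are 1-based
and inclusive at both ends, so a region ``(19, 39)`` covers ``39 - 19 + 1 = 21``
residues.  Any conversion to Python's 0-based half-open slices happens inside
this module only.

Score tracks hold one value per residue on the 0-1 scale; multiply by 100 for
display (epitope-score plots are conventionally drawn on a 0-100 axis).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: closed label vocabulary for annotated regions
REGION_LABELS = frozenset({"epitope", "nonepitope", "reactive", "predicted"})


class AnnotationError(ValueError):
    """Raised for malformed sequences, regions or tracks."""


@dataclasses.dataclass(frozen=True)
class Region:
    """A labeled interval on an antigen, 1-based inclusive."""

    start: int
    end: int
    label: str
    score: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"invalid interval ({self.start}, {self.end}): need 1 <= start <= end"
            )
        if self.label not in REGION_LABELS:
            raise AnnotationError(
                f"unknown region label {self.label!r}; expected one of {sorted(REGION_LABELS)}"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise AnnotationError(f"region score {self.score} outside [0, 1]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> range:
        """1-based residue positions covered by the region."""
        return range(self.start, self.end + 1)


@dataclasses.dataclass
class Antigen:
    """A protein sequence with labeled regions attached."""

    id: str
    sequence: str
    regions: list[Region] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = "".join(self.sequence.split()).upper()
        if not self.sequence:
            raise AnnotationError(f"antigen {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _CANONICAL_SET
        if bad:
            raise AnnotationError(
                f"antigen {self.id!r} contains non-canonical residues {sorted(bad)}; "
                "only the 20 canonical one-letter codes are supported"
            )
        for r in self.regions:
            self._check_region(r)

    def _check_region(self, region: Region) -> None:
        if region.end > len(self.sequence):
            raise AnnotationError(
                f"region ({region.start}, {region.end}) exceeds antigen {self.id!r} "
                f"length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def add_region(self, region: Region) -> None:
        self._check_region(region)
        self.regions.append(region)

    def regions_with_label(self, label: str) -> list[Region]:
        return [r for r in self.regions if r.label == label]

    def subsequence(self, start: int, end: int) -> str:
        """Residues start..end, 1-based inclusive."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise AnnotationError(f"({start}, {end}) out of range for length {len(self)}")
        return self.sequence[start - 1 : end]


@dataclasses.dataclass
class ScoreTrack:
    """Per-residue scores in [0, 1] for one antigen."""

    antigen_id: str
    scores: list[float]

    def __post_init__(self) -> None:
        self.scores = [float(s) for s in self.scores]
        for s in self.scores:
            if not (0.0 <= s <= 1.0):
                raise AnnotationError(f"track score {s} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreTrack):
            return NotImplemented
        return self.antigen_id == other.antigen_id and self.scores == other.scores


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[Antigen]:
    """Read a FASTA file into antigens (regions empty, sequences uppercased)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AnnotationError(f"no FASTA records in {path}")
    return [Antigen(id=rec.id, sequence=str(rec.seq)) for rec in records]


def write_fasta(path: str | Path, antigens: Iterable[Antigen]) -> None:
    with open(path, "w") as fh:
        for ag in antigens:
            fh.write(f">{ag.id}\n")
            seq = ag.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Regions TSV: antigen_id <TAB> start <TAB> end <TAB> label [<TAB> score]


def read_regions(path: str | Path, antigens: Sequence[Antigen]) -> list[Antigen]:
    """Attach regions from a TSV file to the given antigens.

    Rows referencing unknown antigens, inverted or out-of-range intervals, or
    labels outside the vocabulary raise :class:`AnnotationError`.
    """
    by_id = {ag.id: ag for ag in antigens}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "antigen_id":  # header
                continue
            if len(fields) < 4:
                raise AnnotationError(f"{path}:{lineno}: expected >= 4 tab-separated fields")
            ag_id, start, end, label = fields[:4]
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "" else None
            if ag_id not in by_id:
                raise AnnotationError(f"{path}:{lineno}: unknown antigen {ag_id!r}")
            try:
                region = Region(int(start), int(end), label, score)
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            by_id[ag_id].add_region(region)
    return list(antigens)


def write_regions(path: str | Path, antigens: Iterable[Antigen]) -> None:
    with open(path, "w") as fh:
        fh.write("antigen_id\tstart\tend\tlabel\tscore\n")
        for ag in antigens:
            for r in ag.regions:
                score = "" if r.score is None else repr(r.score)
                fh.write(f"{ag.id}\t{r.start}\t{r.end}\t{r.label}\t{score}\n")


# ---------------------------------------------------------------------------
# Score tracks: antigen_id <TAB> position <TAB> score, one row per residue.
# Floats are written with repr() so the round trip is bit-exact.


def write_track(path: str | Path, track: ScoreTrack) -> None:
    with open(path, "w") as fh:
        fh.write("antigen_id\tposition\tscore\n")
        for pos, score in enumerate(track.scores, 1):
            fh.write(f"{track.antigen_id}\t{pos}\t{score!r}\n")


def read_track(path: str | Path, expected_length: int | None = None) -> ScoreTrack:
    antigen_id = None
    scores: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("antigen_id"):
                continue
            ag_id, pos, score = line.split("\t")
            if antigen_id is None:
                antigen_id = ag_id
            elif ag_id != antigen_id:
                raise AnnotationError(f"{path}:{lineno}: mixed antigen ids in one track file")
            if int(pos) != len(scores) + 1:
                raise AnnotationError(f"{path}:{lineno}: positions must be 1..L in order")
            scores.append(float(score))
    if antigen_id is None:
        raise AnnotationError(f"no track rows in {path}")
    if expected_length is not None and len(scores) != expected_length:
        raise AnnotationError(
            f"track length {len(scores)} does not match declared antigen length {expected_length}"
        )
    return ScoreTrack(antigen_id=antigen_id, scores=scores)


def validate_inputs(antigens: Sequence[Antigen]) -> dict[str, int]:
    """Cheap consistency summary used by the CLI ``validate`` command."""
    n_regions = sum(len(ag.regions) for ag in antigens)
    n_epitope = sum(len(ag.regions_with_label("epitope")) for ag in antigens)
    return {
        "n_antigens": len(antigens),
        "total_residues": sum(len(ag) for ag in antigens),
        "n_regions": n_regions,
        "n_epitope_regions": n_epitope,
    }
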