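"""Aligned-sequence containers, region maps and alignment-column classification.

The central object is :class:`MultipleAlignment`, a light wrapper around a set
of equal-length gapped nucleotide sequences over the alphabet ``{A,C,G,T,N,-,?}``.
Coordinates in every user-facing API are 1-based inclusive, the convention of
alignment editors and of published region tables ("alignment sites 1-81");
internal storage is a 0-based numpy character matrix.

Column (site) classification follows the standard parsimony bookkeeping:

* *invariant* — at most one distinct base among the non-missing cells;
* *singleton* — exactly one sequence carries a base different from an
  otherwise uniform residue (phylogenetically uninformative polymorphism,
  in amplicon clone libraries usually PCR/sequencing noise);
* *parsimony-informative* — at least two distinct bases each present in at
  least two sequences;
* *other-variable* — variable but neither singleton nor informative
  (e.g. two different rare bases each in a single sequence).

Gaps, ``N`` and ``?`` are treated as missing data by default (``gap_policy=
"missing"``); ``gap_policy="fifth-state"`` counts ``-`` as an ordinary state
for sensitivity analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN-?")
MISSING = ("-", "N", "?")

__all__ = [
    "ALPHABET",
    "AlignmentError",
    "InputError",
    "MultipleAlignment",
    "Region",
    "RegionMap",
    "SiteClassification",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "classify_sites",
    "extract_region",
    "mask_region",
    "coding_concat",
]


class AlignmentError(ValueError):
    """Rows do not form a rectangular alignment."""


class InputError(ValueError):
    """Malformed input (duplicate ids, illegal characters, bad intervals)."""


@dataclass
class MultipleAlignment:
    """Rectangular gapped alignment with unique row identifiers."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment must contain at least one row")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal row lengths: {sorted(lengths)}")
        if self.length < 1:
            raise AlignmentError("alignment length must be >= 1")
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {dupes}")
        self.rows = [r.upper() for r in self.rows]
        for sid, row in zip(self.ids, self.rows):
            bad = set(row) - ALPHABET
            if bad:
                col = next(i for i, c in enumerate(row, 1) if c in bad)
                raise InputError(
                    f"illegal character {sorted(bad)!r} in sequence {sid!r} "
                    f"(first at column {col})"
                )
        self._array: np.ndarray | None = None

    # -- basic properties -------------------------------------------------
    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def array(self) -> np.ndarray:
        """(n_sequences, length) matrix of single characters."""
        if self._array is None:
            self._array = np.array([list(r) for r in self.rows], dtype="<U1")
        return self._array

    def row(self, sid: str) -> str:
        try:
            return self.rows[self.ids.index(sid)]
        except ValueError:
            raise InputError(f"unknown sequence id {sid!r}") from None

    def subset(self, ids: Sequence[str]) -> "MultipleAlignment":
        return MultipleAlignment([i for i in ids], [self.row(i) for i in ids])

    def take_columns(self, cols0: np.ndarray | list[int]) -> "MultipleAlignment":
        """New alignment from 0-based column indices, order preserved."""
        arr = self.array[:, list(cols0)]
        return MultipleAlignment(list(self.ids), ["".join(r) for r in arr])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MultipleAlignment)
            and self.ids == other.ids
            and self.rows == other.rows
        )


@dataclass(frozen=True)
class Region:
    name: str
    start: int  # 1-based inclusive
    end: int
    role: str  # exon | intron | excluded

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise InputError(f"bad interval {self.name}: {self.start}-{self.end}")
        if self.role not in ("exon", "intron", "excluded"):
            raise InputError(f"unknown region role {self.role!r}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionMap:
    """Named 1-based intervals partitioning an alignment into exons/introns.

    ``frame_offset`` gives the number of leading columns of the concatenated
    exon blocks that precede the first complete codon.
    """

    regions: list[Region]
    frame_offset: int = 0

    def validate(self, aln_length: int | None = None) -> None:
        if aln_length is not None:
            for r in self.regions:
                if r.end > aln_length:
                    raise InputError(
                        f"region {r.name} ({r.start}-{r.end}) exceeds alignment "
                        f"length {aln_length}"
                    )
        exons = self.exons()
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise InputError(f"exon intervals overlap: {a.name}, {b.name}")
        total = sum(r.span for r in exons)
        if exons and (total - self.frame_offset) % 3 != 0:
            raise InputError(
                f"exon columns after frame offset not divisible by 3 "
                f"({total} - {self.frame_offset})"
            )

    def exons(self) -> list[Region]:
        return sorted((r for r in self.regions if r.role == "exon"),
                      key=lambda r: r.start)

    def introns(self) -> list[Region]:
        return sorted((r for r in self.regions if r.role == "intron"),
                      key=lambda r: r.start)

    def excluded(self) -> list[Region]:
        return [r for r in self.regions if r.role == "excluded"]

    def region_of(self, col: int) -> Region | None:
        """Region containing 1-based column ``col`` (first match)."""
        for r in self.regions:
            if r.start <= col <= r.end:
                return r
        return None

    # -- TSV round trip ---------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionMap":
        regions: list[Region] = []
        offset = 0
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for need in ("name", "start", "end", "role"):
                if need not in idx:
                    raise InputError(f"region map missing column {need!r}")
            for line in fh:
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                regions.append(Region(f[idx["name"]], int(f[idx["start"]]),
                                      int(f[idx["end"]]), f[idx["role"]]))
                if "frame_offset" in idx and f[idx["frame_offset"]]:
                    offset = int(f[idx["frame_offset"]])
        return cls(regions, offset)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tstart\tend\trole\tframe_offset\n")
            for r in self.regions:
                fh.write(f"{r.name}\t{r.start}\t{r.end}\t{r.role}\t{self.frame_offset}\n")


@dataclass
class SiteClassification:
    labels: list[str]  # per column: invariant|singleton|informative|other-variable
    n_invariant: int
    n_singleton: int
    n_informative: int
    n_other: int

    @property
    def total(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta_alignment(path: str | Path | io.TextIOBase) -> MultipleAlignment:
    """Read an aligned FASTA file; row order preserved, characters upper-cased."""
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return MultipleAlignment([r.id for r in records], [str(r.seq) for r in records])


def write_fasta_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(row), id=sid, description="")
               for sid, row in zip(aln.ids, aln.rows)]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

def classify_sites(aln: MultipleAlignment, gap_policy: str = "missing") -> SiteClassification:
    """Classify every alignment column as invariant / singleton /
    parsimony-informative / other-variable.

    A column whose cells are all missing counts as invariant (documented
    convention; it carries no signal and must never raise).
    """
    if gap_policy not in ("missing", "fifth-state"):
        raise InputError(f"unknown gap policy {gap_policy!r}")
    missing = set(MISSING) if gap_policy == "missing" else {"N", "?"}
    arr = aln.array
    labels: list[str] = []
    for j in range(aln.length):
        col = arr[:, j]
        obs = col[~np.isin(col, list(missing))]
        if obs.size == 0:
            labels.append("invariant")
            continue
        _, counts = np.unique(obs, return_counts=True)
        if len(counts) <= 1:
            labels.append("invariant")
        elif (counts >= 2).sum() >= 2:
            labels.append("informative")
        elif obs.size - counts.max() == 1:
            labels.append("singleton")
        else:
            labels.append("other-variable")
    return SiteClassification(
        labels,
        labels.count("invariant"),
        labels.count("singleton"),
        labels.count("informative"),
        labels.count("other-variable"),
    )


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------

def _check_interval(aln: MultipleAlignment, start: int, end: int) -> None:
    if start < 1 or end > aln.length or end < start:
        raise InputError(
            f"interval {start}-{end} out of bounds for alignment of length {aln.length}"
        )


def extract_region(aln: MultipleAlignment, start: int, end: int) -> MultipleAlignment:
    """Column slice [start, end], 1-based inclusive."""
    _check_interval(aln, start, end)
    return aln.take_columns(list(range(start - 1, end)))


def mask_region(aln: MultipleAlignment, start: int, end: int) -> MultipleAlignment:
    """Complement of :func:`extract_region`: remove columns [start, end]."""
    _check_interval(aln, start, end)
    keep = [j for j in range(aln.length) if not (start - 1 <= j <= end - 1)]
    if not keep:
        raise InputError("masking the whole alignment leaves no columns")
    return aln.take_columns(keep)


def coding_concat(aln: MultipleAlignment, rm: RegionMap,
                  apply_frame_offset: bool = True) -> MultipleAlignment:
    """Concatenate exon columns in genomic order.

    With ``apply_frame_offset`` the leading out-of-frame columns are dropped
    so the result starts at a codon boundary.
    """
    exons = rm.exons()
    if not exons:
        raise InputError("region map declares no exon intervals")
    rm.validate(aln.length)
    cols: list[int] = []
    for r in exons:
        cols.extend(range(r.start - 1, r.end))
    out = aln.take_columns(cols)
    if apply_frame_offset and rm.frame_offset:
        out = out.take_columns(list(range(rm.frame_offset, out.length)))
    return out


def coding_columns(rm: RegionMap) -> list[int]:
    """0-based alignment column of every exon position in genomic order,
    after dropping the frame offset."""
    cols: list[int] = []
    for r in rm.exons():
        cols.extend(range(r.start - 1, r.end))
    return cols[rm.frame_offset:]
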