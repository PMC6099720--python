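"""Genomic intervals, BED I/O, and nearest-point queries.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Peaks and motif sites are both represented as :class:`GenomicInterval`; the
anchor points of the motif displacement statistic (peak midpoints, motif
centers) are held in a :class:`PointSet`, a per-chromosome sorted array of
integer positions supporting fast nearest-neighbour queries via binary search.
Distances are never compared across chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BedParseError",
    "GenomicInterval",
    "PointSet",
    "build_point_set",
    "midpoint",
    "read_bed",
    "write_bed",
]

_SKIP_PREFIXES = ("track", "browser", "#")


class BedParseError(ValueError):
    """Raised when a BED line cannot be interpreted; message names file and line."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open chromosomal span ``chrom:[start, end)``.

    Parameters
    ----------
    chrom
        Chromosome name; non-empty, no whitespace.
    start, end
        0-based half-open coordinates with ``0 <= start < end``.
    name
        Optional record label (BED column 4).
    score
        Optional real-valued score (BED column 5).
    strand
        One of ``+``, ``-``, ``.``; anything else is coerced to ``.``.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            object.__setattr__(self, "strand", ".")

    @property
    def width(self) -> int:
        return self.end - self.start


def midpoint(interval: GenomicInterval) -> int:
    """Integer midpoint of an interval, ``floor((start + end) / 2)``.

    Even-width intervals take the floor midpoint; the result always lies in
    ``[start, end - 1]``. Strand is ignored (accessibility peaks are
    unstranded).
    """
    return (interval.start + interval.end) // 2


def read_bed(path: str | Path, min_fields: int = 3) -> list[GenomicInterval]:
    """Read a BED-family file (BED3+, broadPeak, narrowPeak) into intervals.

    Lines starting with ``track``, ``browser`` or ``#`` and blank lines are
    skipped.  Only the first six columns are interpreted; extra columns (e.g.
    MACS2 signal/p-value columns) are ignored.  A ``.`` in the name or score
    column is read as missing; an unknown strand character becomes ``.``.

    Raises
    ------
    BedParseError
        On a short line, a non-integer coordinate, or ``start >= end``,
        naming the file and 1-based line number.
    """
    min_fields = max(int(min_fields), 3)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < min_fields:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= {min_fields} fields, "
                    f"got {len(fields)}"
                )
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from None
            if not 0 <= start < end:
                raise BedParseError(
                    f"{path}:{lineno}: require 0 <= start < end, "
                    f"got start={start}, end={end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedParseError(
                        f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name, score, strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return intervals


def _format_bed_line(iv: GenomicInterval) -> str:
    if iv.name is None and iv.score is None and iv.strand == ".":
        return f"{iv.chrom}\t{iv.start}\t{iv.end}"
    name = iv.name if iv.name is not None else "."
    score = "." if iv.score is None else f"{iv.score:g}"
    return f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}"


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3 (bare spans) or BED6 (any annotation present)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(_format_bed_line(iv) + "\n")


class PointSet:
    """Per-chromosome sorted integer genomic positions.

    Duplicates are permitted (two peaks can share a midpoint).  Queries never
    cross chromosomes: a query on a chromosome with no points has no nearest
    distance (``None`` / ``inf``).
    """

    def __init__(self, points: Mapping[str, Sequence[int] | np.ndarray]):
        self._points: dict[str, np.ndarray] = {}
        for chrom, pts in points.items():
            arr = np.sort(np.asarray(pts, dtype=np.int64))
            if arr.size:
                self._points[chrom] = arr

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], mode: str = "midpoint"
    ) -> "PointSet":
        if mode not in ("midpoint", "center"):
            raise ValueError(f"unknown mode {mode!r}")
        by_chrom: dict[str, list[int]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(midpoint(iv))
        return cls(by_chrom)

    def chroms(self) -> list[str]:
        return sorted(self._points)

    def points(self, chrom: str) -> np.ndarray:
        return self._points.get(chrom, np.empty(0, dtype=np.int64))

    def __len__(self) -> int:
        return sum(arr.size for arr in self._points.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._points

    def _neighbour_offsets(
        self, chrom: str, positions: np.ndarray
    ) -> np.ndarray:
        """Signed offset (position - nearest point) per query; inf if no points.

        Ties between two equidistant points are broken toward the upstream
        (smaller-coordinate) point, yielding a positive offset.
        """
        positions = np.asarray(positions, dtype=np.int64)
        arr = self._points.get(chrom)
        out = np.full(positions.shape, np.inf)
        if arr is None or positions.size == 0:
            return out
        idx = np.searchsorted(arr, positions)
        has_left = idx > 0
        has_right = idx < arr.size
        left = arr[np.clip(idx - 1, 0, arr.size - 1)]
        right = arr[np.clip(idx, 0, arr.size - 1)]
        d_left = np.where(has_left, positions - left, np.iinfo(np.int64).max)
        d_right = np.where(has_right, right - positions, np.iinfo(np.int64).max)
        take_left = d_left <= d_right  # tie -> upstream point
        out = np.where(take_left, d_left, -d_right).astype(float)
        return out

    def nearest_distance(self, chrom: str, pos: int) -> int | None:
        """Minimum |pos - p| over points p on ``chrom``; None if none exist."""
        off = self._neighbour_offsets(chrom, np.asarray([pos]))
        if not np.isfinite(off[0]):
            return None
        return int(abs(off[0]))

    def nearest_distances(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized unsigned nearest distances; ``inf`` where no points exist."""
        return np.abs(self._neighbour_offsets(chrom, positions))

    def nearest_signed_offsets(
        self, chrom: str, positions: np.ndarray
    ) -> np.ndarray:
        """Vectorized signed offsets (position - nearest point), upstream ties."""
        return self._neighbour_offsets(chrom, positions)


def build_point_set(
    intervals: Iterable[GenomicInterval], mode: str = "midpoint"
) -> PointSet:
    """Collapse intervals to a :class:`PointSet` of their integer midpoints.

    ``mode="midpoint"`` (peaks) and ``mode="center"`` (motif sites) are the
    same floor-midpoint reduction; the two names document intent at call
    sites.
    """
    return PointSet.from_intervals(intervals, mode=mode)
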