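"""Genomic interval arithmetic and BED/bedGraph I/O.

All coordinates are 0-based half-open (BED/bedGraph native) throughout the
package; intervals sharing only a boundary point do not overlap. Signal
tracks are piecewise-constant histone modification density (HMD) in percent
of nucleosomes bearing a mark; calibrated HMD may exceed 100%, so values are
never clamped, only required to be non-negative. Gaps in a track read as 0.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree

UNSTRANDED = "."


@dataclass
class GenomeInterval:
    """A BED-like record: chrom, 0-based half-open [start, end), optional
    strand ('+', '-', or '.'), name and score."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", UNSTRANDED):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint (floor); the anchor used for interval-shaped loci."""
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


def _opener(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path, expect_strand: bool = False) -> list[GenomeInterval]:
    """Read BED3/BED6 records in file order (gzip transparent).

    With ``expect_strand`` a missing or '.' strand column is an error.
    Malformed lines raise with their 1-based line number.
    """
    out: list[GenomeInterval] = []
    with _opener(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else UNSTRANDED
            if expect_strand and strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand column required")
            try:
                out.append(GenomeInterval(chrom, start, end, strand, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomeInterval], path) -> None:
    """Write BED6 (tab-separated, newline-terminated)."""
    with _opener(path, "wt") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


class HmdTrack:
    """Piecewise-constant HMD signal: per chromosome, sorted non-overlapping
    (start, end, value) segments with value >= 0. Gaps read as 0.
    """

    def __init__(self, segments: Iterable[tuple[str, int, int, float]] = ()):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in segments:
            if end <= start:
                raise ValueError(f"segment end <= start: {chrom}:{start}-{end}")
            if value < 0:
                raise ValueError(f"negative HMD value {value} at {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end, float(value)))
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, segs in per_chrom.items():
            segs.sort()
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            vals = np.array([v for _, _, v in segs], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                bad = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"overlapping segments on {chrom} near position {int(starts[bad + 1])}"
                )
            self._chrom[chrom] = (starts, ends, vals)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chrom)

    def chrom_end(self, chrom: str) -> int:
        """Rightmost covered coordinate (0 for an absent chromosome)."""
        if chrom not in self._chrom:
            return 0
        return int(self._chrom[chrom][1][-1])

    def segments(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, vals = self._chrom[chrom]
            for s, e, v in zip(starts, ends, vals):
                yield chrom, int(s), int(e), float(v)

    def __eq__(self, other) -> bool:
        if not isinstance(other, HmdTrack):
            return NotImplemented
        return list(self.segments()) == list(other.segments())

    def _integral(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the signal over [0, x) for each x (vectorized)."""
        if chrom not in self._chrom:
            return np.zeros_like(x, dtype=np.float64)
        starts, ends, vals = self._chrom[chrom]
        cum = np.concatenate([[0.0], np.cumsum(vals * (ends - starts))])
        idx = np.searchsorted(starts, x, side="right") - 1
        out = np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)
        inside = idx >= 0
        if np.any(inside):
            i = np.maximum(idx, 0)
            partial = np.clip(x - starts[i], 0, ends[i] - starts[i]) * vals[i]
            out = out + np.where(inside, partial, 0.0)
        return out

    def mean_values(self, chrom: str, starts, ends) -> np.ndarray:
        """Coverage-weighted mean over each half-open window; gaps count as 0.

        Window portions at negative coordinates also contribute 0 (the
        caller is responsible for flagging out-of-chromosome windows).
        """
        a = np.clip(np.asarray(starts, dtype=np.int64), 0, None)
        b = np.clip(np.asarray(ends, dtype=np.int64), 0, None)
        widths = np.asarray(ends, dtype=np.float64) - np.asarray(starts, dtype=np.float64)
        if np.any(widths <= 0):
            raise ValueError("windows must have positive width")
        return (self._integral(chrom, b) - self._integral(chrom, a)) / widths

    def to_bins(self, bin_bp: int, chrom_ends: dict[str, int] | None = None) -> "HmdTrack":
        """Resample onto a uniform grid anchored at coordinate 0.

        Each bin's value is the coverage-weighted mean of overlapping
        segments (gaps contribute 0). The grid runs to the last covered
        coordinate rounded up to a full bin, or to ``chrom_ends`` if given.
        """
        if bin_bp <= 0:
            raise ValueError("bin_bp must be positive")
        segs: list[tuple[str, int, int, float]] = []
        chroms = set(self._chrom) | set(chrom_ends or {})
        for chrom in sorted(chroms):
            end = self.chrom_end(chrom)
            if chrom_ends and chrom in chrom_ends:
                end = max(end, chrom_ends[chrom])
            n_bins = -(-end // bin_bp)
            if n_bins == 0:
                continue
            bs = np.arange(n_bins, dtype=np.int64) * bin_bp
            vals = self.mean_values(chrom, bs, bs + bin_bp)
            for s, v in zip(bs, vals):
                segs.append((chrom, int(s), int(s) + bin_bp, float(v)))
        return HmdTrack(segs)


def read_bedgraph(path) -> HmdTrack:
    """Read a 4-column bedGraph (gzip transparent) into an :class:`HmdTrack`.

    Input order is free; output is sorted per chromosome. Overlapping
    segments or negative values are errors.
    """
    segs: list[tuple[str, int, int, float]] = []
    with _opener(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record") from exc
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative HMD value {value}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            segs.append((fields[0], start, end, value))
    return HmdTrack(segs)


def write_bedgraph(track: HmdTrack, path) -> None:
    with _opener(path, "wt") as fh:
        for chrom, start, end, value in track.segments():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def extend(intervals: Sequence[GenomeInterval], pad_bp: int) -> list[GenomeInterval]:
    """Pad both ends by ``pad_bp``, flooring starts at 0; everything else kept."""
    if pad_bp < 0:
        raise ValueError("pad_bp must be >= 0")
    return [
        replace(iv, start=max(0, iv.start - pad_bp), end=iv.end + pad_bp)
        for iv in intervals
    ]


def _subject_trees(subject: Iterable[GenomeInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in subject:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def overlaps_any(
    query: GenomeInterval,
    trees: dict[str, IntervalTree],
    min_overlap_bp: int = 1,
) -> bool:
    """True if any subject interval overlaps query by >= min_overlap_bp."""
    tree = trees.get(query.chrom)
    if tree is None:
        return False
    for hit in tree.overlap(query.start, query.end):
        if min(query.end, hit.end) - max(query.start, hit.begin) >= min_overlap_bp:
            return True
    return False


def filter_by_overlap(
    query: Sequence[GenomeInterval],
    subject: Sequence[GenomeInterval],
    mode: str = "keep",
    min_overlap_bp: int = 1,
) -> list[GenomeInterval]:
    """BEDTools-style overlap filter, query order preserved.

    mode="keep" returns query records overlapping >= min_overlap_bp of at
    least one subject record; mode="remove" the exact complement. Each
    query record is counted once no matter how many subject hits it has.
    """
    if mode not in ("keep", "remove"):
        raise ValueError(f"mode must be 'keep' or 'remove', got {mode!r}")
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees = _subject_trees(subject)
    want_hit = mode == "keep"
    return [q for q in query if overlaps_any(q, trees, min_overlap_bp) == want_hit]


def merge(intervals: Sequence[GenomeInterval], gap_bp: int = 0) -> list[GenomeInterval]:
    """Union of intervals, merging any pair within gap_bp (abutting intervals
    merge at gap 0); output sorted and disjoint, strand/name dropped."""
    if gap_bp < 0:
        raise ValueError("gap_bp must be >= 0")
    out: list[GenomeInterval] = []
    for iv in sorted(intervals, key=GenomeInterval.sort_key):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + gap_bp:
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(GenomeInterval(iv.chrom, iv.start, iv.end))
    return out
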