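"""Broad H3K4me3 domain (BH4D) calling.

A BH4D is a contiguous region of at least ``min_len_bp`` (default 2000 bp)
in which the apparent H3K4me3 HMD is >= ``min_hmd`` percent (default 25) in
every consecutive ``bin_bp`` window (default 50 bp), and which intersects an
annotated transcription start site. Both boundaries are inclusive: a run of
exactly 2000 bp at exactly 25.0% qualifies.

Counting is TSS-level: a domain spanning k TSSs contributes k, and several
domains hitting one TSS contribute 1; domain-level calls are also returned
for transparency. Threshold comparisons use raw HMD with no clamping at
100% — calibrated HMD can exceed 100% through noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomeInterval, HmdTrack


@dataclass
class Bh4dParams:
    min_hmd: float = 25.0      # percent HMD threshold, inclusive
    bin_bp: int = 50           # window size of the scan grid
    min_len_bp: int = 2000     # minimum domain length, inclusive
    grid_offset_bp: int = 0    # bin-grid phase, for sensitivity checks

    def __post_init__(self) -> None:
        if self.min_hmd <= 0:
            raise ValueError("min_hmd must be > 0")
        if self.bin_bp <= 0:
            raise ValueError("bin_bp must be > 0")
        if self.min_len_bp < self.bin_bp:
            raise ValueError("min_len_bp must be >= bin_bp")
        if not 0 <= self.grid_offset_bp < self.bin_bp:
            raise ValueError("grid_offset_bp must lie in [0, bin_bp)")


@dataclass
class Bh4dCall:
    """One called broad domain and the TSS(s) it intersects."""

    domain: GenomeInterval
    n_bins: int
    tss_hits: list[str]
    mean_hmd: float = 0.0


def tss_id(tss: GenomeInterval) -> str:
    """Stable identifier for a TSS point: its name, else its coordinate."""
    return tss.name if tss.name is not None else f"{tss.chrom}:{tss.start}"


def resample_to_bins(track: HmdTrack, bin_bp: int) -> HmdTrack:
    """Resample onto consecutive bins anchored at coordinate 0; each bin is
    the coverage-weighted mean of overlapping segments, gaps contributing 0."""
    return track.to_bins(bin_bp)


def _binned_values(track: HmdTrack, chrom: str, params: Bh4dParams):
    end = track.chrom_end(chrom)
    n = max(0, -(-(end - params.grid_offset_bp) // params.bin_bp))
    if n == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    starts = params.grid_offset_bp + np.arange(n, dtype=np.int64) * params.bin_bp
    return starts, track.mean_values(chrom, starts, starts + params.bin_bp)


def call_broad_domains(
    track: HmdTrack,
    params: Bh4dParams,
    tss: list[GenomeInterval],
) -> list[Bh4dCall]:
    """Call BH4Ds: maximal runs of consecutive bins with HMD >= min_hmd,
    discarding runs shorter than min_len_bp and runs containing no TSS point.

    TSS records are treated as points (their start coordinate); a run
    [run_start, run_end) hits a TSS iff run_start <= tss.start < run_end.
    Calls are returned sorted by position.
    """
    tss_by_chrom: dict[str, list[GenomeInterval]] = {}
    for t in tss:
        tss_by_chrom.setdefault(t.chrom, []).append(t)

    min_bins = -(-params.min_len_bp // params.bin_bp)
    calls: list[Bh4dCall] = []
    for chrom in track.chroms:
        starts, vals = _binned_values(track, chrom, params)
        above = vals >= params.min_hmd
        if not above.any():
            continue
        # maximal runs of True
        edges = np.diff(above.astype(np.int8))
        run_starts = list(np.where(edges == 1)[0] + 1)
        run_ends = list(np.where(edges == -1)[0] + 1)
        if above[0]:
            run_starts.insert(0, 0)
        if above[-1]:
            run_ends.append(len(above))
        for i0, i1 in zip(run_starts, run_ends):
            n_bins = i1 - i0
            if n_bins < min_bins:
                continue
            lo = int(starts[i0])
            hi = int(starts[i1 - 1]) + params.bin_bp
            hits = [
                tss_id(t)
                for t in tss_by_chrom.get(chrom, [])
                if lo <= t.start < hi
            ]
            if not hits:
                continue
            calls.append(
                Bh4dCall(
                    domain=GenomeInterval(
                        chrom, lo, hi, name=";".join(hits),
                        score=float(np.mean(vals[i0:i1])),
                    ),
                    n_bins=n_bins,
                    tss_hits=hits,
                    mean_hmd=float(np.mean(vals[i0:i1])),
                )
            )
    calls.sort(key=lambda c: c.domain.sort_key())
    return calls


def count_tss_bh4d(calls: list[Bh4dCall]) -> int:
    """Number of distinct TSSs covered by any called domain (Fig-style
    'TSS BH4D' count)."""
    return len({t for c in calls for t in c.tss_hits})


def hit_tss_set(calls: list[Bh4dCall]) -> set[str]:
    return {t for c in calls for t in c.tss_hits}


@dataclass
class DomainSetComparison:
    """Partition of the union of hit TSSs from two call sets."""

    shared: set[str]
    only_a: set[str]
    only_b: set[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.shared), len(self.only_a), len(self.only_b)


def compare_domain_sets(
    calls_a: list[Bh4dCall], calls_b: list[Bh4dCall]
) -> DomainSetComparison:
    """Partition hit TSSs into shared / a-only / b-only — e.g. a low-quality
    antibody's apparent-track calls (a) versus a high-quality antibody's (b)."""
    a, b = hit_tss_set(calls_a), hit_tss_set(calls_b)
    return DomainSetComparison(shared=a & b, only_a=a - b, only_b=b - a)


def calls_to_bed(calls: list[Bh4dCall]) -> list[GenomeInterval]:
    """Domains as BED6 records (name = joined TSS ids, score = mean HMD)."""
    return [c.domain for c in calls]
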