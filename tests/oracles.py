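"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives a result by the most literal possible method
(all-pairs scans, per-bp bitmaps, O(n) rescans) and stays independent of
the library code paths it checks.
"""

from __future__ import annotations

import numpy as np


def brute_overlap_keep(query, subject, min_overlap_bp=1):
    """All-pairs overlap scan: query records overlapping any subject record
    by at least min_overlap_bp."""
    kept = []
    for q in query:
        for s in subject:
            if q.chrom != s.chrom:
                continue
            if min(q.end, s.end) - max(q.start, s.start) >= min_overlap_bp:
                kept.append(q)
                break
    return kept


def bitmap_union(intervals, gap_bp=0, chrom_len=10_000):
    """Per-bp bitmap union on a toy chromosome set; returns sorted disjoint
    (chrom, start, end) tuples after bridging gaps <= gap_bp."""
    chroms = sorted({iv.chrom for iv in intervals})
    out = []
    for chrom in chroms:
        mask = np.zeros(chrom_len + gap_bp + 1, dtype=bool)
        for iv in intervals:
            if iv.chrom == chrom:
                mask[iv.start:iv.end] = True
        # bridge gaps of length <= gap_bp between covered runs
        if gap_bp > 0:
            covered = np.where(mask)[0]
            for a, b in zip(covered[:-1], covered[1:]):
                if 1 < b - a <= gap_bp + 1:
                    mask[a:b] = True
        idx = np.where(mask)[0]
        if idx.size == 0:
            continue
        breaks = np.where(np.diff(idx) > 1)[0]
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def rescan_domains(values, bin_bp, min_hmd, min_len_bp, tss_positions):
    """O(n) rescan of a single-chromosome binned track: every maximal run of
    bins with value >= min_hmd is tested for length and TSS content.
    Returns [(start_bp, end_bp, sorted tss positions hit)]."""
    domains = []
    i, n = 0, len(values)
    min_bins = -(-min_len_bp // bin_bp)
    while i < n:
        if values[i] >= min_hmd:
            j = i
            while j < n and values[j] >= min_hmd:
                j += 1
            if j - i >= min_bins:
                lo, hi = i * bin_bp, j * bin_bp
                hits = sorted(t for t in tss_positions if lo <= t < hi)
                if hits:
                    domains.append((lo, hi, hits))
            i = j
        else:
            i += 1
    return domains


def brute_pair_bidirectional(plus_peaks, minus_peaks, max_gap):
    """All-pairs pairing of opposite-strand peaks: a pair qualifies when the
    peaks overlap or their gap is <= max_gap; returns the merged union of
    pair spans as sorted (chrom, start, end) tuples."""
    spans = []
    for p in plus_peaks:
        for m in minus_peaks:
            if p.chrom != m.chrom:
                continue
            gap = max(0, max(p.start, m.start) - min(p.end, m.end))
            if gap <= max_gap:
                spans.append((p.chrom, min(p.start, m.start), max(p.end, m.end)))
    spans.sort()
    merged = []
    for chrom, s, e in spans:
        if merged and merged[-1][0] == chrom and s < merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append([chrom, s, e])
    return [tuple(m) for m in merged]
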