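"""Metagene profiles and per-locus heatmap matrices of HMD.

A metagene profile is the per-bin mean of a signal track across a set of
anchored loci: TSS points, or intervals anchored at their integer midpoint.
Minus-strand anchors can be axis-flipped so upstream/downstream are
biologically oriented. The heatmap matrix is the un-averaged per-locus
version; its column means equal the metagene profile exactly. Bins falling
before the start of a chromosome contribute 0 and are counted in
``n_out_of_bounds``. No smoothing or per-locus normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomeInterval, HmdTrack


@dataclass
class MetageneProfile:
    offsets_bp: np.ndarray     # bin start offsets relative to the anchor
    mean_hmd: np.ndarray       # per-bin mean across loci, percent
    n_loci: int
    n_out_of_bounds: int = 0   # locus-bins that fell before coordinate 0

    def to_rows(self) -> list[dict]:
        return [
            {"offset_bp": int(o), "mean_hmd": float(m), "n_loci": self.n_loci}
            for o, m in zip(self.offsets_bp, self.mean_hmd)
        ]


def _anchor(locus: GenomeInterval) -> int:
    return locus.start if locus.length == 1 else locus.midpoint


def heatmap_matrix(
    track: HmdTrack,
    anchors: list[GenomeInterval],
    flank_bp: int = 2000,
    bin_bp: int = 50,
    strand_aware: bool = False,
    sort: str = "none",
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Per-locus HMD matrix over [anchor - flank, anchor + flank) in bin_bp
    bins; one row per locus.

    Returns (matrix, row_labels, offsets_bp). ``sort="mean_desc"`` orders
    rows by descending row mean; ``strand_aware`` reverses the bins of
    minus-strand loci. Windows truncated by the chromosome start contribute
    0 in the missing bins.
    """
    if not anchors:
        raise ValueError("anchor set is empty")
    if flank_bp <= 0 or bin_bp <= 0 or flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be a positive multiple of bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    offsets = -flank_bp + np.arange(n_bins, dtype=np.int64) * bin_bp
    mat = np.zeros((len(anchors), n_bins))
    labels: list[str] = []
    for i, locus in enumerate(anchors):
        center = _anchor(locus)
        starts = center + offsets
        ends = starts + bin_bp
        # mean_values clips negative coordinates to 0-signal contribution
        row = track.mean_values(locus.chrom, starts, ends)
        if strand_aware and locus.strand == "-":
            row = row[::-1]
        mat[i] = row
        labels.append(locus.name if locus.name is not None else f"{locus.chrom}:{center}")
    if sort == "mean_desc":
        order = np.argsort(-mat.mean(axis=1), kind="stable")
        mat = mat[order]
        labels = [labels[j] for j in order]
    elif sort != "none":
        raise ValueError(f"sort must be 'mean_desc' or 'none', got {sort!r}")
    return mat, labels, offsets


def metagene(
    track: HmdTrack,
    anchors: list[GenomeInterval],
    flank_bp: int = 2000,
    bin_bp: int = 50,
    strand_aware: bool = False,
) -> MetageneProfile:
    """Metagene profile: column means of the per-locus heatmap matrix."""
    mat, _, offsets = heatmap_matrix(
        track, anchors, flank_bp=flank_bp, bin_bp=bin_bp, strand_aware=strand_aware
    )
    oob = sum(
        max(0, (flank_bp - _anchor(a)) // bin_bp) if _anchor(a) < flank_bp else 0
        for a in anchors
    )
    return MetageneProfile(
        offsets_bp=offsets,
        mean_hmd=mat.mean(axis=0),
        n_loci=len(anchors),
        n_out_of_bounds=oob,
    )


def write_profile_tsv(profile: MetageneProfile, path) -> None:
    import pandas as pd

    pd.DataFrame(profile.to_rows()).to_csv(path, sep="\t", index=False)


def write_matrix_tsv(matrix: np.ndarray, labels: list[str], offsets: np.ndarray, path) -> None:
    import pandas as pd

    pd.DataFrame(matrix, index=labels, columns=[int(o) for o in offsets]).to_csv(
        path, sep="\t", index_label="locus"
    )
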