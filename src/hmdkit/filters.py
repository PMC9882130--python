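"""Enhancer candidate definitions and filtering cascades.

Two definitions are implemented. The loose definition calls any DNase
hypersensitive site that overlaps an H3K4me1 peak and no annotated promoter
an enhancer — permissive enough to admit unannotated promoters. The
stringent cascade additionally requires, in order: no Refseq promoter
overlap, then overlap with a TFBS, GRO-Cap TSS, ATAC-seq peak, H3K27ac
peak, FAIRE-seq peak, DNase HS site and P300 peak, and finally contact with
at least one promoter by pol II ChIA-PET. A further refinement removes
candidates on unannotated lncRNA promoters and requires FANTOM5 enhancer
support. Candidate identity is preserved through every step (no
re-merging), so survivor counts refer to input candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .intervals import (
    GenomeInterval,
    _opener,
    _subject_trees,
    filter_by_overlap,
    overlaps_any,
    read_bed,
)

AnchorPair = tuple[GenomeInterval, GenomeInterval]

#: canonical stringent-cascade requirement order (after promoter removal)
CASCADE_FEATURES = ("tfbs", "grocap_tss", "atac", "h3k27ac", "faire", "dnase", "p300")


@dataclass
class FeatureLibrary:
    """Named interval sets consumed by the cascades.

    ``chiapet_promoter_contacts`` holds pol II ChIA-PET interactions as
    anchor pairs. A set left as None is explicitly missing; the cascade
    raises naming it.
    """

    refseq_promoters: list[GenomeInterval] | None = None
    gencode_promoters: list[GenomeInterval] | None = None
    tfbs: list[GenomeInterval] | None = None
    grocap_tss: list[GenomeInterval] | None = None
    atac: list[GenomeInterval] | None = None
    h3k27ac: list[GenomeInterval] | None = None
    faire: list[GenomeInterval] | None = None
    dnase: list[GenomeInterval] | None = None
    p300: list[GenomeInterval] | None = None
    chiapet_promoter_contacts: list[AnchorPair] | None = None
    h3k4me1_peaks: list[GenomeInterval] | None = None
    h3k4me3_peaks: list[GenomeInterval] | None = None
    fantom5_enhancers: list[GenomeInterval] | None = None
    lncrna_promoters: list[GenomeInterval] | None = None

    def require(self, name: str):
        value = getattr(self, name)
        if value is None:
            raise ValueError(f"feature library is missing required set {name!r}")
        return value


def promoter_windows(
    tss: list[GenomeInterval], half_width_bp: int = 1000
) -> list[GenomeInterval]:
    """Promoter intervals as TSS +/- half_width_bp, for annotations that
    provide only TSS points. The window width is a documented knob: survivor
    counts are sensitive to it (and to the annotation release)."""
    return [
        GenomeInterval(
            t.chrom, max(0, t.start - half_width_bp), t.start + half_width_bp,
            t.strand, t.name,
        )
        for t in tss
    ]


@dataclass
class FilterReport:
    """Ordered per-step survivor counts and interval sets; the first step is
    the input set and counts are non-increasing."""

    steps: list[tuple[str, int, list[GenomeInterval]]] = field(default_factory=list)

    def add(self, name: str, surviving: list[GenomeInterval]) -> None:
        self.steps.append((name, len(surviving), surviving))

    @property
    def counts(self) -> list[int]:
        return [n for _, n, _ in self.steps]

    @property
    def survivors(self) -> list[GenomeInterval]:
        return self.steps[-1][2] if self.steps else []

    def to_rows(self) -> list[dict]:
        return [{"step": name, "n_surviving": n} for name, n, _ in self.steps]


def loose_enhancers(
    dnase: list[GenomeInterval],
    h3k4me1_peaks: list[GenomeInterval],
    promoters: list[GenomeInterval],
) -> list[GenomeInterval]:
    """Loose enhancer definition: DNase HS sites overlapping an H3K4me1 peak
    and no annotated promoter."""
    with_me1 = filter_by_overlap(dnase, h3k4me1_peaks, mode="keep")
    return filter_by_overlap(with_me1, promoters, mode="remove")


def h3k4me3_positive(
    candidates: list[GenomeInterval], h3k4me3_peaks: list[GenomeInterval]
) -> list[GenomeInterval]:
    """Candidates overlapping at least one H3K4me3 peak."""
    return filter_by_overlap(candidates, h3k4me3_peaks, mode="keep")


def contacts_promoter(
    candidate: GenomeInterval,
    interactions: list[AnchorPair],
    promoter_trees: dict,
) -> bool:
    """True if the candidate overlaps one anchor of an interaction whose
    partner anchor overlaps a promoter, in either orientation."""
    for a, b in interactions:
        for anchor, partner in ((a, b), (b, a)):
            if candidate.overlap_bp(anchor) > 0 and overlaps_any(
                partner, promoter_trees
            ):
                return True
    return False


def stringent_cascade(
    candidates: list[GenomeInterval],
    library: FeatureLibrary,
    min_tss_distance_bp: int | None = None,
) -> FilterReport:
    """Run the stringent enhancer filter cascade, reporting survivors after
    every step.

    Order: remove Refseq-promoter overlaps; require each of TFBS, GRO-Cap
    TSS, ATAC, H3K27ac, FAIRE, DNase, P300; require a ChIA-PET contact with
    a promoter. All predicates are conjunctive, so the final set is
    order-insensitive; the per-step counts follow this canonical order.
    ``min_tss_distance_bp`` optionally tightens "distal" to a minimum
    distance from any promoter midpoint (off by default: the promoter-
    removal step is the baseline reading of "distal").
    """
    promoters = library.require("refseq_promoters")
    interactions = library.require("chiapet_promoter_contacts")
    for name in CASCADE_FEATURES:
        library.require(name)

    report = FilterReport()
    report.add("input", list(candidates))
    surviving = filter_by_overlap(candidates, promoters, mode="remove")
    if min_tss_distance_bp is not None:
        surviving = [
            c
            for c in surviving
            if all(
                p.chrom != c.chrom
                or min(abs(c.start - p.midpoint), abs(c.end - p.midpoint))
                >= min_tss_distance_bp
                for p in promoters
            )
        ]
    report.add("not_refseq_promoter", surviving)
    for name in CASCADE_FEATURES:
        surviving = filter_by_overlap(surviving, library.require(name), mode="keep")
        report.add(f"has_{name}", surviving)
    promoter_trees = _subject_trees(promoters)
    surviving = [
        c for c in surviving if contacts_promoter(c, interactions, promoter_trees)
    ]
    report.add("chiapet_promoter_contact", surviving)
    return report


def fantom_lncrna_refine(
    candidates: list[GenomeInterval],
    fantom5_enhancers: list[GenomeInterval],
    lncrna_promoters: list[GenomeInterval],
) -> list[GenomeInterval]:
    """Refinement: drop candidates on unannotated lncRNA promoters, then
    require FANTOM5 validated-enhancer support."""
    kept = filter_by_overlap(candidates, lncrna_promoters, mode="remove")
    return filter_by_overlap(kept, fantom5_enhancers, mode="keep")


def validation_overlap(
    candidates: list[GenomeInterval],
    truth_sets: dict[str, list[GenomeInterval]],
) -> dict[str, int]:
    """For each named truth set (e.g. validated enhancers, reproducible
    STARR-seq peaks, bidirectional CAGE regions), the number of candidates
    overlapping at least one truth interval."""
    return {
        name: len(filter_by_overlap(candidates, truth, mode="keep"))
        for name, truth in truth_sets.items()
    }


def replicate_intersect(
    peaks_rep1: list[GenomeInterval], peaks_rep2: list[GenomeInterval]
) -> list[GenomeInterval]:
    """Reproducible peaks: replicate-1 peaks overlapping >=1 replicate-2 peak."""
    return filter_by_overlap(peaks_rep1, peaks_rep2, mode="keep")


def read_bedpe(path) -> list[AnchorPair]:
    """Read ChIA-PET interactions from BEDPE (first six columns used)."""
    pairs: list[AnchorPair] = []
    with _opener(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BEDPE columns")
            try:
                pairs.append(
                    (
                        GenomeInterval(f[0], int(f[1]), int(f[2])),
                        GenomeInterval(f[3], int(f[4]), int(f[5])),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return pairs


def write_bedpe(pairs: list[AnchorPair], path) -> None:
    with _opener(path, "wt") as fh:
        for a, b in pairs:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n"
            )


def load_feature_library(manifest_path) -> FeatureLibrary:
    """Load a FeatureLibrary from a YAML manifest mapping set names to BED
    paths (ChIA-PET interactions to a BEDPE path). Relative paths resolve
    against the manifest's directory. Unknown names are errors."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh) or {}
    valid = {f.name for f in dc_fields(FeatureLibrary)}
    lib = FeatureLibrary()
    for name, rel in manifest.items():
        if name not in valid:
            raise ValueError(f"unknown feature set {name!r} in {manifest_path}")
        path = manifest_path.parent / rel
        if not path.exists():
            raise FileNotFoundError(f"feature set {name!r}: missing file {path}")
        if name == "chiapet_promoter_contacts":
            setattr(lib, name, read_bedpe(path))
        else:
            setattr(lib, name, read_bed(path))
    return lib
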