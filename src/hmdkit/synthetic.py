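"""Synthetic toy genome with the statistical structure the analyses assume.

The generator plants three locus classes on one or more toy chromosomes:

* promoters — a central H3K4me3 plateau (``peak_width_bp`` at
  ``promoter_me3_apex`` percent; at highly transcribed promoters this
  approaches 100%) flanked on both sides by H3K4me2
  (``me2_flank_width_bp`` each side, level drawn per promoter from
  ``me2_flank_level``) and broad low H3K4me1, with a divergent CAGE peak
  pair at the TSS;
* enhancers — high H3K4me1, moderate H3K4me2 and only 1–5% H3K4me3
  (``enhancer_me3_level``), optionally with a divergent CAGE pair;
* unannotated promoters — promoter-shaped loci absent from the TSS
  annotation, the contaminant class that loose enhancer definitions admit.

Profiles are piecewise-constant plateaus aligned to the track bin grid, so
the apparent breadth under any cross-reactivity mixture has an exact closed
form (used by :func:`plant_specificity_scenario` as an independent oracle
for the domain caller). Feature-library sets are planted so that each
cascade candidate's fate at every filtering step is known, and the planted
ground truth is recorded in ``ExpectedCounts``.

One RNG stream (numpy default_rng seeded from the generation spec) drives a
draw order: locus shuffling and placement jitter, per-locus signal levels
and strands, cascade fail-step labels, me3-peak / FANTOM5 / validation /
CAGE subset draws, then per-bin noise (me1, me2, me3, chromosome by
chromosome). Reproducibility is by seed + this order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bh4d import Bh4dParams
from .filters import FeatureLibrary, write_bedpe
from .intervals import GenomeInterval, HmdTrack, write_bed, write_bedgraph
from .specificity import MethylformTrackSet, SpecificityProfile, apparent_track

#: cascade fail-step labels, in canonical cascade order; None = survives all
CASCADE_STEP_LABELS = (
    "tfbs", "grocap_tss", "atac", "h3k27ac", "faire", "dnase", "p300", "chiapet",
)


@dataclass
class SyntheticGenomeSpec:
    seed: int = 0
    n_chroms: int = 2
    chrom_len_bp: int = 1_000_000
    n_promoters: int = 30
    n_enhancers: int = 30
    n_unannotated_promoters: int = 5
    promoter_me3_apex: float = 90.0
    enhancer_me3_level: tuple[float, float] = (1.0, 5.0)
    me2_flank_level: tuple[float, float] = (45.0, 63.0)  # 50-70% of the 90% apex
    me2_flank_width_bp: int = 1500
    peak_width_bp: int = 1000
    noise_sd: float = 0.0
    bin_bp: int = 50
    # background levels chosen as typical of calibrated K562-like tracks
    promoter_me1_level: float = 10.0
    enhancer_me1_level: float = 60.0
    enhancer_me2_level: float = 30.0
    min_locus_gap_bp: int = 5000
    cage_peak_width_bp: int = 20
    cage_gap_bp: int = 360          # inter-peak gap of a divergent pair (<=400)
    cage_enhancer_fraction: float = 0.5
    me3_peak_enhancer_fraction: float = 0.25
    fantom5_fraction: float = 0.3
    validation_fraction: float = 0.3
    cascade_survive_fraction: float = 0.25  # enhancers passing every filter
    n_promoter_candidates: int = 3  # contaminant candidates on real promoters

    def __post_init__(self) -> None:
        for name in (
            "n_chroms", "n_promoters", "n_enhancers", "n_unannotated_promoters",
            "n_promoter_candidates",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.chrom_len_bp <= 0 or self.bin_bp <= 0:
            raise ValueError("chrom_len_bp and bin_bp must be positive")
        if self.peak_width_bp <= 0 or self.me2_flank_width_bp <= 0:
            raise ValueError("widths must be positive")
        if self.peak_width_bp % self.bin_bp or self.me2_flank_width_bp % self.bin_bp:
            raise ValueError(
                "peak_width_bp and me2_flank_width_bp must be multiples of "
                "bin_bp (keeps planted plateaus exact on the scan grid)"
            )
        for name in ("promoter_me3_apex", "noise_sd", "promoter_me1_level",
                     "enhancer_me1_level", "enhancer_me2_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("enhancer_me3_level", "me2_flank_level"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a 0 <= lo <= hi range")


@dataclass
class PromoterLocus:
    """Planted promoter geometry (exact, pre-noise) for closed-form oracles."""

    name: str
    chrom: str
    start: int          # start of the upstream me2 flank
    tss: int
    strand: str
    flank_level: float  # me2 HMD on both flanks
    annotated: bool


@dataclass
class ExpectedCounts:
    """Ground truth the generator planted, for recovery checks."""

    bh4d_tss_true: int = 0
    n_bidirectional_regions: int = 0
    n_loose_enhancers: int = 0
    n_h3k4me3_positive_candidates: int = 0
    cascade_step_names: list[str] = field(default_factory=list)
    cascade_counts: list[int] = field(default_factory=list)
    n_refined: int = 0
    validation: dict[str, int] = field(default_factory=dict)


@dataclass
class SyntheticBundle:
    spec: SyntheticGenomeSpec
    tracks: MethylformTrackSet
    tss: list[GenomeInterval]
    promoters: list[PromoterLocus]          # annotated + unannotated
    enhancers: list[GenomeInterval]
    unannotated_promoters: list[GenomeInterval]
    cage_peaks: list[GenomeInterval]
    candidates: list[GenomeInterval]
    library: FeatureLibrary
    expected: ExpectedCounts
    chiapet_pairs: list = field(default_factory=list)
    validation_truth_sets: dict[str, list[GenomeInterval]] = field(default_factory=dict)


def _arrays_to_track_segments(chrom: str, values: np.ndarray, bin_bp: int):
    """Run-length encode a per-bin value array, dropping zero runs."""
    if values.size == 0:
        return
    change = np.where(np.diff(values) != 0)[0] + 1
    run_starts = np.concatenate([[0], change])
    run_ends = np.concatenate([change, [values.size]])
    for i0, i1 in zip(run_starts, run_ends):
        v = values[i0]
        if v > 0:
            yield (chrom, int(i0) * bin_bp, int(i1) * bin_bp, float(v))


def _subset(rng: np.random.Generator, items: list, fraction: float) -> list:
    k = int(round(fraction * len(items)))
    if k == 0:
        return []
    idx = rng.choice(len(items), size=k, replace=False)
    return [items[i] for i in sorted(idx)]


def generate(spec: SyntheticGenomeSpec) -> SyntheticBundle:
    """Generate the full synthetic bundle with recorded ground truth.

    Raises if the requested loci cannot be placed without overlap on the
    requested chromosomes (suggesting a larger ``chrom_len_bp``).
    """
    rng = np.random.default_rng(spec.seed)
    bin_bp = spec.bin_bp
    n_bins = spec.chrom_len_bp // bin_bp
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]

    # -- placement ---------------------------------------------------------
    prom_fp = 2 * spec.me2_flank_width_bp + spec.peak_width_bp
    enh_fp = spec.peak_width_bp
    loci = (
        [("prom", i) for i in range(spec.n_promoters)]
        + [("uprom", i) for i in range(spec.n_unannotated_promoters)]
        + [("enh", i) for i in range(spec.n_enhancers)]
    )
    if loci and not chroms:
        raise ValueError("cannot place loci: n_chroms is 0")
    order = rng.permutation(len(loci)) if loci else np.empty(0, dtype=int)
    shuffled = [loci[i] for i in order]
    per_chrom: dict[str, list] = {c: [] for c in chroms}
    for j, locus in enumerate(shuffled):
        per_chrom[chroms[j % len(chroms)]].append(locus)

    placements: dict[tuple[str, int], tuple[str, int]] = {}  # locus -> (chrom, start)
    for chrom in chroms:
        cursor = spec.min_locus_gap_bp
        for kind, idx in per_chrom[chrom]:
            gap = int(rng.integers(spec.min_locus_gap_bp, 2 * spec.min_locus_gap_bp))
            start = ((cursor + gap) // bin_bp) * bin_bp
            fp = prom_fp if kind in ("prom", "uprom") else enh_fp
            if start + fp + spec.min_locus_gap_bp > spec.chrom_len_bp:
                raise ValueError(
                    "loci cannot be placed without overlap; "
                    "increase chrom_len_bp or reduce locus counts"
                )
            placements[(kind, idx)] = (chrom, start)
            cursor = start + fp

    # -- signal arrays -----------------------------------------------------
    me1 = {c: np.zeros(n_bins) for c in chroms}
    me2 = {c: np.zeros(n_bins) for c in chroms}
    me3 = {c: np.zeros(n_bins) for c in chroms}

    def fill(arr, chrom, lo_bp, hi_bp, value):
        arr[chrom][lo_bp // bin_bp: hi_bp // bin_bp] = value

    promoters: list[PromoterLocus] = []
    tss_records: list[GenomeInterval] = []
    unannotated_beds: list[GenomeInterval] = []
    # per-locus signal draws in (prom..., uprom..., enh...) index order
    for kind, count, annotated in (
        ("prom", spec.n_promoters, True),
        ("uprom", spec.n_unannotated_promoters, False),
    ):
        for i in range(count):
            chrom, start = placements[(kind, i)]
            flank = spec.me2_flank_width_bp
            peak = spec.peak_width_bp
            level = float(rng.uniform(*spec.me2_flank_level))
            strand = "+" if rng.integers(2) else "-"
            name = f"{kind}_{i}"
            fill(me3, chrom, start + flank, start + flank + peak, spec.promoter_me3_apex)
            fill(me2, chrom, start, start + flank, level)
            fill(me2, chrom, start + flank + peak, start + 2 * flank + peak, level)
            fill(me1, chrom, start, start + 2 * flank + peak, spec.promoter_me1_level)
            tss_pos = start + flank + peak // 2
            locus = PromoterLocus(name, chrom, start, tss_pos, strand, level, annotated)
            promoters.append(locus)
            if annotated:
                tss_records.append(
                    GenomeInterval(chrom, tss_pos, tss_pos + 1, strand, name)
                )
            else:
                unannotated_beds.append(
                    GenomeInterval(chrom, start, start + prom_fp, strand, name)
                )

    enhancers: list[GenomeInterval] = []
    for i in range(spec.n_enhancers):
        chrom, start = placements[("enh", i)]
        level = float(rng.uniform(*spec.enhancer_me3_level))
        fill(me1, chrom, start, start + enh_fp, spec.enhancer_me1_level)
        fill(me2, chrom, start, start + enh_fp, spec.enhancer_me2_level)
        fill(me3, chrom, start, start + enh_fp, level)
        enhancers.append(
            GenomeInterval(chrom, start, start + enh_fp, name=f"enh_{i}", score=level)
        )

    # -- cascade labels and feature library --------------------------------
    n_steps = len(CASCADE_STEP_LABELS)
    fail_step: list[int | None] = []
    for _ in range(spec.n_enhancers):
        if rng.random() < spec.cascade_survive_fraction:
            fail_step.append(None)
        else:
            fail_step.append(int(rng.integers(n_steps)))

    annotated_proms = [p for p in promoters if p.annotated]
    refseq = [
        GenomeInterval(p.chrom, max(0, p.tss - 1000), p.tss + 1000, p.strand, p.name)
        for p in annotated_proms
    ]
    plateau_me3_peaks = [
        GenomeInterval(
            p.chrom,
            p.start + spec.me2_flank_width_bp,
            p.start + spec.me2_flank_width_bp + spec.peak_width_bp,
            name=f"{p.name}_me3peak",
        )
        for p in promoters
    ]
    me3_peak_enh = _subset(rng, enhancers, spec.me3_peak_enhancer_fraction)
    fantom_enh = _subset(rng, enhancers, spec.fantom5_fraction)
    validation_sets = {
        name: _subset(rng, enhancers, spec.validation_fraction)
        for name in ("gasperini", "starrseq", "cage_bidir")
    }

    def feature_set(step_name: str) -> list[GenomeInterval]:
        j = CASCADE_STEP_LABELS.index(step_name)
        return [e for e, s in zip(enhancers, fail_step) if s != j]

    chiapet_pairs = []
    if annotated_proms:
        j_chia = CASCADE_STEP_LABELS.index("chiapet")
        for e, s in zip(enhancers, fail_step):
            if s == j_chia:
                continue
            p = annotated_proms[int(rng.integers(len(annotated_proms)))]
            chiapet_pairs.append(
                (
                    GenomeInterval(e.chrom, e.start, e.end),
                    GenomeInterval(p.chrom, max(0, p.tss - 1000), p.tss + 1000),
                )
            )

    promoter_dhs = plateau_me3_peaks  # open chromatin over the plateau
    library = FeatureLibrary(
        refseq_promoters=refseq,
        gencode_promoters=list(refseq),
        tfbs=feature_set("tfbs"),
        grocap_tss=feature_set("grocap_tss"),
        atac=feature_set("atac"),
        h3k27ac=feature_set("h3k27ac"),
        faire=feature_set("faire"),
        dnase=feature_set("dnase") + list(promoter_dhs),
        p300=feature_set("p300"),
        chiapet_promoter_contacts=chiapet_pairs,
        h3k4me1_peaks=list(enhancers),
        h3k4me3_peaks=plateau_me3_peaks + me3_peak_enh,
        fantom5_enhancers=fantom_enh,
        lncrna_promoters=[
            GenomeInterval(p.chrom, max(0, p.tss - 1000), p.tss + 1000, p.strand, p.name)
            for p in promoters
            if not p.annotated
        ],
    )

    # contaminant candidates sitting on real (annotated) promoter plateaus,
    # removed at the not_refseq_promoter step
    annotated_plateaus = [
        pk for pk, p in zip(plateau_me3_peaks, promoters) if p.annotated
    ]
    prom_candidates = [
        GenomeInterval(pk.chrom, pk.start, pk.end, name=f"promcand_{i}")
        for i, pk in enumerate(annotated_plateaus[: spec.n_promoter_candidates])
    ]
    candidates = list(enhancers) + prom_candidates

    # -- CAGE peaks --------------------------------------------------------
    cage_peaks: list[GenomeInterval] = []
    cage_enh = _subset(rng, enhancers, spec.cage_enhancer_fraction)
    half_gap = spec.cage_gap_bp // 2
    w = spec.cage_peak_width_bp

    def divergent_pair(chrom: str, center: int, label: str) -> None:
        cage_peaks.append(
            GenomeInterval(chrom, center - half_gap - w, center - half_gap,
                           "-", f"{label}_minus")
        )
        cage_peaks.append(
            GenomeInterval(chrom, center + half_gap, center + half_gap + w,
                           "+", f"{label}_plus")
        )

    for p in promoters:
        divergent_pair(p.chrom, p.tss, p.name)
    for e in cage_enh:
        divergent_pair(e.chrom, e.midpoint, e.name)

    # -- noise -------------------------------------------------------------
    if spec.noise_sd > 0:
        for arr in (me1, me2, me3):
            for chrom in chroms:
                arr[chrom] = np.maximum(
                    0.0, arr[chrom] + rng.normal(0.0, spec.noise_sd, n_bins)
                )

    def to_track(arrs) -> HmdTrack:
        segs = []
        for chrom in chroms:
            segs.extend(_arrays_to_track_segments(chrom, arrs[chrom], bin_bp))
        return HmdTrack(segs)

    tracks = MethylformTrackSet(
        tracks={"me1": to_track(me1), "me2": to_track(me2), "me3": to_track(me3)},
        bin_bp=bin_bp,
    )

    # -- expected counts (planted ground truth, noise-free geometry) -------
    default_params = Bh4dParams()
    bh4d_true = sum(
        1
        for p in annotated_proms
        if spec.promoter_me3_apex >= default_params.min_hmd
        and spec.peak_width_bp >= default_params.min_len_bp
    )
    n_cand = len(candidates)
    cascade_counts = [n_cand, len(enhancers)]  # input; after promoter removal
    survivors = len(enhancers)
    for j in range(n_steps):
        survivors = sum(1 for s in fail_step if s is None or s > j)
        cascade_counts.append(survivors)
    final_names = {e.name for e, s in zip(enhancers, fail_step) if s is None}
    expected = ExpectedCounts(
        bh4d_tss_true=bh4d_true,
        n_bidirectional_regions=len(promoters) + len(cage_enh),
        n_loose_enhancers=sum(
            1 for s in fail_step if s != CASCADE_STEP_LABELS.index("dnase")
        ),
        n_h3k4me3_positive_candidates=len(me3_peak_enh) + len(prom_candidates),
        cascade_step_names=["input", "not_refseq_promoter"]
        + [f"has_{n}" for n in CASCADE_FEATURE_STEPS]
        + ["chiapet_promoter_contact"],
        cascade_counts=cascade_counts,
        n_refined=len([e for e in fantom_enh if e.name in final_names]),
        validation={k: len(v) for k, v in validation_sets.items()},
    )
    if not annotated_proms:
        expected.cascade_counts[-1] = 0  # no promoters: nothing can contact one
        expected.n_refined = 0

    bundle = SyntheticBundle(
        spec=spec,
        tracks=tracks,
        tss=tss_records,
        promoters=promoters,
        enhancers=enhancers,
        unannotated_promoters=unannotated_beds,
        cage_peaks=cage_peaks,
        candidates=candidates,
        library=library,
        expected=expected,
        chiapet_pairs=chiapet_pairs,
        validation_truth_sets=validation_sets,
    )
    return bundle


CASCADE_FEATURE_STEPS = ("tfbs", "grocap_tss", "atac", "h3k27ac", "faire", "dnase", "p300")


def plant_specificity_scenario(
    bundle: SyntheticBundle,
    me2_xreact: float,
    params: Bh4dParams | None = None,
) -> tuple[HmdTrack, list[str]]:
    """Build the apparent H3K4me3 track of an antibody with ``me2_xreact``
    weight on H3K4me2, and compute in closed form which annotated TSSs gain
    a broad domain only under cross-reactivity.

    On the planted piecewise-constant shapes the apparent promoter profile
    is exact: plateau at (1-x)*apex, flanks at x*flank_level. A TSS carries
    an apparent BH4D iff the plateau clears the threshold and the
    above-threshold run containing the TSS (plateau alone, or plateau plus
    both flanks when those also clear it) reaches min_len_bp. The expected
    extras are those apparent hits absent from the true-track hits. The
    closed form assumes the generator's noise-free geometry; with
    noise_sd > 0 it is approximate.
    """
    if not 0 <= me2_xreact < 1:
        raise ValueError("me2_xreact must lie in [0, 1)")
    params = params or Bh4dParams()
    spec = bundle.spec
    profile = SpecificityProfile(
        f"synthetic_me2x{me2_xreact:g}",
        {"me3": 1.0 - me2_xreact, "me2": me2_xreact},
    )
    apparent = apparent_track(bundle.tracks, profile, target="me3")

    def has_bh4d(plateau_val: float, flank_val: float) -> bool:
        if plateau_val < params.min_hmd:
            return False
        run = spec.peak_width_bp
        if flank_val >= params.min_hmd:
            run += 2 * spec.me2_flank_width_bp
        return run >= params.min_len_bp

    extras: list[str] = []
    for p in bundle.promoters:
        if not p.annotated:
            continue
        truth_hit = has_bh4d(spec.promoter_me3_apex, 0.0)
        app_hit = has_bh4d(
            (1.0 - me2_xreact) * spec.promoter_me3_apex,
            me2_xreact * p.flank_level,
        )
        if app_hit and not truth_hit:
            extras.append(p.name)
    return apparent, extras


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write the bundle as standard text files: bedGraph tracks, BED6
    annotations, BEDPE interactions, a feature-library manifest, an echo of
    the generation spec and the expected-count ground truth (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for mf, track in sorted(bundle.tracks.tracks.items()):
        write_bedgraph(track, outdir / f"{mf}_hmd.bedgraph")
    write_bed(bundle.tss, outdir / "tss.bed")
    write_bed(bundle.enhancers, outdir / "enhancers.bed")
    write_bed(bundle.unannotated_promoters, outdir / "unannotated_promoters.bed")
    write_bed(bundle.cage_peaks, outdir / "cage_peaks.bed")
    write_bed(bundle.candidates, outdir / "candidates.bed")

    libdir = outdir / "library"
    libdir.mkdir(exist_ok=True)
    manifest = {}
    lib = bundle.library
    from dataclasses import fields as dc_fields

    for f in dc_fields(lib):
        value = getattr(lib, f.name)
        if value is None:
            continue
        if f.name == "chiapet_promoter_contacts":
            rel = "library/chiapet.bedpe"
            write_bedpe(value, outdir / rel)
        else:
            rel = f"library/{f.name}.bed"
            write_bed(value, outdir / rel)
        manifest[f.name] = rel
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    truth = getattr(bundle, "validation_truth_sets", {})
    for name, ivs in sorted(truth.items()):
        write_bed(ivs, outdir / f"truth_{name}.bed")

    with open(outdir / "spec.json", "w") as fh:
        json.dump(asdict(bundle.spec), fh, indent=2, sort_keys=True)
    with open(outdir / "expected_counts.json", "w") as fh:
        json.dump(asdict(bundle.expected), fh, indent=2, sort_keys=True)


def read_spec(path) -> SyntheticGenomeSpec:
    """Read a generation spec from YAML or JSON."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("enhancer_me3_level", "me2_flank_level"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SyntheticGenomeSpec(**raw)
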