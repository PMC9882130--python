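"""Antibody cross-reactivity mixing model.

An imperfect H3K4me3 antibody captures nucleosomes bearing other H3K4
methylforms (chiefly H3K4me2, which flanks promoter H3K4me3 peaks and is
globally more abundant). The apparent signal it reports is modelled as a
convex combination of the true per-methylform HMD tracks, weighted by the
antibody's row-normalized capture fractions. Because H3K4me2 flanks a
central H3K4me3 peak at promoters, off-target me2 capture widens the
apparent me3-enriched region — the mechanism by which low-specificity
antibodies inflate broad-domain calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .intervals import HmdTrack

METHYLFORMS = ("me0", "me1", "me2", "me3")


@dataclass
class SpecificityProfile:
    """Relative capture fractions of one antibody over H3K4 methylforms.

    Fractions are stored un-normalized (as measured, e.g. peptide-array or
    calibrant readout) and row-normalized on use.
    """

    antibody_name: str
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        for mf, f in self.fractions.items():
            if mf not in METHYLFORMS:
                raise ValueError(f"unknown methylform {mf!r}")
            if f < 0:
                raise ValueError(f"negative capture fraction for {mf}")
        if not any(f > 0 for f in self.fractions.values()):
            raise ValueError(
                f"specificity profile {self.antibody_name!r} is all-zero"
            )


def normalize_specificity(
    profile: SpecificityProfile,
    abundance: dict[str, float] | None = None,
) -> dict[str, float]:
    """Scale capture fractions to sum to 1, preserving methylform order.

    ``abundance`` optionally multiplies each fraction by a per-methylform
    scalar before normalization, emulating abundance-driven capture (e.g.
    H3K4me2 being globally more abundant than H3K4me3); default 1.0 each.
    """
    weighted = {
        mf: f * (abundance or {}).get(mf, 1.0) for mf, f in profile.fractions.items()
    }
    total = sum(weighted.values())
    if total <= 0:
        raise ValueError(
            f"specificity profile {profile.antibody_name!r} normalizes to zero"
        )
    return {mf: w / total for mf, w in weighted.items()}


@dataclass
class MethylformTrackSet:
    """True HMD tracks per methylform on a shared bin grid.

    me0 (unmodified) carries no mark by definition and defaults to a
    constant-zero contribution when absent.
    """

    tracks: dict[str, HmdTrack]
    bin_bp: int

    def __post_init__(self) -> None:
        if self.bin_bp <= 0:
            raise ValueError("bin_bp must be positive")
        for mf in self.tracks:
            if mf not in METHYLFORMS:
                raise ValueError(f"unknown methylform {mf!r}")


def apparent_track(
    truth: MethylformTrackSet,
    profile: SpecificityProfile,
    target: str = "me3",
    abundance: dict[str, float] | None = None,
) -> HmdTrack:
    """Apparent signal of an antibody: per bin, the specificity-weighted sum
    of the true methylform tracks.

    ``target`` labels which mark the antibody nominally measures (metadata
    only; it does not change the arithmetic). A nonzero weight on a
    methylform with no truth track is an error, except me0 which defaults
    to zero signal.
    """
    if target not in METHYLFORMS:
        raise ValueError(f"unknown target methylform {target!r}")
    weights = normalize_specificity(profile, abundance)
    chrom_ends: dict[str, int] = {}
    for track in truth.tracks.values():
        for chrom in track.chroms:
            chrom_ends[chrom] = max(chrom_ends.get(chrom, 0), track.chrom_end(chrom))
    binned: dict[str, HmdTrack] = {}
    for mf, w in weights.items():
        if w == 0:
            continue
        if mf not in truth.tracks:
            if mf == "me0":
                continue  # unmodified nucleosomes carry no mark
            raise ValueError(
                f"antibody {profile.antibody_name!r} captures {mf} "
                f"but no {mf} truth track was provided"
            )
        binned[mf] = truth.tracks[mf].to_bins(truth.bin_bp, chrom_ends)

    acc: dict[tuple[str, int, int], float] = {}
    for mf, track in binned.items():
        w = weights[mf]
        for chrom, start, end, value in track.segments():
            key = (chrom, start, end)
            acc[key] = acc.get(key, 0.0) + w * value
    return HmdTrack((c, s, e, v) for (c, s, e), v in acc.items())


def read_specificity_profiles(path) -> dict[str, SpecificityProfile]:
    """Read antibody profiles from a YAML config.

    Format: a mapping of antibody name -> {me0: f, me1: f, me2: f, me3: f}
    (missing methylforms default to 0).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of antibody -> fractions")
    out = {}
    for name, fractions in raw.items():
        out[name] = SpecificityProfile(str(name), {k: float(v) for k, v in fractions.items()})
    return out


def write_specificity_profiles(profiles: dict[str, SpecificityProfile], path) -> None:
    data = {name: dict(p.fractions) for name, p in profiles.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
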