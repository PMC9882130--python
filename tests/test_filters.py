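import numpy as np
import pytest

from hmdkit.filters import (
    CASCADE_FEATURES,
    FeatureLibrary,
    fantom_lncrna_refine,
    h3k4me3_positive,
    load_feature_library,
    loose_enhancers,
    read_bedpe,
    replicate_intersect,
    stringent_cascade,
    validation_overlap,
    write_bedpe,
)
from hmdkit.intervals import GenomeInterval, filter_by_overlap, write_bed


def iv(start, end, name=None, chrom="chr1"):
    return GenomeInterval(chrom, start, end, name=name)


def names(intervals):
    return [i.name for i in intervals]


class TestLooseEnhancers:
    def test_designed_six_dhs_fixture(self):
        # d0: me1 + far from promoters -> kept
        # d1: me1 + overlapping a promoter -> removed
        # d2: no me1 -> removed
        # d3: me1, clear -> kept
        # d4: me1 abutting promoter (half-open, no overlap) -> kept
        # d5: no me1, on promoter -> removed
        dhs = [
            iv(1000, 1400, "d0"), iv(5000, 5400, "d1"), iv(9000, 9400, "d2"),
            iv(13000, 13400, "d3"), iv(17000, 17400, "d4"), iv(21000, 21400, "d5"),
        ]
        me1 = [iv(1200, 1600), iv(5200, 5600), iv(13000, 13100), iv(17000, 17400)]
        promoters = [iv(5300, 6000), iv(17400, 18000), iv(21000, 22000)]
        got = loose_enhancers(dhs, me1, promoters)
        assert names(got) == ["d0", "d3", "d4"]

    def test_empty_dnase_yields_empty(self):
        assert loose_enhancers([], [iv(0, 10)], [iv(20, 30)]) == []


class TestH3k4me3Positive:
    def test_no_peaks_yields_empty(self):
        assert h3k4me3_positive([iv(0, 100)], []) == []

    def test_abutting_peak_excluded(self):
        assert h3k4me3_positive([iv(0, 100)], [iv(100, 200)]) == []

    def test_designed_ten_candidate_fixture(self):
        cands = [iv(i * 1000, i * 1000 + 200, f"c{i}") for i in range(10)]
        peaks = [iv(100, 150), iv(3100, 3150), iv(5000, 5010), iv(9190, 9300)]
        got = h3k4me3_positive(cands, peaks)
        assert names(got) == ["c0", "c3", "c5", "c9"]


def designed_cascade_fixture():
    """8 candidates: one removed at each of the first seven steps, the last
    survives everything. Returns (candidates, library)."""
    cands = [iv(i * 10_000, i * 10_000 + 500, f"c{i}") for i in range(8)]
    promoters = [iv(100, 600, "prom0")]  # overlaps c0 only
    prom_window = iv(100, 600)

    def all_but(k):
        # feature present at every candidate except c{k}
        return [iv(c.start, c.end) for j, c in enumerate(cands) if j != k]

    everywhere = [iv(c.start, c.end) for c in cands]
    library = FeatureLibrary(
        refseq_promoters=promoters,
        tfbs=all_but(1),
        grocap_tss=all_but(2),
        atac=all_but(3),
        h3k27ac=all_but(4),
        faire=all_but(5),
        dnase=all_but(6),
        p300=everywhere,
        chiapet_promoter_contacts=[(iv(70_000, 70_500), prom_window)],
    )
    return cands, library


class TestStringentCascade:
    def test_empty_candidates_report_all_zero(self):
        _, library = designed_cascade_fixture()
        report = stringent_cascade([], library)
        assert report.counts == [0] * 10

    def test_candidate_with_everything_survives(self):
        cands, library = designed_cascade_fixture()
        report = stringent_cascade([cands[7]], library)
        assert report.counts == [1] * 10
        assert names(report.survivors) == ["c7"]

    def test_designed_eight_candidate_fixture_counts(self):
        cands, library = designed_cascade_fixture()
        report = stringent_cascade(cands, library)
        # input 8; each of the seven removal steps drops one; p300 and
        # ChIA-PET keep the last survivor
        assert report.counts == [8, 7, 6, 5, 4, 3, 2, 1, 1, 1]
        assert names(report.survivors) == ["c7"]

    def test_final_survivors_satisfy_every_predicate(self):
        cands, library = designed_cascade_fixture()
        survivors = stringent_cascade(cands, library).survivors
        assert survivors
        for s in survivors:
            assert filter_by_overlap([s], library.refseq_promoters, "keep") == []
            for feat in CASCADE_FEATURES:
                assert filter_by_overlap([s], getattr(library, feat), "keep") == [s]
            assert any(
                s.overlap_bp(a) > 0 or s.overlap_bp(b) > 0
                for a, b in library.chiapet_promoter_contacts
            )

    def test_missing_library_set_error_names_it(self):
        cands, library = designed_cascade_fixture()
        library.p300 = None
        with pytest.raises(ValueError, match="p300"):
            stringent_cascade(cands, library)

    def test_chiapet_contact_orientation_symmetric(self):
        cand = iv(0, 500, "c")
        prom = iv(90_000, 91_000)
        lib_kwargs = dict(
            refseq_promoters=[prom],
            **{f: [iv(0, 500)] for f in CASCADE_FEATURES},
        )
        # candidate on anchor A, promoter on anchor B ... and swapped
        for pair in [(iv(0, 500), prom), (prom, iv(0, 500))]:
            library = FeatureLibrary(chiapet_promoter_contacts=[pair], **lib_kwargs)
            assert names(stringent_cascade([cand], library).survivors) == ["c"]

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_non_increasing_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        cands = [iv(i * 2000, i * 2000 + 500, f"c{i}") for i in range(30)]

        def random_subset():
            mask = rng.random(len(cands)) < 0.7
            return [iv(c.start, c.end) for c, m in zip(cands, mask) if m]

        library = FeatureLibrary(
            refseq_promoters=random_subset(),
            chiapet_promoter_contacts=[
                (iv(c.start, c.end), iv(c.start, c.end)) for c in random_subset()
            ],
            **{f: random_subset() for f in CASCADE_FEATURES},
        )
        report = stringent_cascade(cands, library)
        assert all(a >= b for a, b in zip(report.counts, report.counts[1:]))

    def test_final_set_order_insensitive(self, default_bundle):
        # conjunctive predicates: survivors equal the intersection of every
        # per-predicate keep-set, regardless of application order
        b = default_bundle
        report = stringent_cascade(b.candidates, b.library)
        alt = set(
            c.name
            for c in filter_by_overlap(b.candidates, b.library.refseq_promoters, "remove")
        )
        for feat in CASCADE_FEATURES:
            alt &= {
                c.name
                for c in filter_by_overlap(b.candidates, getattr(b.library, feat), "keep")
            }
        from hmdkit.filters import _subject_trees, contacts_promoter

        trees = _subject_trees(b.library.refseq_promoters)
        alt &= {
            c.name
            for c in b.candidates
            if contacts_promoter(c, b.library.chiapet_promoter_contacts, trees)
        }
        assert {s.name for s in report.survivors} == alt


class TestRefinement:
    def test_lncrna_promoter_candidates_removed(self):
        cands = [iv(0, 100, "on_lnc"), iv(1000, 1100, "clear")]
        got = fantom_lncrna_refine(cands, [iv(0, 2000)], [iv(50, 60)])
        assert names(got) == ["clear"]

    def test_fantom_support_required(self):
        cands = [iv(0, 100, "supported"), iv(1000, 1100, "unsupported")]
        got = fantom_lncrna_refine(cands, [iv(0, 100)], [])
        assert names(got) == ["supported"]

    def test_five_candidate_fixture_one_survivor(self):
        cands = [iv(i * 1000, i * 1000 + 100, f"c{i}") for i in range(5)]
        fantom = [iv(0, 100), iv(2000, 2100)]       # supports c0, c2
        lncrna = [iv(0, 500), iv(3000, 3100)]        # removes c0, c3
        got = fantom_lncrna_refine(cands, fantom, lncrna)
        assert names(got) == ["c2"]


class TestValidationOverlap:
    def test_empty_truth_counts_zero(self):
        assert validation_overlap([iv(0, 10)], {"t": []}) == {"t": 0}

    def test_identity_truth_counts_all(self):
        cands = [iv(i * 100, i * 100 + 50) for i in range(5)]
        assert validation_overlap(cands, {"self": list(cands)}) == {"self": 5}

    def test_planted_counts_recovered(self, default_bundle):
        got = validation_overlap(
            default_bundle.candidates, default_bundle.validation_truth_sets
        )
        assert got == default_bundle.expected.validation


class TestReplicateIntersect:
    def test_identical_replicates_unchanged(self):
        peaks = [iv(0, 100), iv(500, 700)]
        assert replicate_intersect(peaks, list(peaks)) == peaks

    def test_disjoint_replicates_empty(self):
        assert replicate_intersect([iv(0, 100)], [iv(500, 700)]) == []

    def test_twenty_peak_fixture_seven_reproducible(self):
        rep1 = [iv(i * 1000, i * 1000 + 200, f"p{i}") for i in range(20)]
        rep2 = [iv(i * 1000 + 100, i * 1000 + 300) for i in (0, 3, 5, 8, 11, 14, 19)]
        got = replicate_intersect(rep1, rep2)
        assert names(got) == ["p0", "p3", "p5", "p8", "p11", "p14", "p19"]


class TestLibraryIO:
    def test_bedpe_roundtrip(self, tmp_path):
        pairs = [(iv(0, 100), iv(5000, 5100)), (iv(200, 300, chrom="chr2"), iv(900, 950))]
        path = tmp_path / "x.bedpe"
        write_bedpe(pairs, path)
        got = read_bedpe(path)
        assert [(a.start, b.start) for a, b in got] == [(0, 5000), (200, 900)]

    def test_manifest_loading_and_missing_file(self, tmp_path):
        write_bed([iv(0, 100, "p")], tmp_path / "prom.bed")
        write_bedpe([(iv(0, 100), iv(500, 600))], tmp_path / "chia.bedpe")
        (tmp_path / "manifest.yaml").write_text(
            "refseq_promoters: prom.bed\nchiapet_promoter_contacts: chia.bedpe\n"
        )
        lib = load_feature_library(tmp_path / "manifest.yaml")
        assert names(lib.refseq_promoters) == ["p"]
        assert len(lib.chiapet_promoter_contacts) == 1
        assert lib.p300 is None

        (tmp_path / "manifest.yaml").write_text("p300: nothere.bed\n")
        with pytest.raises(FileNotFoundError, match="p300"):
            load_feature_library(tmp_path / "manifest.yaml")

    def test_unknown_set_name_rejected(self, tmp_path):
        (tmp_path / "manifest.yaml").write_text("mystery: x.bed\n")
        with pytest.raises(ValueError, match="mystery"):
            load_feature_library(tmp_path / "manifest.yaml")
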