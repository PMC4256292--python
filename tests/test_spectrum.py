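"""Classification, class/site rates, hotspot calls, orientation comparison."""

import pytest

from strandspectra import repeats, spectrum
from strandspectra.types import (
    MutationClass,
    MutationSubtype,
    SpectrumDataset,
)
from conftest import make_event


class TestClassify:
    @pytest.mark.parametrize(
        "ref,alt,klass,subtype",
        [
            ("C", "A", MutationClass.SUBSTITUTION, MutationSubtype.TRANSVERSION),
            ("G", "A", MutationClass.SUBSTITUTION, MutationSubtype.TRANSITION),
            ("T", "C", MutationClass.SUBSTITUTION, MutationSubtype.TRANSITION),
            ("A", "T", MutationClass.SUBSTITUTION, MutationSubtype.TRANSVERSION),
            ("G", "", MutationClass.SINGLE_BASE_INDEL, MutationSubtype.DELETION),
            ("", "T", MutationClass.SINGLE_BASE_INDEL, MutationSubtype.INSERTION),
            ("GG", "", MutationClass.COMPLEX, MutationSubtype.OTHER),
            ("AC", "A", MutationClass.COMPLEX, MutationSubtype.OTHER),
            ("A", "CG", MutationClass.COMPLEX, MutationSubtype.OTHER),
        ],
    )
    def test_classes(self, ref, alt, klass, subtype):
        assert spectrum.classify_event(ref, alt) == (klass, subtype)

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError, match="not a mutation"):
            spectrum.classify_event("A", "A")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            spectrum.classify_event("N", "A")


class TestClassRate:
    @pytest.mark.parametrize(
        "strain,klass,expected",
        [
            # published worked values: indel class rates per strain
            ("wt", MutationClass.SINGLE_BASE_INDEL, 0.5),
            ("pool-OR1", MutationClass.SINGLE_BASE_INDEL, 33.0),
            ("pool-OR2", MutationClass.SINGLE_BASE_INDEL, 37.0),
        ],
    )
    def test_published_indel_rates(self, summary_datasets, strain, klass, expected):
        rate = spectrum.class_rate(summary_datasets[strain], klass)
        assert round(rate, 1 if expected < 1 else 0) == expected

    def test_zero_events_zero_rate(self, summary_datasets):
        assert spectrum.class_rate(
            summary_datasets["pool-OR1"], MutationClass.COMPLEX
        ) == 0.0

    def test_class_counts_conserve_total(self, summary_datasets):
        for ds in summary_datasets.values():
            per_class = sum(
                len(ds.events_of_class(k)) for k in MutationClass
            )
            assert per_class == len(ds.events)

    def test_homogeneous_in_overall_rate(self, summary_datasets):
        ds = summary_datasets["pool-OR1"]
        scaled = SpectrumDataset(
            ds.strain, ds.locus, ds.events, ds.n_isolates, ds.overall_rate * 3,
            ds.pool_imbalanced, ds.mmr_deficient,
        )
        for k in MutationClass:
            assert spectrum.class_rate(scaled, k) == pytest.approx(
                3 * spectrum.class_rate(ds, k)
            )


class TestSiteRates:
    def test_direct_arithmetic(self, locus):
        # 12 events at one site, 173 isolates, overall rate 57
        pos = 1
        events = [
            make_event(locus, pos, locus.base(pos),
                       "A" if locus.base(pos) != "A" else "C", isolate=f"i{j}")
            for j in range(12)
        ]
        ds = SpectrumDataset("s", locus, events, 173, 57.0)
        (sr,) = spectrum.site_rates(ds)
        assert sr.count == 12
        assert sr.rate == pytest.approx(12 / 173 * 57, rel=1e-12)  # ~3.95

    def test_one_event_bound(self, summary_datasets):
        wt = summary_datasets["wt"]
        assert spectrum.one_event_bound(wt) == pytest.approx(4.2 / 93)

    def test_distinct_sites_one_rate_each(self, locus):
        positions = [1, 3, 5, 7]
        events = [
            make_event(locus, p, locus.base(p),
                       "A" if locus.base(p) != "A" else "C", isolate=f"i{p}")
            for p in positions
        ]
        ds = SpectrumDataset("s", locus, events, 100, 10.0)
        assert len(spectrum.site_rates(ds)) == len(events)

    def test_run_indels_pooled_to_run_span(self, locus):
        runs = repeats.annotate_runs(locus.coding_sequence, min_len=3)
        run = next(r for r in runs if r.length >= 3)
        events = [
            make_event(locus, p, run.base, "", isolate=f"i{p}")
            for p in range(run.start, run.end + 1)
        ]
        ds = SpectrumDataset("s", locus, events, 100, 10.0)
        (sr,) = spectrum.site_rates(ds)
        assert (sr.start, sr.end) == (run.start, run.end)
        assert sr.count == run.length

    def test_substitutions_never_pooled(self, locus):
        runs = repeats.annotate_runs(locus.coding_sequence, min_len=3)
        run = next(r for r in runs if r.length >= 3)
        alt = "A" if run.base != "A" else "C"
        events = [
            make_event(locus, p, run.base, alt, isolate=f"i{p}")
            for p in (run.start, run.start + 1)
        ]
        ds = SpectrumDataset("s", locus, events, 100, 10.0)
        assert len(spectrum.site_rates(ds)) == 2

    def test_site_rates_sum_to_total(self, summary_datasets):
        for ds in summary_datasets.values():
            total = sum(sr.rate for sr in spectrum.site_rates(ds))
            expected = len(ds.events) / ds.n_isolates * ds.overall_rate
            assert total == pytest.approx(expected, rel=1e-9)


class TestHotspots:
    def test_worked_fold(self, locus):
        # mutant site rate ~3.95 vs wt one-event bound (1/93)*4.2 -> fold ~87
        pos = 1
        alt = "A" if locus.base(pos) != "A" else "C"
        events = [
            make_event(locus, pos, locus.base(pos), alt, isolate=f"i{j}")
            for j in range(12)
        ]
        ds = SpectrumDataset("mut", locus, events, 173, 57.0)
        wt = SpectrumDataset("wt", locus, [], 93, 4.2)
        (h,) = spectrum.detect_hotspots(ds, wt)
        assert h.wt_is_bound
        assert h.fold_over_wt == pytest.approx((12 / 173 * 57) / (4.2 / 93), rel=1e-9)
        assert h.fold_over_wt > 80

    def test_identical_datasets_no_hotspots(self, summary_datasets):
        ds = summary_datasets["pool-OR1"]
        assert spectrum.detect_hotspots(ds, ds) == []

    def test_threshold_inclusive(self, locus):
        # construct fold exactly 10: mutant 10 events/100 at rate 1 vs wt 1/100 at 1
        pos = 1
        alt = "A" if locus.base(pos) != "A" else "C"
        mut_events = [
            make_event(locus, pos, locus.base(pos), alt, isolate=f"i{j}")
            for j in range(10)
        ]
        wt_events = [make_event(locus, pos, locus.base(pos), alt)]
        ds = SpectrumDataset("mut", locus, mut_events, 100, 1.0)
        wt = SpectrumDataset("wt", locus, wt_events, 100, 1.0)
        assert len(spectrum.detect_hotspots(ds, wt, fold_threshold=10.0)) == 1
        assert spectrum.detect_hotspots(ds, wt, fold_threshold=10.0001) == []


class TestCompareOrientations:
    def test_site_only_in_or2_bounded(self, locus):
        or2 = locus.flipped()
        pos = 2
        alt = "A" if locus.base(pos) != "A" else "C"
        ev = [make_event(locus, pos, locus.base(pos), alt, isolate=f"i{j}")
              for j in range(5)]
        ds1 = SpectrumDataset("or1", locus, [], 173, 57.0)
        ds2 = SpectrumDataset("or2", or2, ev, 170, 60.0)
        (row,) = spectrum.compare_orientations(ds1, ds2)
        assert row.or1_is_bound and not row.or2_is_bound
        assert row.higher == "OR2" and row.fold_is_bound

    def test_symmetric_counts_fold_one(self, locus):
        or2 = locus.flipped()
        pos = 2
        alt = "A" if locus.base(pos) != "A" else "C"
        ev1 = [make_event(locus, pos, locus.base(pos), alt, isolate=f"a{j}")
               for j in range(4)]
        ev2 = [make_event(locus, pos, locus.base(pos), alt, isolate=f"b{j}")
               for j in range(4)]
        ds1 = SpectrumDataset("or1", locus, ev1, 100, 50.0)
        ds2 = SpectrumDataset("or2", or2, ev2, 100, 50.0)
        (row,) = spectrum.compare_orientations(ds1, ds2)
        assert row.fold == pytest.approx(1.0)
        assert not row.fold_is_bound

    def test_empty_or2_all_bounded(self, locus):
        or2 = locus.flipped()
        positions = [1, 3]
        ev = [
            make_event(locus, p, locus.base(p),
                       "A" if locus.base(p) != "A" else "C", isolate=f"i{p}")
            for p in positions
        ]
        ds1 = SpectrumDataset("or1", locus, ev, 100, 50.0)
        ds2 = SpectrumDataset("or2", or2, [], 100, 50.0)
        rows = spectrum.compare_orientations(ds1, ds2)
        assert len(rows) == 2
        assert all(r.or2_is_bound for r in rows)

    def test_same_orientation_rejected(self, locus):
        ds = SpectrumDataset("a", locus, [], 10, 1.0)
        with pytest.raises(ValueError, match="opposite orientations"):
            spectrum.compare_orientations(ds, ds)
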