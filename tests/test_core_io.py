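"""Readers, writers, round trips, and the CLI plumbing."""

import pytest
from click.testing import CliRunner

from strandspectra import cli, core_io, fluctuation, repeats, spectrum, strandmodel
from strandspectra.types import (
    BoundKind,
    CorrectionFactor,
    ForkEntry,
    HomopolymerRun,
    Hotspot,
    MutationClass,
    MutationSubtype,
    Orientation,
    RateEstimate,
    SiteRate,
    SpectrumDataset,
    StrandRole,
)
from conftest import make_event


def write(path, text):
    path.write_text(text)
    return str(path)


class TestReadLocus:
    def test_direct_read(self, tmp_path):
        p = write(tmp_path / "r.fa", ">x\nATGC\n")
        locus = core_io.read_locus(p, "OR1", "5prime")
        assert len(locus) == 4
        assert locus.orientation is Orientation.OR1
        assert locus.fork_entry is ForkEntry.FIVE_PRIME

    def test_lowercase_normalized(self, tmp_path):
        p = write(tmp_path / "r.fa", ">x\natgc\n")
        assert core_io.read_locus(p, "OR1", "5prime").coding_sequence == "ATGC"

    def test_multi_record_rejected(self, tmp_path):
        p = write(tmp_path / "r.fa", ">x\nATGC\n>y\nATGC\n")
        with pytest.raises(ValueError, match="one FASTA record"):
            core_io.read_locus(p, "OR1", "5prime")

    def test_non_acgt_names_position(self, tmp_path):
        p = write(tmp_path / "r.fa", ">x\nATNGC\n")
        with pytest.raises(ValueError, match="position 3"):
            core_io.read_locus(p, "OR1", "5prime")

    def test_locus_roundtrip(self, tmp_path, locus):
        path = tmp_path / "out.fa"
        core_io.write_locus(locus, path)
        back = core_io.read_locus(path, locus.orientation, locus.fork_entry)
        assert back.coding_sequence == locus.coding_sequence


class TestReadEvents:
    HEADER = "strain\tisolate\tposition\tref\talt\n"

    def test_classified_event(self, tmp_path, locus_c648):
        p = write(tmp_path / "e.tsv", self.HEADER + "S\ti1\t648\tC\tA\n")
        ds = core_io.read_events(p, locus_c648, n_isolates=10, overall_rate=1.0)
        (e,) = ds.events
        assert e.klass is MutationClass.SUBSTITUTION
        assert e.subtype is MutationSubtype.TRANSVERSION

    def test_ref_mismatch_names_line(self, tmp_path, locus_c648):
        p = write(tmp_path / "e.tsv", self.HEADER + "S\ti1\t648\tG\tA\n")
        with pytest.raises(ValueError, match="line 2"):
            core_io.read_events(p, locus_c648, 10, 1.0)

    def test_position_out_of_range(self, tmp_path, locus):
        p = write(tmp_path / "e.tsv", self.HEADER + f"S\ti1\t{len(locus)+1}\tA\tC\n")
        with pytest.raises(ValueError, match="outside locus"):
            core_io.read_events(p, locus, 10, 1.0)

    def test_unparsable_position_names_line(self, tmp_path, locus):
        p = write(tmp_path / "e.tsv", self.HEADER + "S\ti1\tabc\tA\tC\n")
        with pytest.raises(ValueError, match="line 2"):
            core_io.read_events(p, locus, 10, 1.0)

    def test_empty_after_header(self, tmp_path, locus):
        p = write(tmp_path / "e.tsv", self.HEADER)
        ds = core_io.read_events(p, locus, 10, 1.0)
        assert ds.events == []

    def test_dot_means_empty(self, tmp_path, locus):
        pos = 1
        p = write(tmp_path / "e.tsv",
                  self.HEADER + f"S\ti1\t{pos}\t{locus.base(pos)}\t.\n")
        ds = core_io.read_events(p, locus, 10, 1.0)
        assert ds.events[0].klass is MutationClass.SINGLE_BASE_INDEL


class TestTableRoundTrips:
    def test_strand_calls(self, tmp_path, locus_c648, pools):
        runs = repeats.annotate_runs(locus_c648.coding_sequence, 2)
        events = [
            make_event(locus_c648, 648, "C", "A"),
            make_event(locus_c648, 1, locus_c648.coding_sequence[0:2], ""),
        ]
        calls = [strandmodel.assign_event(e, locus_c648, pools, runs) for e in events]
        path = tmp_path / "calls.tsv"
        core_io.write_table(calls, path)
        assert core_io.read_table(path, type(calls[0])) == calls

    def test_site_rates_and_hotspots(self, tmp_path, summary_datasets):
        ds = summary_datasets["pool-OR1"]
        rates = spectrum.site_rates(ds)
        path = tmp_path / "sites.tsv"
        core_io.write_table(rates, path)
        assert core_io.read_table(path, SiteRate) == rates

        hits = spectrum.detect_hotspots(ds, summary_datasets["wt"])
        hpath = tmp_path / "hot.tsv"
        core_io.write_table(hits, hpath, kind=Hotspot)
        assert core_io.read_table(hpath, Hotspot) == hits

    def test_rate_estimates(self, tmp_path):
        from strandspectra.types import FluctuationExperiment

        est = fluctuation.estimate_rate(
            FluctuationExperiment((0, 1, 5, 3, 7, 2, 0, 4, 5, 6), 1e7)
        )
        path = tmp_path / "rates.tsv"
        core_io.write_table([est], path)
        (back,) = core_io.read_table(path, RateEstimate)
        assert back == est

    def test_correction_factors(self, tmp_path):
        cf = CorrectionFactor("single_base_indel", 33.7, BoundKind.EXACT,
                              1122.3, 33.3, 130, 101)
        ind = CorrectionFactor("7:X>Y", None, BoundKind.INDETERMINATE,
                               8.6, 0.33, 0, 0)
        path = tmp_path / "cf.tsv"
        core_io.write_table([cf, ind], path)
        assert core_io.read_table(path, CorrectionFactor) == [cf, ind]

    def test_runs_table(self, tmp_path, locus):
        runs = repeats.annotate_runs(locus.coding_sequence, 2)
        path = tmp_path / "runs.tsv"
        core_io.write_table(runs, path)
        assert core_io.read_table(path, HomopolymerRun) == runs

    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        core_io.write_table([], path, kind=SiteRate)
        assert core_io.read_table(path, SiteRate) == []
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["start", "end", "change", "count", "rate_x1e7", "is_bound"]

    def test_unsupported_type_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unsupported"):
            core_io.write_table([object()], tmp_path / "x.tsv")

    def test_mixed_types_rejected(self, tmp_path, locus):
        runs = repeats.annotate_runs(locus.coding_sequence, 2)
        rates = [SiteRate(1, 1, "A>C", 1, 1.0)]
        with pytest.raises(ValueError, match="single"):
            core_io.write_table(runs + rates, tmp_path / "x.tsv")


class TestCLI:
    def test_simulate_then_analyze(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "fix"
        res = runner.invoke(cli.main, [
            "--seed", "7", "simulate", "--out-dir", str(out),
            "--n-isolates", "50", "--n-cultures", "12",
        ])
        assert res.exit_code == 0, res.output
        meta = core_io.load_config(out / "metadata.yaml")

        res = runner.invoke(cli.main, [
            "rate", "--counts", str(out / "culture_counts.tsv"),
            "--n-final", str(meta["n_final"]),
            "--out", str(tmp_path / "rates.tsv"),
        ])
        assert res.exit_code == 0, res.output
        assert core_io.read_table(tmp_path / "rates.tsv", RateEstimate)

        res = runner.invoke(cli.main, [
            "spectrum", "--fasta", str(out / "reference.fasta"),
            "--events", str(out / "events_mmr_minus.tsv"),
            "--n-isolates", "50",
            "--overall-rate", str(meta["overall_rate_mmr_minus_x1e7"]),
            "--out-class-rates", str(tmp_path / "cls.tsv"),
            "--out-site-rates", str(tmp_path / "sites.tsv"),
        ])
        assert res.exit_code == 0, res.output

        res = runner.invoke(cli.main, [
            "strand", "--fasta", str(out / "reference.fasta"),
            "--events", str(out / "events_mmr_minus.tsv"),
            "--n-isolates", "50",
            "--overall-rate", str(meta["overall_rate_mmr_minus_x1e7"]),
            "--out-calls", str(tmp_path / "calls.tsv"),
            "--out-summary", str(tmp_path / "summary.tsv"),
        ])
        assert res.exit_code == 0, res.output

        res = runner.invoke(cli.main, [
            "mmr", "--fasta", str(out / "reference.fasta"),
            "--events", str(out / "events_mmr_minus.tsv"),
            "--n-isolates", "50",
            "--overall-rate", str(meta["overall_rate_mmr_minus_x1e7"]),
            "--plus-events", str(out / "events_mmr_plus.tsv"),
            "--plus-n-isolates", "50",
            "--plus-overall-rate", str(meta["overall_rate_mmr_plus_x1e7"]),
            "--out", str(tmp_path / "cf.tsv"),
        ])
        assert res.exit_code == 0, res.output

        res = runner.invoke(cli.main, [
            "runs", "--fasta", str(out / "reference.fasta"),
            "--out-runs", str(tmp_path / "runs.tsv"),
            "--out-composition", str(tmp_path / "comp.tsv"),
        ])
        assert res.exit_code == 0, res.output

    def test_config_file_prepopulates_options(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "fix"
        runner.invoke(cli.main, ["--seed", "3", "simulate", "--out-dir", str(out),
                                 "--n-isolates", "20", "--n-cultures", "8"])
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "rate:\n"
            f"  counts: {out / 'culture_counts.tsv'}\n"
            "  n_final: 16384000\n"
            f"  out: {tmp_path / 'rates.tsv'}\n"
        )
        res = runner.invoke(cli.main, ["--config", str(cfg), "rate"])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "rates.tsv").exists()
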