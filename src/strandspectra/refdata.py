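"""Bundled summary counts for the CAN1 pool-imbalance experiment.

These are the published per-strain totals — overall rate, isolates
sequenced, and events per mutation class — for the wild type, the
pyrimidine pool-imbalanced reporter in both orientations, the MMR-null
strain, and the double mutant.  They are inputs, not results: the raw
culture counts and per-site event lists behind them were never deposited,
so analyses that only need class-level totals run from this table.

``dataset_from_summary`` expands a summary into a SpectrumDataset whose
event *positions are synthetic* (placed on a fixture locus); only the
class counts, isolate number and overall rate are real.  Anything
position-sensitive must not be computed from such a dataset, with one
documented exception: ``indel_run_fixture`` places single-base indels so
that the published in-run/out-of-run split is preserved, making the
run-fraction summary computable.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import repeats, synthetic_data
from .types import (
    MutationClass,
    MutationEvent,
    ReporterLocus,
    SpectrumDataset,
)
from .spectrum import classify_event


@dataclass(frozen=True)
class StrainSummary:
    """Published per-strain totals: rate on the 1e-7 scale, 95% CI,
    isolates sequenced, and events per class."""

    strain: str
    overall_rate: float
    ci: tuple[float, float]
    n_isolates: int
    substitutions: int
    single_base_indels: int
    complex_events: int
    pool_imbalanced: bool
    mmr_deficient: bool

    @property
    def total_events(self) -> int:
        return self.substitutions + self.single_base_indels + self.complex_events


STRAIN_SUMMARIES: dict[str, StrainSummary] = {
    "wt": StrainSummary("wt", 4.2, (1.6, 4.4), 93, 65, 11, 17, False, False),
    "pool-OR1": StrainSummary("pool-OR1", 57.0, (43, 103), 173, 72, 101, 0, True, False),
    "pool-OR2": StrainSummary("pool-OR2", 60.0, (40, 108), 170, 80, 104, 0, True, False),
    "mmr-null": StrainSummary("mmr-null", 66.0, (53.4, 90), 164, 62, 106, 1, False, True),
    "pool-mmr-null": StrainSummary(
        "pool-mmr-null", 2236.0, (1883, 3272), 259, 131, 130, 3, True, True
    ),
}

#: Double mutant: published split of single-base indels into those inside
#: mononucleotide runs of length >= 3 versus all single-base indels
#: considered for that summary (127 of 128).
DOUBLE_MUTANT_INDELS_IN_RUNS = (127, 128)

#: MMR-null single mutant: same fraction, 91%.
MMR_NULL_INDEL_RUN_FRACTION = 0.91


def _positions_cycle(positions: list[int]):
    i = 0
    while True:
        yield positions[i % len(positions)]
        i += 1


def _build_events(
    strain: str,
    locus: ReporterLocus,
    n_sub: int,
    n_indel: int,
    n_complex: int,
    n_isolates: int,
    indel_positions: list[int] | None = None,
) -> list[MutationEvent]:
    seq = locus.coding_sequence
    runs = repeats.annotate_runs(seq, min_len=3)
    run_positions = [r.start for r in runs] or [1]
    if indel_positions is None:
        indel_positions = run_positions
    sub_positions = [
        p for p in range(1, len(seq)) if repeats.run_containing(runs, p) is None
    ] or [1]
    events: list[MutationEvent] = []

    def add(position: int, ref: str, alt: str) -> None:
        klass, subtype = classify_event(ref, alt)
        isolate = f"iso{(len(events) % n_isolates) + 1}"
        events.append(
            MutationEvent(strain, isolate, position, ref, alt, klass, subtype)
        )

    gen = _positions_cycle(sub_positions)
    for _ in range(n_sub):
        p = next(gen)
        ref = seq[p - 1]
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
        add(p, ref, alt)
    gen = _positions_cycle(indel_positions)
    for _ in range(n_indel):
        p = next(gen)
        add(p, seq[p - 1], "")
    gen = _positions_cycle(sub_positions)
    for _ in range(n_complex):
        p = next(gen)
        add(p, seq[p - 1 : p + 1], "")
    return events


def reference_locus() -> ReporterLocus:
    """Deterministic fixture locus used to host the synthetic placements."""
    return synthetic_data.fixture_locus(1000, seed=11, name="reporter-fixture")


def dataset_from_summary(
    name: str, locus: ReporterLocus | None = None
) -> SpectrumDataset:
    """Expand a strain summary into a dataset with synthetic positions."""
    s = STRAIN_SUMMARIES[name]
    if locus is None:
        locus = reference_locus()
    events = _build_events(
        s.strain, locus, s.substitutions, s.single_base_indels, s.complex_events,
        s.n_isolates,
    )
    return SpectrumDataset(
        strain=s.strain, locus=locus, events=events,
        n_isolates=s.n_isolates, overall_rate=s.overall_rate,
        pool_imbalanced=s.pool_imbalanced, mmr_deficient=s.mmr_deficient,
    )


def indel_run_fixture(locus: ReporterLocus | None = None) -> SpectrumDataset:
    """Double-mutant indel set honoring the published in-run split.

    Synthetic placement: of the 128 single-base indels in the published
    summary, 127 are placed inside mononucleotide runs of length >= 3 and
    one outside any such run.
    """
    if locus is None:
        locus = reference_locus()
    seq = locus.coding_sequence
    runs = repeats.annotate_runs(seq, min_len=3)
    in_run, total = DOUBLE_MUTANT_INDELS_IN_RUNS
    run_positions = [r.start for r in runs]
    # a position in no run of length >= 3 (and not adjacent to one)
    all2 = repeats.annotate_runs(seq, min_len=2)
    outside = next(
        p for p in range(1, len(seq) + 1)
        if repeats.run_containing(runs, p) is None
        and repeats.run_containing(all2, p) is None
    )
    s = STRAIN_SUMMARIES["pool-mmr-null"]
    events = _build_events(
        s.strain, locus, 0, in_run, 0, s.n_isolates, indel_positions=run_positions
    )
    out_events = _build_events(s.strain, locus, 0, total - in_run, 0,
                               s.n_isolates, indel_positions=[outside])
    return SpectrumDataset(
        strain=s.strain, locus=locus, events=events + out_events,
        n_isolates=s.n_isolates, overall_rate=s.overall_rate,
        pool_imbalanced=True, mmr_deficient=True,
    )
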