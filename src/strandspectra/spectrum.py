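"""Mutation classification, class/site-specific rates, and hotspot calls.

Rates follow the standard reporter-gene bookkeeping: a class or site rate
is (events / isolates sequenced) x overall locus rate.  The denominator is
the number of isolates sequenced, not total mutations — the two differ
when isolates carry several mutations — because the published worked class
rates only reproduce with the isolate denominator.

A site with zero observed events is not assigned rate zero but the
one-event upper bound (1 / isolates) x overall rate, printed with '<'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from . import repeats
from .types import (
    Hotspot,
    HomopolymerRun,
    MutationClass,
    MutationEvent,
    MutationSubtype,
    PURINES,
    SiteRate,
    SpectrumDataset,
)

log = logging.getLogger(__name__)

#: Fold-over-wild-type threshold defining a hotspot.
HOTSPOT_FOLD = 10.0


def classify_event(ref: str, alt: str) -> tuple[MutationClass, MutationSubtype]:
    """Classify a ref->alt change.

    Single-base substitutions split into transitions (purine<->purine or
    pyrimidine<->pyrimidine) and transversions; single-base indels into
    insertions and deletions; everything longer is complex/other.
    """
    for s in (ref, alt):
        if any(b not in "ACGT" for b in s):
            raise ValueError(f"ref/alt must be ACGT or empty, got {s!r}")
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref!r}): not a mutation")
    if len(ref) == 1 and len(alt) == 1:
        same_family = (ref in PURINES) == (alt in PURINES)
        sub = MutationSubtype.TRANSITION if same_family else MutationSubtype.TRANSVERSION
        return MutationClass.SUBSTITUTION, sub
    if abs(len(ref) - len(alt)) == 1 and min(len(ref), len(alt)) == 0:
        sub = MutationSubtype.INSERTION if len(alt) == 1 else MutationSubtype.DELETION
        return MutationClass.SINGLE_BASE_INDEL, sub
    return MutationClass.COMPLEX, MutationSubtype.OTHER


def class_rate(dataset: SpectrumDataset, klass: MutationClass) -> float:
    """(events of class / isolates sequenced) x overall rate, 1e-7 scale."""
    if dataset.n_isolates <= 0:
        raise ValueError("dataset has no sequenced isolates")
    count = len(dataset.events_of_class(klass))
    return count / dataset.n_isolates * dataset.overall_rate


def one_event_bound(dataset: SpectrumDataset) -> float:
    """Rate a single observed event would imply: the '<' bound used for
    zero-observation sites."""
    if dataset.n_isolates <= 0:
        raise ValueError("dataset has no sequenced isolates")
    return 1.0 / dataset.n_isolates * dataset.overall_rate


def _site_key(event: MutationEvent, runs: Sequence[HomopolymerRun]) -> tuple[int, int, str]:
    """Aggregation key for an event.

    Single-base indels inside a homopolymer run take the run's full span
    and a base-level descriptor (the deleted/inserted base cannot be
    localized within a run); substitutions and complex events keep their
    own coordinates and are never pooled across positions.
    """
    if event.klass is MutationClass.SINGLE_BASE_INDEL:
        run = repeats.run_containing(runs, event.position)
        base = event.ref or event.alt
        op = "del" if event.ref else "ins"
        if run is not None and run.base == base:
            return (run.start, run.end, f"{op}{base}")
        return (event.position, event.position, f"{op}{base}")
    end = event.position + max(len(event.ref), 1) - 1
    return (event.position, end, event.change)


def site_rates(
    dataset: SpectrumDataset,
    runs: Sequence[HomopolymerRun] | None = None,
) -> list[SiteRate]:
    """One SiteRate per distinct (site-or-run, change), sorted by position."""
    if runs is None:
        runs = repeats.annotate_runs(dataset.locus.coding_sequence, min_len=2)
    groups: dict[tuple[int, int, str], int] = {}
    for e in dataset.events:
        key = _site_key(e, runs)
        groups[key] = groups.get(key, 0) + 1
    out = [
        SiteRate(
            start=start,
            end=end,
            change=change,
            count=count,
            rate=count / dataset.n_isolates * dataset.overall_rate,
            is_bound=False,
        )
        for (start, end, change), count in groups.items()
    ]
    out.sort(key=lambda s: s.key)
    return out


def _rate_lookup(
    rates: Sequence[SiteRate], key: tuple[int, int, str], bound: float
) -> tuple[float, bool, int]:
    """(rate, is_bound, count) for a site key, substituting the one-event
    bound when the dataset saw nothing there."""
    for sr in rates:
        if sr.key == key:
            return sr.rate, False, sr.count
    return bound, True, 0


def detect_hotspots(
    dataset: SpectrumDataset,
    wt_dataset: SpectrumDataset,
    fold_threshold: float = HOTSPOT_FOLD,
) -> list[Hotspot]:
    """Sites whose rate is >= ``fold_threshold``-fold the wild-type rate.

    Wild-type sites with zero events use the one-event bound as the
    denominator, which is conservative (the true fold can only be larger).
    The threshold is inclusive.
    """
    if dataset.locus.coding_sequence != wt_dataset.locus.coding_sequence:
        raise ValueError("datasets must share the same reporter sequence")
    runs = repeats.annotate_runs(dataset.locus.coding_sequence, min_len=2)
    wt_rates = site_rates(wt_dataset, runs)
    wt_bound = one_event_bound(wt_dataset)
    hotspots = []
    for sr in site_rates(dataset, runs):
        wt_rate, wt_is_bound, _ = _rate_lookup(wt_rates, sr.key, wt_bound)
        fold = sr.rate / wt_rate
        if fold >= fold_threshold:
            hotspots.append(
                Hotspot(
                    strain=dataset.strain,
                    site=sr,
                    wt_rate=wt_rate,
                    wt_is_bound=wt_is_bound,
                    fold_over_wt=fold,
                )
            )
    log.info(
        "%s: %d hotspot(s) at >=%g-fold over %s among %d sites",
        dataset.strain, len(hotspots), fold_threshold, wt_dataset.strain,
        len(site_rates(dataset, runs)),
    )
    return hotspots


@dataclass(frozen=True)
class OrientationComparison:
    """Rates for one site in the two reporter orientations.

    ``fold`` is the larger rate over the smaller; when the smaller side is
    a one-event bound the fold is itself a lower bound ('>=').
    """

    start: int
    end: int
    change: str
    rate_or1: float
    rate_or2: float
    or1_is_bound: bool
    or2_is_bound: bool
    fold: float
    higher: str  # "OR1", "OR2" or "equal"
    fold_is_bound: bool


def compare_orientations(
    dataset_or1: SpectrumDataset,
    dataset_or2: SpectrumDataset,
    wt_dataset: SpectrumDataset | None = None,
    fold_threshold: float = HOTSPOT_FOLD,
) -> list[OrientationComparison]:
    """Per-site rate comparison between the two reporter orientations.

    Sites compared are the union of hotspot sites of both strains (when a
    wild-type baseline is supplied) or of all observed sites otherwise; a
    side with zero events contributes its one-event bound, flagged.
    """
    if dataset_or1.locus.coding_sequence != dataset_or2.locus.coding_sequence:
        raise ValueError("datasets must share the same reporter sequence")
    if dataset_or1.locus.orientation == dataset_or2.locus.orientation:
        raise ValueError("datasets must have opposite orientations")
    runs = repeats.annotate_runs(dataset_or1.locus.coding_sequence, min_len=2)
    r1 = site_rates(dataset_or1, runs)
    r2 = site_rates(dataset_or2, runs)
    if wt_dataset is not None:
        keys = {h.site.key for h in detect_hotspots(dataset_or1, wt_dataset, fold_threshold)}
        keys |= {h.site.key for h in detect_hotspots(dataset_or2, wt_dataset, fold_threshold)}
    else:
        keys = {sr.key for sr in r1} | {sr.key for sr in r2}
    b1, b2 = one_event_bound(dataset_or1), one_event_bound(dataset_or2)
    rows = []
    for key in sorted(keys):
        v1, bound1, _ = _rate_lookup(r1, key, b1)
        v2, bound2, _ = _rate_lookup(r2, key, b2)
        hi, lo = max(v1, v2), min(v1, v2)
        higher = "equal" if v1 == v2 else ("OR1" if v1 > v2 else "OR2")
        lo_is_bound = bound1 if higher == "OR2" else bound2 if higher == "OR1" else False
        rows.append(
            OrientationComparison(
                start=key[0], end=key[1], change=key[2],
                rate_or1=v1, rate_or2=v2,
                or1_is_bound=bound1, or2_is_bound=bound2,
                fold=hi / lo, higher=higher, fold_is_bound=lo_is_bound,
            )
        )
    return rows
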