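"""Homopolymer-run annotation and repeat-length analyses.

Mononucleotide runs are hotspots for strand-slippage indels, with the
indel rate rising roughly exponentially in run length.  Runs are computed
on the coding strand; a G-run and its complementary C-run are the same
physical site and are reported once, with the coding-strand base.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .types import HomopolymerRun, MutationClass, MutationEvent, SiteRate, SpectrumDataset

log = logging.getLogger(__name__)


def annotate_runs(sequence: str, min_len: int = 2) -> list[HomopolymerRun]:
    """All maximal homopolymer runs of length >= ``min_len``, sorted by start.

    Positions are 1-based.  ``min_len`` defaults to 2 so that thresholds
    (e.g. the >=3 cutoff used for the headline indel fraction) remain
    analysis-time choices.
    """
    if any(b not in "ACGT" for b in sequence):
        raise ValueError("sequence must be strictly ACGT")
    runs: list[HomopolymerRun] = []
    i = 0
    n = len(sequence)
    while i < n:
        j = i
        while j + 1 < n and sequence[j + 1] == sequence[i]:
            j += 1
        length = j - i + 1
        if length >= min_len:
            runs.append(HomopolymerRun(start=i + 1, length=length, base=sequence[i]))
        i = j + 1
    return runs


def run_containing(runs: Sequence[HomopolymerRun], position: int) -> HomopolymerRun | None:
    """The run covering a 1-based position, or None."""
    for r in runs:
        if r.contains(position):
            return r
    return None


def fraction_in_runs(
    dataset: SpectrumDataset,
    runs: Sequence[HomopolymerRun] | None = None,
    min_len: int = 3,
) -> tuple[int, int, float | None]:
    """(k, n, k/n): single-base indels inside runs of length >= min_len.

    Returns fraction ``None`` when the dataset has no single-base indels.
    """
    if runs is None:
        runs = annotate_runs(dataset.locus.coding_sequence, min_len=2)
    eligible = [r for r in runs if r.length >= min_len]
    indels = dataset.events_of_class(MutationClass.SINGLE_BASE_INDEL)
    n = len(indels)
    if n == 0:
        return 0, 0, None
    k = sum(1 for e in indels if run_containing(eligible, e.position) is not None)
    frac = k / n
    log.info("%d of %d single-base indels fall in runs >= %d (%.1f%%)",
             k, n, min_len, 100 * frac)
    return k, n, frac


@dataclass(frozen=True)
class RunLengthFit:
    """Least-squares fit of ln(rate) against run length."""

    slope: float
    intercept: float
    lengths: tuple[int, ...]
    rates: tuple[float, ...]


def run_length_rate_relation(
    site_rates: Iterable[SiteRate],
    runs: Sequence[HomopolymerRun],
    aggregate: str = "sum",
) -> RunLengthFit:
    """Aggregate indel site rates by run length and fit ln(rate) ~ length.

    ``aggregate`` is "sum" (default) or "mean" of the site rates sharing a
    run length.  A positive slope indicates the expected exponential
    increase of slippage rate with repeat length; the fit is reported, not
    enforced.
    """
    if aggregate not in ("sum", "mean"):
        raise ValueError("aggregate must be 'sum' or 'mean'")
    by_len: dict[int, list[float]] = {}
    for sr in site_rates:
        if sr.is_bound or sr.rate <= 0:
            continue
        run = next((r for r in runs if r.start == sr.start and r.end == sr.end), None)
        if run is None:
            run = run_containing(runs, sr.start)
        if run is None:
            continue
        by_len.setdefault(run.length, []).append(sr.rate)
    agg = {
        L: (sum(v) if aggregate == "sum" else sum(v) / len(v)) for L, v in by_len.items()
    }
    agg = {L: r for L, r in agg.items() if r > 0}
    if len(agg) < 2:
        raise ValueError("need >= 2 distinct run lengths with nonzero rates to fit")
    lengths = sorted(agg)
    y = np.log([agg[L] for L in lengths])
    slope, intercept = np.polyfit(np.asarray(lengths, dtype=float), y, 1)
    return RunLengthFit(
        slope=float(slope),
        intercept=float(intercept),
        lengths=tuple(lengths),
        rates=tuple(agg[L] for L in lengths),
    )


def base_composition(sequence: str) -> dict[str, dict[str, float]]:
    """Per-base counts and fractions; counts sum to the sequence length."""
    if any(b not in "ACGT" for b in sequence):
        raise ValueError("sequence must be strictly ACGT")
    counts = {b: sequence.count(b) for b in "ACGT"}
    n = len(sequence)
    return {
        "counts": {b: float(c) for b, c in counts.items()},
        "fractions": {b: (c / n if n else 0.0) for b, c in counts.items()},
    }
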