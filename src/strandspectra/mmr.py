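"""Mismatch-repair correction efficiency.

The correction factor (CF) for a site or mutation class is the ratio of
its mutation rate in an MMR-deficient (msh2-null) background to the rate
in the matched MMR-proficient background: a CF of 32 means 31 of 32
errors of that kind are normally corrected.  Zero-event sides use the
one-event bound and propagate a bound flag; a 0/0 comparison is reported
as indeterminate rather than a number.
"""

from __future__ import annotations

import logging
from typing import Sequence

from . import repeats, spectrum
from .types import (
    BoundKind,
    CorrectionFactor,
    MutationClass,
    SpectrumDataset,
)

log = logging.getLogger(__name__)

Scope = MutationClass | tuple[int, int, str]


def _scope_rate(dataset: SpectrumDataset, scope: Scope) -> tuple[float, bool, int, str]:
    """(rate, is_bound, count, label) for a class or site scope."""
    if isinstance(scope, MutationClass):
        count = len(dataset.events_of_class(scope))
        label = scope.value
        if count == 0:
            return spectrum.one_event_bound(dataset), True, 0, label
        return spectrum.class_rate(dataset, scope), False, count, label
    runs = repeats.annotate_runs(dataset.locus.coding_sequence, min_len=2)
    rates = spectrum.site_rates(dataset, runs)
    bound = spectrum.one_event_bound(dataset)
    rate, is_bound, count = spectrum._rate_lookup(rates, scope, bound)
    start, end, change = scope
    label = f"{start}-{end}:{change}" if start != end else f"{start}:{change}"
    return rate, is_bound, count, label


def correction_factor(
    scope: Scope,
    dataset_mmr_minus: SpectrumDataset,
    dataset_mmr_plus: SpectrumDataset,
) -> CorrectionFactor:
    """CF = rate(MMR-deficient) / rate(MMR-proficient) for a site or class.

    A zero-event MMR-deficient side makes the CF an upper bound; a
    zero-event MMR-proficient side makes it a lower bound; both zero make
    it indeterminate (counts reported, no number invented).
    """
    if dataset_mmr_minus.locus.coding_sequence != dataset_mmr_plus.locus.coding_sequence:
        raise ValueError("datasets must share the same reporter sequence")
    if not dataset_mmr_minus.mmr_deficient:
        raise ValueError("numerator dataset must be MMR-deficient")
    if dataset_mmr_plus.mmr_deficient:
        raise ValueError("denominator dataset must be MMR-proficient")
    num, num_bound, num_count, label = _scope_rate(dataset_mmr_minus, scope)
    den, den_bound, den_count, _ = _scope_rate(dataset_mmr_plus, scope)
    if num_bound and den_bound:
        return CorrectionFactor(
            scope=label, cf=None, bound=BoundKind.INDETERMINATE,
            numerator_rate=num, denominator_rate=den,
            numerator_count=0, denominator_count=0,
        )
    if num_bound:
        bound = BoundKind.UPPER_BOUND
    elif den_bound:
        bound = BoundKind.LOWER_BOUND
    else:
        bound = BoundKind.EXACT
    cf = num / den
    log.info("CF(%s) = %.3g (%s): %.3g / %.3g x1e-7", label, cf, bound.value, num, den)
    return CorrectionFactor(
        scope=label, cf=cf, bound=bound,
        numerator_rate=num, denominator_rate=den,
        numerator_count=num_count, denominator_count=den_count,
    )


def cf_ratio(a: CorrectionFactor, b: CorrectionFactor) -> tuple[float, BoundKind]:
    """Ratio a.cf / b.cf across backgrounds, carrying the weaker bound.

    Exact beats a one-sided bound; any one-sided bound beats indeterminate.
    """
    if a.cf is None or b.cf is None:
        raise ValueError("cannot form a ratio with an indeterminate CF")
    strength = {
        BoundKind.EXACT: 0,
        BoundKind.LOWER_BOUND: 1,
        BoundKind.UPPER_BOUND: 1,
        BoundKind.INDETERMINATE: 2,
    }
    weaker = a.bound if strength[a.bound] >= strength[b.bound] else b.bound
    return a.cf / b.cf, weaker


def classify_hotspot_origin(
    in_pool_mutant: bool,
    in_mmr_mutant: bool,
    in_double_mutant: bool,
) -> str | None:
    """Speculative origin of a double-mutant hotspot.

    ``mmr_driven``: hotspot only in the MMR-deficient single mutant (its
    existence reflects loss of repair, enhanced by the pool imbalance);
    ``pool_driven``: only in the pool-imbalanced single mutant (enhanced
    by loss of MMR); ``synergistic``: in both singles.  Sites that are not
    double-mutant hotspots are excluded (None).
    """
    if not in_double_mutant:
        log.info("site not a double-mutant hotspot: excluded from classification")
        return None
    if in_mmr_mutant and in_pool_mutant:
        return "synergistic"
    if in_mmr_mutant:
        return "mmr_driven"
    if in_pool_mutant:
        return "pool_driven"
    return None


def hotspot_origin_table(
    hotspots_pool: Sequence, hotspots_mmr: Sequence, hotspots_double: Sequence
) -> dict[tuple[int, int, str], str | None]:
    """Origin classification for every double-mutant hotspot site."""
    keys_pool = {h.site.key for h in hotspots_pool}
    keys_mmr = {h.site.key for h in hotspots_mmr}
    out = {}
    for h in hotspots_double:
        k = h.site.key
        out[k] = classify_hotspot_origin(k in keys_pool, k in keys_mmr, True)
    return out
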