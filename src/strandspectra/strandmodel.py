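"""Assignment of mutations to leading- or lagging-strand synthesis.

The model: a replication fork enters the reporter from the end nearest
the origin and traverses it once.  The nascent leading strand is
synthesized in the direction of fork movement, so its template is the
strand read 3'->5' along that direction; inverting the gene relative to
the origin swaps the roles of the two strands.

Under a known dNTP pool imbalance, each observed substitution admits two
mechanistic explanations — a misinsertion on the coding-strand template or
on the noncoding-strand template — that implicate different dNTPs.  When
exactly one of the implicated dNTPs is in excess, the error is attributed
to the polymerase copying that template, hence to a strand.  Single-base
indels in homopolymer runs are assigned by the nucleotide incorporated
immediately past the run, whose excess stabilizes the slipped
intermediate.  Ambiguous events are unassigned: that is a first-class
result, not an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from . import repeats
from .types import (
    DNTPPools,
    ForkEntry,
    HomopolymerRun,
    MutationClass,
    MutationEvent,
    MutationSubtype,
    ReporterLocus,
    StrandCall,
    StrandRole,
    TemplateStrand,
    complement,
)

log = logging.getLogger(__name__)


def template_roles(locus: ReporterLocus) -> dict[TemplateStrand, StrandRole]:
    """Which strand templates leading vs lagging synthesis.

    Derivation: with the fork entering at the coding strand's 5' end, the
    fork moves in the coding strand's 5'->3' direction; the leading-strand
    template must be read 3'->5' in that direction, which is the
    noncoding strand.  Fork entry at the 3' end swaps the roles.
    """
    if locus.fork_entry is ForkEntry.FIVE_PRIME:
        return {
            TemplateStrand.CODING: StrandRole.LAGGING,
            TemplateStrand.NONCODING: StrandRole.LEADING,
        }
    return {
        TemplateStrand.CODING: StrandRole.LEADING,
        TemplateStrand.NONCODING: StrandRole.LAGGING,
    }


@dataclass(frozen=True)
class MisinsertionCandidate:
    """One of the two mechanistic explanations of a substitution."""

    template_strand: TemplateStrand
    template_base: str
    misinserted: str  # the dNTP whose misinsertion produces the change


def substitution_candidates(
    event: MutationEvent, locus: ReporterLocus
) -> tuple[MisinsertionCandidate, MisinsertionCandidate]:
    """The two misinsertion explanations of a coding-strand change X->Y.

    Copying the coding strand, the nascent base opposite template X became
    complement(Y); copying the noncoding strand (template complement(X)),
    the nascent base became Y.
    """
    if event.klass is not MutationClass.SUBSTITUTION:
        raise ValueError("substitution_candidates requires a substitution event")
    x, y = event.ref, event.alt
    if locus.base(event.position) != x:
        raise ValueError(
            f"event ref {x!r} does not match locus base at {event.position}"
        )
    return (
        MisinsertionCandidate(TemplateStrand.CODING, x, complement(y)),
        MisinsertionCandidate(TemplateStrand.NONCODING, complement(x), y),
    )


def assign_substitution(
    event: MutationEvent, locus: ReporterLocus, pools: DNTPPools
) -> StrandCall:
    """Strand call for a substitution under the pool imbalance.

    Candidates whose misinserted dNTP is in the excess set survive; a
    unique survivor names the template strand and, via the fork geometry,
    the strand whose synthesis made the error.
    """
    excess = pools.excess_set
    cands = substitution_candidates(event, locus)
    survivors = [c for c in cands if c.misinserted in excess]
    roles = template_roles(locus)
    if len(survivors) == 1:
        c = survivors[0]
        return StrandCall(
            event=event,
            call=roles[c.template_strand],
            template_strand=c.template_strand,
            implicated_dntp=c.misinserted,
            rationale=(
                f"d{c.misinserted}TP (in excess) misinserted opposite template "
                f"{c.template_base} on the {c.template_strand.value} strand"
            ),
        )
    reason = (
        "no candidate misinsertion uses an excess dNTP"
        if not survivors
        else "both candidate misinsertions use excess dNTPs"
    )
    return StrandCall(event, StrandRole.UNASSIGNED, None, None, reason)


def _next_dntp_past_run(
    run: HomopolymerRun, locus: ReporterLocus, template: TemplateStrand
) -> str | None:
    """The dNTP incorporated immediately after a polymerase crosses the
    run, for the given template strand; None at a sequence boundary.

    Reading the coding template 3'->5' means traversing coding positions
    downward, so the base past the run is its 5' flank (start-1); on the
    noncoding template synthesis traverses coding positions upward and the
    next incorporated base equals the coding base at end+1.
    """
    if template is TemplateStrand.CODING:
        if run.start <= 1:
            return None
        return complement(locus.base(run.start - 1))
    if run.end >= len(locus):
        return None
    return locus.base(run.end + 1)


def assign_run_indel(
    event: MutationEvent,
    locus: ReporterLocus,
    pools: DNTPPools,
    runs: Sequence[HomopolymerRun] | None = None,
) -> StrandCall:
    """Strand call for a single-base indel inside a homopolymer run.

    For each strand the nucleotide incorporated just past the run is
    computed; strands whose next dNTP is in excess could have stabilized
    the slipped intermediate by rapid extension.  A unique qualifying
    strand yields a call; zero or two yield unassigned.
    """
    if event.klass is not MutationClass.SINGLE_BASE_INDEL:
        raise ValueError("assign_run_indel requires a single-base indel event")
    if runs is None:
        runs = repeats.annotate_runs(locus.coding_sequence, min_len=2)
    run = repeats.run_containing(runs, event.position)
    if run is None:
        return StrandCall(event, StrandRole.UNASSIGNED, None, None, "no run context")
    excess = pools.excess_set
    roles = template_roles(locus)
    qualifying: list[tuple[TemplateStrand, str]] = []
    for template in (TemplateStrand.CODING, TemplateStrand.NONCODING):
        nxt = _next_dntp_past_run(run, locus, template)
        if nxt is not None and nxt in excess:
            qualifying.append((template, nxt))
    if len(qualifying) == 1:
        template, nxt = qualifying[0]
        return StrandCall(
            event=event,
            call=roles[template],
            template_strand=template,
            implicated_dntp=nxt,
            rationale=(
                f"slippage in {run.base}-run {run.start}-{run.end} stabilized by "
                f"excess d{nxt}TP incorporated past the run on the "
                f"{template.value} template"
            ),
        )
    reason = (
        "neither strand's next nucleotide past the run is in excess"
        if not qualifying
        else "both strands' next nucleotides past the run are in excess"
    )
    return StrandCall(event, StrandRole.UNASSIGNED, None, None, reason)


def assign_event(
    event: MutationEvent,
    locus: ReporterLocus,
    pools: DNTPPools,
    runs: Sequence[HomopolymerRun] | None = None,
) -> StrandCall:
    """Dispatch on mutation class; complex events are always unassigned."""
    if event.klass is MutationClass.SUBSTITUTION:
        return assign_substitution(event, locus, pools)
    if event.klass is MutationClass.SINGLE_BASE_INDEL:
        return assign_run_indel(event, locus, pools, runs)
    return StrandCall(
        event, StrandRole.UNASSIGNED, None, None, "complex event: not modeled"
    )


def assignment_table(
    pools: DNTPPools, locus: ReporterLocus | None = None
) -> dict[tuple[str, str], StrandCall]:
    """Exhaustive audit: every ordered substitution X->Y mapped to its call.

    With a strictly pyrimidine (or strictly purine) excess set every one
    of the 12 substitution types is uniquely assigned, because
    complementation swaps purines and pyrimidines between the two
    candidate misinsertions.
    """
    from .types import Orientation

    if locus is None:
        locus = ReporterLocus(
            "audit", "ACGT", Orientation.OR1, ForkEntry.FIVE_PRIME
        )
    pos_of = {b: i + 1 for i, b in enumerate(locus.coding_sequence[:4])}
    table = {}
    for x in "ACGT":
        for y in "ACGT":
            if x == y:
                continue
            position = pos_of.get(x) or locus.coding_sequence.index(x) + 1
            ev = MutationEvent(
                strain="audit", isolate="audit", position=position,
                ref=x, alt=y,
                klass=MutationClass.SUBSTITUTION,
                subtype=MutationSubtype.TRANSVERSION,  # subtype irrelevant here
            )
            table[(x, y)] = assign_substitution(ev, locus, pools)
    return table


def summarize_calls(calls: Sequence[StrandCall]) -> dict[str, int]:
    """Counts of leading / lagging / unassigned among a set of calls."""
    out = {r.value: 0 for r in StrandRole}
    for c in calls:
        out[c.call.value] += 1
    return out
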