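"""Domain types shared across the pipeline.

Coordinates are 1-based, inclusive, on the coding strand throughout the
package; multi-base sites (homopolymer runs) are carried as start-end spans.
Mutation rates are carried internally in units of 1e-7 per locus per
generation, the scale on which reporter-gene rates are conventionally
printed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: Scale factor between the internal rate unit and absolute rate per
#: locus per generation: internal 1.0 == 1e-7 / locus / generation.
RATE_SCALE = 1e-7


def complement(base: str) -> str:
    return COMPLEMENT[base]


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class Orientation(str, enum.Enum):
    """Reporter orientation relative to the replication origin.

    OR1 is the natural orientation; OR2 is the gene inverted in place,
    which swaps which strand serves as the leading-strand template.
    """

    OR1 = "OR1"
    OR2 = "OR2"


class ForkEntry(str, enum.Enum):
    """Which end of the coding strand the replication fork enters first."""

    FIVE_PRIME = "5prime"
    THREE_PRIME = "3prime"


class MutationClass(str, enum.Enum):
    SUBSTITUTION = "substitution"
    SINGLE_BASE_INDEL = "single_base_indel"
    COMPLEX = "complex"


class MutationSubtype(str, enum.Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"
    INSERTION = "insertion"
    DELETION = "deletion"
    OTHER = "other"


class StrandRole(str, enum.Enum):
    LEADING = "leading"
    LAGGING = "lagging"
    UNASSIGNED = "unassigned"


class TemplateStrand(str, enum.Enum):
    CODING = "coding"
    NONCODING = "noncoding"


class BoundKind(str, enum.Enum):
    EXACT = "exact"
    LOWER_BOUND = "lower_bound"
    UPPER_BOUND = "upper_bound"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ReporterLocus:
    """A forward-mutation reporter gene with replication-fork metadata.

    ``fork_entry`` names the coding-strand end nearest the replication
    origin; together with the sequence it determines which strand is the
    leading-strand template (see :mod:`strandspectra.strandmodel`).
    """

    name: str
    coding_sequence: str
    orientation: Orientation
    fork_entry: ForkEntry

    def __post_init__(self) -> None:
        if not self.coding_sequence:
            raise ValueError("coding_sequence must be non-empty")
        for i, b in enumerate(self.coding_sequence, start=1):
            if b not in "ACGT":
                raise ValueError(
                    f"non-ACGT character {b!r} at position {i} in locus "
                    f"{self.name!r}"
                )

    def __len__(self) -> int:
        return len(self.coding_sequence)

    def base(self, position: int) -> str:
        """Coding-strand base at a 1-based position."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside locus of length {len(self)}")
        return self.coding_sequence[position - 1]

    def flipped(self) -> "ReporterLocus":
        """The same physical locus with the gene inverted relative to the
        origin: orientation label and fork entry both switch."""
        return replace(
            self,
            orientation=(
                Orientation.OR2 if self.orientation is Orientation.OR1 else Orientation.OR1
            ),
            fork_entry=(
                ForkEntry.THREE_PRIME
                if self.fork_entry is ForkEntry.FIVE_PRIME
                else ForkEntry.FIVE_PRIME
            ),
        )


@dataclass(frozen=True)
class MutationEvent:
    """One observed change in one isolate, in coding-strand coordinates.

    ``ref``/``alt`` may be empty (insertions/deletions).  ``position`` is
    the 1-based first affected base; for an insertion it is the base after
    which material is inserted.
    """

    strain: str
    isolate: str
    position: int
    ref: str
    alt: str
    klass: MutationClass
    subtype: MutationSubtype

    @property
    def change(self) -> str:
        """Compact ref>alt descriptor, '.' for an empty side."""
        return f"{self.ref or '.'}>{self.alt or '.'}"


@dataclass(frozen=True)
class DNTPPools:
    """dNTP abundances as fold change over wild type.

    The excess set E is every nucleotide whose fold change is at least
    ``excess_threshold``; with the pool imbalance studied here
    (dCTP ~26x, dTTP ~14x, dATP ~2x, dGTP ~1x) the default threshold of 5
    yields E = {C, T}.
    """

    fold_over_wt: Mapping[str, float]
    excess_threshold: float = 5.0

    def __post_init__(self) -> None:
        missing = set("ACGT") - set(self.fold_over_wt)
        if missing:
            raise ValueError(f"fold_over_wt missing nucleotides: {sorted(missing)}")
        if any(v <= 0 for v in self.fold_over_wt.values()):
            raise ValueError("fold changes must be positive")
        if self.excess_threshold <= 0:
            raise ValueError("excess_threshold must be positive")

    @property
    def excess_set(self) -> frozenset[str]:
        return frozenset(
            n for n, f in self.fold_over_wt.items() if f >= self.excess_threshold
        )


#: Pool imbalance of the ribonucleotide-reductase allosteric mutant:
#: elevated pyrimidine pools, near-normal purine pools.
RNR1_Y285A_POOLS = DNTPPools({"A": 2.0, "C": 26.0, "G": 1.0, "T": 14.0})

#: Balanced pools (every fold change 1): nothing is in excess.
WT_POOLS = DNTPPools({"A": 1.0, "C": 1.0, "G": 1.0, "T": 1.0})


@dataclass
class SpectrumDataset:
    """A strain's sequenced mutation spectrum plus its overall rate.

    ``n_isolates`` is the number of independent resistant isolates
    sequenced; the event list may exceed it when isolates carry more than
    one mutation.  ``overall_rate`` is on the 1e-7 scale.
    """

    strain: str
    locus: ReporterLocus
    events: list[MutationEvent]
    n_isolates: int
    overall_rate: float
    pool_imbalanced: bool = False
    mmr_deficient: bool = False

    def __post_init__(self) -> None:
        if self.n_isolates < 0:
            raise ValueError("n_isolates must be non-negative")
        distinct = {e.isolate for e in self.events}
        if self.n_isolates < len(distinct):
            raise ValueError(
                f"n_isolates ({self.n_isolates}) < distinct isolates with "
                f"events ({len(distinct)})"
            )

    def events_of_class(self, klass: MutationClass) -> list[MutationEvent]:
        return [e for e in self.events if e.klass is klass]


@dataclass(frozen=True)
class FluctuationExperiment:
    """Resistant-colony counts from parallel cultures.

    ``n_final`` is cells per culture at plating (N_t); ``plating_fraction``
    the fraction of each culture plated on selective medium.
    """

    counts: tuple[int, ...]
    n_final: float
    plating_fraction: float = 1.0

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise ValueError("need at least 2 cultures")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.n_final <= 0:
            raise ValueError("n_final must be positive")
        if not 0 < self.plating_fraction <= 1:
            raise ValueError("plating_fraction must be in (0, 1]")


@dataclass(frozen=True)
class RateEstimate:
    """Mutation-rate point estimate with confidence limits.

    ``m`` is expected mutational events per culture; ``rate`` and the CI
    are per locus per generation on the 1e-7 scale.
    """

    m: float
    rate: float
    ci_low: float
    ci_high: float
    method: str  # "median" or "p0"

    def __post_init__(self) -> None:
        if not self.ci_low <= self.rate <= self.ci_high:
            raise ValueError("CI must contain the point estimate")


@dataclass(frozen=True)
class SiteRate:
    """Rate of a particular change at a particular site (or run span).

    When ``is_bound`` is set the site had zero observed events and the
    rate is the one-event upper bound, conventionally printed with '<'.
    """

    start: int
    end: int
    change: str
    count: int
    rate: float
    is_bound: bool = False

    @property
    def site_label(self) -> str:
        return str(self.start) if self.start == self.end else f"{self.start}-{self.end}"

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.change)


@dataclass(frozen=True)
class Hotspot:
    """A site whose rate is at least ``fold_over_wt``-fold the wild-type
    rate at the same site (one-event bound where wt saw nothing)."""

    strain: str
    site: SiteRate
    wt_rate: float
    wt_is_bound: bool
    fold_over_wt: float


@dataclass(frozen=True)
class StrandCall:
    """Leading/lagging assignment of one mutation event.

    For substitutions ``implicated_dntp`` is the misinserted nucleotide;
    for run indels it is the next nucleotide incorporated past the run,
    whose excess stabilizes the slipped intermediate.
    """

    event: MutationEvent
    call: StrandRole
    template_strand: TemplateStrand | None
    implicated_dntp: str | None
    rationale: str

    def __post_init__(self) -> None:
        if self.call is not StrandRole.UNASSIGNED:
            if self.template_strand is None or self.implicated_dntp is None:
                raise ValueError(
                    "assigned calls must carry template strand and dNTP"
                )


@dataclass(frozen=True)
class CorrectionFactor:
    """Mismatch-repair correction efficiency for a site or class.

    cf = rate without MMR / rate with MMR.  A one-event bound on either
    side makes the ratio a bound; when both sides saw nothing the record
    is indeterminate and carries no number.
    """

    scope: str
    cf: float | None
    bound: BoundKind
    numerator_rate: float
    denominator_rate: float
    numerator_count: int
    denominator_count: int


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of identical bases on the coding strand."""

    start: int
    length: int
    base: str

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end
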