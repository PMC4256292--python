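"""File formats: FASTA reference, TSV tables, YAML configuration.

All tables are tab-separated with a header row; empty ref/alt fields are
written as '.'.  Every table the pipeline writes can be read back into
identical records (round-trip identity), which the test suite asserts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Callable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .spectrum import OrientationComparison, classify_event
from .types import (
    BoundKind,
    CorrectionFactor,
    ForkEntry,
    HomopolymerRun,
    Hotspot,
    MutationClass,
    MutationEvent,
    MutationSubtype,
    Orientation,
    RateEstimate,
    ReporterLocus,
    SiteRate,
    SpectrumDataset,
    StrandCall,
    StrandRole,
    TemplateStrand,
)

log = logging.getLogger(__name__)


def read_locus(
    fasta_path: str | Path,
    orientation: Orientation | str,
    fork_entry: ForkEntry | str,
) -> ReporterLocus:
    """Read a single-record FASTA reference; sequence is upper-cased and
    must be strictly ACGT (the offending position is named otherwise)."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{fasta_path}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    for i, b in enumerate(seq, start=1):
        if b not in "ACGT":
            raise ValueError(f"{fasta_path}: non-ACGT character {b!r} at position {i}")
    return ReporterLocus(
        name=rec.id,
        coding_sequence=seq,
        orientation=Orientation(orientation),
        fork_entry=ForkEntry(fork_entry),
    )


def write_locus(locus: ReporterLocus, fasta_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{locus.name}\n")
        for i in range(0, len(locus.coding_sequence), 70):
            fh.write(locus.coding_sequence[i : i + 70] + "\n")


def _check_event_against_locus(
    row_no: int, position: int, ref: str, locus: ReporterLocus
) -> None:
    if not 1 <= position <= len(locus):
        raise ValueError(
            f"line {row_no}: position {position} outside locus of length {len(locus)}"
        )
    if ref:
        end = position + len(ref) - 1
        if end > len(locus):
            raise ValueError(f"line {row_no}: ref runs past the end of the locus")
        expected = locus.coding_sequence[position - 1 : end]
        if expected != ref:
            raise ValueError(
                f"line {row_no}: ref {ref!r} does not match reference "
                f"{expected!r} at position {position}"
            )


def read_events(
    tsv_path: str | Path,
    locus: ReporterLocus,
    n_isolates: int,
    overall_rate: float,
    strain: str | None = None,
    pool_imbalanced: bool = False,
    mmr_deficient: bool = False,
) -> SpectrumDataset:
    """Read a mutation-call table into a classified SpectrumDataset.

    Columns: strain, isolate, position, ref, alt ('.' for an empty side).
    Rows whose ref disagrees with the reference, or whose position is out
    of range, raise with the offending line number.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    required = ["strain", "isolate", "position", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{tsv_path}: missing columns {missing}")
    events: list[MutationEvent] = []
    for idx, row in df.iterrows():
        row_no = idx + 2  # 1-based, after the header
        try:
            position = int(row["position"])
        except ValueError:
            raise ValueError(
                f"line {row_no}: unparsable position {row['position']!r}"
            ) from None
        ref = "" if row["ref"] in (".", "") else row["ref"].upper()
        alt = "" if row["alt"] in (".", "") else row["alt"].upper()
        _check_event_against_locus(row_no, position, ref, locus)
        try:
            klass, subtype = classify_event(ref, alt)
        except ValueError as e:
            raise ValueError(f"line {row_no}: {e}") from None
        events.append(
            MutationEvent(
                strain=row["strain"], isolate=row["isolate"], position=position,
                ref=ref, alt=alt, klass=klass, subtype=subtype,
            )
        )
    inferred_strain = strain or (events[0].strain if events else "unknown")
    log.info("%s: read %d events for strain %s", tsv_path, len(events), inferred_strain)
    return SpectrumDataset(
        strain=inferred_strain, locus=locus, events=events,
        n_isolates=n_isolates, overall_rate=overall_rate,
        pool_imbalanced=pool_imbalanced, mmr_deficient=mmr_deficient,
    )


def read_culture_counts(tsv_path: str | Path) -> dict[str, list[int]]:
    """Counts per culture, grouped by experiment_id."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"experiment_id": str, "count": int})
    if not {"experiment_id", "count"} <= set(df.columns):
        raise ValueError(f"{tsv_path}: expected columns experiment_id, count")
    return {
        k: [int(c) for c in g["count"]] for k, g in df.groupby("experiment_id", sort=True)
    }


# ---------------------------------------------------------------------------
# Generic record tables


def _event_to_row(e: MutationEvent) -> dict[str, Any]:
    return {
        "strain": e.strain, "isolate": e.isolate, "position": e.position,
        "ref": e.ref or ".", "alt": e.alt or ".",
        "klass": e.klass.value, "subtype": e.subtype.value,
    }


def _event_from_row(r: dict[str, Any]) -> MutationEvent:
    return MutationEvent(
        strain=str(r["strain"]), isolate=str(r["isolate"]),
        position=int(r["position"]),
        ref="" if r["ref"] == "." else str(r["ref"]),
        alt="" if r["alt"] == "." else str(r["alt"]),
        klass=MutationClass(r["klass"]), subtype=MutationSubtype(r["subtype"]),
    )


def _site_to_row(s: SiteRate) -> dict[str, Any]:
    return {
        "start": s.start, "end": s.end, "change": s.change, "count": s.count,
        "rate_x1e7": s.rate, "is_bound": s.is_bound,
    }


def _site_from_row(r: dict[str, Any]) -> SiteRate:
    return SiteRate(
        start=int(r["start"]), end=int(r["end"]), change=str(r["change"]),
        count=int(r["count"]), rate=float(r["rate_x1e7"]),
        is_bound=_as_bool(r["is_bound"]),
    )


def _as_bool(v: Any) -> bool:
    if isinstance(v, str):
        return v.lower() == "true"
    return bool(v)


_TABLE_CODECS: dict[type, tuple[Callable, Callable]] = {}


def _register(kind: type, to_row: Callable, from_row: Callable) -> None:
    _TABLE_CODECS[kind] = (to_row, from_row)


_register(MutationEvent, _event_to_row, _event_from_row)
_register(SiteRate, _site_to_row, _site_from_row)

_register(
    HomopolymerRun,
    lambda r: {"start": r.start, "length": r.length, "base": r.base},
    lambda r: HomopolymerRun(int(r["start"]), int(r["length"]), str(r["base"])),
)

_register(
    RateEstimate,
    lambda e: {
        "m": e.m, "rate_x1e7": e.rate, "ci_low_x1e7": e.ci_low,
        "ci_high_x1e7": e.ci_high, "method": e.method,
    },
    lambda r: RateEstimate(
        m=float(r["m"]), rate=float(r["rate_x1e7"]), ci_low=float(r["ci_low_x1e7"]),
        ci_high=float(r["ci_high_x1e7"]), method=str(r["method"]),
    ),
)

_register(
    Hotspot,
    lambda h: {
        "strain": h.strain, **_site_to_row(h.site),
        "wt_rate_x1e7": h.wt_rate, "wt_is_bound": h.wt_is_bound,
        "fold_over_wt": h.fold_over_wt,
    },
    lambda r: Hotspot(
        strain=str(r["strain"]), site=_site_from_row(r),
        wt_rate=float(r["wt_rate_x1e7"]), wt_is_bound=_as_bool(r["wt_is_bound"]),
        fold_over_wt=float(r["fold_over_wt"]),
    ),
)

_register(
    StrandCall,
    lambda c: {
        **_event_to_row(c.event), "call": c.call.value,
        "template_strand": c.template_strand.value if c.template_strand else ".",
        "implicated_dntp": c.implicated_dntp or ".",
        "rationale": c.rationale,
    },
    lambda r: StrandCall(
        event=_event_from_row(r), call=StrandRole(r["call"]),
        template_strand=(
            None if r["template_strand"] == "." else TemplateStrand(r["template_strand"])
        ),
        implicated_dntp=None if r["implicated_dntp"] == "." else str(r["implicated_dntp"]),
        rationale=str(r["rationale"]),
    ),
)

_register(
    CorrectionFactor,
    lambda c: {
        "scope": c.scope, "cf": "." if c.cf is None else c.cf,
        "bound": c.bound.value,
        "numerator_rate_x1e7": c.numerator_rate,
        "denominator_rate_x1e7": c.denominator_rate,
        "numerator_count": c.numerator_count,
        "denominator_count": c.denominator_count,
    },
    lambda r: CorrectionFactor(
        scope=str(r["scope"]), cf=None if r["cf"] == "." else float(r["cf"]),
        bound=BoundKind(r["bound"]),
        numerator_rate=float(r["numerator_rate_x1e7"]),
        denominator_rate=float(r["denominator_rate_x1e7"]),
        numerator_count=int(r["numerator_count"]),
        denominator_count=int(r["denominator_count"]),
    ),
)

_register(
    OrientationComparison,
    lambda o: {
        "start": o.start, "end": o.end, "change": o.change,
        "rate_or1_x1e7": o.rate_or1, "rate_or2_x1e7": o.rate_or2,
        "or1_is_bound": o.or1_is_bound, "or2_is_bound": o.or2_is_bound,
        "fold": o.fold, "higher": o.higher, "fold_is_bound": o.fold_is_bound,
    },
    lambda r: OrientationComparison(
        start=int(r["start"]), end=int(r["end"]), change=str(r["change"]),
        rate_or1=float(r["rate_or1_x1e7"]), rate_or2=float(r["rate_or2_x1e7"]),
        or1_is_bound=_as_bool(r["or1_is_bound"]), or2_is_bound=_as_bool(r["or2_is_bound"]),
        fold=float(r["fold"]), higher=str(r["higher"]),
        fold_is_bound=_as_bool(r["fold_is_bound"]),
    ),
)


def write_table(records: Sequence, path: str | Path, kind: type | None = None) -> None:
    """Write records of one registered type as a TSV (header always written).

    ``kind`` is required for an empty record list.
    """
    if kind is None:
        if not records:
            raise ValueError("kind must be given for an empty record list")
        kind = type(records[0])
    if kind not in _TABLE_CODECS:
        raise ValueError(f"unsupported table type {kind.__name__}")
    if any(type(r) is not kind for r in records):
        raise ValueError("records must all be of a single registered type")
    to_row, from_row = _TABLE_CODECS[kind]
    rows = [to_row(r) for r in records]
    if rows:
        df = pd.DataFrame(rows)
    else:
        # header-only file: derive columns from a probe of the codec
        df = pd.DataFrame(columns=list(_header_for(kind)))
    df.to_csv(path, sep="\t", index=False)
    log.info("wrote %d %s row(s) to %s", len(rows), kind.__name__, path)


_HEADER_PROBES: dict[type, tuple[str, ...]] = {
    MutationEvent: ("strain", "isolate", "position", "ref", "alt", "klass", "subtype"),
    SiteRate: ("start", "end", "change", "count", "rate_x1e7", "is_bound"),
    HomopolymerRun: ("start", "length", "base"),
    RateEstimate: ("m", "rate_x1e7", "ci_low_x1e7", "ci_high_x1e7", "method"),
    Hotspot: (
        "strain", "start", "end", "change", "count", "rate_x1e7", "is_bound",
        "wt_rate_x1e7", "wt_is_bound", "fold_over_wt",
    ),
    StrandCall: (
        "strain", "isolate", "position", "ref", "alt", "klass", "subtype",
        "call", "template_strand", "implicated_dntp", "rationale",
    ),
    CorrectionFactor: (
        "scope", "cf", "bound", "numerator_rate_x1e7", "denominator_rate_x1e7",
        "numerator_count", "denominator_count",
    ),
    OrientationComparison: (
        "start", "end", "change", "rate_or1_x1e7", "rate_or2_x1e7",
        "or1_is_bound", "or2_is_bound", "fold", "higher", "fold_is_bound",
    ),
}


def _header_for(kind: type) -> tuple[str, ...]:
    return _HEADER_PROBES[kind]


def read_table(path: str | Path, kind: type) -> list:
    """Read back a table written by :func:`write_table`."""
    if kind not in _TABLE_CODECS:
        raise ValueError(f"unsupported table type {kind.__name__}")
    _, from_row = _TABLE_CODECS[kind]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [from_row(dict(row)) for _, row in df.iterrows()]


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML configuration mirroring the CLI flags."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
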