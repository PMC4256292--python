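"""Generators for fluctuation assays and mutation spectra.

Everything the pipeline consumes can be simulated here: resistant-colony
counts with the Luria-Delbrueck distribution (mutations arise at random
during deterministic exponential growth; a clone founded at generation g
contributes 2^(G-g) resistant cells at plating), and reporter spectra in
which per-site error propensities follow the mechanistic rules of
pool-imbalance mutagenesis — misinsertion of excess dNTPs opposite
pyrimidine templates, extension favored by excess downstream nucleotides,
and homopolymer slippage whose rate grows exponentially with run length.

Mismatch repair is modeled as per-category thinning: an error of category
c survives repair with probability equal to its retention (1/CF).  The
MMR-proficient dataset's overall rate is scaled by the expected retained
propensity fraction, so planted correction factors are recoverable by
construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import repeats
from .types import (
    DNTPPools,
    FluctuationExperiment,
    ForkEntry,
    MutationClass,
    MutationEvent,
    MutationSubtype,
    Orientation,
    ReporterLocus,
    SpectrumDataset,
    complement,
)
from .spectrum import classify_event

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Knobs of both generators; every stochastic call is seeded.

    ``true_rate`` is the absolute mutation rate per locus per cell
    division (e.g. 4e-7); ``overall_rate`` is the spectrum dataset's
    bookkeeping rate on the 1e-7 print scale.  ``mmr_retention`` maps an
    error category to the probability that MMR fails to correct it
    (retention = 1/CF): substitutions, indels in A:T runs, indels in G:C
    runs.
    """

    seed: int = 0
    # fluctuation assay
    true_rate: float = 4e-7
    n_initial: int = 1000
    n_final: float = 1.6384e7  # n_initial * 2**14
    n_cultures: int = 24
    plating_fraction: float = 1.0
    # spectrum propensities
    sub_base_weight: float = 1.0
    excess_misinsertion_multiplier: float = 50.0
    extension_multiplier: float = 2.0
    indel_base_weight: float = 120.0
    indel_slope: float = 0.9
    # mismatch repair retention (1/CF) per category
    mmr_retention: dict = field(
        default_factory=lambda: {
            "substitution": 1 / 20,
            "indel_at": 1 / 300,
            "indel_gc": 1 / 10,
        }
    )
    n_isolates: int = 200
    overall_rate: float = 2000.0
    multi_mutation_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_final <= self.n_initial:
            raise ValueError("n_final must exceed n_initial")
        if not 0 <= self.multi_mutation_rate <= 1:
            raise ValueError("multi_mutation_rate must be a probability")
        for k, v in self.mmr_retention.items():
            if not 0 < v <= 1:
                raise ValueError(f"retention for {k!r} must be in (0, 1]")


def simulate_fluctuation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> FluctuationExperiment:
    """Resistant-colony counts for ``n_cultures`` parallel cultures.

    Growth is deterministic doubling from ``n_initial`` over
    G = round(log2(n_final/n_initial)) generations (no death, no mutant
    fitness cost).  Mutations in generation g are Poisson with mean
    rate x (cells dividing that generation); each founds a clone of
    2^(G-g) resistant cells.  Plating a fraction < 1 binomially thins the
    final counts.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    generations = round(math.log2(config.n_final / config.n_initial))
    if generations < 1:
        raise ValueError("need at least one generation of growth")
    counts = np.zeros(config.n_cultures, dtype=np.int64)
    for g in range(1, generations + 1):
        dividing = config.n_initial * 2 ** (g - 1)
        muts = rng.poisson(config.true_rate * dividing, size=config.n_cultures)
        counts += muts * 2 ** (generations - g)
    if config.plating_fraction < 1.0:
        counts = rng.binomial(counts, config.plating_fraction)
    n_final = config.n_initial * 2**generations
    return FluctuationExperiment(
        counts=tuple(int(c) for c in counts),
        n_final=float(n_final),
        plating_fraction=config.plating_fraction,
    )


@dataclass(frozen=True)
class _ErrorTemplate:
    """A potential error with its raw propensity and repair category."""

    position: int
    ref: str
    alt: str
    klass: MutationClass
    subtype: MutationSubtype
    category: str
    propensity: float


def _downstream_excess_factor(
    seq: str, position: int, template_coding: bool, excess: frozenset, mult: float
) -> float:
    """Extension bonus: one ``mult`` factor per downstream template base
    (up to 3) whose complementary dNTP is in excess.

    On the coding template, synthesis proceeds toward lower coding
    positions and incorporates complement(coding base); on the noncoding
    template it proceeds toward higher positions and incorporates the
    coding base itself.
    """
    n = 0
    for i in range(1, 4):
        p = position - i if template_coding else position + i
        if not 1 <= p <= len(seq):
            break
        incorporated = complement(seq[p - 1]) if template_coding else seq[p - 1]
        if incorporated in excess:
            n += 1
    return mult**n


def error_propensities(
    locus: ReporterLocus, pools: DNTPPools, config: SimulationConfig
) -> list[_ErrorTemplate]:
    """Raw (pre-MMR) propensity for every modeled error at every site."""
    seq = locus.coding_sequence
    excess = pools.excess_set
    out: list[_ErrorTemplate] = []
    for pos in range(1, len(seq) + 1):
        ref = seq[pos - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            w = 0.0
            for template_coding in (True, False):
                mis = complement(alt) if template_coding else alt
                wc = config.sub_base_weight
                if mis in excess:
                    wc *= config.excess_misinsertion_multiplier
                wc *= _downstream_excess_factor(
                    seq, pos, template_coding, excess, config.extension_multiplier
                )
                w += wc
            klass, subtype = classify_event(ref, alt)
            out.append(
                _ErrorTemplate(pos, ref, alt, klass, subtype, "substitution", w)
            )
    for run in repeats.annotate_runs(seq, min_len=2):
        w = config.indel_base_weight * math.exp(config.indel_slope * run.length)
        # slippage stabilized when the nucleotide incorporated just past
        # the run (on either strand) is in excess
        nxt_coding = complement(seq[run.start - 2]) if run.start > 1 else None
        nxt_noncod = seq[run.end] if run.end < len(seq) else None
        if (nxt_coding in excess) or (nxt_noncod in excess):
            w *= 2.0
        category = "indel_at" if run.base in "AT" else "indel_gc"
        out.append(
            _ErrorTemplate(
                run.start, run.base, "", MutationClass.SINGLE_BASE_INDEL,
                MutationSubtype.DELETION, category, w,
            )
        )
    return out


def _sample_dataset(
    strain: str,
    locus: ReporterLocus,
    templates: list[_ErrorTemplate],
    probs: np.ndarray,
    overall_rate: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    mmr_deficient: bool,
    pool_imbalanced: bool,
) -> SpectrumDataset:
    events = []
    for i in range(config.n_isolates):
        isolate = f"i{i + 1:05d}"
        n_events = 1 + int(rng.random() < config.multi_mutation_rate)
        for idx in rng.choice(len(templates), size=n_events, p=probs):
            t = templates[idx]
            events.append(
                MutationEvent(
                    strain=strain, isolate=isolate, position=t.position,
                    ref=t.ref, alt=t.alt, klass=t.klass, subtype=t.subtype,
                )
            )
    return SpectrumDataset(
        strain=strain, locus=locus, events=events,
        n_isolates=config.n_isolates, overall_rate=overall_rate,
        pool_imbalanced=pool_imbalanced,
        mmr_deficient=mmr_deficient,
    )


def simulate_spectrum(
    locus: ReporterLocus,
    pools: DNTPPools,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SpectrumDataset, SpectrumDataset]:
    """(MMR-proficient, MMR-deficient) spectrum datasets for one locus.

    The deficient dataset samples ``n_isolates`` isolates from the raw
    propensities at ``overall_rate``; the proficient dataset samples from
    retention-thinned propensities, with its overall rate scaled by the
    expected retained fraction so that planted CFs are recoverable.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    templates = error_propensities(locus, pools, config)
    raw = np.array([t.propensity for t in templates])
    if raw.sum() <= 0:
        raise ValueError("total error propensity is zero")
    retention = np.array([config.mmr_retention[t.category] for t in templates])
    thinned = raw * retention
    retained_fraction = thinned.sum() / raw.sum()

    imbalanced = bool(pools.excess_set)
    ds_minus = _sample_dataset(
        "sim-mmr-minus", locus, templates, raw / raw.sum(),
        config.overall_rate, config, rng,
        mmr_deficient=True, pool_imbalanced=imbalanced,
    )
    ds_plus = _sample_dataset(
        "sim-mmr-plus", locus, templates, thinned / thinned.sum(),
        config.overall_rate * retained_fraction, config, rng,
        mmr_deficient=False, pool_imbalanced=imbalanced,
    )
    log.info(
        "simulated spectra: %d templates, retained propensity fraction %.4g",
        len(templates), retained_fraction,
    )
    return ds_plus, ds_minus


def fixture_locus(
    length: int = 1000,
    seed: int = 0,
    orientation: Orientation = Orientation.OR1,
    fork_entry: ForkEntry = ForkEntry.FIVE_PRIME,
    name: str = "synthetic-reporter",
) -> ReporterLocus:
    """A random reporter sequence with guaranteed homopolymer support.

    One run of each base is planted (A x3, C x4, G x5, T x6, with guard
    bases so the runs stay maximal), so repeat-length analyses always have
    runs of every base and of every length from 3 to 6.
    """
    if length < 100:
        raise ValueError("length must be >= 100")
    rng = np.random.default_rng(seed)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
    planted = [("A", 3), ("C", 4), ("G", 5), ("T", 6)]
    slot = length // (len(planted) + 1)
    for k, (base, run_len) in enumerate(planted, start=1):
        s = k * slot  # 0-based start of the run
        for i in range(run_len):
            seq[s + i] = base
        guard = "C" if base != "C" else "G"
        seq[s - 1] = guard
        seq[s + run_len] = guard
    return ReporterLocus(
        name=name, coding_sequence="".join(seq),
        orientation=orientation, fork_entry=fork_entry,
    )
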