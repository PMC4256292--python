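import pytest

from strandspectra import refdata, synthetic_data
from strandspectra.types import (
    ForkEntry,
    MutationClass,
    MutationEvent,
    Orientation,
    ReporterLocus,
    RNR1_Y285A_POOLS,
)
from strandspectra.spectrum import classify_event


@pytest.fixture(scope="session")
def locus():
    """Deterministic 1 kb fixture locus with planted homopolymer runs."""
    return refdata.reference_locus()


@pytest.fixture(scope="session")
def locus_c648(locus):
    """Fixture locus guaranteed to carry a C at position 648 (the
    worked-example substitution site)."""
    seq = list(locus.coding_sequence)
    seq[647] = "C"
    if seq[646] == "C":
        seq[646] = "A"
    if seq[648] == "C":
        seq[648] = "A"
    return ReporterLocus("reporter-c648", "".join(seq),
                         Orientation.OR1, ForkEntry.FIVE_PRIME)


@pytest.fixture(scope="session")
def pools():
    return RNR1_Y285A_POOLS


@pytest.fixture(scope="session")
def summary_datasets(locus):
    """All five strain summaries expanded onto the shared fixture locus."""
    return {
        name: refdata.dataset_from_summary(name, locus)
        for name in refdata.STRAIN_SUMMARIES
    }


def make_event(locus, position, ref, alt, strain="s", isolate="i1"):
    klass, subtype = classify_event(ref, alt)
    return MutationEvent(strain, isolate, position, ref, alt, klass, subtype)


@pytest.fixture(scope="session")
def sim_spectra(locus, pools):
    """One moderately sized simulated spectrum pair, shared across tests."""
    config = synthetic_data.SimulationConfig(seed=42, n_isolates=2000)
    return synthetic_data.simulate_spectrum(locus, pools, config)
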