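import numpy as np
import pytest

from abequant import (
    SeqNoise,
    WindowCounts,
    count_bases,
    example_alleles,
    example_edit_model,
    example_site,
    simulate_amplicon_reads,
)


@pytest.fixture(scope="session")
def site():
    return example_site()


@pytest.fixture(scope="session")
def alleles():
    return example_alleles()


@pytest.fixture(scope="session")
def reference_read(alleles):
    """The unedited mutant-allele amplicon as a plain read."""
    return alleles[0].sequence


def make_counts(site, per_position_bases):
    """Build WindowCounts from {position: {base: count}} deviations.

    Positions not mentioned get the reference base for every read; the read
    total is the maximum position total supplied (positions mentioned must
    all sum to the same total).
    """
    totals = {
        pos: sum(bases.values()) for pos, bases in per_position_bases.items()
    }
    n = max(totals.values()) if totals else 100
    assert all(t == n for t in totals.values()), "position totals must agree"
    counts = np.zeros((23, 5), dtype=np.int64)
    order = "ACGTN"
    ref = site.window_reference
    for pos in range(1, 24):
        if pos in per_position_bases:
            for base, c in per_position_bases[pos].items():
                counts[pos - 1, order.index(base)] += c
        else:
            counts[pos - 1, order.index(ref[pos - 1])] = n
    return WindowCounts(site=site, counts=counts, reads_located=n)


@pytest.fixture(scope="session")
def simulated_counts(site, alleles):
    """Treated (target rate 0.9, bystander 0.5) and control counts at depth
    2000 with realistic substitution error, shared across tests."""
    treated = simulate_amplicon_reads(
        alleles,
        example_edit_model(0.9, 0.5),
        SeqNoise(depth=2000, sub_error=0.002, seed=11),
    )
    control = simulate_amplicon_reads(
        alleles,
        example_edit_model(0.0, 0.0),
        SeqNoise(depth=2000, sub_error=0.002, seed=12),
    )
    return count_bases(treated, site), count_bases(control, site)
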