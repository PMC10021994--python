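"""Shared fixtures: small hand-built matrices and a mid-size simulated
population reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from karyolink.model import (
    CALL_HET,
    CALL_MISSING,
    CALL_P1,
    CALL_P2,
    GenotypeMatrix,
    MarkerLocus,
)

P1, P2, H, M = CALL_P1, CALL_P2, CALL_HET, CALL_MISSING


def make_matrix(rows, contigs=None, positions=None, samples=None,
                parent_calls=None, n_alt=None):
    """Build a GenotypeMatrix from a list of call-code rows."""
    calls = np.array(rows, dtype=np.int8)
    n_mark, n_samp = calls.shape
    if contigs is None:
        contigs = ["c1"] * n_mark
    if positions is None:
        positions = [1000 * (i + 1) for i in range(n_mark)]
    if samples is None:
        samples = [f"S{i + 1:02d}" for i in range(n_samp)]
    if n_alt is None:
        n_alt = [1] * n_mark
    markers = [
        MarkerLocus(c, p, "A", "C", n_alt=a)
        for c, p, a in zip(contigs, positions, n_alt)
    ]
    pc = (
        np.full(n_mark, CALL_P1, dtype=np.int8)
        if parent_calls is None
        else np.array(parent_calls, dtype=np.int8)
    )
    return GenotypeMatrix(markers, samples, calls, parent_sample="parent",
                          parent_calls=pc)


# ---------------------------------------------------------------------------
# the hand-counted filter-cascade fixture (20 markers x 12 samples)
# ---------------------------------------------------------------------------

# base segregation patterns over samples S01..S12 (S12 is the contaminant)
_A = [P1] * 5 + [P2] * 6 + [P2]          # 5:6 clean pattern
_A_HET = [P1] * 5 + [P2] * 6 + [H]       # same, S12 heterozygous
_A2 = [P1] * 4 + [P2] * 7 + [P2]         # _A with S05 flipped (block of 2)
_ISL = [P1, P1, P2, P1, P1] + [P2] * 6 + [P2]  # _A with S03 flipped (island)
_SKEW = [P1] * 12                         # all-P1: k_minor = 0
_MISS = [M, M, P1, P1, P1] + [P2] * 6 + [P2]   # _A with S01/S02 missing
_B = [P1, P2, P1, P2, P1, P2, P1, P2, P1, P2, P1, P2]   # alternating
_B2 = [P1, P2, P1, P2, P1, P2, P1, P2, P1, P2, P2, P2]  # _B with S11 flipped


@pytest.fixture()
def cascade_fixture():
    """20-marker x 12-sample matrix exercising every strict-cascade rule.

    Hand-counted outcome (see test_acceptance): sample S12 is removed as a
    heterokaryon; markers 3 (triallelic), 5 (parent missing), 9 (>10 %
    missing), 13 (binomial skew) and 11 (double-crossover island) are
    removed; the remaining 15 markers and 11 samples survive.
    """
    rows = [
        _A_HET,  # 1
        _A_HET,  # 2
        _A,      # 3  triallelic
        _A_HET,  # 4
        _A,      # 5  parent missing
        _A_HET,  # 6
        _A2,     # 7
        _A2,     # 8
        _MISS,   # 9  2/11 missing after contaminant removal
        _A,      # 10
        _ISL,    # 11 single-marker island for S03
        _A,      # 12
        _SKEW,   # 13 k=0 binomial skew
        _A,      # 14
        _A,      # 15
        _A,      # 16
        _B,      # 17 (contig c2)
        _B2,     # 18
        _B2,     # 19
        _B,      # 20
    ]
    contigs = ["c1"] * 16 + ["c2"] * 4
    positions = [1000 * (i + 1) for i in range(16)] + [1000 * (i + 1) for i in range(4)]
    n_alt = [1] * 20
    n_alt[2] = 2  # marker 3 triallelic
    parent_calls = [P1] * 20
    parent_calls[4] = M  # marker 5 unphased
    m = make_matrix(rows, contigs, positions, n_alt=n_alt,
                    parent_calls=parent_calls)
    expected_keys = {("c1", 1000 * i) for i in (1, 2, 4, 6, 7, 8, 10, 12, 14, 15, 16)}
    expected_keys |= {("c2", 1000 * i) for i in (1, 2, 3, 4)}
    return m, expected_keys


# ---------------------------------------------------------------------------
# simulated populations
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def clean_sim():
    """4 chromosomes x 3 contigs, 88 offspring, no noise: for chain /
    map-recovery tests."""
    from karyolink.synthetic_data import SimConfig, simulate_genome, simulate_meiosis

    cfg = SimConfig(
        n_chromosomes=4,
        chromosome_length=1_000_000,
        contigs_per_chromosome=3,
        marker_spacing_mean=25_000,
        n_offspring=88,
        extra_crossover_rate=0.5,
        flip_contigs=True,
        seed=11,
    )
    genome = simulate_genome(cfg)
    matrix, truth = simulate_meiosis(cfg, genome)
    return cfg, genome, matrix, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Same design with contaminants, missing calls and errors."""
    from karyolink.synthetic_data import SimConfig, simulate_genome, simulate_meiosis

    cfg = SimConfig(
        n_chromosomes=4,
        chromosome_length=1_000_000,
        contigs_per_chromosome=3,
        marker_spacing_mean=25_000,
        n_offspring=88,
        extra_crossover_rate=0.5,
        heterokaryon_fraction=0.1,
        missing_rate=0.03,
        error_rate=0.002,
        seed=13,
    )
    genome = simulate_genome(cfg)
    matrix, truth = simulate_meiosis(cfg, genome)
    return cfg, genome, matrix, truth
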