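"""Strict and lenient marker filter cascades as ordered, testable rules.

The strict cascade (used for the core linkage map):

1. position filter: called count, allele frequency, per-position HET
2. heterokaryon sample removal (> ``max_het_frac_sample`` HET calls)
3. position filter repeated
4. all remaining HET calls set to MISSING
5. structural: multiallelic, parent-unphased, > 10 % missing positions
6. binomial segregation-skew test (cumulative minor-allele p < 0.01)
7. double-crossover island filter
8. samples with > 10 % missing positions removed
9. small linked-cluster filter (< ``min_cluster_size`` unique patterns)

"More than" thresholds are strict inequalities throughout; boundary cases
are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.stats import binom

from .model import (
    CALL_HET,
    CALL_MISSING,
    CALL_P1,
    CALL_P2,
    GenotypeMatrix,
)


@dataclass
class FilterConfig:
    min_called: int = 40
    min_af: float = 0.2
    max_af: float = 0.8
    max_het_frac_position: float = 0.1
    max_het_frac_sample: float = 0.1
    max_missing_positions: Union[int, float] = 0.1  # fraction if < 1, else count
    max_missing_samples: float = 0.1
    maf_binom_alpha: float = 0.01
    min_cluster_size: int = 5
    cluster_lod: float = 5.5
    island_threshold: int = 1
    max_het_calls_position: Optional[int] = None  # lenient: count, not fraction
    mode: str = "strict"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_af <= self.max_af <= 1.0):
            raise ValueError("require 0 <= min_af <= max_af <= 1")

    @classmethod
    def strict(cls, **overrides) -> "FilterConfig":
        return cls(**{"mode": "strict", **overrides})

    @classmethod
    def lenient(cls, **overrides) -> "FilterConfig":
        defaults = dict(
            min_called=10,
            min_af=0.05,
            max_af=0.95,
            max_missing_positions=30,
            max_het_calls_position=1,
            mode="lenient",
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class FilterReport:
    """Ordered per-rule removal counts."""

    steps: list[tuple[str, int, str]] = field(default_factory=list)
    flagged_samples: list[str] = field(default_factory=list)
    unusable_samples: list[str] = field(default_factory=list)
    n_markers_in: int = 0
    n_samples_in: int = 0
    n_markers_out: int = 0
    n_samples_out: int = 0

    def record(self, rule: str, n_removed: int, axis: str = "position") -> None:
        self.steps.append((rule, int(n_removed), axis))

    def removed(self, axis: str = "position") -> int:
        return sum(n for _, n, a in self.steps if a == axis)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.steps, columns=["rule", "n_removed", "axis"])


# ---------------------------------------------------------------------------
# per-position statistics
# ---------------------------------------------------------------------------

def _position_stats(m: GenotypeMatrix):
    c = m.calls
    n_called = (c != CALL_MISSING).sum(axis=1)
    n_het = (c == CALL_HET).sum(axis=1)
    n_p1 = (c == CALL_P1).sum(axis=1)
    n_p2 = (c == CALL_P2).sum(axis=1)
    return n_called, n_het, n_p1, n_p2


def filter_positions_basic(
    m: GenotypeMatrix, cfg: FilterConfig, report: Optional[FilterReport] = None
) -> GenotypeMatrix:
    """Keep positions by called count, P2 allele frequency and HET fraction.

    Rule order: called-count, AF (HET excluded from the denominator), HET
    fraction.  A position whose called-non-HET count is zero fails the AF
    rule.
    """
    n_called, n_het, n_p1, n_p2 = _position_stats(m)
    keep = n_called >= cfg.min_called
    if report is not None:
        report.record("min_called", int((~keep).sum()))
    hom = n_p1 + n_p2
    with np.errstate(invalid="ignore", divide="ignore"):
        p2f = np.where(hom > 0, n_p2 / np.maximum(hom, 1), np.nan)
    af_ok = (hom > 0) & (p2f >= cfg.min_af) & (p2f <= cfg.max_af)
    if report is not None:
        report.record("allele_frequency", int((keep & ~af_ok).sum()))
    keep &= af_ok
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
    het_ok = het_frac <= cfg.max_het_frac_position
    if report is not None:
        report.record("het_fraction_position", int((keep & ~het_ok).sum()))
    keep &= het_ok
    return m.subset_markers(keep)


def detect_heterokaryon_samples(
    m: GenotypeMatrix,
    max_het_frac_sample: float = 0.1,
    report: Optional[FilterReport] = None,
) -> tuple[list[str], GenotypeMatrix]:
    """Flag and remove samples with more than ``max_het_frac_sample`` HET
    calls (strict inequality). Samples with zero non-missing calls are
    reported separately as unusable and also removed."""
    c = m.calls
    n_called = (c != CALL_MISSING).sum(axis=0)
    n_het = (c == CALL_HET).sum(axis=0)
    unusable = n_called == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
    flagged = (frac > max_het_frac_sample) & ~unusable
    flagged_names = [s for s, f in zip(m.samples, flagged) if f]
    unusable_names = [s for s, f in zip(m.samples, unusable) if f]
    if report is not None:
        report.record("heterokaryon_samples", len(flagged_names), axis="sample")
        report.flagged_samples.extend(flagged_names)
        report.unusable_samples.extend(unusable_names)
        if unusable_names:
            report.record("unusable_samples", len(unusable_names), axis="sample")
    keep = ~(flagged | unusable)
    return flagged_names, m.subset_samples(np.flatnonzero(keep))


def set_het_missing(m: GenotypeMatrix) -> GenotypeMatrix:
    out = m.copy()
    out.calls[out.calls == CALL_HET] = CALL_MISSING
    return out


def structural_filters(
    m: GenotypeMatrix, cfg: FilterConfig, report: Optional[FilterReport] = None
) -> GenotypeMatrix:
    """Remove multiallelic positions, parent-unphased positions, and
    positions exceeding the missing-call threshold, in that order."""
    n_alt = np.array([mk.n_alt for mk in m.markers])
    keep = n_alt == 1
    if report is not None:
        report.record("multiallelic", int((~keep).sum()))
    phased = ~m.unphased
    if report is not None:
        report.record("parent_unphased", int((keep & ~phased).sum()))
    keep &= phased
    n_missing = (m.calls == CALL_MISSING).sum(axis=1)
    thr = cfg.max_missing_positions
    if isinstance(thr, float) and thr < 1:
        miss_ok = n_missing <= thr * m.n_samples
    else:
        miss_ok = n_missing <= thr
    if report is not None:
        report.record("missing_positions", int((keep & ~miss_ok).sum()))
    keep &= miss_ok
    return m.subset_markers(keep)


def maf_binomial_test(k_minor: int, n_called: int) -> float:
    """Cumulative binomial tail P(X <= k_minor) for X ~ Bin(n_called, 1/2).

    ``k_minor`` is the smaller of the two allele counts; positions with a
    p-value below the configured alpha are treated as segregation-skewed.
    """
    if n_called <= 0:
        raise ValueError("n_called must be positive")
    if not (0 <= k_minor <= n_called):
        raise ValueError("require 0 <= k_minor <= n_called")
    return float(binom.cdf(k_minor, n_called, 0.5))


def binomial_skew_filter(
    m: GenotypeMatrix, alpha: float = 0.01, report: Optional[FilterReport] = None
) -> GenotypeMatrix:
    _, _, n_p1, n_p2 = _position_stats(m)
    k = np.minimum(n_p1, n_p2)
    n = n_p1 + n_p2
    p = np.ones(m.n_markers)
    ok = n > 0
    p[ok] = binom.cdf(k[ok], n[ok], 0.5)
    keep = p >= alpha
    keep &= ok  # zero-informative positions removed here defensively
    if report is not None:
        report.record("binomial_skew", int((~keep).sum()))
    return m.subset_markers(keep)


def double_crossover_filter(
    m: GenotypeMatrix,
    island_threshold: int = 1,
    report: Optional[FilterReport] = None,
) -> GenotypeMatrix:
    """Remove positions showing single-marker "islands": a sample whose call
    differs from equal calls at both physically adjacent markers on the same
    contig (a pattern requiring a double crossover).

    First/last markers of a contig are never removed; contigs with < 3
    markers are skipped.  A position is removed when at least
    ``island_threshold`` samples show an island.
    """
    keep = np.ones(m.n_markers, dtype=bool)
    for contig, rows in m.contig_rows().items():
        if len(rows) < 3:
            continue
        c = m.calls[rows]
        left, mid, right = c[:-2], c[1:-1], c[2:]
        informative = (
            ((left == CALL_P1) | (left == CALL_P2))
            & ((mid == CALL_P1) | (mid == CALL_P2))
            & ((right == CALL_P1) | (right == CALL_P2))
        )
        island = informative & (left == right) & (mid != left)
        bad = island.sum(axis=1) >= island_threshold
        keep[rows[1:-1][bad]] = False
    if report is not None:
        report.record("double_crossover_island", int((~keep).sum()))
    return m.subset_markers(keep)


def filter_samples_missing(
    m: GenotypeMatrix, max_missing: float = 0.1, report: Optional[FilterReport] = None
) -> GenotypeMatrix:
    n_missing = (m.calls == CALL_MISSING).sum(axis=0)
    keep = n_missing <= max_missing * max(m.n_markers, 1)
    if report is not None:
        report.record("sample_missing", int((~keep).sum()), axis="sample")
    return m.subset_samples(np.flatnonzero(keep))


def small_cluster_filter(
    m: GenotypeMatrix,
    cluster_lod: float = 5.5,
    min_cluster_size: int = 5,
    min_shared: int = 10,
    report: Optional[FilterReport] = None,
) -> GenotypeMatrix:
    """Remove markers in linkage clusters with fewer than
    ``min_cluster_size`` *unique* segregation patterns.

    Markers are deduplicated by identical call pattern; connected
    components at LOD > ``cluster_lod`` are computed over the unique
    patterns only.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    from .linkage_core import pairwise_linkage

    if m.n_markers == 0:
        return m
    patterns: dict[tuple, int] = {}
    pattern_of = np.empty(m.n_markers, dtype=int)
    for i in range(m.n_markers):
        key = tuple(m.calls[i].tolist())
        pattern_of[i] = patterns.setdefault(key, len(patterns))
    uniq_rows = np.array(
        [np.flatnonzero(pattern_of == u)[0] for u in range(len(patterns))]
    )
    sub = m.calls[uniq_rows]
    rf, lod, n = pairwise_linkage(sub)
    adj = (lod > cluster_lod) & (n >= min_shared)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    comp_sizes = np.bincount(labels, minlength=n_comp)
    keep_pattern = comp_sizes[labels] >= min_cluster_size
    keep = keep_pattern[pattern_of]
    if report is not None:
        report.record("small_cluster", int((~keep).sum()))
    return m.subset_markers(keep)


# ---------------------------------------------------------------------------
# cascades
# ---------------------------------------------------------------------------

def filter_strict(
    m: GenotypeMatrix, cfg: Optional[FilterConfig] = None, min_shared: int = 10
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full strict cascade in order; returns matrix and report."""
    cfg = cfg or FilterConfig.strict()
    rep = FilterReport(n_markers_in=m.n_markers, n_samples_in=m.n_samples)
    m = filter_positions_basic(m, cfg, rep)
    _, m = detect_heterokaryon_samples(m, cfg.max_het_frac_sample, rep)
    m = filter_positions_basic(m, cfg, rep)
    m = set_het_missing(m)
    m = structural_filters(m, cfg, rep)
    m = binomial_skew_filter(m, cfg.maf_binom_alpha, rep)
    m = double_crossover_filter(m, cfg.island_threshold, rep)
    m = filter_samples_missing(m, cfg.max_missing_samples, rep)
    m = small_cluster_filter(
        m, cfg.cluster_lod, cfg.min_cluster_size, min_shared, rep
    )
    rep.n_markers_out = m.n_markers
    rep.n_samples_out = m.n_samples
    return m, rep


def filter_lenient(
    m: GenotypeMatrix,
    cfg: Optional[FilterConfig] = None,
    drop_samples: Optional[list[str]] = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Lenient cascade used for the forced-order map.

    ``drop_samples`` carries the heterokaryon calls from a strict run.
    Positions failing the binomial skew test are *not* removed here, so
    distorted regions stay in the map.
    """
    cfg = cfg or FilterConfig.lenient()
    rep = FilterReport(n_markers_in=m.n_markers, n_samples_in=m.n_samples)
    if drop_samples is None:
        drop_samples, m = detect_heterokaryon_samples(
            m, cfg.max_het_frac_sample, rep
        )
    else:
        keep = [s for s in m.samples if s not in set(drop_samples)]
        rep.record("heterokaryon_samples", m.n_samples - len(keep), axis="sample")
        m = m.subset_samples(keep)

    # position filter: min called, minor allele frequency
    n_called, n_het, n_p1, n_p2 = _position_stats(m)
    keep = n_called >= cfg.min_called
    rep.record("min_called", int((~keep).sum()))
    hom = n_p1 + n_p2
    with np.errstate(invalid="ignore", divide="ignore"):
        minor = np.where(hom > 0, np.minimum(n_p1, n_p2) / np.maximum(hom, 1), 0.0)
    af_ok = (hom > 0) & (minor >= cfg.min_af)
    rep.record("minor_allele_frequency", int((keep & ~af_ok).sum()))
    keep &= af_ok
    m = m.subset_markers(keep)

    # parent heterozygous positions
    phased = ~m.unphased
    rep.record("parent_unphased", int((~phased).sum()))
    m = m.subset_markers(phased)

    # more than one HET call across samples
    n_het = (m.calls == CALL_HET).sum(axis=1)
    max_het = cfg.max_het_calls_position if cfg.max_het_calls_position is not None else 1
    het_ok = n_het <= max_het
    rep.record("het_calls_position", int((~het_ok).sum()))
    m = m.subset_markers(het_ok)

    m = set_het_missing(m)

    # biallelic only
    n_alt = np.array([mk.n_alt for mk in m.markers])
    rep.record("multiallelic", int((n_alt != 1).sum()))
    m = m.subset_markers(n_alt == 1)

    # missing-call count
    n_missing = (m.calls == CALL_MISSING).sum(axis=1)
    thr = cfg.max_missing_positions
    if isinstance(thr, float) and thr < 1:
        thr = thr * m.n_samples
    miss_ok = n_missing <= thr
    rep.record("missing_positions", int((~miss_ok).sum()))
    m = m.subset_markers(miss_ok)

    rep.n_markers_out = m.n_markers
    rep.n_samples_out = m.n_samples
    return m, rep
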