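"""Two-point linkage, linkage-group clustering, map construction and the
forced-order contig-chaining map.

The two-point LOD for a haploid 1:1 population (equivalent to a backcross)
with ``n`` informative offspring of which ``r`` are recombinant:

    LOD = (n - r) * log10(2 * (1 - r_hat)) + r * log10(2 * r_hat)

with ``r_hat = r / n`` and LOD = n * log10(2) when r = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    CALL_MISSING,
    CALL_P1,
    CALL_P2,
    AssemblyIndex,
    GenotypeMatrix,
    MarkerLocus,
    TraitTable,
)

logger = logging.getLogger(__name__)

LOG10_2 = math.log10(2.0)


# ---------------------------------------------------------------------------
# two-point statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoPointResult:
    rf: float
    lod: float
    n_informative: int

    @property
    def informative(self) -> bool:
        return self.n_informative > 0


def _lod_from_rn(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized LOD; r may exceed n/2 (repulsion noise), giving LOD <= 0."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(n > 0, r / np.maximum(n, 1), 0.5)
        rf_c = np.clip(rf, 1e-12, 1 - 1e-12)
        lod = (n - r) * np.log10(2.0 * (1.0 - rf_c)) + r * np.log10(2.0 * rf_c)
    lod = np.where(r == 0, n * LOG10_2, lod)
    lod = np.where(n == 0, 0.0, lod)
    return lod


def two_point_linkage(
    g_a: np.ndarray, g_b: np.ndarray, min_shared: int = 10
) -> TwoPointResult:
    """Two-point recombination fraction and LOD between two call vectors.

    Samples carrying HET or MISSING in either vector are ignored.  A pair
    with fewer than ``min_shared`` informative samples is returned with
    ``n_informative`` as observed but callers should treat it as
    uninformative for clustering.
    """
    g_a = np.asarray(g_a)
    g_b = np.asarray(g_b)
    ok_a = (g_a == CALL_P1) | (g_a == CALL_P2)
    ok_b = (g_b == CALL_P1) | (g_b == CALL_P2)
    both = ok_a & ok_b
    n = int(both.sum())
    if n == 0:
        return TwoPointResult(rf=0.5, lod=0.0, n_informative=0)
    r = int((g_a[both] != g_b[both]).sum())
    rf = min(r / n, 0.5)
    lod = float(_lod_from_rn(np.array(r), np.array(n)))
    return TwoPointResult(rf=rf, lod=lod, n_informative=n)


def pairwise_linkage(calls: np.ndarray):
    """All-pairs (rf, lod, n_informative) matrices for a call table.

    HET and MISSING are both treated as uninformative.  ``rf`` is capped at
    0.5 (repulsion beyond 0.5 is sampling noise in a phased haploid
    population); LOD is computed from the raw discordance so that rf > 0.5
    pairs score at or below zero.
    """
    calls = np.asarray(calls)
    valid = ((calls == CALL_P1) | (calls == CALL_P2)).astype(np.float64)
    p2 = (calls == CALL_P2).astype(np.float64) * valid
    p1 = valid - p2
    n = valid @ valid.T
    concord = p1 @ p1.T + p2 @ p2.T
    r = n - concord
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(n > 0, r / np.maximum(n, 1), 0.5)
    lod = _lod_from_rn(r, n)
    return np.minimum(rf, 0.5), lod, n.astype(np.int64)


def map_distance(rf, function: str = "haldane", rf_cap: float = 0.49):
    """Convert recombination fraction(s) to centimorgans.

    haldane: -50 ln(1 - 2 rf); kosambi: 25 ln((1 + 2 rf)/(1 - 2 rf)).
    rf >= ``rf_cap`` is capped (the distance of the cap is returned).
    """
    arr = np.asarray(rf, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any((arr < 0) | (arr > 0.5)):
        raise ValueError("rf must lie in [0, 0.5]")
    capped = np.minimum(arr, rf_cap)
    if function == "haldane":
        cm = -50.0 * np.log1p(-2.0 * capped)
    elif function == "kosambi":
        cm = 25.0 * np.log((1.0 + 2.0 * capped) / (1.0 - 2.0 * capped))
    else:
        raise ValueError(f"unknown map function {function!r}")
    return float(cm[0]) if scalar else cm


# ---------------------------------------------------------------------------
# map containers
# ---------------------------------------------------------------------------

@dataclass
class LinkageGroup:
    name: str
    markers: list[MarkerLocus]
    cm: np.ndarray  # cumulative, non-decreasing, cm[0] == 0
    junction_after: Optional[np.ndarray] = None  # per-interval: crosses contigs

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def genetic_length(self) -> float:
        return float(self.cm[-1] - self.cm[0]) if len(self.cm) else 0.0

    @property
    def longest_interval(self) -> float:
        return float(np.max(np.diff(self.cm))) if len(self.cm) > 1 else 0.0

    @property
    def contigs(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.markers:
            seen.setdefault(m.contig, None)
        return list(seen)

    def physical_between_bp(self) -> int:
        """Sum over contigs of (max marker pos - min marker pos)."""
        spans: dict[str, list[int]] = {}
        for m in self.markers:
            spans.setdefault(m.contig, [m.pos, m.pos])
            spans[m.contig][0] = min(spans[m.contig][0], m.pos)
            spans[m.contig][1] = max(spans[m.contig][1], m.pos)
        return sum(b - a for a, b in spans.values())

    def physical_contig_bp(self, assembly: AssemblyIndex) -> int:
        return sum(assembly.contig_lengths[c] for c in self.contigs)


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    unplaced: list[MarkerLocus] = field(default_factory=list)
    map_function: str = "haldane"

    @property
    def n_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    @property
    def total_cm(self) -> float:
        return sum(g.genetic_length for g in self.groups)

    def total_between_bp(self) -> int:
        return sum(g.physical_between_bp() for g in self.groups)

    def total_contig_bp(self, assembly: AssemblyIndex) -> int:
        return sum(g.physical_contig_bp(assembly) for g in self.groups)

    def equals(self, other: "GeneticMap", cm_tol: float = 1e-6) -> bool:
        if len(self.groups) != len(other.groups):
            return False
        for a, b in zip(self.groups, other.groups):
            if a.name != b.name:
                return False
            if [m.key for m in a.markers] != [m.key for m in b.markers]:
                return False
            if not np.allclose(a.cm, b.cm, atol=cm_tol):
                return False
        return True


@dataclass
class MapSummary:
    """Totals and derived genome-wide figures for one map."""

    total_cm: float
    between_mb: float
    contig_mb: float
    assembly_mb: float

    @property
    def rate_cm_per_mb(self) -> float:
        """Total genetic length over total physical length between markers."""
        if self.between_mb <= 0:
            raise ValueError("zero physical length between markers")
        return self.total_cm / self.between_mb

    @property
    def rate_cm_per_mb_contig(self) -> float:
        """Alternative denominator: total represented contig length."""
        if self.contig_mb <= 0:
            raise ValueError("zero contig length")
        return self.total_cm / self.contig_mb

    @property
    def pct_assembly_contigs(self) -> float:
        return 100.0 * self.contig_mb / self.assembly_mb

    @property
    def pct_assembly_between(self) -> float:
        return 100.0 * self.between_mb / self.assembly_mb


def summarize_lengths(
    genetic_cm: Sequence[float],
    between_mb: Sequence[float],
    contig_mb: Sequence[float],
    assembly_mb: float,
) -> MapSummary:
    """Build a :class:`MapSummary` from per-linkage-group totals."""
    return MapSummary(
        total_cm=float(np.sum(genetic_cm)),
        between_mb=float(np.sum(between_mb)),
        contig_mb=float(np.sum(contig_mb)),
        assembly_mb=float(assembly_mb),
    )


def summarize_map(gmap: GeneticMap, assembly: AssemblyIndex) -> MapSummary:
    return MapSummary(
        total_cm=gmap.total_cm,
        between_mb=gmap.total_between_bp() / 1e6,
        contig_mb=gmap.total_contig_bp(assembly) / 1e6,
        assembly_mb=assembly.total_length / 1e6,
    )


def percent_change(old: float, new: float) -> float:
    """100 * (new - old) / old."""
    return 100.0 * (new - old) / old


# ---------------------------------------------------------------------------
# clustering and ordering
# ---------------------------------------------------------------------------

def cluster_linkage_groups(
    m: GenotypeMatrix, lod_threshold: float = 5.5, min_shared: int = 10
) -> list[np.ndarray]:
    """Single-linkage connected components at LOD > threshold.

    Groups are numbered deterministically by descending marker count, then
    by first contig name.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    if m.n_markers == 0:
        return []
    _, lod, n = pairwise_linkage(m.calls)
    adj = (lod > lod_threshold) & (n >= min_shared)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [np.flatnonzero(labels == k) for k in range(n_comp)]
    groups.sort(key=lambda idx: (-len(idx), m.markers[idx[0]].contig, m.markers[idx[0]].pos))
    return groups


def _path_length(order: np.ndarray, dist: np.ndarray) -> float:
    return float(dist[order[:-1], order[1:]].sum())


def _two_opt(order: np.ndarray, dist: np.ndarray, max_rounds: int = 50) -> np.ndarray:
    """2-opt improvement for an open path (segment reversal)."""
    n = len(order)
    improved = True
    rounds = 0
    while improved and rounds < max_rounds:
        improved = False
        rounds += 1
        for i in range(n - 1):
            a = dist[order[i - 1], order[i]] if i > 0 else 0.0
            for j in range(i + 1, n):
                b = dist[order[j], order[j + 1]] if j < n - 1 else 0.0
                new_a = dist[order[i - 1], order[j]] if i > 0 else 0.0
                new_b = dist[order[i], order[j + 1]] if j < n - 1 else 0.0
                delta = (new_a + new_b) - (a + b)
                if delta < -1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True
                    a = dist[order[i - 1], order[i]] if i > 0 else 0.0
    return order


def order_markers(m: GenotypeMatrix, rows: Optional[np.ndarray] = None) -> np.ndarray:
    """Seriation of one linkage group: greedy nearest-neighbour paths from
    several deterministic starts, improved by 2-opt, minimizing the sum of
    adjacent recombination fractions.

    Returns row indices into ``m`` in map order.  Orientation is normalized
    so the first marker has the lexicographically smaller (contig, pos).
    Ties fall back to physical input order (stable greedy scan).
    """
    if rows is None:
        rows = np.arange(m.n_markers)
    rows = np.asarray(rows)
    k = len(rows)
    if k <= 2:
        return rows
    rf, lod, n = pairwise_linkage(m.calls[rows])
    dist = rf.copy()
    dist[n == 0] = 0.5
    np.fill_diagonal(dist, np.inf)

    starts = range(k) if k <= 12 else np.linspace(0, k - 1, 10, dtype=int)
    best_order = None
    best_len = np.inf
    for s in starts:
        order = [s]
        used = np.zeros(k, dtype=bool)
        used[s] = True
        while len(order) < k:
            d = dist[order[-1]].copy()
            d[used] = np.inf
            nxt = int(np.argmin(d))  # stable: first minimum in input order
            order.append(nxt)
            used[nxt] = True
        order = _two_opt(np.array(order), np.where(np.isinf(dist), 0.5, dist))
        length = _path_length(order, np.where(np.isinf(dist), 0.5, dist))
        if length < best_len - 1e-12:
            best_len = length
            best_order = order
    first, last = rows[best_order[0]], rows[best_order[-1]]
    if m.markers[first].key > m.markers[last].key:
        best_order = best_order[::-1]
    return rows[best_order]


def _cumulative_cm(
    m: GenotypeMatrix, order: np.ndarray, map_function: str
) -> np.ndarray:
    calls = m.calls[order]
    rf = np.empty(len(order) - 1)
    for i in range(len(order) - 1):
        tp = two_point_linkage(calls[i], calls[i + 1], min_shared=1)
        rf[i] = tp.rf
    cm = np.concatenate([[0.0], np.cumsum(map_distance(rf, map_function))])
    return cm


def build_strict_map(
    m: GenotypeMatrix,
    lod_threshold: float = 5.5,
    map_function: str = "haldane",
    min_shared: int = 10,
) -> GeneticMap:
    """Cluster, order and accumulate cM for a strictly filtered matrix.

    Single-marker groups are emitted as unplaced and excluded from totals.
    """
    groups_idx = cluster_linkage_groups(m, lod_threshold, min_shared)
    groups: list[LinkageGroup] = []
    unplaced: list[MarkerLocus] = []
    for idx in groups_idx:
        if len(idx) < 2:
            unplaced.extend(m.markers[i] for i in idx)
            continue
        order = order_markers(m, idx)
        cm = _cumulative_cm(m, order, map_function)
        contigs = [m.markers[i].contig for i in order]
        junction = np.array(
            [contigs[i] != contigs[i + 1] for i in range(len(order) - 1)]
        )
        groups.append(
            LinkageGroup(
                name="",  # named below
                markers=[m.markers[i] for i in order],
                cm=cm,
                junction_after=junction,
            )
        )
    groups.sort(key=lambda g: (-g.n_markers, g.markers[0].contig, g.markers[0].pos))
    for i, g in enumerate(groups, start=1):
        g.name = f"LG{i}"
    return GeneticMap(groups, unplaced=unplaced, map_function=map_function)


# ---------------------------------------------------------------------------
# trait placement
# ---------------------------------------------------------------------------

@dataclass
class TraitPlacement:
    linkage_group: Optional[str]
    best_marker: Optional[MarkerLocus]
    best_lod: float
    best_rf: float
    neighbor_lods: list[tuple[str, float]]
    placed: bool


def map_trait_as_marker(
    m: GenotypeMatrix,
    gmap: GeneticMap,
    trait: TraitTable,
    lod_threshold: float = 5.5,
    min_shared: int = 10,
) -> TraitPlacement:
    """Place a binary trait as a pseudo-marker: the LG/interval whose marker
    maximizes two-point LOD with the trait vector, with LODs to the map
    neighbours of the best marker reported."""
    vec = trait.as_call_vector(m.samples)
    n_scored = int((vec != CALL_MISSING).sum())
    if n_scored < min_shared:
        return TraitPlacement(None, None, 0.0, 0.5, [], placed=False)
    idx = m.marker_index()
    best = (None, -np.inf, 0.5)  # (marker, lod, rf)
    for lg in gmap.groups:
        for mk in lg.markers:
            row = idx.get(mk.id)
            if row is None:
                continue
            tp = two_point_linkage(vec, m.calls[row], min_shared=min_shared)
            if tp.n_informative >= min_shared and tp.lod > best[1]:
                best = (mk, tp.lod, tp.rf)
    if best[0] is None or best[1] < lod_threshold:
        return TraitPlacement(None, best[0], float(max(best[1], 0.0)),
                              best[2], [], placed=False)
    best_marker, best_lod, best_rf = best
    lg_name = None
    neighbors: list[tuple[str, float]] = []
    for lg in gmap.groups:
        keys = [mk.id for mk in lg.markers]
        if best_marker.id in keys:
            lg_name = lg.name
            j = keys.index(best_marker.id)
            for jj in (j - 1, j + 1):
                if 0 <= jj < len(keys):
                    row = idx[keys[jj]]
                    tp = two_point_linkage(vec, m.calls[row], min_shared=1)
                    neighbors.append((keys[jj], tp.lod))
            break
    return TraitPlacement(lg_name, best_marker, float(best_lod), float(best_rf),
                          neighbors, placed=True)


# ---------------------------------------------------------------------------
# forced order: contig chaining, imputation, map
# ---------------------------------------------------------------------------

@dataclass
class ContigChain:
    entries: list[tuple[str, str]]  # (contig, orientation "+"/"-")
    junction_lods: list[float] = field(default_factory=list)

    @property
    def contigs(self) -> list[str]:
        return [c for c, _ in self.entries]


def _contig_end_patterns(m: GenotypeMatrix, min_shared: int):
    """For each contig with markers: (head_row, tail_row) where each end is
    the most distal marker, falling back to the second-most-distal when the
    distal one has no informative calls."""
    ends = {}
    for contig, rows in m.contig_rows().items():
        def pick(candidates):
            for r in candidates:
                informative = ((m.calls[r] == CALL_P1) | (m.calls[r] == CALL_P2)).sum()
                if informative >= min_shared:
                    return r
            return None
        head = pick(rows[:2])
        tail = pick(rows[::-1][:2])
        ends[contig] = (head, tail, rows)
    return ends


def chain_contigs(
    m: GenotypeMatrix, lod_threshold: float = 5.5, min_shared: int = 10
) -> tuple[list[ContigChain], list[dict]]:
    """Join contigs whose most distal markers are linked above
    ``lod_threshold`` into oriented chains.

    Edges between contig ends are ranked by LOD; a greedy matching accepts
    each edge when both ends are still free and the contigs are not already
    in the same chain (no cycles).  Rejected competitors are returned as a
    conflict log.
    """
    ends = _contig_end_patterns(m, min_shared)
    contigs = list(ends)
    candidates = []
    for i, ca in enumerate(contigs):
        for cb in contigs[i + 1 :]:
            for ea in ("head", "tail"):
                ra = ends[ca][0 if ea == "head" else 1]
                if ra is None:
                    continue
                for eb in ("head", "tail"):
                    rb = ends[cb][0 if eb == "head" else 1]
                    if rb is None:
                        continue
                    tp = two_point_linkage(m.calls[ra], m.calls[rb], min_shared)
                    if tp.n_informative >= min_shared and tp.lod > lod_threshold:
                        candidates.append((tp.lod, ca, ea, cb, eb))
    candidates.sort(key=lambda t: (-t[0], t[1], t[3], t[2], t[4]))

    parent = {c: c for c in contigs}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    used_ends: set[tuple[str, str]] = set()
    accepted: list[tuple[float, str, str, str, str]] = []
    conflicts: list[dict] = []
    for lod, ca, ea, cb, eb in candidates:
        if (ca, ea) in used_ends or (cb, eb) in used_ends:
            conflicts.append(
                {"contig_a": ca, "end_a": ea, "contig_b": cb, "end_b": eb,
                 "lod": lod, "reason": "end already joined"}
            )
            continue
        if find(ca) == find(cb):
            conflicts.append(
                {"contig_a": ca, "end_a": ea, "contig_b": cb, "end_b": eb,
                 "lod": lod, "reason": "would close a cycle"}
            )
            continue
        used_ends.add((ca, ea))
        used_ends.add((cb, eb))
        parent[find(ca)] = find(cb)
        accepted.append((lod, ca, ea, cb, eb))

    # adjacency: contig -> {end: (other_contig, other_end, lod)}
    adj: dict[str, dict[str, tuple[str, str, float]]] = {c: {} for c in contigs}
    for lod, ca, ea, cb, eb in accepted:
        adj[ca][ea] = (cb, eb, lod)
        adj[cb][eb] = (ca, ea, lod)

    chains: list[ContigChain] = []
    visited: set[str] = set()
    for c in contigs:
        if c in visited or len(adj[c]) == 2:
            continue
        # start of a chain (degree 0 or 1)
        entries: list[tuple[str, str]] = []
        lods: list[float] = []
        cur = c
        # entry end: the free one; exit via the joined one
        if not adj[cur]:
            visited.add(cur)
            chains.append(ContigChain([(cur, "+")]))
            continue
        exit_end = next(iter(adj[cur]))
        orient = "+" if exit_end == "tail" else "-"
        entries.append((cur, orient))
        visited.add(cur)
        while exit_end in adj[cur]:
            nxt, nxt_end, lod = adj[cur][exit_end]
            lods.append(lod)
            orient = "+" if nxt_end == "head" else "-"
            entries.append((nxt, orient))
            visited.add(nxt)
            cur = nxt
            exit_end = "tail" if nxt_end == "head" else "head"
        if entries[-1][0] < entries[0][0]:  # normalize direction
            entries = [(c, "+" if o == "-" else "-") for c, o in reversed(entries)]
            lods = lods[::-1]
        chains.append(ContigChain(entries, lods))
    # any ring (all degree 2) would be skipped above; cycles are prevented
    # by the union-find, so every contig is visited.
    chains.sort(key=lambda ch: (-len(ch.entries), ch.entries[0][0]))
    return chains, conflicts


def impute_missing_forced(m: GenotypeMatrix) -> GenotypeMatrix:
    """Forward-fill missing calls along physical order within each contig;
    a leading missing run takes the first non-missing call.  Samples fully
    missing on a contig are left missing and counted in ``meta``."""
    out = m.copy()
    n_unfilled = 0
    for contig, rows in out.contig_rows().items():
        block = out.calls[rows]
        for s in range(block.shape[1]):
            col = block[:, s]
            miss = col == CALL_MISSING
            if not miss.any():
                continue
            if miss.all():
                n_unfilled += 1
                continue
            last = CALL_MISSING
            for i in range(len(col)):
                if col[i] != CALL_MISSING:
                    last = col[i]
                elif last != CALL_MISSING:
                    col[i] = last
            first_called = col[col != CALL_MISSING][0]
            col[col == CALL_MISSING] = first_called
        out.calls[rows] = block
    out.meta["unfilled_contig_samples"] = n_unfilled
    return out


def build_forced_map(
    m: GenotypeMatrix,
    chains: list[ContigChain],
    map_function: str = "haldane",
) -> GeneticMap:
    """Forced-order map: physical marker order within contigs, chain order
    across contigs, cumulative cM from adjacent-pair recombination
    fractions (junction intervals included)."""
    rows_by_contig = m.contig_rows()
    groups: list[LinkageGroup] = []
    unplaced: list[MarkerLocus] = []
    for chain in chains:
        order: list[int] = []
        for contig, orient in chain.entries:
            rows = rows_by_contig.get(contig)
            if rows is None:
                continue
            order.extend(rows if orient == "+" else rows[::-1])
        if len(order) < 2:
            unplaced.extend(m.markers[i] for i in order)
            continue
        order = np.array(order)
        cm = _cumulative_cm(m, order, map_function)
        contigs = [m.markers[i].contig for i in order]
        junction = np.array(
            [contigs[i] != contigs[i + 1] for i in range(len(order) - 1)]
        )
        groups.append(
            LinkageGroup("", [m.markers[i] for i in order], cm, junction)
        )
    groups.sort(key=lambda g: (-g.n_markers, g.markers[0].contig, g.markers[0].pos))
    for i, g in enumerate(groups, start=1):
        g.name = f"LG{i}"
    return GeneticMap(groups, unplaced=unplaced, map_function=map_function)


# ---------------------------------------------------------------------------
# the r-bar shuffling statistic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RbarResult:
    inter: float
    intra: float

    @property
    def rbar(self) -> float:
        return self.inter + self.intra


def compute_rbar(
    chromosome_lengths: Sequence[float],
    gametes: Sequence[dict],
) -> RbarResult:
    """Expected fraction of random locus pairs whose alleles are shuffled in
    a gamete.

    inter-chromosomal component: (1 - sum p_i^2) / 2 with p_i the
    chromosome length fractions (independent assortment).  The
    intra-chromosomal component is the probability that two uniformly
    chosen loci land on the same chromosome *and* derive from different
    parental haplotypes, averaged over gametes: for a gamete whose
    chromosome i splits into parental spans A + B = L_i, the discordant
    same-chromosome pair fraction is 2 A B / L_i^2.

    ``gametes``: one dict per gamete mapping chromosome index -> sorted
    crossover breakpoint positions (bp).
    """
    L = np.asarray(chromosome_lengths, dtype=float)
    if np.any(L <= 0):
        raise ValueError("chromosome lengths must be positive")
    p = L / L.sum()
    inter = (1.0 - float(np.sum(p**2))) / 2.0
    if len(gametes) == 0:
        raise ValueError("empty gamete set: intra component undefined")
    intra_vals = []
    for g in gametes:
        acc = 0.0
        for i, length in enumerate(L):
            bps = np.asarray(g.get(i, ()), dtype=float)
            segs = np.diff(np.concatenate([[0.0], np.sort(bps), [length]]))
            a = float(segs[::2].sum())
            b = length - a
            acc += p[i] ** 2 * (2.0 * a * b / length**2)
        intra_vals.append(acc)
    return RbarResult(inter=inter, intra=float(np.mean(intra_vals)))
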