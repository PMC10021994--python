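"""linkage_core: two-point statistics, map functions, clustering, ordering,
strict and forced maps, contig chaining, imputation, summaries and r-bar."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from karyolink.linkage_core import (
    ContigChain,
    GeneticMap,
    LinkageGroup,
    build_forced_map,
    build_strict_map,
    chain_contigs,
    cluster_linkage_groups,
    compute_rbar,
    impute_missing_forced,
    map_distance,
    map_trait_as_marker,
    order_markers,
    pairwise_linkage,
    percent_change,
    summarize_lengths,
    summarize_map,
    two_point_linkage,
)
from karyolink.model import MarkerLocus, TraitTable

from conftest import H, M, P1, P2, make_matrix


def _flip(vec, idx):
    out = list(vec)
    for i in idx:
        out[i] = 1 - out[i]
    return out


class TestTwoPointLinkage:
    def test_identical_vectors(self):
        v = np.array([P1, P2] * 44)
        tp = two_point_linkage(v, v)
        assert tp.rf == 0.0
        assert tp.lod == pytest.approx(88 * math.log10(2), abs=1e-9)

    def test_rf_half_gives_zero_lod(self):
        a = np.array([P1] * 10 + [P2] * 10)
        b = np.array(([P1] * 5 + [P2] * 5) * 2)
        tp = two_point_linkage(a, b)
        assert tp.rf == 0.5
        assert tp.lod == pytest.approx(0.0, abs=1e-9)

    def test_n20_r4(self):
        a = [P1] * 10 + [P2] * 10
        b = _flip(a, [0, 1, 10, 11])
        tp = two_point_linkage(np.array(a), np.array(b))
        assert tp.rf == pytest.approx(0.2)
        expected = 16 * math.log10(1.6) + 4 * math.log10(0.4)
        assert tp.lod == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(1.67, abs=0.01)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        t1, t2 = two_point_linkage(a, b), two_point_linkage(b, a)
        assert (t1.rf, t1.lod, t1.n_informative) == (t2.rf, t2.lod, t2.n_informative)

    def test_global_phase_flip_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        t1 = two_point_linkage(a, b)
        t2 = two_point_linkage(1 - a, 1 - b)
        assert t1.rf == t2.rf and t1.lod == pytest.approx(t2.lod)

    def test_missing_and_het_excluded(self):
        a = np.array([P1, P2, M, H, P1])
        b = np.array([P1, P1, P1, P1, M])
        tp = two_point_linkage(a, b)
        assert tp.n_informative == 2
        assert tp.rf == pytest.approx(0.5)

    def test_pairwise_matches_scalar(self):
        rng = np.random.default_rng(2)
        calls = rng.choice([P1, P2, M, H], p=[0.45, 0.45, 0.05, 0.05],
                           size=(6, 60)).astype(np.int8)
        rf, lod, n = pairwise_linkage(calls)
        for i in range(6):
            for j in range(6):
                tp = two_point_linkage(calls[i], calls[j])
                assert rf[i, j] == pytest.approx(tp.rf)
                assert lod[i, j] == pytest.approx(tp.lod, abs=1e-9)
                assert n[i, j] == tp.n_informative


class TestMapDistance:
    def test_zero(self):
        assert map_distance(0.0) == 0.0
        assert map_distance(0.0, "kosambi") == 0.0

    def test_haldane_closed_form(self):
        assert map_distance(0.2, "haldane") == pytest.approx(
            -50 * math.log(0.6), abs=1e-9
        )
        assert map_distance(0.2, "haldane") == pytest.approx(25.54, abs=0.01)

    def test_kosambi_closed_form(self):
        assert map_distance(0.2, "kosambi") == pytest.approx(
            25 * math.log(1.4 / 0.6), abs=1e-9
        )
        assert map_distance(0.2, "kosambi") == pytest.approx(21.18, abs=0.01)

    def test_cap(self):
        assert map_distance(0.5) == map_distance(0.49)

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            map_distance(-0.01)
        with pytest.raises(ValueError):
            map_distance(0.51)
        with pytest.raises(ValueError):
            map_distance(0.2, "morgan")


class TestClustering:
    def _three_markers(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 60).astype(np.int8)
        b = np.array(_flip(a, range(3)), dtype=np.int8)   # rf 0.05 vs a
        c = np.array(_flip(b, range(3, 6)), dtype=np.int8)  # rf 0.05 vs b
        return make_matrix([a.tolist(), b.tolist(), c.tolist()],
                           samples=[f"s{i}" for i in range(60)])

    def test_transitive_single_linkage(self):
        m = self._three_markers()
        _, lod, _ = pairwise_linkage(m.calls)
        assert lod[0, 1] > 5.5 and lod[1, 2] > 5.5
        groups = cluster_linkage_groups(m, 5.5)
        assert len(groups) == 1 and len(groups[0]) == 3

    def test_all_unlinked_singletons(self):
        rng = np.random.default_rng(4)
        rows = rng.integers(0, 2, size=(3, 40)).astype(np.int8)
        m = make_matrix(rows.tolist(), samples=[f"s{i}" for i in range(40)])
        groups = cluster_linkage_groups(m, 5.5)
        assert len(groups) == 3

    def test_two_components(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 60).astype(np.int8)
        b = np.array(_flip(a, [0]), dtype=np.int8)
        c = rng.integers(0, 2, 60).astype(np.int8)
        d = np.array(_flip(c, [1]), dtype=np.int8)
        m = make_matrix([a.tolist(), b.tolist(), c.tolist(), d.tolist()],
                        samples=[f"s{i}" for i in range(60)])
        groups = cluster_linkage_groups(m, 5.5)
        assert sorted(len(g) for g in groups) == [2, 2]


def brute_force_best_path(dist: np.ndarray) -> float:
    """Exhaustive-permutation minimum of the adjacent-distance sum."""
    n = dist.shape[0]
    best = np.inf
    for perm in itertools.permutations(range(n)):
        if perm[0] > perm[-1]:
            continue  # skip mirror duplicates
        length = sum(dist[perm[i], perm[i + 1]] for i in range(n - 1))
        best = min(best, length)
    return best


class TestOrderMarkers:
    def _chain_matrix(self, k, flips_per_step=2, n=80, seed=6, shuffle=True):
        rng = np.random.default_rng(seed)
        base = rng.integers(0, 2, n).astype(np.int8)
        rows = [base.tolist()]
        used = list(range(n))
        rng.shuffle(used)
        ptr = 0
        for _ in range(k - 1):
            rows.append(_flip(rows[-1], used[ptr : ptr + flips_per_step]))
            ptr += flips_per_step
        order = list(range(k))
        if shuffle:
            rng.shuffle(order)
        m = make_matrix([rows[i] for i in order],
                        samples=[f"s{i}" for i in range(n)])
        # markers got re-sorted by position; map original index -> row
        true_rank = np.argsort(order)  # row i holds original order[i]
        return m, np.array(order)

    def test_recovers_monotone_order(self):
        m, scrambled = self._chain_matrix(6)
        rows = order_markers(m)
        recovered = [scrambled[i] for i in rows]
        assert recovered == sorted(recovered) or recovered == sorted(
            recovered, reverse=True
        )

    def test_matches_exhaustive_optimum(self):
        for seed in (6, 7, 8):
            m, _ = self._chain_matrix(7, seed=seed)
            rows = order_markers(m)
            rf, _, _ = pairwise_linkage(m.calls)
            got = sum(rf[rows[i], rows[i + 1]] for i in range(len(rows) - 1))
            assert got == pytest.approx(brute_force_best_path(rf), abs=1e-12)

    def test_two_markers_trivial(self):
        m = make_matrix([[P1, P2], [P2, P1]])
        assert len(order_markers(m)) == 2

    def test_duplicate_patterns_stable(self):
        m = make_matrix([[P1, P2, P1, P2]] * 3)
        rows = order_markers(m)
        assert sorted(rows.tolist()) == [0, 1, 2]


class TestBuildStrictMap:
    def _equidistant(self):
        # 3 markers, adjacent rf = 0.1 on n=20
        a = [P1] * 10 + [P2] * 10
        b = _flip(a, [0, 10])
        c = _flip(b, [1, 11])
        return make_matrix([a, b, c], samples=[f"s{i}" for i in range(20)])

    def test_three_equidistant_markers(self):
        m = self._equidistant()
        gmap = build_strict_map(m, lod_threshold=2.0)
        assert len(gmap.groups) == 1
        expected = 2 * map_distance(0.1)
        assert gmap.groups[0].genetic_length == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(22.3, abs=0.1)

    def test_identical_markers_zero_length(self):
        m = make_matrix([[P1, P2] * 20] * 4, samples=[f"s{i}" for i in range(40)])
        gmap = build_strict_map(m, lod_threshold=5.5)
        assert len(gmap.groups) == 1
        assert gmap.groups[0].genetic_length == 0.0

    def test_singleton_unplaced(self):
        rng = np.random.default_rng(9)
        rows = rng.integers(0, 2, size=(2, 40)).astype(np.int8).tolist()
        m = make_matrix(rows, samples=[f"s{i}" for i in range(40)])
        gmap = build_strict_map(m, lod_threshold=5.5)
        assert len(gmap.groups) == 0
        assert len(gmap.unplaced) == 2

    def test_reversal_invariance(self):
        m = self._equidistant()
        gmap = build_strict_map(m, lod_threshold=2.0)
        lg = gmap.groups[0]
        rev = LinkageGroup(
            lg.name,
            list(reversed(lg.markers)),
            np.concatenate([[0.0], np.cumsum(np.diff(lg.cm)[::-1])]),
        )
        assert rev.genetic_length == pytest.approx(lg.genetic_length)

    def test_simulator_map_length_recovery(self, clean_sim):
        cfg, genome, matrix, truth = clean_sim
        from karyolink.marker_filtering import filter_strict

        filtered, _ = filter_strict(matrix)
        gmap = build_strict_map(filtered)
        expected = 100.0 * cfg.n_chromosomes * (1 + cfg.extra_crossover_rate)
        assert abs(gmap.total_cm - expected) / expected < 0.10


class TestTraitMapping:
    def test_trait_equal_to_marker(self, clean_sim):
        _, _, matrix, _ = clean_sim
        from karyolink.marker_filtering import filter_strict

        filtered, _ = filter_strict(matrix)
        gmap = build_strict_map(filtered)
        lg = gmap.groups[0]
        target = lg.markers[len(lg.markers) // 2]
        row = filtered.marker_index()[target.id]
        # trait scored on 30 samples, copying the marker's pattern
        values = {
            s: int(filtered.calls[row, i])
            for i, s in enumerate(filtered.samples[:30])
            if filtered.calls[row, i] in (0, 1)
        }
        placement = map_trait_as_marker(filtered, gmap, TraitTable(values))
        assert placement.placed
        assert placement.linkage_group == lg.name
        assert placement.best_rf == pytest.approx(0.0)
        assert len(placement.neighbor_lods) >= 1

    def test_independent_trait_unplaced(self, clean_sim):
        _, _, matrix, _ = clean_sim
        from karyolink.marker_filtering import filter_strict

        filtered, _ = filter_strict(matrix)
        gmap = build_strict_map(filtered)
        rng = np.random.default_rng(10)
        values = {s: int(rng.integers(2)) for s in filtered.samples[:30]}
        placement = map_trait_as_marker(filtered, gmap, TraitTable(values))
        assert not placement.placed

    def test_sparse_trait_unplaced(self, clean_sim):
        _, _, matrix, _ = clean_sim
        from karyolink.marker_filtering import filter_strict

        filtered, _ = filter_strict(matrix)
        gmap = build_strict_map(filtered)
        placement = map_trait_as_marker(
            filtered, gmap, TraitTable({filtered.samples[0]: 1})
        )
        assert not placement.placed


class TestChainContigs:
    def _two_contig_matrix(self, n=80, junction_flips=2, seed=11):
        """Contigs X and Y adjacent on one chromosome: tail(X) ~ head(Y)."""
        rng = np.random.default_rng(seed)
        base = rng.integers(0, 2, n).astype(np.int8)
        rows, contigs, pos = [], [], []
        cur = base.tolist()
        for i in range(4):
            rows.append(cur)
            contigs.append("X")
            pos.append((i + 1) * 1000)
            cur = _flip(cur, [2 * i, 2 * i + 1])
        for i in range(4):
            rows.append(cur)
            contigs.append("Y")
            pos.append((i + 1) * 1000)
            cur = _flip(cur, [20 + 2 * i, 21 + 2 * i])
        return make_matrix(rows, contigs=contigs, positions=pos,
                           samples=[f"s{i}" for i in range(n)])

    def test_simple_chain(self):
        m = self._two_contig_matrix()
        chains, conflicts = chain_contigs(m, lod_threshold=5.5)
        assert len(chains) == 1
        assert chains[0].contigs == ["X", "Y"]
        assert chains[0].entries[0][1] == "+" and chains[0].entries[1][1] == "+"

    def test_no_edges_all_isolated(self):
        rng = np.random.default_rng(12)
        rows = rng.integers(0, 2, size=(4, 40)).astype(np.int8).tolist()
        m = make_matrix(rows, contigs=["X", "X", "Y", "Y"],
                        positions=[1000, 2000, 1000, 2000],
                        samples=[f"s{i}" for i in range(40)])
        chains, _ = chain_contigs(m, lod_threshold=5.5)
        assert sorted(len(c.entries) for c in chains) == [1, 1]

    def test_max_lod_wins_conflict_logged(self):
        n = 80
        rng = np.random.default_rng(13)
        base = rng.integers(0, 2, n).astype(np.int8).tolist()
        rows, contigs, pos = [], [], []
        for i, c in enumerate(["X", "X"]):
            rows.append(base)
            contigs.append(c)
            pos.append((i + 1) * 1000)
        y_head = base  # rf 0 with tail(X): highest LOD
        z_head = _flip(base, range(6))  # linked but weaker
        for i, (c, v) in enumerate([("Y", y_head), ("Y", y_head),
                                    ("Z", z_head), ("Z", z_head)]):
            rows.append(v)
            contigs.append(c)
            pos.append((i % 2 + 1) * 1000)
        m = make_matrix(rows, contigs=contigs, positions=pos,
                        samples=[f"s{i}" for i in range(n)])
        chains, conflicts = chain_contigs(m, lod_threshold=5.5)
        joined = next(c for c in chains if len(c.entries) > 1)
        assert set(joined.contigs) >= {"X", "Y"}
        assert any(c["reason"] == "end already joined" for c in conflicts)

    def test_recovers_true_adjacency(self, clean_sim):
        cfg, genome, matrix, truth = clean_sim
        chains, _ = chain_contigs(matrix, lod_threshold=5.5)
        truth_order = genome.true_contig_order()
        got = {tuple(c.contigs) for c in chains if len(c.entries) > 1}
        for chrom, layout in truth_order.items():
            names = [n for n, _ in layout]
            assert tuple(names) in got or tuple(reversed(names)) in got

    def test_orientation_matches_truth(self, clean_sim):
        cfg, genome, matrix, truth = clean_sim
        chains, _ = chain_contigs(matrix, lod_threshold=5.5)
        truth_order = genome.true_contig_order()
        by_first = {c.contigs[0]: c for c in chains if len(c.entries) > 1}
        by_last = {c.contigs[-1]: c for c in chains if len(c.entries) > 1}
        for chrom, layout in truth_order.items():
            names = [n for n, _ in layout]
            orients = [o for _, o in layout]
            chain = by_first.get(names[0]) or by_last.get(names[0])
            assert chain is not None
            entries = chain.entries
            if entries[0][0] != names[0]:
                entries = [(c, "+" if o == "-" else "-") for c, o in reversed(entries)]
            assert [c for c, _ in entries] == names
            # relative orientation must match truth (up to global flip)
            rel_true = [o == orients[0] for o in orients]
            rel_got = [o == entries[0][1] for _, o in entries]
            assert rel_got == rel_true


class TestImputation:
    def test_forward_fill(self):
        m = make_matrix([[P1], [M], [P2]])
        out = impute_missing_forced(m)
        assert out.calls[:, 0].tolist() == [P1, P1, P2]

    def test_leading_missing_backfilled(self):
        m = make_matrix([[M], [P2], [P2]])
        out = impute_missing_forced(m)
        assert out.calls[:, 0].tolist() == [P2, P2, P2]

    def test_identity_when_complete(self):
        m = make_matrix([[P1, P2], [P2, P1]])
        assert impute_missing_forced(m).equals(m)

    def test_contig_boundary_respected(self):
        m = make_matrix([[P1], [M]], contigs=["c1", "c2"], positions=[1000, 1000])
        out = impute_missing_forced(m)
        assert out.calls[1, 0] == M  # never filled across contigs
        assert out.meta["unfilled_contig_samples"] == 1


class TestBuildForcedMap:
    def test_zero_length_single_contig(self):
        m = make_matrix([[P1, P2]] * 3)
        chains = [ContigChain([("c1", "+")])]
        gmap = build_forced_map(m, chains)
        assert gmap.groups[0].genetic_length == 0.0

    def test_junction_contributes_haldane(self):
        a = [P1] * 10 + [P2] * 10
        b = _flip(a, [0, 10])  # rf 0.1 across the junction
        m = make_matrix([a, a, b, b], contigs=["X", "X", "Y", "Y"],
                        positions=[1000, 2000, 1000, 2000],
                        samples=[f"s{i}" for i in range(20)])
        gmap = build_forced_map(m, [ContigChain([("X", "+"), ("Y", "+")])])
        assert gmap.groups[0].genetic_length == pytest.approx(
            map_distance(0.1), abs=1e-9
        )
        assert gmap.groups[0].junction_after.tolist() == [False, True, False]

    def test_simulator_chain_map(self, clean_sim):
        cfg, genome, matrix, truth = clean_sim
        chains, _ = chain_contigs(matrix, lod_threshold=5.5)
        imputed = impute_missing_forced(matrix)
        gmap = build_forced_map(imputed, chains)
        assert len(gmap.groups) == cfg.n_chromosomes
        expected = 100.0 * cfg.n_chromosomes * (1 + cfg.extra_crossover_rate)
        assert abs(gmap.total_cm - expected) / expected < 0.10


class TestSummaries:
    def test_rate_closed_form(self):
        s = summarize_lengths([60.0, 40.0], [2.5, 2.5], [3.0, 3.0], 10.0)
        assert s.rate_cm_per_mb == pytest.approx(20.0)
        assert s.pct_assembly_contigs == pytest.approx(60.0)

    def test_zero_physical_raises(self):
        s = summarize_lengths([10.0], [0.0], [0.0], 10.0)
        with pytest.raises(ValueError):
            _ = s.rate_cm_per_mb

    def test_summarize_map_consistent(self, clean_sim):
        cfg, genome, matrix, _ = clean_sim
        chains, _ = chain_contigs(matrix, lod_threshold=5.5)
        imputed = impute_missing_forced(matrix)
        gmap = build_forced_map(imputed, chains)
        s = summarize_map(gmap, genome.assembly)
        assert s.total_cm == pytest.approx(gmap.total_cm)
        assert s.assembly_mb == pytest.approx(genome.assembly.total_length / 1e6)
        assert 0 < s.pct_assembly_between <= s.pct_assembly_contigs <= 100.0

    def test_percent_change(self):
        assert percent_change(100.0, 107.0) == pytest.approx(7.0)
        assert percent_change(4.56, 4.07) == pytest.approx(-10.75, abs=0.01)


def brute_force_intra(chrom_lengths, gametes, n_loci=1000):
    """Discretized pair-enumeration oracle for the intra component."""
    L = np.asarray(chrom_lengths, float)
    p = L / L.sum()
    vals = []
    for g in gametes:
        acc = 0.0
        for ci, length in enumerate(L):
            xs = (np.arange(n_loci) + 0.5) * length / n_loci
            par = np.searchsorted(np.sort(np.asarray(g.get(ci, ()))), xs) % 2
            diff = (par[:, None] != par[None, :]).mean()
            acc += p[ci] ** 2 * diff
        vals.append(acc)
    return float(np.mean(vals))


class TestComputeRbar:
    def test_two_chromosomes_no_crossovers(self):
        res = compute_rbar([100.0, 100.0], [{0: [], 1: []}])
        assert res.inter == pytest.approx(0.25)
        assert res.intra == pytest.approx(0.0)
        assert res.rbar == pytest.approx(0.25)

    def test_midpoint_crossover_intra_half(self):
        gametes = [{0: [50.0]} for _ in range(5)]
        res = compute_rbar([100.0], gametes)
        assert res.intra == pytest.approx(0.5)
        oracle = brute_force_intra([100.0], gametes)
        assert abs(res.intra - oracle) < 1e-3

    def test_matches_brute_force(self):
        rng = np.random.default_rng(21)
        lengths = [120.0, 80.0, 50.0]
        gametes = []
        for _ in range(20):
            g = {}
            for ci, L in enumerate(lengths):
                k = rng.poisson(1.2)
                g[ci] = np.sort(rng.uniform(0, L, k))
            gametes.append(g)
        res = compute_rbar(lengths, gametes)
        oracle = brute_force_intra(lengths, gametes)
        assert abs(res.intra - oracle) < 1e-3

    def test_assortment_dominates_crossovers(self):
        """10 equal chromosomes, 1 uniform crossover each: inter = 0.45 and
        inter/intra is about an order of magnitude."""
        rng = np.random.default_rng(22)
        lengths = [1.0] * 10
        gametes = [
            {ci: [rng.uniform(0, 1)] for ci in range(10)} for _ in range(400)
        ]
        res = compute_rbar(lengths, gametes)
        assert res.inter == pytest.approx(0.45)
        # E[2u(1-u)] = 1/3 per chromosome; weighted by p_i^2 = 1/100 each
        assert res.intra == pytest.approx(10 * 0.01 * (1 / 3), rel=0.1)
        assert 8 < res.inter / res.intra < 20

    def test_empty_gametes_error(self):
        with pytest.raises(ValueError):
            compute_rbar([100.0], [])
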