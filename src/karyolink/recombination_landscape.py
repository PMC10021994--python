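"""Per-interval crossover counts tested against a marker-distance-weighted
multinomial null, with BH correction, ~500 kb binning and the
distance-crossover correlation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .linkage_core import GeneticMap
from .model import GenotypeMatrix

INTERVAL_COLUMNS = [
    "linkage_group",
    "contig_a",
    "pos_a",
    "contig_b",
    "pos_b",
    "distance",
    "is_junction",
    "count",
]


@dataclass
class CrossoverTable:
    """Ordered adjacent-marker intervals with physical distances and
    crossover counts summed over offspring."""

    table: pd.DataFrame
    breakpoints: dict[str, list[int]] = field(default_factory=dict)
    # breakpoints: sample -> interval row indices where that offspring switches

    @property
    def total_crossovers(self) -> int:
        return int(self.table["count"].sum())

    def testable(self) -> pd.DataFrame:
        """Intervals entering the multinomial null: non-junction, d > 0."""
        t = self.table
        return t[(~t["is_junction"]) & (t["distance"] > 0)]


def count_crossovers(m: GenotypeMatrix, gmap: GeneticMap) -> CrossoverTable:
    """Count, per interval between adjacent map markers, the offspring whose
    calls differ at the flanking markers.

    Expects an imputed (missing-free) matrix; any residual missing call at a flank
    makes that offspring uninformative for the interval.  Junction
    intervals (adjacent markers on different contigs) are counted but
    flagged; their physical distance is NaN.
    """
    idx = m.marker_index()
    rows = []
    breakpoints: dict[str, list[int]] = {s: [] for s in m.samples}
    interval_no = 0
    for lg in gmap.groups:
        for i in range(lg.n_markers - 1):
            a, b = lg.markers[i], lg.markers[i + 1]
            ra, rb = idx[a.id], idx[b.id]
            ca, cb = m.calls[ra], m.calls[rb]
            informative = (ca >= 0) & (cb >= 0) & (ca < 2) & (cb < 2)
            diff = informative & (ca != cb)
            junction = a.contig != b.contig
            rows.append(
                (
                    lg.name,
                    a.contig,
                    a.pos,
                    b.contig,
                    b.pos,
                    np.nan if junction else float(b.pos - a.pos),
                    junction,
                    int(diff.sum()),
                )
            )
            for s in np.flatnonzero(diff):
                breakpoints[m.samples[s]].append(interval_no)
            interval_no += 1
    table = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    return CrossoverTable(table, breakpoints)


def interval_null_probabilities(distances: Sequence[float]) -> np.ndarray:
    """p_i = d_i / sum(d): crossover probability proportional to marker
    distance."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty interval set")
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError("distances must be positive and finite")
    return d / d.sum()


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


@dataclass
class LandscapeResult:
    """Interval table with empirical tail p-values, BH q-values and flags."""

    table: pd.DataFrame
    n_draws: int
    alpha: float
    seed: Optional[int]

    @property
    def n_flagged_high(self) -> int:
        return int((self.table["flag"] == "high").sum())

    @property
    def n_flagged_low(self) -> int:
        return int((self.table["flag"] == "low").sum())


def multinomial_interval_test(
    observed: Sequence[int],
    probabilities: Sequence[float],
    n_draws: int = 10_000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    joint_tails: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> LandscapeResult:
    """Resampling test of per-interval crossover counts.

    Draws ``n_draws`` multinomial samples of the observed total T with the
    given probabilities; empirical tails use the (1 + k) / (N + 1)
    pseudocount convention with inclusive comparison (>= / <=).  BH is
    applied separately within each tail unless ``joint_tails``.
    """
    obs = np.asarray(observed, dtype=np.int64)
    p = np.asarray(probabilities, dtype=float)
    if obs.shape != p.shape:
        raise ValueError("observed and probabilities length mismatch")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("probabilities must sum to 1")
    total = int(obs.sum())
    rng = rng if rng is not None else np.random.default_rng(seed)

    n_ge = np.zeros(obs.size, dtype=np.int64)
    n_le = np.zeros(obs.size, dtype=np.int64)
    if total > 0:
        chunk = max(1, min(n_draws, 4_000_000 // max(obs.size, 1)))
        remaining = n_draws
        while remaining > 0:
            take = min(chunk, remaining)
            draws = rng.multinomial(total, p, size=take)
            n_ge += (draws >= obs).sum(axis=0)
            n_le += (draws <= obs).sum(axis=0)
            remaining -= take
        p_more = (1.0 + n_ge) / (n_draws + 1.0)
        p_less = (1.0 + n_le) / (n_draws + 1.0)
    else:
        p_more = np.ones(obs.size)
        p_less = np.ones(obs.size)

    if joint_tails:
        q_all = bh_adjust(np.concatenate([p_more, p_less]))
        q_more, q_less = q_all[: obs.size], q_all[obs.size :]
    else:
        q_more = bh_adjust(p_more)
        q_less = bh_adjust(p_less)
    flag = np.full(obs.size, "none", dtype=object)
    if total > 0:
        flag[q_more < alpha] = "high"
        flag[q_less < alpha] = "low"
    table = pd.DataFrame(
        {
            "observed": obs,
            "p_null": p,
            "expected": total * p,
            "p_more": p_more,
            "p_less": p_less,
            "q_more": q_more,
            "q_less": q_less,
            "flag": flag,
        }
    )
    return LandscapeResult(table, n_draws=n_draws, alpha=alpha, seed=seed)


def run_interval_test(
    xo: CrossoverTable,
    n_draws: int = 10_000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    joint_tails: bool = False,
) -> LandscapeResult:
    """Convenience wrapper: run the multinomial test on the testable
    intervals of a :class:`CrossoverTable`, carrying coordinates through."""
    sub = xo.testable()
    probs = interval_null_probabilities(sub["distance"].to_numpy())
    res = multinomial_interval_test(
        sub["count"].to_numpy(), probs, n_draws=n_draws, seed=seed,
        alpha=alpha, joint_tails=joint_tails,
    )
    coords = sub.reset_index(drop=True)[
        ["linkage_group", "contig_a", "pos_a", "contig_b", "pos_b", "distance"]
    ]
    res.table = pd.concat([coords, res.table], axis=1)
    return res


def bin_intervals(xo: CrossoverTable, target_span: int = 500_000) -> CrossoverTable:
    """Greedy accumulation of adjacent intervals along each contig until the
    cumulative distance reaches ``target_span``; bins never cross contig
    boundaries (junction intervals are dropped).  Totals are conserved over
    the non-junction intervals."""
    rows = []
    t = xo.table
    cur = None
    for _, r in t.iterrows():
        if r["is_junction"]:
            if cur is not None:
                rows.append(cur)
                cur = None
            continue
        if cur is not None and cur["contig_a"] != r["contig_a"]:
            rows.append(cur)
            cur = None
        if cur is None:
            cur = {
                "linkage_group": r["linkage_group"],
                "contig_a": r["contig_a"],
                "pos_a": r["pos_a"],
                "contig_b": r["contig_b"],
                "pos_b": r["pos_b"],
                "distance": r["distance"],
                "is_junction": False,
                "count": r["count"],
            }
        else:
            cur["pos_b"] = r["pos_b"]
            cur["contig_b"] = r["contig_b"]
            cur["distance"] += r["distance"]
            cur["count"] += r["count"]
        if cur["distance"] >= target_span:
            rows.append(cur)
            cur = None
    if cur is not None:
        rows.append(cur)
    return CrossoverTable(pd.DataFrame(rows, columns=INTERVAL_COLUMNS))


def distance_crossover_correlation(xo: CrossoverTable):
    """Spearman correlation (rho, p) between interval physical distance and
    crossover count.  Returns (nan, nan) for constant input."""
    sub = xo.testable()
    if len(sub) < 3:
        raise ValueError("need at least 3 testable intervals")
    d = sub["distance"].to_numpy()
    c = sub["count"].to_numpy()
    if np.all(d == d[0]) or np.all(c == c[0]):
        return float("nan"), float("nan")
    rho, pval = spearmanr(d, c)
    return float(rho), float(pval)


def genetic_vs_physical_profile(
    gmap: GeneticMap, jump_window_bp: int = 100_000
) -> dict[str, dict]:
    """Per-LG (contig, physical pos, cumulative cM) series plus the largest
    cM increment over any physical window of at most ``jump_window_bp``
    within a contig."""
    out: dict[str, dict] = {}
    for lg in gmap.groups:
        if lg.n_markers < 2:
            out[lg.name] = {"profile": pd.DataFrame(
                columns=["contig", "pos", "cm"]), "max_jump": 0.0,
                "jump_contig": None}
            continue
        df = pd.DataFrame(
            {
                "contig": [m.contig for m in lg.markers],
                "pos": [m.pos for m in lg.markers],
                "cm": lg.cm,
            }
        )
        max_jump, jump_contig, jump_pos = 0.0, None, None
        for contig, sub in df.groupby("contig", sort=False):
            pos = sub["pos"].to_numpy()
            cm = sub["cm"].to_numpy()
            j = 0
            for i in range(len(pos)):
                while pos[i] - pos[j] > jump_window_bp:
                    j += 1
                jump = cm[i] - cm[j]
                if jump > max_jump:
                    max_jump, jump_contig, jump_pos = float(jump), contig, int(pos[j])
        out[lg.name] = {
            "profile": df,
            "max_jump": max_jump,
            "jump_contig": jump_contig,
            "jump_pos": jump_pos,
        }
    return out
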