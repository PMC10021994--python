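"""Genome-architecture scans: telomere-motif runs at contig ends, sliding
GC / gene-density windows, centromere candidates, intergenic spaces and the
uniform-placement spacing simulation."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import AssemblyIndex, GeneSet

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# telomeres
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TelomereHit:
    contig: str
    end: str  # "5p" or "3p"
    motif: str
    repeat_count: int
    start: int  # 1-based inclusive span of the run
    stop: int


def scan_telomeres(
    assembly: AssemblyIndex,
    motif: str = "CACTAA",
    min_repeats: int = 4,
    window: int = 1000,
) -> list[TelomereHit]:
    """Find maximal tandem runs of ``motif`` (either strand) within
    ``window`` bp of a contig end; the longest qualifying run per end is
    reported.  Contigs shorter than the window are searched whole."""
    if not assembly.has_sequences:
        raise ValueError("telomere scan requires sequences")
    hits: list[TelomereHit] = []
    motifs = {motif.upper(), reverse_complement(motif.upper())}
    for contig, length in assembly.contig_lengths.items():
        seq = assembly.sequences[contig]
        best: dict[str, Optional[TelomereHit]] = {"5p": None, "3p": None}
        for mo in motifs:
            for match in re.finditer(f"(?:{mo})+", seq):
                n_rep = (match.end() - match.start()) // len(mo)
                if n_rep < min_repeats:
                    continue
                run = TelomereHit(
                    contig, "", mo, n_rep, match.start() + 1, match.end()
                )
                if match.start() < window:
                    cur = best["5p"]
                    if cur is None or n_rep > cur.repeat_count:
                        best["5p"] = TelomereHit(
                            contig, "5p", mo, n_rep, run.start, run.stop
                        )
                if match.end() > length - window:
                    cur = best["3p"]
                    if cur is None or n_rep > cur.repeat_count:
                        best["3p"] = TelomereHit(
                            contig, "3p", mo, n_rep, run.start, run.stop
                        )
        hits.extend(h for h in best.values() if h is not None)
    return hits


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

@dataclass
class WindowTrack:
    table: pd.DataFrame  # contig, start, end, gc, gene_density

    @property
    def genome_mean_gc(self) -> float:
        t = self.table
        w = (t["end"] - t["start"] + 1).to_numpy(float)
        return float(np.average(t["gc"].to_numpy(float), weights=w))


def _gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    gc = seq.count("G") + seq.count("C")
    return gc / acgt


def window_gc_gene_density(
    assembly: AssemblyIndex,
    genes: GeneSet,
    window: int = 30_000,
    step: int = 10_000,
) -> WindowTrack:
    """GC fraction (Ns excluded from the denominator) and gene coverage
    fraction in windows of ``window`` bp every ``step`` bp, starting at 1.
    Trailing windows shorter than window/2 are dropped, longer ones are
    truncated at the contig end."""
    if not assembly.has_sequences:
        raise ValueError("window scan requires sequences")
    rows = []
    for contig, length in assembly.contig_lengths.items():
        seq = assembly.sequences[contig]
        merged = genes.merged(contig)
        starts = np.array([a for a, _ in merged])
        ends = np.array([b for _, b in merged])
        for w_start in range(1, length + 1, step):
            w_end = min(w_start + window - 1, length)
            w_len = w_end - w_start + 1
            if w_len < window / 2:
                break  # trailing stub dropped; nothing longer follows
            gc = _gc_fraction(seq[w_start - 1 : w_end])
            if len(starts):
                ov = np.minimum(ends, w_end) - np.maximum(starts, w_start) + 1
                covered = int(np.clip(ov, 0, None).sum())
            else:
                covered = 0
            rows.append((contig, w_start, w_end, gc, covered / w_len))
            if w_end == length:
                break  # the contig end is covered; later windows are sub-spans
    return WindowTrack(
        pd.DataFrame(rows, columns=["contig", "start", "end", "gc", "gene_density"])
    )


# ---------------------------------------------------------------------------
# centromere candidates
# ---------------------------------------------------------------------------

def _gene_free_runs(genes: GeneSet, contig: str, length: int) -> list[tuple[int, int]]:
    """Complement of the merged gene intervals on [1, length], terminal
    flanks included."""
    merged = genes.merged(contig)
    runs = []
    prev_end = 0
    for a, b in merged:
        if a > prev_end + 1:
            runs.append((prev_end + 1, a - 1))
        prev_end = max(prev_end, b)
    if prev_end < length:
        runs.append((prev_end + 1, length))
    return runs


def call_centromere_candidates(
    assembly: AssemblyIndex,
    genes: GeneSet,
    min_gene_free: int = 20_000,
    gc_margin: float = 0.02,
    genome_gc: Optional[float] = None,
) -> pd.DataFrame:
    """Maximal gene-free runs of at least ``min_gene_free`` bp whose GC is
    below the genome-wide mean minus ``gc_margin`` (fractions, i.e. 0.02 =
    two percentage points).  Several candidates per contig are allowed."""
    if not assembly.has_sequences:
        raise ValueError("centromere scan requires sequences")
    if genome_gc is None:
        genome_gc = _gc_fraction("".join(assembly.sequences.values()))
    rows = []
    for contig, length in assembly.contig_lengths.items():
        for a, b in _gene_free_runs(genes, contig, length):
            if b - a + 1 < min_gene_free:
                continue
            gc = _gc_fraction(assembly.sequence(contig, a, b))
            if np.isnan(gc) or gc > genome_gc - gc_margin:
                continue
            rows.append((contig, a, b, b - a + 1, gc))
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "length", "gc"]
    )


# ---------------------------------------------------------------------------
# intergenic spacing
# ---------------------------------------------------------------------------

@dataclass
class IntergenicDistribution:
    observed: Optional[np.ndarray] = None
    simulated: Optional[list[np.ndarray]] = None

    @property
    def observed_median(self) -> float:
        return float(np.median(self.observed))

    @property
    def simulated_median(self) -> float:
        return float(np.median(np.concatenate(self.simulated)))


def intergenic_spaces(
    genes: GeneSet, contig_lengths: Optional[Mapping[str, int]] = None
) -> IntergenicDistribution:
    """Interior gaps between consecutive genes per contig.

    Gap = next_start - prev_end - 1 under 1-based inclusive intervals, with
    prev_end tracking the running maximum so contained genes cannot produce
    spurious gaps.  Overlapping genes yield no gap (negatives discarded);
    adjacency yields gap 0.  Terminal flanks are excluded.
    """
    gaps: list[int] = []
    for contig, ivs in genes.genes.items():
        if len(ivs) < 2:
            continue
        prev_end = ivs[0].end
        for g in ivs[1:]:
            gap = g.start - prev_end - 1
            if gap >= 0:
                gaps.append(gap)
            prev_end = max(prev_end, g.end)
    return IntergenicDistribution(observed=np.asarray(gaps, dtype=np.int64))


def simulate_uniform_gene_spacing(
    gene_lengths: Mapping[str, Sequence[int]],
    contig_lengths: Mapping[str, int],
    n_reps: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> IntergenicDistribution:
    """Null model of uniformly placed genes: per contig keep the observed
    gene lengths and split the free (non-genic) length into n+1 gaps by
    stick-breaking (n independent uniform cuts => symmetric Dirichlet).
    Interior gaps of every replicate are returned."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    free: dict[str, int] = {}
    for contig, lens in gene_lengths.items():
        f = contig_lengths[contig] - int(np.sum(lens))
        if f < 0:
            raise ValueError(f"gene lengths exceed contig {contig}")
        free[contig] = f
    reps: list[np.ndarray] = []
    for _ in range(n_reps):
        gaps: list[np.ndarray] = []
        for contig, lens in gene_lengths.items():
            n = len(lens)
            if n < 2:
                continue
            cuts = np.sort(rng.uniform(0.0, free[contig], size=n))
            all_gaps = np.diff(np.concatenate([[0.0], cuts, [free[contig]]]))
            gaps.append(all_gaps[1:-1])  # interior only
        reps.append(
            np.concatenate(gaps) if gaps else np.empty(0)
        )
    return IntergenicDistribution(simulated=reps)
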