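"""Simulator for haploid mapping populations.

Generates a multi-contig assembly carved out of hidden chromosomes, SNP
markers with roughly exponential spacing, offspring gametes with obligate
and Poisson extra crossovers, optional hotspots, viability-based
segregation distortion, heterokaryon contaminants, missing calls and
genotyping errors — together with the ground truth needed for
parameter-recovery tests.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    CALL_HET,
    CALL_MISSING,
    CALL_P1,
    CALL_P2,
    AssemblyIndex,
    GeneSet,
    GenotypeMatrix,
    MarkerLocus,
)

_BASES = np.array(list("ACGT"))


@dataclass
class Hotspot:
    chrom: int  # chromosome index
    start: int  # 1-based bp, inclusive
    end: int
    multiplier: float


@dataclass
class DistortionLocus:
    chrom: int
    pos: int
    coefficient: float  # rejection probability for the disfavoured allele
    disfavoured: int = 1  # allele code (P2 by default)


@dataclass
class SimConfig:
    n_chromosomes: int = 10
    chromosome_length: int = 2_000_000
    chromosome_lengths: Optional[list[int]] = None
    contigs_per_chromosome: int = 1
    marker_spacing_mean: float = 40_000.0
    n_offspring: int = 88
    obligate_crossover: bool = True
    extra_crossover_rate: float = 0.5  # Poisson lambda per chromosome
    hotspots: list[Hotspot] = field(default_factory=list)
    distortion_loci: list[DistortionLocus] = field(default_factory=list)
    heterokaryon_fraction: float = 0.0
    missing_rate: float = 0.0
    error_rate: float = 0.0
    with_sequences: bool = False
    telomere_motif: Optional[str] = None  # e.g. "CACTAA"
    telomere_repeats: int = 7
    flip_contigs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("heterokaryon_fraction", "missing_rate", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.extra_crossover_rate < 0:
            raise ValueError("extra_crossover_rate must be >= 0")

    @property
    def lengths(self) -> list[int]:
        if self.chromosome_lengths is not None:
            return list(self.chromosome_lengths)
        return [self.chromosome_length] * self.n_chromosomes


@dataclass
class ContigSpan:
    name: str
    chrom: int
    chrom_start: int  # 1-based inclusive span on the chromosome
    chrom_end: int
    orientation: str  # "+" or "-"

    @property
    def length(self) -> int:
        return self.chrom_end - self.chrom_start + 1


@dataclass
class SimGenome:
    assembly: AssemblyIndex
    spans: list[ContigSpan]
    markers: list[MarkerLocus]  # sorted by (contig, local pos)
    marker_chrom: np.ndarray  # chromosome index per marker
    marker_chrom_pos: np.ndarray  # chromosome coordinate per marker
    chromosome_lengths: list[int]

    def true_contig_order(self) -> dict[int, list[tuple[str, str]]]:
        """Per chromosome: contigs in physical order with orientation."""
        out: dict[int, list[tuple[str, str]]] = {}
        for span in sorted(self.spans, key=lambda s: (s.chrom, s.chrom_start)):
            out.setdefault(span.chrom, []).append((span.name, span.orientation))
        return out


@dataclass
class SimTruth:
    breakpoints: list[dict]  # per offspring: {chrom index: array of bp}
    second_gamete_breakpoints: dict  # contaminant sample -> {chrom: array}
    contaminants: list[str]
    hotspots: list[Hotspot]
    distortion_loci: list[DistortionLocus]
    realized_p2_freq: np.ndarray  # per marker, before noise
    samples: list[str]
    seed: int

    def gametes(self, exclude_contaminants: bool = True) -> list[dict]:
        bad = set(self.contaminants) if exclude_contaminants else set()
        return [
            bp for s, bp in zip(self.samples, self.breakpoints) if s not in bad
        ]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _cut_chromosome(length: int, n_contigs: int, rng: np.random.Generator):
    """Cut [1, length] into contiguous spans; boundaries are evenly spaced
    with +-25 % jitter so no fragment degenerates."""
    if n_contigs <= 1:
        return [(1, length)]
    step = length / n_contigs
    bounds = [0]
    for i in range(1, n_contigs):
        jitter = rng.uniform(-0.25, 0.25) * step
        bounds.append(int(round(i * step + jitter)))
    bounds.append(length)
    return [(bounds[i] + 1, bounds[i + 1]) for i in range(n_contigs)]


def simulate_genome(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> SimGenome:
    """Build the assembly frame: chromosomes fragmented into contigs,
    markers placed with exponential spacing, optional sequences with
    telomere motifs written onto chromosome-end contig ends."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lengths = cfg.lengths

    spans: list[ContigSpan] = []
    raw_spans: list[tuple[int, int, int]] = []  # (chrom, start, end)
    for ci, L in enumerate(lengths):
        for s, e in _cut_chromosome(L, cfg.contigs_per_chromosome, rng):
            raw_spans.append((ci, s, e))
    name_order = rng.permutation(len(raw_spans))
    names = [f"tig{int(i) + 1:03d}" for i in name_order]
    for (chrom, s, e), name in zip(raw_spans, names):
        orient = "-" if (cfg.flip_contigs and rng.random() < 0.5) else "+"
        spans.append(ContigSpan(name, chrom, s, e, orient))

    # markers: exponential inter-marker spacing along each chromosome
    marker_records = []
    for ci, L in enumerate(lengths):
        pos = 0.0
        while True:
            pos += rng.exponential(cfg.marker_spacing_mean)
            p = int(np.ceil(pos))
            if p > L:
                break
            marker_records.append((ci, p))
    # map chromosome coordinates to contig-local ones
    by_chrom: dict[int, list[ContigSpan]] = {}
    for span in spans:
        by_chrom.setdefault(span.chrom, []).append(span)
    markers: list[MarkerLocus] = []
    chrom_idx: list[int] = []
    chrom_pos: list[int] = []
    seen: set[tuple[str, int]] = set()
    for ci, p in marker_records:
        span = next(
            s for s in by_chrom[ci] if s.chrom_start <= p <= s.chrom_end
        )
        local = (
            p - span.chrom_start + 1
            if span.orientation == "+"
            else span.chrom_end - p + 1
        )
        if (span.name, local) in seen:
            continue
        seen.add((span.name, local))
        ref, alt = rng.choice(4, size=2, replace=False)
        markers.append(
            MarkerLocus(span.name, local, str(_BASES[ref]), str(_BASES[alt]))
        )
        chrom_idx.append(ci)
        chrom_pos.append(p)

    order = sorted(range(len(markers)), key=lambda i: markers[i].key)
    markers = [markers[i] for i in order]
    chrom_idx = np.array([chrom_idx[i] for i in order], dtype=np.int64)
    chrom_pos = np.array([chrom_pos[i] for i in order], dtype=np.int64)

    contig_lengths = {s.name: s.length for s in spans}
    sequences = None
    if cfg.with_sequences:
        sequences = {}
        for span in spans:
            seq = "".join(rng.choice(_BASES, size=span.length))
            sequences[span.name] = seq
        if cfg.telomere_motif:
            run = cfg.telomere_motif.upper() * cfg.telomere_repeats
            for span in spans:
                L = lengths[span.chrom]
                seq = sequences[span.name]
                if len(run) > span.length:
                    continue
                # chromosome terminus -> which local end of the contig
                t5 = span.chrom_start == 1
                t3 = span.chrom_end == L
                if span.orientation == "-":
                    t5, t3 = t3, t5
                if t5:
                    seq = run + seq[len(run):]
                if t3:
                    seq = seq[: len(seq) - len(run)] + run
                sequences[span.name] = seq

    assembly = AssemblyIndex(contig_lengths, sequences)
    return SimGenome(assembly, spans, markers, chrom_idx, chrom_pos, list(lengths))


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _hotspot_segments(length: int, hotspots: Sequence[Hotspot]):
    """Piecewise-constant crossover intensity on [0, length]."""
    bounds = {0.0, float(length)}
    for h in hotspots:
        bounds.add(float(h.start - 1))
        bounds.add(float(h.end))
    edges = np.array(sorted(bounds))
    mult = np.ones(len(edges) - 1)
    for h in hotspots:
        mid_ok = (edges[:-1] >= h.start - 1) & (edges[1:] <= h.end)
        mult[mid_ok] *= h.multiplier
    weights = np.diff(edges) * mult
    return edges, weights / weights.sum()


def _sample_positions(
    edges: np.ndarray, probs: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    if k == 0:
        return np.empty(0)
    seg = rng.choice(len(probs), size=k, p=probs)
    lo, hi = edges[seg], edges[seg + 1]
    return np.sort(rng.uniform(lo, hi))


def _gamete_allele(breakpoints: np.ndarray, start: int, pos) -> np.ndarray:
    """Parental origin (0/1) at position(s) for one chromosome."""
    return (start + np.searchsorted(breakpoints, pos)) % 2


def simulate_meiosis(
    cfg: SimConfig,
    genome: SimGenome,
    rng: Optional[np.random.Generator] = None,
    rejection_cap: int = 100_000,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw gametes for ``cfg.n_offspring`` offspring and genotype them at
    the simulated markers.

    Per chromosome the crossover count is (1 if obligate else 0) +
    Poisson(lambda); positions are drawn proportional to the hotspot
    intensity.  Distortion is viability resampling: a gamete carrying the
    disfavoured allele at a distortion locus is rejected with the locus
    coefficient and redrawn.  Contaminant samples are unions of two
    independent gametes (HET where they differ).  Missing and error noise
    are applied last; truth is recorded before noise.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    lengths = genome.chromosome_lengths
    n_chrom = len(lengths)
    seg_cache = [
        _hotspot_segments(L, [h for h in cfg.hotspots if h.chrom == ci])
        for ci, L in enumerate(lengths)
    ]
    dist_by_chrom: dict[int, list[DistortionLocus]] = {}
    for d in cfg.distortion_loci:
        dist_by_chrom.setdefault(d.chrom, []).append(d)

    def draw_gamete() -> tuple[dict, np.ndarray]:
        for _ in range(rejection_cap):
            bps: dict[int, np.ndarray] = {}
            starts = np.empty(n_chrom, dtype=np.int64)
            ok = True
            for ci in range(n_chrom):
                k = (1 if cfg.obligate_crossover else 0) + rng.poisson(
                    cfg.extra_crossover_rate
                )
                edges, probs = seg_cache[ci]
                bps[ci] = _sample_positions(edges, probs, int(k), rng)
                starts[ci] = rng.integers(2)
            for ci, loci in dist_by_chrom.items():
                for d in loci:
                    allele = int(_gamete_allele(bps[ci], starts[ci], d.pos))
                    if allele == d.disfavoured and rng.random() < d.coefficient:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                return bps, starts
        raise RuntimeError("distortion rejection loop exceeded cap")

    n = cfg.n_offspring
    samples = [f"off{i + 1:03d}" for i in range(n)]
    n_markers = len(genome.markers)
    calls = np.empty((n_markers, n), dtype=np.int8)

    def genotype(bps: dict, starts: np.ndarray) -> np.ndarray:
        g = np.empty(n_markers, dtype=np.int8)
        for ci in range(n_chrom):
            rows = genome.marker_chrom == ci
            g[rows] = _gamete_allele(
                bps[ci], starts[ci], genome.marker_chrom_pos[rows]
            )
        return g

    breakpoints: list[dict] = []
    gametes_calls = []
    for _ in range(n):
        bps, starts = draw_gamete()
        breakpoints.append({ci: bps[ci] for ci in range(n_chrom)})
        gametes_calls.append(genotype(bps, starts))
    for j, g in enumerate(gametes_calls):
        calls[:, j] = g

    n_cont = int(round(cfg.heterokaryon_fraction * n))
    cont_idx = (
        np.sort(rng.choice(n, size=n_cont, replace=False)) if n_cont else np.array([], dtype=int)
    )
    contaminants = [samples[i] for i in cont_idx]
    second_bps: dict[str, dict] = {}
    for i in cont_idx:
        bps, starts = draw_gamete()
        second_bps[samples[i]] = {ci: bps[ci] for ci in range(n_chrom)}
        g2 = genotype(bps, starts)
        g1 = calls[:, i].copy()
        merged = np.where(g1 == g2, g1, CALL_HET).astype(np.int8)
        calls[:, i] = merged

    realized_p2 = (calls == CALL_P2).sum(axis=1) / np.maximum(
        ((calls == CALL_P1) | (calls == CALL_P2)).sum(axis=1), 1
    )

    if cfg.error_rate > 0:
        hom = (calls == CALL_P1) | (calls == CALL_P2)
        flip = hom & (rng.random(calls.shape) < cfg.error_rate)
        calls[flip] = 1 - calls[flip]
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = CALL_MISSING

    matrix = GenotypeMatrix(
        genome.markers,
        samples,
        calls,
        parent_sample="parent",
        parent_calls=np.full(n_markers, CALL_P1, dtype=np.int8),
        meta={"sim_seed": cfg.seed},
    )
    truth = SimTruth(
        breakpoints=breakpoints,
        second_gamete_breakpoints=second_bps,
        contaminants=contaminants,
        hotspots=list(cfg.hotspots),
        distortion_loci=list(cfg.distortion_loci),
        realized_p2_freq=realized_p2,
        samples=samples,
        seed=cfg.seed,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    genome: SimGenome,
    n_genes: int,
    clustering: str = "uniform",
    gene_length_mean: float = 1200.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> GeneSet:
    """Place genes on the simulated contigs.

    ``uniform`` draws gap sizes by stick-breaking (the Dirichlet null the
    spacing analysis assumes); ``clustered`` packs genes into dense blocks
    separated by the remaining free length, giving the bimodal gap
    signature.
    """
    if clustering not in ("uniform", "clustered"):
        raise ValueError(f"unknown clustering mode {clustering!r}")
    rng = rng if rng is not None else np.random.default_rng(seed or 0)
    if n_genes == 0:
        return GeneSet()
    contig_lengths = genome.assembly.contig_lengths
    names = list(contig_lengths)
    lens = np.array([contig_lengths[c] for c in names], dtype=float)
    alloc = rng.multinomial(n_genes, lens / lens.sum())
    gs = GeneSet()
    for contig, n_c in zip(names, alloc):
        if n_c == 0:
            continue
        L = contig_lengths[contig]
        glens = np.maximum(
            rng.exponential(gene_length_mean, size=n_c).astype(int), 200
        )
        total = int(glens.sum())
        if total >= L:
            raise ValueError(
                f"total gene length {total} does not fit contig {contig} ({L})"
            )
        free = L - total
        if clustering == "uniform":
            cuts = np.sort(rng.uniform(0, free, size=n_c))
            gaps = np.diff(np.concatenate([[0.0], cuts, [float(free)]]))
        else:
            block = 8
            n_blocks = max(1, int(np.ceil(n_c / block)))
            small = rng.integers(0, 60, size=n_c + 1).astype(float)
            # gaps at block boundaries absorb nearly all free length
            boundary = np.linspace(0, n_c, n_blocks + 1, dtype=int)[1:-1]
            small[boundary] = 0.0
            leftover = free - small.sum()
            if leftover < 0:
                small[:] = 0.0
                leftover = float(free)
            share = np.zeros(n_c + 1)
            big_slots = np.concatenate([[0], boundary, [n_c]])
            share[big_slots] = leftover / len(big_slots)
            gaps = small + share
        pos = 1
        for g_len, gap in zip(glens, gaps[:-1]):
            start = pos + int(round(gap))
            end = min(start + int(g_len) - 1, L)
            start = min(start, L)
            gs.add(contig, start, max(start, end), "+" if rng.random() < 0.5 else "-")
            pos = end + 1
    return gs


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def emit_dataset(
    genome: SimGenome,
    matrix: GenotypeMatrix,
    truth: SimTruth,
    outdir: str,
    genes: Optional[GeneSet] = None,
    parent_name: str = "parent",
    orientation_seed: Optional[int] = None,
) -> dict[str, str]:
    """Write VCF (parent column first), FASTA or length index, GFF3 and a
    truth JSON.  REF/ALT orientation is randomized per marker so reloading
    exercises phase resolution; the reloaded matrix equals the input."""
    import os

    from .io_formats import (
        write_assembly_fai,
        write_assembly_fasta,
        write_gene_set_gff3,
    )

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    rng = np.random.default_rng(
        orientation_seed if orientation_seed is not None else truth.seed + 7
    )

    vcf_path = os.path.join(outdir, "genotypes.vcf")
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=karyolink-sim seed={truth.seed}\n")
        for name, length in genome.assembly.contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + parent_name
            + "\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i, mk in enumerate(matrix.markers):
            flip = bool(rng.integers(2))
            ref, alt = (mk.alt_allele, mk.ref_allele) if flip else (
                mk.ref_allele, mk.alt_allele
            )
            p1_gt, p2_gt = ("1", "0") if flip else ("0", "1")
            gts = [p1_gt]  # parent carries P1 by construction
            for code in matrix.calls[i]:
                if code == CALL_P1:
                    gts.append(p1_gt)
                elif code == CALL_P2:
                    gts.append(p2_gt)
                elif code == CALL_HET:
                    gts.append("0/1")
                else:
                    gts.append(".")
            fh.write(
                f"{mk.contig}\t{mk.pos}\t{mk.id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    paths["vcf"] = vcf_path

    if genome.assembly.has_sequences:
        fasta_path = os.path.join(outdir, "assembly.fasta")
        write_assembly_fasta(genome.assembly, fasta_path)
        paths["fasta"] = fasta_path
    fai_path = os.path.join(outdir, "assembly.fai")
    write_assembly_fai(genome.assembly, fai_path)
    paths["fai"] = fai_path

    if genes is not None:
        gff_path = os.path.join(outdir, "genes.gff3")
        write_gene_set_gff3(genes, gff_path)
        paths["gff3"] = gff_path

    truth_path = os.path.join(outdir, "truth.json")
    payload = {
        "seed": truth.seed,
        "contaminants": truth.contaminants,
        "hotspots": [vars(h) for h in truth.hotspots],
        "distortion_loci": [vars(d) for d in truth.distortion_loci],
        "contig_layout": [vars(s) for s in genome.spans],
        "chromosome_lengths": genome.chromosome_lengths,
        "breakpoints": {
            s: {str(ci): np.asarray(b).tolist() for ci, b in bp.items()}
            for s, bp in zip(truth.samples, truth.breakpoints)
        },
        "realized_p2_freq": truth.realized_p2_freq.tolist(),
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    paths["truth"] = truth_path
    return paths
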