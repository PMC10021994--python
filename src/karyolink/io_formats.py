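"""Readers and writers for the standard formats the pipeline touches.

VCF (GT subfield only), FASTA (+ ``.fai``), GFF3, BED and TSV.  Everything
is loaded into the in-memory model of :mod:`karyolink.model`; internal
coordinates are 1-based inclusive, BED output is 0-based half-open.
"""

from __future__ import annotations

import logging
import os
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

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

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _code_from_alleles(alleles: list[int]) -> int:
    """Map GT allele indices to a raw (REF-oriented) call code.

    Haploid ``0``/``1`` and diploid homozygote dialects collapse to the
    allele code; true heterozygotes become HET; anything containing a
    missing allele is MISSING.  Allele indices >= 2 (second ALT) are not
    representable in a biallelic table and become MISSING.
    """
    if not alleles or any(a < 0 for a in alleles):
        return CALL_MISSING
    uniq = set(alleles)
    if len(uniq) > 1:
        return CALL_HET
    a = alleles[0]
    if a == 0:
        return CALL_P1
    if a == 1:
        return CALL_P2
    return CALL_MISSING


def load_genotype_matrix(vcf_path: str, parent_sample: str) -> GenotypeMatrix:
    """Load a VCF of SNP calls into a phase-resolved :class:`GenotypeMatrix`.

    The parent column is removed from the sample axis and used to anchor
    phase: wherever the parent is called and homozygous, codes are flipped
    so that the parent's allele is P1.  Markers with a missing or
    heterozygous parent call keep raw REF/ALT orientation and are flagged
    unphased (``parent_calls != P1``).

    Non-SNP records (indels, MNPs) are skipped with a logged count.
    Multiallelic SNPs are kept and flagged via ``MarkerLocus.n_alt`` so the
    strict filter can drop them explicitly.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    if parent_sample not in vcf.samples:
        raise ValueError(f"parent sample {parent_sample!r} absent from VCF header")
    samples = [s for s in vcf.samples if s != parent_sample]
    parent_idx = vcf.samples.index(parent_sample)
    offspring_idx = [i for i, s in enumerate(vcf.samples) if s != parent_sample]

    markers: list[MarkerLocus] = []
    rows: list[np.ndarray] = []
    parent_calls: list[int] = []
    n_skipped_non_snp = 0
    n_skipped_dup = 0
    seen: set[tuple[str, int]] = set()

    for v in vcf:
        alts = v.ALT or []
        if (
            not alts
            or len(v.REF) != 1
            or any(len(a) != 1 for a in alts)
            or v.REF not in "ACGTN"
        ):
            n_skipped_non_snp += 1
            continue
        key = (v.CHROM, v.POS)
        if key in seen:
            n_skipped_dup += 1
            continue
        seen.add(key)
        genos = v.genotypes  # [[a, b, phased], ...] or [[a, phased], ...]
        codes = np.empty(len(vcf.samples), dtype=np.int8)
        for i, g in enumerate(genos):
            codes[i] = _code_from_alleles([int(a) for a in g[:-1]])
        p = codes[parent_idx]
        row = codes[offspring_idx]
        if p == CALL_P2:
            # phase flip: parent's allele becomes P1 everywhere
            flipped = row.copy()
            flipped[row == CALL_P1] = CALL_P2
            flipped[row == CALL_P2] = CALL_P1
            row = flipped
            p = CALL_P1
        markers.append(
            MarkerLocus(v.CHROM, v.POS, v.REF, ",".join(alts), n_alt=len(alts))
        )
        rows.append(row)
        parent_calls.append(p)

    if n_skipped_non_snp:
        logger.info("skipped %d non-SNP records", n_skipped_non_snp)
    if n_skipped_dup:
        logger.info("skipped %d duplicate positions", n_skipped_dup)

    calls = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(
        markers,
        samples,
        calls,
        parent_sample=parent_sample,
        parent_calls=np.array(parent_calls, dtype=np.int8),
        meta={
            "skipped_non_snp": n_skipped_non_snp,
            "skipped_duplicate": n_skipped_dup,
            "vcf_path": os.fspath(vcf_path),
        },
    )


# ---------------------------------------------------------------------------
# FASTA / .fai
# ---------------------------------------------------------------------------

def load_assembly(path: str) -> AssemblyIndex:
    """Load contig lengths (and sequences if given a FASTA).

    Accepts a FASTA file or a samtools ``.fai``-style length index (first
    two columns: name, length).  Sequence access is available iff a FASTA
    was given.
    """
    with open(path) as fh:
        head = fh.read(1)
    if head == "":
        raise ValueError(f"{path}: empty file")
    if head == ">":
        lengths: dict[str, int] = {}
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(path, "fasta"):
            if rec.id in lengths:
                raise ValueError(f"duplicate contig name {rec.id!r}")
            seqs[rec.id] = str(rec.seq).upper()
            lengths[rec.id] = len(rec.seq)
        return AssemblyIndex(lengths, seqs)
    lengths = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            name = parts[0]
            if name in lengths:
                raise ValueError(f"duplicate contig name {name!r}")
            lengths[name] = int(parts[1])
    if not lengths:
        raise ValueError(f"{path}: no contigs parsed")
    return AssemblyIndex(lengths, None)


def write_assembly_fasta(assembly: AssemblyIndex, path: str, width: int = 70) -> None:
    if not assembly.has_sequences:
        raise ValueError("assembly has no sequences to write")
    with open(path, "w") as fh:
        for name in assembly.contig_lengths:
            seq = assembly.sequences[name]
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_assembly_fai(assembly: AssemblyIndex, path: str) -> None:
    with open(path, "w") as fh:
        for name, length in assembly.contig_lengths.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def load_gene_set(gff_path: str) -> GeneSet:
    """Load a GFF3, keeping only rows whose feature type is ``gene``.

    Records with start > end are rejected and counted; overlapping genes
    are retained as-is.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = _create_gff_db(gff_path)
    except EmptyInputError:
        return GeneSet()
    gs = GeneSet()
    n_bad = 0
    for feat in db.features_of_type("gene"):
        if feat.start > feat.end:
            n_bad += 1
            continue
        gs.add(feat.seqid, feat.start, feat.end, feat.strand or "+")
    if n_bad:
        logger.info("rejected %d gene records with start > end", n_bad)
    return gs


def _create_gff_db(gff_path: str):
    import gffutils

    return gffutils.create_db(
        os.fspath(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def write_gene_set_gff3(genes: GeneSet, path: str, source: str = "karyolink") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        i = 0
        for contig, g in genes:
            i += 1
            fh.write(
                f"{contig}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID=gene{i:05d}\n"
            )


# ---------------------------------------------------------------------------
# TSV / BED result tracks
# ---------------------------------------------------------------------------

def write_map_tsv(gmap, path: str) -> None:
    """Genetic map as TSV: marker, contig, pos, linkage_group, cM."""
    rows = []
    for lg in gmap.groups:
        for m, cm in zip(lg.markers, lg.cm):
            rows.append((m.id, m.contig, m.pos, lg.name, float(cm)))
    df = pd.DataFrame(rows, columns=["marker", "contig", "pos", "linkage_group", "cM"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_map_tsv(path: str):
    """Re-load a genetic map written by :func:`write_map_tsv`.

    Marker ref/alt alleles are not serialized; the returned map compares
    equal on (marker id, contig, pos, group, cM).
    """
    from .linkage_core import GeneticMap, LinkageGroup

    df = pd.read_csv(path, sep="\t")
    groups = []
    for name, sub in df.groupby("linkage_group", sort=False):
        markers = [
            MarkerLocus(str(c), int(p)) for c, p in zip(sub["contig"], sub["pos"])
        ]
        groups.append(LinkageGroup(str(name), markers, sub["cM"].to_numpy(float)))
    return GeneticMap(groups)


def write_landscape_tsv(result, path: str) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def read_landscape_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(df: pd.DataFrame, path: str, name_col: Optional[str] = None,
              score_col: Optional[str] = None) -> None:
    """Write intervals with 1-based inclusive ``contig/start/end`` columns
    as 0-based half-open BED."""
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fields = [str(row["contig"]), str(int(row["start"]) - 1), str(int(row["end"]))]
            if name_col is not None:
                fields.append(str(row[name_col]))
            if score_col is not None:
                fields.append(f"{row[score_col]:.6g}")
            fh.write("\t".join(fields) + "\n")


def write_genotype_tsv(m: GenotypeMatrix, path: str) -> None:
    """Call table as TSV (codes P1/P2/HET/. per sample column)."""
    names = {CALL_P1: "P1", CALL_P2: "P2", CALL_HET: "HET", CALL_MISSING: "."}
    with open(path, "w") as fh:
        fh.write("marker\tcontig\tpos\tparent\t" + "\t".join(m.samples) + "\n")
        for i, mk in enumerate(m.markers):
            row = [names[int(c)] for c in m.calls[i]]
            fh.write(
                f"{mk.id}\t{mk.contig}\t{mk.pos}\t{names[int(m.parent_calls[i])]}\t"
                + "\t".join(row)
                + "\n"
            )
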