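"""Core domain types shared across the pipeline.

Coordinate conventions: all internal coordinates are 1-based inclusive
(VCF/GFF3 style).  BED output is converted to 0-based half-open at write
time only.

Genotype call codes (``int8``):

====== =====================================================
code   meaning
====== =====================================================
``0``  P1 — allele carried by the sequenced parent homokaryon
``1``  P2 — the other parental allele
``2``  HET — heterozygous call (heterokaryon signal)
``-1`` MISSING
====== =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

CALL_P1: int = 0
CALL_P2: int = 1
CALL_HET: int = 2
CALL_MISSING: int = -1

_VALID_CODES = frozenset({CALL_P1, CALL_P2, CALL_HET, CALL_MISSING})


@dataclass(frozen=True)
class MarkerLocus:
    """A biallelic (or flagged multiallelic) SNP position on a contig."""

    contig: str
    pos: int  # 1-based
    ref_allele: str = "N"
    alt_allele: str = "N"
    n_alt: int = 1

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"marker position must be >= 1, got {self.pos}")

    @property
    def id(self) -> str:
        return f"{self.contig}:{self.pos}"

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.pos)


class GenotypeMatrix:
    """Markers x offspring call table with parental phase.

    The sequenced parent is *not* a column: its (phase-resolved) call per
    marker is held in ``parent_calls`` so that per-position statistics run
    over offspring only.  After phase resolution the parent call is ``P1``
    wherever the parent was called and homozygous; ``HET``/``MISSING``
    parent calls leave the marker unphased.
    """

    def __init__(
        self,
        markers: Sequence[MarkerLocus],
        samples: Sequence[str],
        calls: np.ndarray,
        parent_sample: Optional[str] = None,
        parent_calls: Optional[np.ndarray] = None,
        meta: Optional[dict] = None,
    ) -> None:
        markers = list(markers)
        samples = list(samples)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(markers), len(samples)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(markers)} markers x {len(samples)} samples"
            )
        bad = set(np.unique(calls)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid call codes: {sorted(bad)}")
        keys = [m.key for m in markers]
        if sorted(keys) != keys:
            order = np.argsort(
                np.arange(len(markers)),
                kind="stable",
            )
            order = sorted(range(len(markers)), key=lambda i: keys[i])
            markers = [markers[i] for i in order]
            calls = calls[order]
            if parent_calls is not None:
                parent_calls = np.asarray(parent_calls)[order]
            keys = [m.key for m in markers]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (contig, pos) markers")
        if parent_calls is None:
            parent_calls = np.full(len(markers), CALL_P1, dtype=np.int8)
        else:
            parent_calls = np.asarray(parent_calls, dtype=np.int8)
            if parent_calls.shape != (len(markers),):
                raise ValueError("parent_calls length mismatch")
        self.markers: list[MarkerLocus] = markers
        self.samples: list[str] = samples
        self.calls: np.ndarray = calls
        self.parent_sample = parent_sample
        self.parent_calls: np.ndarray = parent_calls
        self.meta: dict = dict(meta or {})

    # -- basic introspection -------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def contigs(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.markers:
            seen.setdefault(m.contig, None)
        return list(seen)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.pos for m in self.markers], dtype=np.int64)

    @property
    def marker_contigs(self) -> np.ndarray:
        return np.array([m.contig for m in self.markers])

    @property
    def unphased(self) -> np.ndarray:
        """Boolean per marker: parent missing or heterozygous."""
        return self.parent_calls != CALL_P1

    def marker_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.markers)}

    def contig_rows(self) -> dict[str, np.ndarray]:
        """Row indices per contig, in physical order."""
        out: dict[str, list[int]] = {}
        for i, m in enumerate(self.markers):
            out.setdefault(m.contig, []).append(i)
        return {c: np.array(rows) for c, rows in out.items()}

    # -- subsetting ----------------------------------------------------------

    def subset_markers(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            [self.markers[i] for i in keep],
            self.samples,
            self.calls[keep],
            self.parent_sample,
            self.parent_calls[keep],
            self.meta,
        )

    def subset_samples(self, keep) -> "GenotypeMatrix":
        if len(keep) and isinstance(next(iter(keep)), str):
            name_to_i = {s: i for i, s in enumerate(self.samples)}
            keep = [name_to_i[s] for s in keep]
        keep = np.asarray(list(keep))
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.markers,
            [self.samples[i] for i in keep],
            self.calls[:, keep],
            self.parent_sample,
            self.parent_calls,
            self.meta,
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.markers),
            list(self.samples),
            self.calls.copy(),
            self.parent_sample,
            self.parent_calls.copy(),
            dict(self.meta),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            [m.key for m in self.markers] == [m.key for m in other.markers]
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.parent_calls, other.parent_calls)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<GenotypeMatrix {self.n_markers} markers x "
            f"{self.n_samples} samples>"
        )


class AssemblyIndex:
    """Contig lengths, optionally with sequence access (1-based inclusive)."""

    def __init__(
        self,
        contig_lengths: Mapping[str, int],
        sequences: Optional[Mapping[str, str]] = None,
    ) -> None:
        for name, length in contig_lengths.items():
            if length < 1:
                raise ValueError(f"contig {name} has length {length} < 1")
        self.contig_lengths: dict[str, int] = dict(contig_lengths)
        self.sequences: Optional[dict[str, str]] = (
            {k: str(v).upper() for k, v in sequences.items()}
            if sequences is not None
            else None
        )

    @property
    def has_sequences(self) -> bool:
        return self.sequences is not None

    @property
    def total_length(self) -> int:
        return sum(self.contig_lengths.values())

    def sequence(self, contig: str, start: int = 1, end: Optional[int] = None) -> str:
        if self.sequences is None:
            raise ValueError("assembly loaded without sequences")
        seq = self.sequences[contig]
        if end is None:
            end = len(seq)
        return seq[start - 1 : end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contig_lengths


@dataclass(frozen=True)
class GeneInterval:
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad gene interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GeneSet:
    """Per-contig sorted gene intervals (overlap allowed)."""

    def __init__(self, genes: Optional[Mapping[str, Iterable[GeneInterval]]] = None):
        self.genes: dict[str, list[GeneInterval]] = {}
        if genes:
            for contig, ivs in genes.items():
                self.genes[contig] = sorted(ivs, key=lambda g: (g.start, g.end))

    def add(self, contig: str, start: int, end: int, strand: str = "+") -> None:
        self.genes.setdefault(contig, []).append(GeneInterval(start, end, strand))
        self.genes[contig].sort(key=lambda g: (g.start, g.end))

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.genes.values())

    def merged(self, contig: str) -> list[tuple[int, int]]:
        """Merge overlapping/book-ended intervals on one contig."""
        ivs = self.genes.get(contig, [])
        out: list[list[int]] = []
        for g in ivs:
            if out and g.start <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], g.end)
            else:
                out.append([g.start, g.end])
        return [(a, b) for a, b in out]

    def __iter__(self):
        for contig in self.genes:
            for g in self.genes[contig]:
                yield contig, g


@dataclass
class TraitTable:
    """sample -> binary score (0/1); absent samples are unscored."""

    values: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, v in self.values.items():
            if v not in (0, 1):
                raise ValueError(f"trait value for {s} must be 0/1, got {v}")

    def as_call_vector(self, samples: Sequence[str]) -> np.ndarray:
        """Encode as a marker-like call vector (0/1 -> P1/P2, unscored -> MISSING)."""
        out = np.full(len(samples), CALL_MISSING, dtype=np.int8)
        for i, s in enumerate(samples):
            if s in self.values:
                out[i] = CALL_P1 if self.values[s] == 0 else CALL_P2
        return out
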