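"""Nucleotide composition and strand skew per genome partition.

Mitochondrial strand asymmetry is summarized by

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed on the majority strand.  Partitions (whole genome, PCGs, tRNAs,
rRNAs, control regions, or a single gene) use each member feature's
majority-strand span — not its coding orientation — so that the skews of all
partitions are comparable statements about the same strand.  Positions shared
by overlapping features within a partition are counted once.  N bases are
tallied separately and excluded from percentage and skew denominators.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .annotation import (AnnotationError, MitoAnnotation, PartitionSelector,
                         feature_length)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (report tables; Python's round is half-even)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def count_bases(seq: str) -> dict[str, int]:
    """Exact A/C/G/T/N counts, case-insensitive; other symbols are an error."""
    counts = Counter(seq.upper())
    bad = set(counts) - set("ACGTN")
    if bad:
        raise AnnotationError(
            f"non-nucleotide symbols in sequence: {sorted(bad)}")
    return {b: counts.get(b, 0) for b in "ACGTN"}


def skews(counts) -> tuple[float | None, float | None]:
    """(AT skew, GC skew) from counts *or* percentages.

    Both formulas are scale-invariant, so integer counts and printed
    percentages give identical values.  A skew whose denominator is zero is
    returned as None (undefined), never as an infinity.
    """
    a, t = float(counts["A"]), float(counts["T"])
    g, c = float(counts["G"]), float(counts["C"])
    at = (a - t) / (a + t) if a + t > 0 else None
    gc = (g - c) / (g + c) if g + c > 0 else None
    return at, gc


@dataclass(frozen=True)
class PartitionComposition:
    """Base counts, percentages and skews for one genome partition.

    ``total_bp`` is the number of genomic positions counted (each position
    once, even where member features overlap); ``member_bp`` is the sum of
    the member feature lengths, the figure printed in published size
    columns.  The two differ exactly by the within-partition overlap bp.
    """

    partition: str
    A: int
    C: int
    G: int
    T: int
    N: int
    total_bp: int
    member_bp: int = 0

    def __post_init__(self) -> None:
        if self.member_bp == 0:
            object.__setattr__(self, "member_bp", self.total_bp)

    @property
    def acgt(self) -> int:
        return self.A + self.C + self.G + self.T

    def pct(self, base: str) -> float | None:
        if self.acgt == 0:
            return None
        return 100.0 * getattr(self, base) / self.acgt

    @property
    def pct_AT(self) -> float | None:
        if self.acgt == 0:
            return None
        return 100.0 * (self.A + self.T) / self.acgt

    @property
    def pct_GC(self) -> float | None:
        if self.acgt == 0:
            return None
        return 100.0 * (self.G + self.C) / self.acgt

    @property
    def at_skew(self) -> float | None:
        return skews(self._counts())[0]

    @property
    def gc_skew(self) -> float | None:
        return skews(self._counts())[1]

    def _counts(self) -> dict[str, int]:
        return {"A": self.A, "C": self.C, "G": self.G, "T": self.T,
                "N": self.N}

    @classmethod
    def from_sequence(cls, seq: str, partition: str,
                      member_bp: int = 0) -> "PartitionComposition":
        c = count_bases(seq)
        return cls(partition=partition, A=c["A"], C=c["C"], G=c["G"],
                   T=c["T"], N=c["N"], total_bp=len(seq),
                   member_bp=member_bp)

    def as_row(self, ndigits: int = 2) -> dict:
        """Report row rounded half-up, the convention of printed tables."""
        def r(v):
            return None if v is None else round_half_up(v, ndigits)
        return {
            "partition": self.partition, "size_bp": self.member_bp,
            "counted_bp": self.total_bp,
            "A%": r(self.pct("A")), "G%": r(self.pct("G")),
            "T%": r(self.pct("T")), "C%": r(self.pct("C")),
            "GC%": r(self.pct_GC), "AT%": r(self.pct_AT),
            "AT_skew": r(self.at_skew), "GC_skew": r(self.gc_skew),
        }


def partition_composition(annotation: MitoAnnotation,
                          selector: PartitionSelector | str
                          ) -> PartitionComposition:
    """Composition of a partition, counting each genomic position once.

    The partition is the union of the member features' majority-strand spans
    on the circle; for ``whole`` it is the entire circular sequence.
    """
    if isinstance(selector, str):
        selector = PartitionSelector(selector)
    if annotation.sequence is None:
        raise AnnotationError("partition_composition requires a sequence")
    L = annotation.genome_length
    if selector.label == "whole":
        return PartitionComposition.from_sequence(annotation.sequence,
                                                  "whole")
    members = selector.resolve(annotation)
    mask = np.zeros(L, dtype=bool)
    member_bp = 0
    for f in members:
        n = feature_length(f, L)
        member_bp += n
        idx = (np.arange(f.start - 1, f.start - 1 + n)) % L
        mask[idx] = True
    arr = np.frombuffer(annotation.sequence.encode(), dtype="S1")
    seq = b"".join(arr[mask]).decode()
    return PartitionComposition.from_sequence(seq, selector.label,
                                              member_bp=member_bp)


def composition_table(annotations, partitions=("whole", "PCG", "tRNA",
                                               "rRNA", "CR"),
                      ndigits: int = 2) -> pd.DataFrame:
    """Composition/skew matrix (one row per genome per partition)."""
    if isinstance(annotations, MitoAnnotation):
        annotations = [annotations]
    rows = []
    for ann in annotations:
        for label in partitions:
            try:
                comp = partition_composition(ann, label)
            except AnnotationError:
                continue
            row = {"taxon": ann.taxon}
            row.update(comp.as_row(ndigits))
            rows.append(row)
    return pd.DataFrame(rows)
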