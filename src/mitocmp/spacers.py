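"""Intergenic-nucleotide (IGN) ledger: spacers and overlaps on the circle.

For consecutive features i, i+1 along the majority strand,

    ign(i) = start(i+1) - end(i) - 1

is positive for an intergenic spacer, negative for an overlap and zero for
contiguous features; strand plays no role (adjacency is positional).  The
last -> first pair closes the circle, so the ledger always satisfies the
tiling identity  sum(feature lengths) + sum(signed ign) = genome length.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import AnnotationError, MitoAnnotation, feature_length


@dataclass(frozen=True)
class IGNEntry:
    left: str            # feature whose 3' (positional) end opens the gap
    right: str           # next feature along the majority strand
    ign: int
    wrap_junction: bool = False


@dataclass
class IGNLedger:
    genome_length: int
    entries: list[IGNEntry]
    feature_bp: int

    @property
    def spacers(self) -> list[IGNEntry]:
        return [e for e in self.entries if e.ign > 0]

    @property
    def overlaps(self) -> list[IGNEntry]:
        return [e for e in self.entries if e.ign < 0]

    def as_table(self) -> pd.DataFrame:
        rows = [{"left": e.left, "right": e.right, "ign": e.ign,
                 "class": ("spacer" if e.ign > 0 else
                           "overlap" if e.ign < 0 else "contiguous"),
                 "wrap_junction": e.wrap_junction}
                for e in self.entries]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class LedgerSummary:
    n_spacers: int
    spacer_bp: int
    n_overlaps: int
    overlap_bp: int
    n_major_spacers: int
    major_threshold: int
    longest_spacer: IGNEntry | None
    largest_overlap: IGNEntry | None


def ign_ledger(annotation: MitoAnnotation) -> IGNLedger:
    """Signed IGN for every consecutive circular feature pair.

    Features must be in positional order (a wrap feature last); the closing
    pair spans the origin.  CRs participate like any other feature.
    """
    feats = annotation.features
    if not feats:
        raise AnnotationError("no features to ledger")
    L = annotation.genome_length
    entries: list[IGNEntry] = []
    total_len = 0
    for i, f in enumerate(feats):
        total_len += feature_length(f, L)
        g = feats[(i + 1) % len(feats)]
        closing = i == len(feats) - 1
        if closing:
            # effective end of the last feature on the unrolled axis
            eff_end = f.end if f.wraps else f.end - L
            ign = g.start - eff_end - 1
        else:
            if f.wraps:
                raise AnnotationError(
                    f"{f.name}: wrap feature must be last in the list")
            ign = g.start - f.end - 1
        if ign < -(L // 2):
            raise AnnotationError(
                f"{f.name}->{g.name}: overlap {-ign} bp spans more than half "
                "the genome; feature list is probably mis-sorted")
        entries.append(IGNEntry(left=f.name, right=g.name, ign=ign,
                                wrap_junction=closing))
    return IGNLedger(genome_length=L, entries=entries, feature_bp=total_len)


def tiling_identity(ledger: IGNLedger) -> int:
    """Reconstructed circumference: sum of lengths plus signed gaps."""
    return ledger.feature_bp + sum(e.ign for e in ledger.entries)


def summarize_ledger(ledger: IGNLedger,
                     major_threshold: int = 10) -> LedgerSummary:
    """Counts, total bp and extremes of spacers/overlaps.

    "Major" spacers are strictly longer than ``major_threshold`` bp.
    """
    spacers = ledger.spacers
    overlaps = ledger.overlaps
    return LedgerSummary(
        n_spacers=len(spacers),
        spacer_bp=sum(e.ign for e in spacers),
        n_overlaps=len(overlaps),
        overlap_bp=sum(-e.ign for e in overlaps),
        n_major_spacers=sum(1 for e in spacers if e.ign > major_threshold),
        major_threshold=major_threshold,
        longest_spacer=max(spacers, key=lambda e: e.ign, default=None),
        largest_overlap=min(overlaps, key=lambda e: e.ign, default=None),
    )
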