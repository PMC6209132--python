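"""Codon extraction, start/stop detection, codon usage and RSCU.

Relative synonymous codon usage for codon *c* encoding amino acid *aa* is

    RSCU(c) = count(c) * k_aa / sum of counts over the k_aa synonymous codons

so 1 means unbiased usage within the family, and the family's RSCU values
always sum to its degeneracy.  The default genetic code is the invertebrate
mitochondrial code (NCBI translation table 5), under which AGA/AGG encode
Ser and only TAA/TAG are stops; insect mitochondrial PCGs frequently end in
an incomplete stop (a trailing T or TA completed to TAA by polyadenylation),
which is never counted as a codon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import pandas as pd

from Bio.Data import CodonTable

#: Accepted mitochondrial initiation codons (ATN plus the TTG/GTG variants).
DEFAULT_START_CODONS = ("ATA", "ATT", "ATG", "ATC", "TTG", "GTG")

COMPLETE_STOPS = ("TAA", "TAG")

BASES = "ACGT"
ALL_CODONS = tuple("".join(p) for p in product(BASES, repeat=3))


class CodonError(ValueError):
    pass


@lru_cache(maxsize=None)
def genetic_code(code_id: int = 5) -> dict[str, str]:
    """codon -> amino acid, stops mapped to '*'."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


@lru_cache(maxsize=None)
def sense_codons(code_id: int = 5) -> tuple[str, ...]:
    code = genetic_code(code_id)
    return tuple(c for c in ALL_CODONS if code[c] != "*")


@lru_cache(maxsize=None)
def codon_families(code_id: int = 5) -> dict[str, tuple[str, ...]]:
    """amino acid -> its synonymous (sense) codons."""
    fam: dict[str, list[str]] = {}
    code = genetic_code(code_id)
    for codon in sense_codons(code_id):
        fam.setdefault(code[codon], []).append(codon)
    return {aa: tuple(cs) for aa, cs in fam.items()}


# ---------------------------------------------------------------------------

def extract_codons(cds: str) -> tuple[list[str], str]:
    """Split an oriented CDS into complete codons plus trailing remainder."""
    cds = cds.upper()
    if not cds:
        raise CodonError("empty coding sequence")
    n = len(cds) // 3
    return [cds[3 * i:3 * i + 3] for i in range(n)], cds[3 * n:]


@dataclass(frozen=True)
class CodonReport:
    """Start/stop codon call for one gene."""

    gene: str
    start_codon: str
    stop_codon: str          # complete "TAA"/"TAG" or incomplete "T"/"TA"
    incomplete_stop: bool
    nonstandard_start: bool = False
    nonstandard_stop: bool = False


def detect_start_stop(cds: str, gene: str = "?",
                      accepted_starts=DEFAULT_START_CODONS) -> CodonReport:
    """Identify initiation and termination codons of an oriented CDS.

    The stop is the last complete codon when it is TAA/TAG; otherwise a
    trailing remainder of 1-2 nt is reported as an incomplete stop (T / TA).
    A start outside the accepted set is flagged, not fatal.
    """
    codons, rest = extract_codons(cds)
    if len(cds) < 6:
        raise CodonError(f"{gene}: CDS shorter than two codons")
    start = codons[0]
    nonstandard_start = start not in accepted_starts
    if rest:
        return CodonReport(gene=gene, start_codon=start, stop_codon=rest,
                           incomplete_stop=True,
                           nonstandard_start=nonstandard_start,
                           nonstandard_stop=rest not in ("T", "TA"))
    stop = codons[-1]
    return CodonReport(gene=gene, start_codon=start, stop_codon=stop,
                       incomplete_stop=False,
                       nonstandard_start=nonstandard_start,
                       nonstandard_stop=stop not in COMPLETE_STOPS)


# ---------------------------------------------------------------------------

@dataclass
class CodonUsage:
    """Aggregated codon counts under one genetic code."""

    counts: dict[str, int]
    code_id: int = 5

    def __post_init__(self) -> None:
        self.counts = {c: int(self.counts.get(c, 0)) for c in ALL_CODONS}

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def per_aa(self) -> dict[str, int]:
        code = genetic_code(self.code_id)
        out: dict[str, int] = {}
        for codon, n in self.counts.items():
            if n:
                out[code[codon]] = out.get(code[codon], 0) + n
        return out


def codon_counts(genes, exclude_stops: bool = True,
                 code_id: int = 5) -> CodonUsage:
    """Aggregate codon counts over oriented CDSs.

    ``genes`` maps gene name -> CDS (a bare list of CDSs is also accepted).
    With ``exclude_stops`` a terminal TAA/TAG is omitted; trailing incomplete
    remainders are always omitted; internal stops are counted but reported
    as a warning naming the gene and codon position.
    """
    if not isinstance(genes, dict):
        genes = {f"gene{i + 1}": g for i, g in enumerate(genes)}
    code = genetic_code(code_id)
    counts: dict[str, int] = {}
    for name, cds in genes.items():
        codons, _rest = extract_codons(cds)
        if exclude_stops and codons and codons[-1] in COMPLETE_STOPS:
            codons = codons[:-1]
        for pos, codon in enumerate(codons):
            if code.get(codon) == "*" and pos < len(codons) - 1:
                warnings.warn(
                    f"{name}: internal stop codon {codon} at codon "
                    f"position {pos + 1}", stacklevel=2)
            counts[codon] = counts.get(codon, 0) + 1
    return CodonUsage(counts=counts, code_id=code_id)


def rscu(usage: CodonUsage) -> dict[str, float]:
    """Per-codon RSCU; families with zero total get all-zero values."""
    values: dict[str, float] = {}
    for aa, codons in codon_families(usage.code_id).items():
        total = sum(usage.counts[c] for c in codons)
        k = len(codons)
        for c in codons:
            values[c] = (usage.counts[c] * k / total) if total else 0.0
    return values


def missing_codons(usage: CodonUsage) -> set[str]:
    """Sense codons never observed."""
    return {c for c in sense_codons(usage.code_id) if usage.counts[c] == 0}


def rscu_table(usage: CodonUsage, ndigits: int = 2) -> pd.DataFrame:
    """Codon / amino acid / count / RSCU table, grouped by family."""
    from .composition import round_half_up
    code = genetic_code(usage.code_id)
    values = rscu(usage)
    rows = [{"codon": c, "aa": code[c], "count": usage.counts[c],
             "RSCU": round_half_up(values[c], ndigits)}
            for c in sense_codons(usage.code_id)]
    df = pd.DataFrame(rows)
    return df.sort_values(["aa", "codon"]).reset_index(drop=True)


def most_frequent_codons(usage: CodonUsage) -> dict[str, str]:
    """Per amino acid, the most used codon (ties broken alphabetically)."""
    out: dict[str, str] = {}
    for aa, codons in codon_families(usage.code_id).items():
        if sum(usage.counts[c] for c in codons) == 0:
            continue
        out[aa] = max(sorted(codons), key=lambda c: (usage.counts[c],))
    return out
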