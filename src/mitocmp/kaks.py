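"""Pairwise Ka/Ks by the Nei-Gojobori (1986) counting method.

Site counting: each codon position contributes the fraction of its possible
single-nucleotide changes that are synonymous, with changes producing a stop
codon removed from the denominator; synonymous sites S and nonsynonymous
sites N therefore always satisfy S + N = 3 per codon.  Differences between a
codon pair differing at d positions are averaged with equal weight over all
d! minimal mutational pathways, excluding pathways that pass through a stop
codon (if every pathway is blocked, all are used).  Proportions pS = Sd/S
and pN = Nd/N are corrected for multiple hits with the Jukes-Cantor formula

    K = -(3/4) * ln(1 - (4/3) p)

and the ratio Ka/Ks (< 1 purifying, = 1 neutral, > 1 positive selection) is
reported as missing when Ks is zero or either proportion is saturated
(p >= 3/4).  Input sequences are assumed codon-aligned; alignment itself is
out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import pandas as pd

from .codons import BASES, genetic_code

NEUTRAL_TOL = 1e-6


class KaKsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Site and difference counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng_sites(codon: str, code_id: int = 5) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    code = genetic_code(code_id)
    codon = codon.upper()
    aa = code.get(codon)
    if aa is None:
        raise KaKsError(f"not a codon: {codon!r}")
    if aa == "*":
        raise KaKsError(f"stop codon {codon} has no site decomposition")
    s = 0.0
    for pos in range(3):
        syn = 0
        viable = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if code[mutant] == "*":
                continue
            viable += 1
            if code[mutant] == aa:
                syn += 1
        s += syn / viable if viable else 0.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng_differences(codon1: str, codon2: str,
                   code_id: int = 5) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences.

    Averages over all orders of applying the differing positions; pathways
    through intermediate (or terminal) stop codons are excluded, falling back
    to the unrestricted average when every pathway is blocked.
    """
    code = genetic_code(code_id)
    c1, c2 = codon1.upper(), codon2.upper()
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order) -> tuple[float, float, bool]:
        sd = nd = 0.0
        current = c1
        clean = True
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if code[nxt] == "*" or code[current] == "*":
                clean = False
            if code[nxt] == code[current] and code[nxt] != "*":
                sd += 1
            else:
                nd += 1
            current = nxt
        return sd, nd, clean

    paths = [walk(order) for order in permutations(diff)]
    clean_paths = [p for p in paths if p[2]]
    pool = clean_paths or paths
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


# ---------------------------------------------------------------------------
# Pairwise statistic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KaKsResult:
    gene: str
    pair: tuple[str, str]
    codons: int                 # codon pairs actually compared
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    saturated: bool

    @property
    def ratio(self) -> float | None:
        if self.Ka is None or self.Ks is None or self.Ks == 0.0:
            return None
        return self.Ka / self.Ks


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p < 0:
        raise KaKsError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def check_aligned(cds1: str, cds2: str) -> None:
    """Minimal 'already aligned' contract: equal length, codon-sized."""
    if len(cds1) != len(cds2):
        raise KaKsError(
            f"sequences differ in length ({len(cds1)} vs {len(cds2)}); "
            "codon-aware alignment must be done upstream")
    if len(cds1) % 3:
        raise KaKsError("aligned length is not a multiple of 3")


def pairwise_kaks(cds1: str, cds2: str, code_id: int = 5, gene: str = "?",
                  pair: tuple[str, str] = ("seq1", "seq2")) -> KaKsResult:
    """Nei-Gojobori Ka/Ks for one aligned coding sequence pair.

    Codon columns containing a gap ('-') or N in either sequence, or a stop
    codon in either sequence (terminal stops included), are dropped pairwise.
    S and N are averaged over the two sequences.
    """
    cds1, cds2 = cds1.upper(), cds2.upper()
    check_aligned(cds1, cds2)
    code = genetic_code(code_id)
    S1 = N1 = S2 = N2 = 0.0
    Sd = Nd = 0.0
    ncod = 0
    for i in range(0, len(cds1), 3):
        a, b = cds1[i:i + 3], cds2[i:i + 3]
        if set(a + b) - set(BASES):
            continue
        if code[a] == "*" or code[b] == "*":
            continue
        ncod += 1
        sa, na = ng_sites(a, code_id)
        sb, nb = ng_sites(b, code_id)
        S1 += sa
        N1 += na
        S2 += sb
        N2 += nb
        ds, dn = ng_differences(a, b, code_id)
        Sd += ds
        Nd += dn
    if ncod == 0:
        raise KaKsError(f"{gene}: no comparable codons")
    S = (S1 + S2) / 2.0
    N = (N1 + N2) / 2.0
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    return KaKsResult(gene=gene, pair=pair, codons=ncod, S=S, N=N,
                      Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
                      saturated=(Ks is None or Ka is None))


def classify_ratio(ratio: float, tol: float = NEUTRAL_TOL) -> str:
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"


def rank_genes_by_kaks(results) -> pd.DataFrame:
    """Per-gene mean Ka/Ks, ascending, with selection classification.

    Pairs with undefined ratios (Ks = 0 or saturated) are dropped from the
    means; a gene with no defined pair is excluded with a warning.  Equal
    means keep first-appearance input order (stable sort).
    """
    order: list[str] = []
    by_gene: dict[str, list[float]] = {}
    for res in results:
        if res.gene not in by_gene:
            by_gene[res.gene] = []
            order.append(res.gene)
        r = res.ratio
        if r is not None:
            by_gene[res.gene].append(r)
    rows = []
    for gene in order:
        ratios = by_gene[gene]
        if not ratios:
            warnings.warn(f"{gene}: no pair with a defined Ka/Ks ratio; "
                          "excluded from ranking", stacklevel=2)
            continue
        mean = sum(ratios) / len(ratios)
        rows.append({"gene": gene, "mean_ratio": mean, "n_pairs": len(ratios),
                     "selection": classify_ratio(mean)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("mean_ratio", kind="stable").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Transition/transversion saturation
# ---------------------------------------------------------------------------

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class SaturationPoint:
    pair: tuple[str, str]
    compared: int
    distance: float             # p-distance over compared columns
    transitions: int
    transversions: int

    @property
    def ts_tv_ratio(self) -> float | None:
        if self.transversions == 0:
            return None
        return self.transitions / self.transversions


def ts_tv_saturation(seq1: str, seq2: str,
                     pair: tuple[str, str] = ("seq1", "seq2")
                     ) -> SaturationPoint:
    """Transition/transversion counts and p-distance of an aligned pair.

    Columns with a gap or N in either sequence are skipped; A<->G and C<->T
    are transitions, every other difference a transversion.
    """
    if len(seq1) != len(seq2):
        raise KaKsError("aligned sequences must have equal length")
    seq1, seq2 = seq1.upper(), seq2.upper()
    ts = tv = compared = 0
    for a, b in zip(seq1, seq2):
        if a not in BASES or b not in BASES:
            continue
        compared += 1
        if a == b:
            continue
        if {a, b} <= _PURINES or {a, b} <= _PYRIMIDINES:
            ts += 1
        else:
            tv += 1
    if compared == 0:
        raise KaKsError("no comparable columns")
    return SaturationPoint(pair=pair, compared=compared,
                           distance=(ts + tv) / compared,
                           transitions=ts, transversions=tv)


def kaks_long_table(results, ndigits: int = 4) -> pd.DataFrame:
    """Long-format (gene, pair, Ka, Ks, ratio) table for reporting."""
    rows = []
    for r in results:
        rows.append({"gene": r.gene, "seq1": r.pair[0], "seq2": r.pair[1],
                     "codons": r.codons,
                     "Ka": None if r.Ka is None else round(r.Ka, ndigits),
                     "Ks": None if r.Ks is None else round(r.Ks, ndigits),
                     "ratio": (None if r.ratio is None
                               else round(r.ratio, ndigits)),
                     "saturated": r.saturated})
    return pd.DataFrame(rows)
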