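"""Signed circular gene orders and pairwise rearrangement comparison.

A mitogenome's gene order is modelled as a circular sequence of signed gene
symbols, the sign being the strand relative to the majority strand.  Against
a reference order each gene is classified by two independent observations —
did its strand flip, and did it keep its positional neighbourhood? —

    sign unchanged, >=1 neighbour retained     -> conserved
    sign unchanged, both neighbours changed    -> transposed
    sign flipped,  both neighbours retained    -> inverted (flip in place)
    sign flipped,  any neighbour changed       -> inverse_transposed

Retention is judged on unsigned neighbour names so that a neighbour's own
strand flip does not disturb an otherwise conserved gene, and "at least one
retained" keeps the genes flanking a moved gene conserved (they keep their
other neighbour).  An in-place inversion must retain *both* neighbours —
a flipped gene that kept only one neighbour has moved.  Breakpoints count
the query's signed adjacencies (a,b) absent from the reference in both
readings ((a,b) and (-b,-a)); shared blocks are maximal runs of >=2 genes
whose successive signed adjacencies are all preserved.

This per-gene rule is a defined positional proxy for rearrangement-scenario
labels; full tandem-duplication-random-loss scenario reconstruction (as done
by common-interval explorers such as CREx) is deliberately out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .annotation import MitoAnnotation

SignedGene = tuple[str, int]     # (symbol, +1 | -1)

EVENT_KINDS = ("conserved", "transposed", "inverted", "inverse_transposed")


class GeneOrderError(ValueError):
    pass


def parse_signed(symbol: str) -> SignedGene:
    symbol = symbol.strip()
    if symbol.startswith("-"):
        return symbol[1:], -1
    return symbol.lstrip("+"), +1


def format_signed(gene: SignedGene) -> str:
    name, sign = gene
    return ("-" if sign < 0 else "") + name


@dataclass(frozen=True)
class GeneOrder:
    """A taxon's circular signed gene order (majority-strand reading)."""

    taxon: str
    order: tuple[SignedGene, ...]
    anchor: str = "cox1"

    def __post_init__(self) -> None:
        names = [g for g, _ in self.order]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise GeneOrderError(
                f"{self.taxon}: duplicate gene symbols {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.order)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.order)

    def sign_of(self, gene: str) -> int:
        for name, sign in self.order:
            if name == gene:
                return sign
        raise KeyError(gene)

    def rotated_to(self, anchor: str | None = None) -> "GeneOrder":
        """Linearize for display so that ``anchor`` comes first."""
        anchor = anchor or self.anchor
        names = [g for g, _ in self.order]
        if anchor not in names:
            return self
        i = names.index(anchor)
        return GeneOrder(taxon=self.taxon,
                         order=self.order[i:] + self.order[:i],
                         anchor=anchor)

    def linearized(self, anchor: str | None = None) -> str:
        return ",".join(format_signed(g)
                        for g in self.rotated_to(anchor).order)

    @classmethod
    def from_string(cls, taxon: str, text: str,
                    anchor: str = "cox1") -> "GeneOrder":
        order = tuple(parse_signed(s) for s in text.split(",") if s.strip())
        return cls(taxon=taxon, order=order, anchor=anchor)


def order_from_annotation(annotation: MitoAnnotation,
                          include_crs: bool = False) -> GeneOrder:
    """Signed order in positional (majority-strand) occurrence."""
    order = []
    for f in annotation.features:
        if f.category == "CR" and not include_crs:
            continue
        order.append((f.name, -1 if f.strand == "-" else +1))
    return GeneOrder(taxon=annotation.taxon, order=tuple(order))


def read_order_tsv(path: str | Path) -> list[GeneOrder]:
    orders = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        taxon, _, text = line.partition("\t")
        if text:
            orders.append(GeneOrder.from_string(taxon, text))
    return orders


def write_order_tsv(orders, path: str | Path) -> None:
    lines = ["# taxon\torder"]
    for o in orders:
        lines.append(f"{o.taxon}\t" +
                     ",".join(format_signed(g) for g in o.order))
    Path(path).write_text("\n".join(lines) + "\n")


def ancestral_insect_order() -> GeneOrder:
    """The putative ancestral insect order used as rearrangement reference."""
    ref = resources.files("mitocmp.data") / "ancestral_insect_order.tsv"
    with resources.as_file(ref) as path:
        return read_order_tsv(path)[0]


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------

def _adjacencies(order: tuple[SignedGene, ...]) -> set[tuple[SignedGene,
                                                             SignedGene]]:
    n = len(order)
    return {(order[i], order[(i + 1) % n]) for i in range(n)}


def _adjacency_preserved(adj, reference_adjacencies) -> bool:
    a, b = adj
    flipped = ((b[0], -b[1]), (a[0], -a[1]))
    return adj in reference_adjacencies or flipped in reference_adjacencies


def _neighbors(order: tuple[SignedGene, ...]) -> dict[str, frozenset[str]]:
    n = len(order)
    out = {}
    for i, (name, _sign) in enumerate(order):
        left = order[(i - 1) % n][0]
        right = order[(i + 1) % n][0]
        out[name] = frozenset((left, right))
    return out


@dataclass
class OrderComparison:
    query: str
    reference: str
    per_gene: dict[str, str]
    shared_blocks: list[list[SignedGene]]
    breakpoints: int
    only_query: frozenset[str] = field(default_factory=frozenset)
    only_reference: frozenset[str] = field(default_factory=frozenset)

    def genes_with(self, kind: str) -> set[str]:
        return {g for g, k in self.per_gene.items() if k == kind}


def _restrict(order: GeneOrder, keep: frozenset[str]) -> tuple[SignedGene,
                                                               ...]:
    return tuple(g for g in order.order if g[0] in keep)


def compare_orders(query: GeneOrder, reference: GeneOrder) -> OrderComparison:
    """Per-gene rearrangement classification, shared blocks, breakpoints.

    Genes present in only one order are reported and excluded from the
    comparison (both orders must share at least two genes).
    """
    common = query.genes & reference.genes
    only_q = query.genes - common
    only_r = reference.genes - common
    if len(common) < 2:
        raise GeneOrderError("gene sets are (nearly) disjoint: "
                             f"{len(common)} shared genes")
    if only_q or only_r:
        warnings.warn(
            f"excluding unshared genes (query-only {sorted(only_q)}, "
            f"reference-only {sorted(only_r)})", stacklevel=2)
    q = _restrict(query, common)
    r = _restrict(reference, common)
    q_nb, r_nb = _neighbors(q), _neighbors(r)
    q_sign = {name: sign for name, sign in q}
    r_sign = {name: sign for name, sign in r}
    per_gene: dict[str, str] = {}
    for name in (g for g, _ in q):
        flipped = q_sign[name] != r_sign[name]
        kept = len(q_nb[name] & r_nb[name])
        if not flipped:
            per_gene[name] = "conserved" if kept >= 1 else "transposed"
        else:
            per_gene[name] = ("inverted" if q_nb[name] == r_nb[name]
                              else "inverse_transposed")
    r_adj = _adjacencies(r)
    n = len(q)
    breakpoints = sum(
        0 if _adjacency_preserved((q[i], q[(i + 1) % n]), r_adj) else 1
        for i in range(n))
    return OrderComparison(query=query.taxon, reference=reference.taxon,
                           per_gene=per_gene,
                           shared_blocks=shared_blocks(query, reference),
                           breakpoints=breakpoints,
                           only_query=frozenset(only_q),
                           only_reference=frozenset(only_r))


def shared_blocks(query: GeneOrder,
                  reference: GeneOrder) -> list[list[SignedGene]]:
    """Maximal runs of >=2 genes with preserved signed adjacency.

    Reported in query orientation and positional order.  When every adjacency
    is preserved the whole circle is a single block.
    """
    common = query.genes & reference.genes
    q = _restrict(query, common)
    r = _restrict(reference, common)
    n = len(q)
    if n < 2:
        return []
    r_adj = _adjacencies(r)
    ok = [_adjacency_preserved((q[i], q[(i + 1) % n]), r_adj)
          for i in range(n)]
    if all(ok):
        return [list(q)]
    # break the circle at a non-preserved adjacency, then scan runs
    start = ok.index(False) + 1
    blocks: list[list[SignedGene]] = []
    run: list[SignedGene] = [q[start % n]]
    for k in range(n):
        i = (start + k) % n
        if ok[i]:
            run.append(q[(i + 1) % n])
        else:
            if len(run) >= 2:
                blocks.append(run)
            run = [q[(i + 1) % n]]
    if len(run) >= 2:
        blocks.append(run)
    return blocks


def breakpoint_count(query: GeneOrder, reference: GeneOrder) -> int:
    return compare_orders(query, reference).breakpoints
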