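"""Synthetic circular mitogenomes with known ground truth.

The generator emulates the statistical structure of a thrips-like
mitogenome: a circular molecule of ~15 kb with an AT-rich base composition,
a tiled feature template (13 PCGs, 22 tRNAs, 2 rRNAs, 2 CRs) carrying signed
inter-feature gaps (spacers/overlaps) copied from the published layout,
protein-coding genes with proper start codons, stop codons or planted
incomplete stops, control regions with planted conserved elements, and
pairs of coding sequences evolved under a chosen dN/dS (omega).

Everything is deterministic for a fixed seed.  Overlapping features are
written onto the circle in positional order, the later feature taking
precedence in the shared span, so whatever a PCG keeps at its downstream
(positional-end) junction — the stop codon of a majority-strand gene, the
start codon of a minority-strand one — is compromised when that junction
lies inside an overlap, exactly the compromise real overlapping
mitochondrial genes make.  The coordinate-level ground truth (IGN ledger,
gene order, tiling) is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import (GeneFeature, MitoAnnotation, feature_length,
                         reverse_complement, thrips_palmi_table)
from .codons import genetic_code, sense_codons
from .gene_order import GeneOrder, SignedGene

BASE_ORDER = "ACGT"

#: Whole-genome base probabilities (pA, pC, pG, pT) of the modelled thrips
#: mitogenome, matching its printed composition (A 42.71%, C 11.58%,
#: G 10.14%, T 35.58%).
DEFAULT_BASE_PROBS = (0.43, 0.11, 0.10, 0.36)


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Template
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateEntry:
    """One feature slot: length plus the signed gap to the next feature."""

    name: str
    category: str
    strand: str
    length: int
    ign_after: int
    start_codon: str | None = None    # force a specific initiation codon


def table1_template() -> tuple[TemplateEntry, ...]:
    """The published T. palmi layout as a reusable synthetic template."""
    ann = thrips_palmi_table()
    L = ann.genome_length
    entries = []
    feats = ann.features
    for i, f in enumerate(feats):
        if i + 1 < len(feats):
            ign = feats[i + 1].start - f.end - 1
        else:
            ign = feats[0].start - (f.end if f.wraps else f.end - L) - 1
        entries.append(TemplateEntry(
            name=f.name, category=f.category, strand=f.strand,
            length=feature_length(f, L), ign_after=ign,
            start_codon=f.start_codon if f.name == "cox1" else None))
    return tuple(entries)


def uniform_template(n_genes: int = 8, gene_length: int = 120,
                     spacer: int = 5) -> tuple[TemplateEntry, ...]:
    """A small non-overlapping PCG-only template for focused tests."""
    return tuple(TemplateEntry(name=f"g{i + 1}", category="PCG", strand="+",
                               length=gene_length, ign_after=spacer)
                 for i in range(n_genes))


# ---------------------------------------------------------------------------
# Spec and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CRElementSpec:
    """Which conserved elements to plant in synthetic control regions."""

    polyt_len: int = 6
    taa_units: int = 4            # tandem TAA repeats
    tata: bool = True
    gant_n: int = 2               # G A{n} T
    stem: int = 8
    loop: int = 5
    ga_rich_len: int = 0          # 0 = element absent (as in T. palmi)
    filler_a_prob: float = 0.85   # filler drawn from {A, C}: AT-rich like
                                  # real CRs, yet unable to pair with itself
                                  # or spell any T/G-containing motif


@dataclass
class SyntheticSpec:
    template: tuple[TemplateEntry, ...] = field(default_factory=table1_template)
    genome_length: int | None = None     # derived from template when None
    base_probs: tuple[float, float, float, float] = DEFAULT_BASE_PROBS
    codon_profile: dict[str, float] | None = None
    cr_elements: CRElementSpec | None = CRElementSpec()
    origin_offset: int = 0               # rotate so features cross the origin
    code_id: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise SyntheticError("base_probs must sum to 1")
        tiled = sum(e.length + e.ign_after for e in self.template)
        if self.genome_length is None:
            self.genome_length = tiled
        elif self.genome_length != tiled:
            raise SyntheticError(
                f"template tiles {tiled} bp but genome_length is "
                f"{self.genome_length}: untileable")
        for e in self.template:
            if -e.ign_after >= e.length:
                raise SyntheticError(
                    f"{e.name}: overlap {-e.ign_after} exceeds feature length")


@dataclass
class GroundTruth:
    spec: SyntheticSpec
    order: tuple[SignedGene, ...]
    ign: list[tuple[str, str, int]]       # (left, right, signed ign)
    cds: dict[str, str]                   # PCGs, coding orientation, as planted
    start_codons: dict[str, str]
    stop_codons: dict[str, str]           # "TAA"/"TAG" or incomplete "T"/"TA"
    cr_elements: dict[str, dict]          # region -> planted element positions

    @property
    def spacer_bp(self) -> int:
        return sum(g for _, _, g in self.ign if g > 0)

    @property
    def overlap_bp(self) -> int:
        return sum(-g for _, _, g in self.ign if g < 0)


# ---------------------------------------------------------------------------
# Sequence builders
# ---------------------------------------------------------------------------

def _codon_probs(spec: SyntheticSpec) -> tuple[list[str], np.ndarray]:
    codons = list(sense_codons(spec.code_id))
    if spec.codon_profile is not None:
        p = np.array([spec.codon_profile.get(c, 0.0) for c in codons])
        if p.sum() <= 0:
            raise SyntheticError("codon_profile assigns no mass to sense codons")
        return codons, p / p.sum()
    # Excluding the (AT-rich) stop codons from an i.i.d.-base product
    # distribution shifts the realized base composition away from base_probs,
    # so fit adjusted per-base weights whose sense-codon mixture reproduces
    # the target composition.
    target = np.array(spec.base_probs)
    counts = np.array([[c.count(b) / 3.0 for b in BASE_ORDER]
                       for c in codons])
    base_p = target.copy()
    for _ in range(60):
        w = np.array([base_p[BASE_ORDER.index(c[0])]
                      * base_p[BASE_ORDER.index(c[1])]
                      * base_p[BASE_ORDER.index(c[2])] for c in codons])
        w /= w.sum()
        realized = counts.T @ w
        if np.max(np.abs(realized - target)) < 1e-10:
            break
        base_p = base_p * target / realized
        base_p /= base_p.sum()
    w = np.array([base_p[BASE_ORDER.index(c[0])]
                  * base_p[BASE_ORDER.index(c[1])]
                  * base_p[BASE_ORDER.index(c[2])] for c in codons])
    return codons, w / w.sum()


def _random_bases(n: int, probs, rng) -> str:
    return "".join(rng.choice(list(BASE_ORDER), size=n, p=list(probs)))


def _random_pcg(length: int, spec: SyntheticSpec, rng,
                start_codon: str | None) -> tuple[str, str, str]:
    """(cds, start, stop); incomplete stop planted when length % 3 != 0."""
    if length < 6:
        raise SyntheticError("PCG shorter than two codons")
    codons, p = _codon_probs(spec)
    n, r = divmod(length, 3)
    start = start_codon or rng.choice(("ATA", "ATT", "ATG"))
    if r == 0:
        stop = rng.choice(("TAA", "TAG"))
        middle = rng.choice(codons, size=n - 2, p=p)
        cds = start + "".join(middle) + stop
    else:
        stop = "TA"[:r]
        middle = rng.choice(codons, size=n - 1, p=p)
        cds = start + "".join(middle) + stop
    return cds, start, stop


def build_cr(length: int, elements: CRElementSpec, rng) -> tuple[str, dict]:
    """A control-region sequence with the requested elements planted.

    Elements are laid out left to right (polyT at the 5' end, then the
    [TAA]n stretch, TATA, G(A)nT, the stem-loop, and optionally a GA-rich
    tract), separated by C-guards so no element arises by accident earlier
    than its planted position; filler is drawn from {A, C} which can neither
    pair with itself nor spell any T/G-containing motif.
    """
    guard = "CCC"
    parts: list[str] = []
    planted: dict = {}
    pos = 1

    def put(text: str, key: str | None = None, extra: dict | None = None):
        nonlocal pos
        if key is not None:
            planted[key] = {"start": pos, "length": len(text)}
            if extra:
                planted[key].update(extra)
        parts.append(text)
        pos += len(text)

    put("T" * elements.polyt_len, "polyT")
    put(guard)
    put("TAA" * elements.taa_units, "taa_stretch", {"unit": "TAA"})
    put(guard)
    if elements.tata:
        put("TATA", "tata")
        put(guard)
    if elements.gant_n:
        put("G" + "A" * elements.gant_n + "T", "gant")
        put(guard)
    if elements.stem:
        arm = "".join(rng.choice(["G", "T"], size=elements.stem,
                                 p=[0.5, 0.5]))
        if arm.count("G") < 2:          # keep the 3' arm from being A-rich
            arm = "G" + arm[1:-1] + "G"
        hairpin = arm + "C" * elements.loop + reverse_complement(arm)
        put(hairpin, "stem_loop",
            {"stem": elements.stem, "loop": elements.loop})
        put(guard)
    if elements.ga_rich_len:
        tract = "".join(rng.choice(["A", "G"], size=elements.ga_rich_len,
                                   p=[0.8, 0.2]))
        put(tract, "ga_rich")
        put("CCCCC")
    used = sum(len(p) for p in parts)
    if used > length:
        raise SyntheticError(
            f"CR of {length} bp cannot hold the planted elements ({used} bp)")
    pa = elements.filler_a_prob
    put("".join(rng.choice(["A", "C"], size=length - used, p=[pa, 1 - pa])))
    return "".join(parts), planted


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

def generate_genome(spec: SyntheticSpec) -> tuple[MitoAnnotation, GroundTruth]:
    """Assemble a synthetic annotated circular genome from a spec.

    Deterministic for a fixed ``spec.seed``.  The returned annotation has its
    sequence attached; the ground truth records what was planted.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length
    genome = np.array(list(_random_bases(L, spec.base_probs, rng)))

    starts: list[int] = []
    pos = 1
    for e in spec.template:
        starts.append(pos)
        pos += e.length + e.ign_after

    cds: dict[str, str] = {}
    start_codons: dict[str, str] = {}
    stop_codons: dict[str, str] = {}
    cr_planted: dict[str, dict] = {}
    for e, start in zip(spec.template, starts):
        if e.category == "PCG":
            seq, sc, st = _random_pcg(e.length, spec, rng, e.start_codon)
            cds[e.name] = seq
            start_codons[e.name] = sc
            stop_codons[e.name] = st
        elif e.category == "CR" and spec.cr_elements is not None:
            seq, planted = build_cr(e.length, spec.cr_elements, rng)
            cr_planted[e.name] = planted
        else:
            seq = _random_bases(e.length, spec.base_probs, rng)
        if e.strand == "-":
            seq = reverse_complement(seq)
        idx = (np.arange(start - 1, start - 1 + e.length)) % L
        genome[idx] = list(seq)

    offset = spec.origin_offset % L
    features: list[GeneFeature] = []
    for e, start in zip(spec.template, starts):
        s0 = (start - 1 + offset) % L
        e0 = (start - 1 + e.length - 1 + offset) % L
        features.append(GeneFeature(
            name=e.name, category=e.category, strand=e.strand,
            start=s0 + 1, end=e0 + 1, wraps=e0 < s0,
            declared_size=e.length,
            start_codon=start_codons.get(e.name),
            stop_codon=stop_codons.get(e.name)))
    features.sort(key=lambda f: f.start)
    sequence = "".join(np.roll(genome, offset))
    ann = MitoAnnotation(genome_length=L, features=features,
                         sequence=sequence, taxon=f"synthetic_{spec.seed}")

    names = [e.name for e in spec.template]
    truth = GroundTruth(
        spec=spec,
        order=tuple((e.name, -1 if e.strand == "-" else +1)
                    for e in spec.template),
        ign=[(e.name, names[(i + 1) % len(names)], e.ign_after)
             for i, e in enumerate(spec.template)],
        cds=cds, start_codons=start_codons, stop_codons=stop_codons,
        cr_elements=cr_planted)
    return ann, truth


def write_fasta(annotation: MitoAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{annotation.taxon}\n")
        seq = annotation.sequence or ""
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Coding-sequence evolution under a fixed omega
# ---------------------------------------------------------------------------

def random_cds(n_codons: int, seed: int = 0, code_id: int = 5,
               start: str = "ATG") -> str:
    """An in-frame stop-free CDS of ``n_codons`` codons (start included)."""
    rng = np.random.default_rng(seed)
    codons = list(sense_codons(code_id))
    body = rng.choice(codons, size=n_codons - 1)
    return start + "".join(body)


def evolve_cds(cds: str, omega: float, divergence: float, seed: int = 0,
               code_id: int = 5) -> str:
    """Mutate a CDS so that nonsynonymous changes are thinned by omega.

    Single-base proposals (uniform site, uniform alternative base) are
    accepted with probability 1 when synonymous and ``omega`` when
    nonsynonymous; proposals creating a stop codon are always rejected.
    Accepted substitutions are planted until their count reaches
    ``round(divergence * len(cds))``, so the expected substitutions/site
    equals ``divergence`` (multiple hits at one site can occur).  This is an
    acceptance-thinning process, not a full codon model: adequate for coarse
    omega recovery, and documented as such.
    """
    if omega < 0:
        raise SyntheticError("omega must be non-negative")
    if divergence < 0:
        raise SyntheticError("divergence must be non-negative")
    cds = cds.upper()
    if len(cds) % 3:
        raise SyntheticError("CDS length must be a multiple of 3")
    code = genetic_code(code_id)
    seq = list(cds)
    n = len(seq)
    target = round(divergence * n)
    if target == 0:
        return cds
    rng = np.random.default_rng(seed)
    accepted = 0
    attempts = 0
    max_attempts = 1000 * target + 10000
    others = {b: [c for c in BASE_ORDER if c != b] for b in BASE_ORDER}
    while accepted < target:
        attempts += 1
        if attempts > max_attempts:
            raise SyntheticError(
                "evolve_cds failed to reach the target divergence "
                f"(omega={omega}); too few acceptable substitutions")
        i = int(rng.integers(n))
        new = others[seq[i]][int(rng.integers(3))]
        c0 = i - i % 3
        old_codon = "".join(seq[c0:c0 + 3])
        new_codon = old_codon[:i % 3] + new + old_codon[i % 3 + 1:]
        if code.get(new_codon, "*") == "*" or code.get(old_codon, "*") == "*":
            continue
        synonymous = code[new_codon] == code[old_codon]
        if synonymous or rng.random() < omega:
            seq[i] = new
            accepted += 1
    return "".join(seq)


# ---------------------------------------------------------------------------
# Planted rearrangements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transposition:
    block: tuple[str, ...]
    after: str


@dataclass(frozen=True)
class Inversion:
    block: tuple[str, ...]


@dataclass(frozen=True)
class InverseTransposition:
    block: tuple[str, ...]
    after: str


@dataclass(frozen=True)
class TDRL:
    """Tandem duplication of ``block`` then loss of one copy per gene.

    ``keep_first[i]`` keeps gene i from the first (left) copy; the block is
    replaced by the kept genes of copy 1 followed by those of copy 2.
    """

    block: tuple[str, ...]
    keep_first: tuple[bool, ...]


def _locate_block(order: list[SignedGene], block: tuple[str, ...]
                  ) -> tuple[list[SignedGene], int]:
    """Rotate so the block is contiguous and non-wrapping; return start."""
    names = [g for g, _ in order]
    try:
        idx = [names.index(b) for b in block]
    except ValueError as exc:
        raise SyntheticError(f"block gene missing from order: {exc}") from exc
    n = len(order)
    first = idx[0]
    rotated = order[first:] + order[:first]
    rnames = [g for g, _ in rotated]
    if [rnames.index(b) for b in block] != list(range(len(block))):
        raise SyntheticError(f"block {block} is not contiguous in the order")
    return rotated, 0


def apply_rearrangements(order: GeneOrder, ops) -> GeneOrder:
    """Apply rearrangement operations left to right to a signed order."""
    current = list(order.order)
    for op in ops:
        if isinstance(op, Inversion):
            rotated, s = _locate_block(current, op.block)
            k = len(op.block)
            seg = [(g, -sgn) for g, sgn in reversed(rotated[s:s + k])]
            current = rotated[:s] + seg + rotated[s + k:]
        elif isinstance(op, (Transposition, InverseTransposition)):
            rotated, s = _locate_block(current, op.block)
            k = len(op.block)
            if op.after in op.block:
                raise SyntheticError("destination inside the moved block")
            seg = rotated[s:s + k]
            rest = rotated[:s] + rotated[s + k:]
            if isinstance(op, InverseTransposition):
                seg = [(g, -sgn) for g, sgn in reversed(seg)]
            names = [g for g, _ in rest]
            dest = names.index(op.after) + 1
            current = rest[:dest] + seg + rest[dest:]
        elif isinstance(op, TDRL):
            if len(op.keep_first) != len(op.block):
                raise SyntheticError("keep_first length must match block")
            rotated, s = _locate_block(current, op.block)
            k = len(op.block)
            seg = rotated[s:s + k]
            kept = ([g for g, keep in zip(seg, op.keep_first) if keep] +
                    [g for g, keep in zip(seg, op.keep_first) if not keep])
            current = rotated[:s] + kept + rotated[s + k:]
        else:
            raise SyntheticError(f"unknown rearrangement op {op!r}")
    # the circle was rotated while locating blocks; relinearize at the
    # original first gene for readable output
    first = order.order[0][0]
    names = [g for g, _ in current]
    if first in names:
        i = names.index(first)
        current = current[i:] + current[:i]
    return GeneOrder(taxon=order.taxon + "_rearranged",
                     order=tuple(current), anchor=order.anchor)
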