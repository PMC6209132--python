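"""Data model and I/O for circular annotated mitochondrial genomes.

Animal mitogenomes are small circular molecules carrying a nearly fixed gene
complement: 13 protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and one or more
control regions (CRs).  This module holds the annotation as plain data —
1-based inclusive coordinates on the majority strand, with circular wrap
represented explicitly — and provides the coordinate arithmetic and oriented
sequence extraction the downstream analyses rely on.

Coordinates are 1-based inclusive throughout (the convention of published
gene tables); there is no 0-based mode.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

CATEGORIES = ("PCG", "tRNA", "rRNA", "CR")

#: Number of genes (CRs excluded) in a canonical animal mitogenome.
CANONICAL_GENE_COUNT = 37

_LOCATION_RE = re.compile(r"^\s*(\d+)\s*[-–]\s*(\d+)\s*(?:\+\s*(\d+))?\s*$")

_TABLE_COLUMNS = ("name", "category", "strand", "start", "end", "wraps",
                  "anticodon", "declared_size", "start_codon", "stop_codon",
                  "declared_ign")


class AnnotationError(ValueError):
    """Malformed annotation input (bad location, duplicate gene, ...)."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the circular genome.

    ``end < start`` never occurs here: a feature crossing the origin is
    normalized at parse time to ``wraps=True`` with ``end`` giving the
    position after the origin (so CR1 "15020-15333+175" has start=15020,
    end=175, wraps=True).
    """

    name: str
    category: str
    strand: str = "+"
    start: int = 1
    end: int = 1
    wraps: bool = False
    anticodon: str | None = None
    declared_size: int | None = None
    start_codon: str | None = None
    stop_codon: str | None = None
    declared_ign: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise AnnotationError(
                f"{self.name}: unknown category {self.category!r}")
        if self.strand not in "+-":
            raise AnnotationError(f"{self.name}: strand must be '+' or '-'")
        if self.start < 1 or self.end < 1:
            raise AnnotationError(f"{self.name}: coordinates are 1-based")
        if self.anticodon is not None and self.category != "tRNA":
            raise AnnotationError(
                f"{self.name}: anticodon only meaningful for tRNAs")

    def length(self, genome_length: int) -> int:
        return feature_length(self, genome_length)


def feature_length(f: GeneFeature, genome_length: int) -> int:
    """Length in bp of a feature on a circle of ``genome_length``.

    Non-wrapping: ``end - start + 1``; wrapping: the two arcs
    ``(L - start + 1) + end``.
    """
    if f.wraps:
        if f.start > genome_length or f.end > genome_length:
            raise AnnotationError(f"{f.name}: coordinates exceed genome length")
        return (genome_length - f.start + 1) + f.end
    if f.end < f.start:
        raise AnnotationError(
            f"{f.name}: end < start on a non-wrapping feature "
            "(zero- or negative-length)")
    if f.end > genome_length:
        raise AnnotationError(f"{f.name}: coordinates exceed genome length")
    return f.end - f.start + 1


@dataclass
class MitoAnnotation:
    """A circular annotated mitogenome: length, ordered features, sequence."""

    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    sequence: str | None = None
    taxon: str = "genome"

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.genome_length:
                raise AnnotationError(
                    f"sequence length {len(self.sequence)} != genome_length "
                    f"{self.genome_length}")
            bad = set(self.sequence) - set("ACGTN")
            if bad:
                raise AnnotationError(
                    f"sequence contains non-ACGTN symbols: {sorted(bad)}")

    def __iter__(self):
        return iter(self.features)

    def by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def of_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    @property
    def gene_count(self) -> int:
        return sum(1 for f in self.features if f.category != "CR")

    def validate(self) -> dict:
        """Collect (not raise) consistency issues: a validation report."""
        report: dict = {"errors": [], "warnings": [], "size_mismatches": []}
        seen: set[str] = set()
        for f in self.features:
            if f.category != "CR":
                if f.name in seen:
                    report["errors"].append(f"duplicate gene name {f.name}")
                seen.add(f.name)
            try:
                got = feature_length(f, self.genome_length)
            except AnnotationError as exc:
                report["errors"].append(str(exc))
                continue
            if f.declared_size is not None and got != f.declared_size:
                report["size_mismatches"].append(
                    {"name": f.name, "declared": f.declared_size,
                     "computed": got})
        if self.gene_count != CANONICAL_GENE_COUNT:
            report["warnings"].append(
                f"{self.gene_count} genes excluding CRs "
                f"(canonical animal mitogenome has {CANONICAL_GENE_COUNT})")
        wrap_idx = [i for i, f in enumerate(self.features) if f.wraps]
        if wrap_idx and wrap_idx != [len(self.features) - 1]:
            report["warnings"].append(
                "wrap feature is not last in the feature list")
        return report


@dataclass(frozen=True)
class PartitionSelector:
    """Selects a genome partition: whole, a category, or single:<gene>."""

    label: str

    def resolve(self, annotation: MitoAnnotation) -> list[GeneFeature]:
        if self.label == "whole":
            return list(annotation.features)
        if self.label in CATEGORIES:
            members = annotation.of_category(self.label)
            if not members:
                raise AnnotationError(
                    f"partition {self.label!r} is empty for "
                    f"{annotation.taxon}")
            return members
        if self.label.startswith("single:"):
            name = self.label.split(":", 1)[1]
            try:
                return [annotation.by_name(name)]
            except KeyError:
                raise AnnotationError(
                    f"partition {self.label!r}: no such gene") from None
        raise AnnotationError(f"unresolvable partition label {self.label!r}")


# ---------------------------------------------------------------------------
# Parsing the tabular gene-table representation
# ---------------------------------------------------------------------------

def parse_location(text: str, row_name: str = "?") -> tuple[int, int, bool]:
    """Parse "start-end" (en dash accepted) with optional "+N" wrap suffix.

    Returns (start, end, wraps); for a wrap, end is the post-origin arm N.
    """
    m = _LOCATION_RE.match(str(text))
    if not m:
        raise AnnotationError(f"row {row_name}: malformed location {text!r}")
    start, end = int(m.group(1)), int(m.group(2))
    if m.group(3) is not None:
        return start, int(m.group(3)), True
    return start, end, False


def _infer_category(name: str) -> str:
    low = name.lower()
    if low.startswith("trn"):
        return "tRNA"
    if low.startswith("rrn"):
        return "rRNA"
    if low.startswith("cr") or "control" in low:
        return "CR"
    return "PCG"


def _opt(value, cast=str):
    if value is None:
        return None
    text = str(value).strip()
    if text in ("", ".", "nan", "None"):
        return None
    if cast is int:
        return int(float(text))     # tolerate pandas' float-ified columns
    return cast(text)


def parse_feature_table(rows: Iterable[Mapping] | pd.DataFrame,
                        genome_length: int | None = None,
                        sequence: str | None = None,
                        taxon: str = "genome") -> MitoAnnotation:
    """Build a :class:`MitoAnnotation` from tabular records.

    Each row needs ``name`` and either a ``location`` string or explicit
    ``start``/``end``; ``category``, ``strand``, ``size``, ``anticodon``,
    ``start_codon``, ``stop_codon`` and ``ign`` are optional.  Declared sizes
    are kept and cross-checked by :meth:`MitoAnnotation.validate`, never
    silently dropped.
    """
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict("records")
    features: list[GeneFeature] = []
    max_end = 0
    for row in rows:
        name = _opt(row.get("name") or row.get("gene"))
        if not name:
            raise AnnotationError(f"row without a gene name: {dict(row)!r}")
        if "location" in row and _opt(row.get("location")) is not None:
            start, end, wraps = parse_location(row["location"], name)
        else:
            try:
                start, end = int(row["start"]), int(row["end"])
            except (KeyError, TypeError, ValueError):
                raise AnnotationError(
                    f"row {name}: needs location or start/end") from None
            raw_wraps = row.get("wraps", False)
            if isinstance(raw_wraps, str):
                raw_wraps = raw_wraps.strip().lower() in ("true", "1", "yes")
            wraps = bool(raw_wraps) or end < start
        category = _opt(row.get("category")) or _infer_category(name)
        features.append(GeneFeature(
            name=name,
            category=category,
            strand=_opt(row.get("strand")) or "+",
            start=start,
            end=end,
            wraps=wraps,
            anticodon=_opt(row.get("anticodon")),
            declared_size=_opt(row.get("size") or row.get("declared_size"),
                               int),
            start_codon=_opt(row.get("start_codon")),
            stop_codon=_opt(row.get("stop_codon")),
            declared_ign=_opt(row.get("ign") or row.get("declared_ign"), int),
        ))
        max_end = max(max_end, start, 0 if wraps else end)
    if genome_length is None:
        if sequence is not None:
            genome_length = len(sequence)
        else:
            genome_length = max_end
    names = [f.name for f in features if f.category != "CR"]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise AnnotationError(f"duplicate non-CR gene names: {sorted(dupes)}")
    features.sort(key=lambda f: f.start)
    ann = MitoAnnotation(genome_length=genome_length, features=features,
                         sequence=sequence, taxon=taxon)
    return ann


def load_gene_table(path: str | Path, genome_length: int | None = None,
                    sequence: str | None = None,
                    taxon: str | None = None) -> MitoAnnotation:
    """Read a '#'-commented TSV gene table (see data/thrips_palmi_genes.tsv)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return parse_feature_table(
        df, genome_length=genome_length, sequence=sequence,
        taxon=taxon or Path(path).stem)


def to_table(annotation: MitoAnnotation) -> pd.DataFrame:
    """Normalized tabular form; round-trips through parse_feature_table."""
    rows = []
    for f in annotation.features:
        rows.append({
            "name": f.name, "category": f.category, "strand": f.strand,
            "start": f.start, "end": f.end, "wraps": f.wraps,
            "anticodon": f.anticodon, "declared_size": f.declared_size,
            "start_codon": f.start_codon, "stop_codon": f.stop_codon,
            "declared_ign": f.declared_ign,
        })
    return pd.DataFrame(rows, columns=list(_TABLE_COLUMNS))


def write_gene_table(annotation: MitoAnnotation, path: str | Path) -> None:
    df = to_table(annotation)
    with open(path, "w") as fh:
        fh.write(f"# taxon={annotation.taxon} "
                 f"genome_length={annotation.genome_length}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_normalized_table(path: str | Path) -> MitoAnnotation:
    genome_length = None
    taxon = "genome"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            key, _, val = token.partition("=")
            if key == "genome_length":
                genome_length = int(val)
            elif key == "taxon":
                taxon = val
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"name": str, "category": str, "strand": str,
                            "anticodon": str, "start_codon": str,
                            "stop_codon": str})
    return parse_feature_table(df, genome_length=genome_length, taxon=taxon)


# ---------------------------------------------------------------------------
# GenBank flat files
# ---------------------------------------------------------------------------

def load_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Alias -> canonical symbol table (upper-cased aliases)."""
    if path is None:
        ref = resources.files("mitocmp.data") / "gene_synonyms.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("alias\t"):
            continue
        alias, canonical = line.split("\t")
        table[alias.strip().upper()] = canonical.strip()
    return table


_TRNA_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _canonical_name(raw: str, synonyms: dict[str, str]) -> str:
    key = raw.strip().upper()
    if key in synonyms:
        return synonyms[key]
    m = re.match(r"^TRN([A-Z])[12]?$", key)
    if m:
        return "trn" + m.group(1) + key[4:] if len(key) > 4 else "trn" + m.group(1)
    m = re.match(r"^TRNA-([A-Z]{3})[ _]?([12])?$", key)
    if m and m.group(1) in _TRNA_AA3:
        return "trn" + _TRNA_AA3[m.group(1)] + (m.group(2) or "")
    return raw.strip()


def read_genbank(source, synonyms: dict[str, str] | None = None,
                 assume_circular: bool = False) -> MitoAnnotation:
    """Read an annotated GenBank flat file into a :class:`MitoAnnotation`.

    Feature names are mapped to canonical symbols through the (editable)
    synonym table; ``join(...)`` locations spanning the origin become a single
    wrap feature; the record sequence is attached.
    """
    if isinstance(source, (str, Path)):
        record = SeqIO.read(str(source), "genbank")
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        record = SeqIO.read(source, "genbank")
    else:
        record = source
    if synonyms is None:
        synonyms = load_synonyms()
    topology = (record.annotations or {}).get("topology", "")
    if topology != "circular" and not assume_circular:
        warnings.warn(
            f"record {record.id}: topology is {topology or 'unspecified'!r}, "
            "treating as circular anyway (pass assume_circular=True to "
            "silence)", stacklevel=2)
    L = len(record.seq)
    kind_map = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                "misc_feature": "CR", "D-loop": "CR"}
    features: list[GeneFeature] = []
    cr_seen = 0
    for feat in record.features:
        if feat.type not in kind_map:
            continue
        category = kind_map[feat.type]
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product")
               or quals.get("note") or ["?"])[0]
        name = _canonical_name(raw, synonyms)
        if category == "CR":
            if not name.upper().startswith("CR"):
                cr_seen += 1
                name = f"CR{cr_seen}"
        loc = feat.location
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        start = int(parts[0].start) + 1
        end = int(parts[-1].end)
        wraps = False
        if len(parts) > 1 and int(parts[0].start) == 0 and end == L:
            # join(x..L, 1..y): a single feature across the origin
            start = int(parts[1].start) + 1
            end = int(parts[0].end)
            wraps = True
        strand = "-" if loc.strand == -1 else "+"
        features.append(GeneFeature(
            name=name, category=category, strand=strand,
            start=start, end=end, wraps=wraps,
            anticodon=_opt((quals.get("anticodon") or [None])[0])
            if category == "tRNA" else None))
    if not features:
        warnings.warn(f"record {record.id}: no annotated features found",
                      stacklevel=2)
    features.sort(key=lambda f: f.start)
    return MitoAnnotation(genome_length=L, features=features,
                          sequence=str(record.seq).upper(),
                          taxon=record.id or "genome")


# ---------------------------------------------------------------------------
# Sequence access
# ---------------------------------------------------------------------------

def extract_span(annotation: MitoAnnotation, f: GeneFeature) -> str:
    """Majority-strand span of a feature (no reverse complement)."""
    if annotation.sequence is None:
        raise AnnotationError(
            f"{f.name}: sequence required but absent from annotation")
    L = annotation.genome_length
    n = feature_length(f, L)
    doubled = annotation.sequence + annotation.sequence
    return doubled[f.start - 1:f.start - 1 + n]


def extract_sequence(annotation: MitoAnnotation, f: GeneFeature) -> str:
    """Feature sequence in coding orientation (revcomp for minority strand)."""
    span = extract_span(annotation, f)
    return reverse_complement(span) if f.strand == "-" else span


def read_fasta_sequence(path: str | Path) -> str:
    record = SeqIO.read(str(path), "fasta")
    return str(record.seq).upper()


# ---------------------------------------------------------------------------
# Bundled reference fixture
# ---------------------------------------------------------------------------

def thrips_palmi_table() -> MitoAnnotation:
    """The published T. palmi gene table (39 features, 15,333 bp circle)."""
    ref = resources.files("mitocmp.data") / "thrips_palmi_genes.tsv"
    with resources.as_file(ref) as path:
        return load_gene_table(path, genome_length=15333, taxon="T_palmi")
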