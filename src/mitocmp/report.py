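"""Profile one or more annotated mitogenomes and emit comparison tables.

``run_profile`` runs every analysis stage that its inputs support — the
composition/skew matrix, codon usage and RSCU, the IGN ledger, the gene
order, control-region annotation — then the cross-genome comparisons
(composition matrix, missing-codon comparison, per-gene Ka/Ks for
equal-length coding sequences, pairwise order comparisons against a
reference).  Tables are written as TSV with floats at 2 decimal places;
the JSON bundle keeps full precision.  A stage failing for one genome is
recorded and the remaining genomes proceed.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import codons as cod
from . import composition as comp
from . import control_region as cr
from . import gene_order as go
from . import kaks as kk
from . import spacers as sp
from .annotation import MitoAnnotation, extract_sequence, to_table

log = logging.getLogger("mitocmp")

DEFAULT_PARTITIONS = ("whole", "PCG", "tRNA", "rRNA", "CR")


@dataclass
class RunConfig:
    inputs: list[MitoAnnotation]
    output_dir: str | Path = "mitocmp_out"
    partitions: tuple[str, ...] = DEFAULT_PARTITIONS
    major_spacer_threshold: int = 10
    cr_params: cr.CRParams = field(default_factory=cr.CRParams)
    code_id: int = 5
    exclude_stops: bool = True
    reference_order: go.GeneOrder | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValueError("at least one input genome is required")
        for label in self.partitions:
            if label not in DEFAULT_PARTITIONS and \
                    not label.startswith("single:"):
                raise ValueError(f"unknown partition label {label!r}")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")


def _cr_annotation_json(ann: MitoAnnotation, params: cr.CRParams) -> dict:
    out = {}
    for f in ann.of_category("CR"):
        seq = extract_sequence(ann, f)
        a = cr.annotate_cr(seq, params, region=f.name)
        out[f.name] = {
            "length": a.length, "polyT": a.polyT,
            "taa_stretch": a.taa_stretch, "tata_motif": a.tata_motif,
            "gant_motif": a.gant_motif, "ga_rich": a.ga_rich,
            "stem_loop": (None if a.stem_loop is None else
                          {"stem": a.stem_loop.stem, "loop": a.stem_loop.loop,
                           "five_prime_start": a.stem_loop.five_prime_start}),
            "elements_found": a.elements_found,
        }
    return out


def _profile_one(ann: MitoAnnotation, config: RunConfig, outdir: Path) -> dict:
    result: dict = {"taxon": ann.taxon}
    log.info("stage=validate taxon=%s", ann.taxon)
    result["validation"] = ann.validate()

    ledger = sp.ign_ledger(ann)
    summary = sp.summarize_ledger(ledger, config.major_spacer_threshold)
    log.info("stage=ign taxon=%s spacers=%d overlaps=%d", ann.taxon,
             summary.n_spacers, summary.n_overlaps)
    _write_tsv(ledger.as_table(), outdir / f"{ann.taxon}.ign.tsv")
    result["ign_summary"] = {
        "n_spacers": summary.n_spacers, "spacer_bp": summary.spacer_bp,
        "n_overlaps": summary.n_overlaps, "overlap_bp": summary.overlap_bp,
        "n_major_spacers": summary.n_major_spacers,
        "major_threshold": summary.major_threshold,
        "longest_spacer": (summary.longest_spacer.left,
                           summary.longest_spacer.right,
                           summary.longest_spacer.ign)
        if summary.longest_spacer else None,
        "largest_overlap": (summary.largest_overlap.left,
                            summary.largest_overlap.right,
                            summary.largest_overlap.ign)
        if summary.largest_overlap else None,
        "tiling": sp.tiling_identity(ledger),
    }

    order = go.order_from_annotation(ann)
    result["gene_order"] = order.linearized()
    go.write_order_tsv([order], outdir / f"{ann.taxon}.order.tsv")
    _write_tsv(to_table(ann), outdir / f"{ann.taxon}.annotation.tsv")

    if ann.sequence is not None:
        log.info("stage=composition taxon=%s", ann.taxon)
        table = comp.composition_table(ann, config.partitions)
        _write_tsv(table, outdir / f"{ann.taxon}.composition.tsv")
        result["composition"] = table.to_dict("records")

        log.info("stage=codons taxon=%s code=%d", ann.taxon, config.code_id)
        genes = {f.name: extract_sequence(ann, f)
                 for f in ann.of_category("PCG")}
        if genes:
            usage = cod.codon_counts(genes, config.exclude_stops,
                                     config.code_id)
            _write_tsv(cod.rscu_table(usage),
                       outdir / f"{ann.taxon}.rscu.tsv")
            result["n_codons"] = usage.n_codons
            result["missing_codons"] = sorted(cod.missing_codons(usage))
            result["start_stop"] = {
                name: {"start": (rep := cod.detect_start_stop(s, name)
                                 ).start_codon,
                       "stop": rep.stop_codon,
                       "incomplete": rep.incomplete_stop}
                for name, s in genes.items()}

        if ann.of_category("CR"):
            log.info("stage=control_region taxon=%s", ann.taxon)
            result["control_regions"] = _cr_annotation_json(
                ann, config.cr_params)
    return result


def _cross_genome(anns: list[MitoAnnotation], config: RunConfig,
                  outdir: Path, bundle: dict) -> None:
    with_seq = [a for a in anns if a.sequence is not None]
    table = comp.composition_table(with_seq, config.partitions)
    if not table.empty:
        _write_tsv(table, outdir / "composition_matrix.tsv")

    results = []
    for a, b in itertools.combinations(with_seq, 2):
        genes_a = {f.name: extract_sequence(a, f)
                   for f in a.of_category("PCG")}
        genes_b = {f.name: extract_sequence(b, f)
                   for f in b.of_category("PCG")}
        for gene in sorted(set(genes_a) & set(genes_b)):
            if len(genes_a[gene]) != len(genes_b[gene]):
                log.warning("stage=kaks gene=%s pair=%s/%s skipped "
                            "(unaligned lengths)", gene, a.taxon, b.taxon)
                continue
            # drop any incomplete-stop remainder to stay on codon boundaries
            usable = len(genes_a[gene]) - len(genes_a[gene]) % 3
            results.append(kk.pairwise_kaks(
                genes_a[gene][:usable], genes_b[gene][:usable],
                config.code_id, gene=gene, pair=(a.taxon, b.taxon)))
    if results:
        _write_tsv(kk.kaks_long_table(results), outdir / "kaks.tsv")
        ranking = kk.rank_genes_by_kaks(results)
        _write_tsv(ranking, outdir / "kaks_ranking.tsv")
        bundle["kaks_ranking"] = ranking.to_dict("records")

    reference = config.reference_order
    comparisons = {}
    for ann in anns:
        ref = reference or (go.order_from_annotation(anns[0])
                            if ann is not anns[0] else None)
        if ref is None:
            continue
        order = go.order_from_annotation(ann)
        try:
            res = go.compare_orders(order, ref)
        except go.GeneOrderError as exc:
            log.warning("stage=order taxon=%s error=%s", ann.taxon, exc)
            continue
        comparisons[ann.taxon] = {
            "reference": res.reference, "breakpoints": res.breakpoints,
            "per_gene": res.per_gene,
            "shared_blocks": [[go.format_signed(g) for g in block]
                              for block in res.shared_blocks],
        }
    if comparisons:
        bundle["order_comparisons"] = comparisons


def run_profile(config: RunConfig) -> dict:
    """Run the whole pipeline; returns (and writes) the report bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run start: %d genome(s), partitions=%s, major_spacer>%d",
             len(config.inputs), ",".join(config.partitions),
             config.major_spacer_threshold)
    bundle: dict = {"genomes": [], "errors": {}}
    for ann in config.inputs:
        try:
            bundle["genomes"].append(_profile_one(ann, config, outdir))
        except Exception as exc:      # keep the other genomes going
            log.error("taxon=%s failed: %s", ann.taxon, exc)
            bundle["errors"][ann.taxon] = str(exc)
    try:
        _cross_genome(config.inputs, config, outdir, bundle)
    except Exception as exc:
        log.error("cross-genome stage failed: %s", exc)
        bundle["errors"]["cross_genome"] = str(exc)
    with open(outdir / "bundle.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=str)
    return bundle
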