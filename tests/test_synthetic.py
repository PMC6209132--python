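"""Synthetic genome generator: determinism, ground truth, rearrangements."""

import numpy as np
import pytest

import mitocmp as m
from mitocmp.synthetic import SyntheticError, _codon_probs


class TestGenerateGenome:
    def test_deterministic_for_fixed_seed(self):
        a1, _ = m.generate_genome(m.SyntheticSpec(seed=9))
        a2, _ = m.generate_genome(m.SyntheticSpec(seed=9))
        assert a1.sequence == a2.sequence
        assert a1.features == a2.features

    def test_different_seeds_differ(self):
        a1, _ = m.generate_genome(m.SyntheticSpec(seed=9))
        a2, _ = m.generate_genome(m.SyntheticSpec(seed=10))
        assert a1.sequence != a2.sequence

    def test_template_tiles_exactly(self, synthetic_genome):
        ann, truth = synthetic_genome
        assert ann.genome_length == 15333
        ledger = m.ign_ledger(ann)
        assert m.tiling_identity(ledger) == 15333

    def test_planted_ign_ledger_reproduced(self, synthetic_genome):
        ann, truth = synthetic_genome
        ledger = m.ign_ledger(ann)
        got = {(e.left, e.right): e.ign for e in ledger.entries}
        for left, right, ign in truth.ign:
            assert got[(left, right)] == ign

    def test_planted_order_reproduced(self, synthetic_genome):
        ann, truth = synthetic_genome
        order = m.order_from_annotation(ann, include_crs=True)
        # rotate the planted order to the first annotated feature
        names = [g for g, _ in truth.order]
        i = names.index(order.order[0][0])
        assert order.order == truth.order[i:] + truth.order[:i]

    def test_base_composition_near_target(self):
        """A+T lands within binomial tolerance of the configured 79%."""
        ann, _ = m.generate_genome(m.SyntheticSpec(seed=1))
        comp = m.partition_composition(ann, "whole")
        assert comp.pct_AT == pytest.approx(79.0, abs=1.5)

    def test_origin_offset_produces_wrap_feature(self):
        ann, _ = m.generate_genome(m.SyntheticSpec(seed=2,
                                                   origin_offset=175))
        wrap = [f for f in ann.features if f.wraps]
        assert len(wrap) == 1 and wrap[0].name == "CR1"
        assert m.feature_length(wrap[0], ann.genome_length) == 489

    def test_start_codons_planted(self, synthetic_genome):
        # a gene's positional-end junction is rewritten by an overlapping
        # next feature: that junction holds the start codon of a minority-
        # strand gene and the stop codon of a majority-strand one
        ann, truth = synthetic_genome
        ledger = m.ign_ledger(ann)
        clear_tail = {e.left for e in ledger.entries if e.ign >= 0}
        checked = 0
        for f in ann.of_category("PCG"):
            if f.strand == "-" and f.name not in clear_tail:
                continue
            cds = m.extract_sequence(ann, f)
            assert cds[:3] == truth.start_codons[f.name], f.name
            checked += 1
        assert checked >= 12
        assert truth.start_codons["cox1"] == "TTG"

    def test_stop_codons_on_non_overlapped_genes(self, synthetic_genome):
        ann, truth = synthetic_genome
        ledger = m.ign_ledger(ann)
        clear_tail = {e.left for e in ledger.entries if e.ign >= 0}
        checked = 0
        for f in ann.of_category("PCG"):
            if f.strand == "+" and f.name not in clear_tail:
                continue
            cds = m.extract_sequence(ann, f)
            rep = m.detect_start_stop(cds, f.name)
            assert rep.stop_codon == truth.stop_codons[f.name], f.name
            checked += 1
        assert checked >= 8

    def test_incomplete_stop_planted_for_atp8_slot(self, synthetic_genome):
        _, truth = synthetic_genome
        assert truth.stop_codons["atp8"] == "T"      # 169 bp = 56 codons + 1

    def test_untileable_template_rejected_before_generation(self):
        with pytest.raises(SyntheticError, match="untileable"):
            m.SyntheticSpec(template=m.uniform_template(4), genome_length=17)

    def test_codon_sampler_matches_target_composition(self):
        codons, p = _codon_probs(m.SyntheticSpec(seed=0))
        freq = {b: 0.0 for b in "ACGT"}
        for c, w in zip(codons, p):
            for b in c:
                freq[b] += w / 3
        for b, target in zip("ACGT", (0.43, 0.11, 0.10, 0.36)):
            assert freq[b] == pytest.approx(target, abs=1e-6)

    def test_tiling_identity_holds_across_random_genomes(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            n = int(rng.integers(4, 12))
            template = tuple(
                m.TemplateEntry(name=f"g{i}", category="PCG", strand="+",
                                length=int(rng.integers(2, 60)) * 3,
                                ign_after=int(rng.integers(-10, 40)))
                for i in range(n))
            try:
                spec = m.SyntheticSpec(template=template, cr_elements=None,
                                       seed=int(rng.integers(2 ** 31)))
            except SyntheticError:
                continue                      # overlap larger than feature
            ann, _ = m.generate_genome(spec)
            assert m.tiling_identity(m.ign_ledger(ann)) == ann.genome_length


class TestEvolveCds:
    def test_divergence_zero_identity(self):
        cds = m.random_cds(100, seed=1)
        assert m.evolve_cds(cds, omega=0.5, divergence=0.0, seed=2) == cds

    def test_omega_zero_only_synonymous(self):
        """With omega 0 every planted event is synonymous, so the two
        sequences translate identically."""
        code = m.genetic_code(5)
        cds = m.random_cds(2000, seed=5)
        out = m.evolve_cds(cds, omega=0.0, divergence=0.08, seed=6)
        for i in range(0, len(cds), 3):
            assert code[cds[i:i + 3]] == code[out[i:i + 3]]

    def test_negative_omega_rejected(self):
        with pytest.raises(SyntheticError):
            m.evolve_cds("ATGGCA", omega=-0.1, divergence=0.1)

    def test_divergence_scale(self):
        cds = m.random_cds(3000, seed=8)
        out = m.evolve_cds(cds, omega=1.0, divergence=0.05, seed=9)
        diffs = sum(a != b for a, b in zip(cds, out))
        # multiple hits can coincide, so observed <= planted events
        assert 0.035 * len(cds) <= diffs <= 0.05 * len(cds)


class TestRearrangements:
    def test_identity_ops(self, ancestor):
        assert m.apply_rearrangements(ancestor, []).order == ancestor.order

    def test_block_transposition(self):
        o = m.GeneOrder(taxon="t", order=(("a", 1), ("b", 1), ("c", 1),
                                          ("d", 1), ("e", 1)))
        res = m.apply_rearrangements(o, [m.Transposition(block=("b", "c"),
                                                         after="e")])
        assert [g for g, _ in res.order] == ["a", "d", "e", "b", "c"]

    def test_inversion_flips_and_reverses(self):
        o = m.GeneOrder(taxon="t", order=(("a", 1), ("b", 1), ("c", 1),
                                          ("d", 1)))
        res = m.apply_rearrangements(o, [m.Inversion(block=("b", "c"))])
        assert res.order == (("a", 1), ("c", -1), ("b", -1), ("d", 1))

    def test_tdrl_keep_pattern_hand_computed(self):
        # duplicate a-b-c-d; keep a,c from copy 1 and b,d from copy 2:
        # a b c d -> (a b c d)(a b c d) -> a c b d
        o = m.GeneOrder(taxon="t", order=(("a", 1), ("b", 1), ("c", 1),
                                          ("d", 1), ("e", 1)))
        res = m.apply_rearrangements(
            o, [m.TDRL(block=("a", "b", "c", "d"),
                       keep_first=(True, False, True, False))])
        assert [g for g, _ in res.order] == ["a", "c", "b", "d", "e"]

    def test_non_contiguous_block_rejected(self):
        o = m.GeneOrder(taxon="t", order=(("a", 1), ("b", 1), ("c", 1)))
        with pytest.raises(SyntheticError, match="contiguous"):
            m.apply_rearrangements(o, [m.Inversion(block=("a", "c"))])

    def test_missing_gene_rejected(self, ancestor):
        with pytest.raises(SyntheticError):
            m.apply_rearrangements(ancestor,
                                   [m.Inversion(block=("nope",))])
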