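"""Nei-Gojobori Ka/Ks against independent brute-force oracles."""

import math
from itertools import permutations, product

import pytest
from Bio.Seq import Seq

import mitocmp as m
from mitocmp.kaks import KaKsError

BASES = "ACGT"


# ---------------------------------------------------------------------------
# Independent oracles (Biopython translation, direct enumeration)
# ---------------------------------------------------------------------------

def _aa(codon):
    return str(Seq(codon).translate(table=5))


def oracle_sites(codon):
    """Enumerate all 9 single-base changes directly."""
    s = 0.0
    for pos in range(3):
        outcomes = []
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if _aa(mut) == "*":
                continue
            outcomes.append(_aa(mut) == _aa(codon))
        if outcomes:
            s += sum(outcomes) / len(outcomes)
    return s, 3.0 - s


def oracle_differences(c1, c2):
    """Average syn/nonsyn steps over all orders of the differing positions,
    dropping orders that visit a stop codon (all orders if none survive)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _aa(nxt) == "*":
                blocked = True
            if _aa(nxt) == _aa(cur) and _aa(nxt) != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    keep = [p for p in paths if not p[2]] or paths
    return (sum(p[0] for p in keep) / len(keep),
            sum(p[1] for p in keep) / len(keep))


SENSE = [c for c in ("".join(p) for p in product(BASES, repeat=3))
         if _aa(c) != "*"]


class TestSites:
    def test_gly_third_position_fully_synonymous(self):
        assert m.ng_sites("GGA") == (1.0, 2.0)

    def test_phe_one_third(self):
        s, n = m.ng_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(KaKsError):
            m.ng_sites("TAA")

    def test_all_sense_codons_match_oracle(self):
        for codon in SENSE:
            got = m.ng_sites(codon)
            want = oracle_sites(codon)
            assert got[0] == pytest.approx(want[0], abs=1e-12), codon
            assert got[0] + got[1] == pytest.approx(3.0)

    def test_gene_sites_invariant_under_codon_order(self, rng):
        codons = list(rng.choice(SENSE, size=60))
        total = sum(m.ng_sites(c)[0] for c in codons)
        rng.shuffle(codons)
        assert sum(m.ng_sites(c)[0] for c in codons) == pytest.approx(total)


class TestDifferences:
    def test_all_sense_codon_pairs_match_oracle(self):
        """Pathway-averaged differences agree with the enumerator on every
        sense-codon pair under the invertebrate mitochondrial code."""
        for c1 in SENSE:
            for c2 in SENSE:
                got = m.ng_differences(c1, c2)
                want = oracle_differences(c1, c2)
                assert got == pytest.approx(want, abs=1e-12), (c1, c2)


class TestPairwise:
    def test_identical_sequences(self):
        cds = "ATGGCATTACGT"
        res = m.pairwise_kaks(cds, cds)
        assert res.Sd == res.Nd == 0.0
        assert res.Ka == res.Ks == 0.0

    def test_single_synonymous_change_matches_oracle(self):
        s1 = "ATG" + "GGA" * 8          # 9 codons
        s2 = "ATG" + "GGA" * 7 + "GGT"  # one synonymous 3rd-position change
        res = m.pairwise_kaks(s1, s2)
        S = sum(oracle_sites(c)[0] for c in [s1[i:i + 3]
                                             for i in range(0, 27, 3)])
        S2 = sum(oracle_sites(c)[0] for c in [s2[i:i + 3]
                                              for i in range(0, 27, 3)])
        pS = 1.0 / ((S + S2) / 2)
        assert res.Ka == 0.0
        assert res.Ks == pytest.approx(-0.75 * math.log(1 - 4 * pS / 3))

    def test_symmetry(self, rng):
        c1 = "".join(rng.choice(SENSE, size=50))
        c2 = "".join(rng.choice(SENSE, size=50))
        a = m.pairwise_kaks(c1, c2)
        b = m.pairwise_kaks(c2, c1)
        for attr in ("S", "N", "Sd", "Nd", "pS", "pN", "Ks", "Ka"):
            x, y = getattr(a, attr), getattr(b, attr)
            assert x == pytest.approx(y, abs=1e-12)

    def test_gap_and_n_codons_dropped_pairwise(self):
        res = m.pairwise_kaks("ATGGGANNNTTA", "ATGGGTCCC---")
        assert res.codons == 2            # ATG/ATG and GGA/GGT survive

    def test_only_synonymous_single_changes_gives_exact_ka_zero(self):
        """Planting one synonymous change per codon leaves Ka exactly 0."""
        base = ["GGA", "CCT", "TCA", "GTT", "CGA"] * 10
        mutated = []
        code = m.genetic_code(5)
        for i, c in enumerate(base):
            if i % 3 == 0:
                for b in BASES:
                    alt = c[:2] + b
                    if alt != c and code[alt] == code[c]:
                        mutated.append(alt)
                        break
                else:
                    mutated.append(c)
            else:
                mutated.append(c)
        res = m.pairwise_kaks("".join(base), "".join(mutated))
        assert res.Nd == 0.0 and res.Ka == 0.0 and res.Ks > 0

    def test_saturated_reported_missing(self):
        # maximally different codons at every position push pN toward 3/4
        s1 = "GGA" * 40
        s2 = "CCT" * 40
        res = m.pairwise_kaks(s1, s2)
        assert res.saturated
        assert res.ratio is None

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(KaKsError):
            m.pairwise_kaks("ATGGGA", "ATG")


class TestOmegaRecovery:
    def test_omega_recovered_from_simulation(self):
        """A pair evolved at omega=0.2 (10,000 codons) is estimated within
        +/-0.05 by the Nei-Gojobori ratio."""
        cds = m.random_cds(10000, seed=3)
        evolved = m.evolve_cds(cds, omega=0.2, divergence=0.1, seed=7)
        res = m.pairwise_kaks(cds, evolved)
        assert res.ratio == pytest.approx(0.2, abs=0.05)


class TestRanking:
    def _res(self, gene, ka, ks):
        return m.KaKsResult(gene=gene, pair=("a", "b"), codons=10, S=20,
                            N=40, Sd=1, Nd=1, pS=0.05, pN=0.025, Ks=ks,
                            Ka=ka, saturated=False)

    def test_ascending_order(self):
        df = m.rank_genes_by_kaks([self._res("b", 0.9, 1.0),
                                   self._res("a", 0.1, 1.0)])
        assert list(df["gene"]) == ["a", "b"]

    def test_classification(self):
        df = m.rank_genes_by_kaks([self._res("atp8", 1.7, 1.0),
                                   self._res("cox1", 0.078, 1.0),
                                   self._res("x", 1.0, 1.0)])
        by = df.set_index("gene")["selection"]
        assert by["atp8"] == "positive"
        assert by["cox1"] == "purifying"
        assert by["x"] == "neutral"

    def test_equal_means_keep_input_order(self):
        df = m.rank_genes_by_kaks([self._res(g, 0.5, 1.0)
                                   for g in ("z", "m", "a")])
        assert list(df["gene"]) == ["z", "m", "a"]

    def test_undefined_gene_excluded_with_warning(self):
        res = m.KaKsResult(gene="dead", pair=("a", "b"), codons=5, S=10,
                           N=20, Sd=0, Nd=0, pS=0, pN=0, Ks=0.0, Ka=0.0,
                           saturated=False)
        with pytest.warns(UserWarning, match="dead"):
            df = m.rank_genes_by_kaks([res, self._res("ok", 0.5, 1.0)])
        assert list(df["gene"]) == ["ok"]


class TestTsTv:
    def test_identical(self):
        p = m.ts_tv_saturation("ACGT", "ACGT")
        assert (p.transitions, p.transversions, p.distance) == (0, 0, 0.0)

    def test_single_transition(self):
        p = m.ts_tv_saturation("AG", "GG")
        assert (p.transitions, p.transversions) == (1, 0)
        assert p.distance == 0.5
        assert p.ts_tv_ratio is None

    def test_against_per_column_oracle(self, rng):
        s1 = "".join(rng.choice(list(BASES), size=1000))
        s2 = "".join(rng.choice(list(BASES), size=1000))
        p = m.ts_tv_saturation(s1, s2)
        ts = tv = 0
        for a, b in zip(s1, s2):
            if a == b:
                continue
            if {a, b} in ({"A", "G"}, {"C", "T"}):
                ts += 1
            else:
                tv += 1
        assert (p.transitions, p.transversions) == (ts, tv)
        assert p.transitions + p.transversions == \
            round(p.distance * p.compared)

    def test_gaps_and_n_skipped(self):
        p = m.ts_tv_saturation("AC-GN", "ACTGA")
        assert p.compared == 3

    def test_no_columns_is_error(self):
        with pytest.raises(KaKsError):
            m.ts_tv_saturation("NNN", "NNN")
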